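"""Gene filtering applied before unsupervised deconvolution.

Three steps, in the fixed order the pipeline uses them:

1. probe collapse — one probe per gene, keeping the probe with the
   highest variance across samples (unmapped probes dropped);
2. expression-norm percentile filter — drop genes whose raw-profile
   Euclidean norm falls in the lowest ``low_norm_pct`` % (noise) or the
   highest ``high_norm_pct`` % (outliers);
3. coefficient-of-variation filter — keep genes with sd/mean >= cv_min.

All statistics are computed on the raw linear profiles; sd uses the
unbiased (p - 1) denominator and percentiles interpolate linearly
between closest ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, ValidationError

__all__ = ["FilterSpec", "collapse_probes", "filter_by_norm", "filter_by_cv", "apply_filters"]


@dataclass(frozen=True)
class FilterSpec:
    """Cutoffs for the norm/CV filters.

    ``low_norm_pct``/``high_norm_pct`` are percentages of genes trimmed at
    the low/high end of the expression-norm distribution; ``cv_min`` is an
    optional lower bound on the coefficient of variation.  The named
    presets: "default" = (5, 5, no CV), "mdl" = (5, 5, CV >= 0.4) — the
    latter because highly variable genes sharpen the model-order score.
    """

    low_norm_pct: float = 5.0
    high_norm_pct: float = 5.0
    cv_min: float | None = None

    def __post_init__(self):
        if not (0 <= self.low_norm_pct < 100 and 0 <= self.high_norm_pct < 100):
            raise ValidationError("norm percentages must lie in [0, 100)")
        if self.low_norm_pct + self.high_norm_pct >= 100:
            raise ValidationError("low_norm_pct + high_norm_pct must be < 100")
        if self.cv_min is not None and self.cv_min < 0:
            raise ValidationError("cv_min must be non-negative")

    @classmethod
    def preset(cls, name: str) -> "FilterSpec":
        if name == "default":
            return cls(5.0, 5.0, None)
        if name == "mdl":
            return cls(5.0, 5.0, 0.4)
        raise ValueError(f"unknown filter preset {name!r}")


def collapse_probes(expr: ExpressionMatrix, probe_to_gene: dict[str, str]) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    Probes absent from ``probe_to_gene`` are dropped.  When several probes
    map to the same gene, the probe whose raw profile has the highest
    unbiased sample variance wins; ties keep the probe earliest in input
    order.  Gene ids replace probe ids, ordered by first appearance.
    """
    variances = expr.values.var(axis=1, ddof=1) if expr.n_samples > 1 else \
        np.zeros(expr.n_genes)
    best: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for i, probe in enumerate(expr.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        if gene not in best:
            best[gene] = (variances[i], i)
            order.append(gene)
        elif variances[i] > best[gene][0]:
            best[gene] = (variances[i], i)
    if not best:
        raise ValidationError("no probes map to a gene; probe map exhausted the matrix")
    rows = [best[g][1] for g in order]
    return ExpressionMatrix(expr.values[rows], order, list(expr.sample_ids))


def filter_by_norm(expr: ExpressionMatrix, spec: FilterSpec) -> ExpressionMatrix:
    """Drop genes with extreme expression-vector norms.

    Genes whose Euclidean norm is strictly below the ``low_norm_pct``-th
    percentile or strictly above the ``(100 - high_norm_pct)``-th
    percentile are removed; gene order is otherwise preserved.
    """
    norms = np.linalg.norm(expr.values, axis=1)
    keep = np.ones(expr.n_genes, dtype=bool)
    if spec.low_norm_pct > 0:
        keep &= norms >= np.percentile(norms, spec.low_norm_pct)
    if spec.high_norm_pct > 0:
        keep &= norms <= np.percentile(norms, 100.0 - spec.high_norm_pct)
    if keep.sum() < 2:
        raise ValidationError("norm filter leaves fewer than 2 genes")
    return _take(expr, keep)


def filter_by_cv(expr: ExpressionMatrix, cv_min: float) -> ExpressionMatrix:
    """Keep genes whose coefficient of variation (sd/mean) is >= cv_min.

    Genes with zero mean are always removed (CV undefined).
    """
    if cv_min < 0:
        raise ValidationError("cv_min must be non-negative")
    means = expr.values.mean(axis=1)
    sds = expr.values.std(axis=1, ddof=1) if expr.n_samples > 1 else \
        np.zeros(expr.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means > 0, sds / means, -np.inf)
    keep = cv >= cv_min
    if keep.sum() < 2:
        raise ValidationError("CV filter leaves fewer than 2 genes")
    return _take(expr, keep)


def apply_filters(expr: ExpressionMatrix, spec: FilterSpec) -> ExpressionMatrix:
    """Norm filter followed by the CV filter (the pipeline's fixed order)."""
    out = filter_by_norm(expr, spec)
    if spec.cv_min is not None:
        out = filter_by_cv(out, spec.cv_min)
    return out


def _take(expr: ExpressionMatrix, keep: np.ndarray) -> ExpressionMatrix:
    ids = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(expr.values[keep], ids, list(expr.sample_ids))
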