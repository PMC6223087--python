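"""High-level modelling interface: ``Deconvolution(...).fit() -> Results``.

The class wraps the pipeline the lower-level modules implement —
optional filtering, marker-driven (semi-supervised) or cluster-driven
(unsupervised) proportion estimation, optional NMF refinement,
signature estimation with standard errors — and routes automatically to
the under-determined estimator when types outnumber samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import ClusterResult, cluster_genes, select_cluster_subsets
from .datatypes import (
    DeconvolutionResult,
    ExpressionMatrix,
    MarkerSets,
    ProportionMatrix,
    SignatureMatrix,
    ValidationError,
)
from .model_selection import MDLCurve, select_num_types
from .preprocess import FilterSpec, apply_filters
from .signatures import estimate_signatures
from .stage1 import build_meta_profiles, estimate_proportions_stage1
from .stage2 import NmfConfig, constrained_nmf
from .underdetermined import estimate_proportions_underdetermined

__all__ = ["Deconvolution", "DeconvolutionResults"]


class Deconvolution:
    """Complete deconvolution model for a bulk expression mixture.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes x samples mixture in linear scale.
    markers : MarkerSets, optional
        Marker gene lists; their presence selects semi-supervised mode.
    k : int, optional
        Number of types for unsupervised mode (clusters replace
        markers).  ``k="auto"`` runs MDL model-order selection first.
    filter_spec : FilterSpec, optional
        Norm/CV pre-filter applied before unsupervised clustering.

    Examples
    --------
    >>> from deblend import Deconvolution
    >>> from deblend.synthetic import standard_fixtures
    >>> bundle = standard_fixtures(["overdet_noiseless"])["overdet_noiseless"]
    >>> res = Deconvolution(bundle.X, markers=bundle.markers).fit()
    >>> res.proportions.values.sum(axis=0).round(8).tolist()[:3]
    [1.0, 1.0, 1.0]
    """

    def __init__(self, expr: ExpressionMatrix, markers: MarkerSets | None = None,
                 k: int | str | None = None, filter_spec: FilterSpec | None = None,
                 seed: int = 0):
        if markers is None and k is None:
            raise ValidationError("provide markers (semi-supervised) or k (unsupervised)")
        if markers is not None:
            markers.check_against(expr)
        self.expr = expr
        self.markers = markers
        self.k = k
        self.filter_spec = filter_spec
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "Deconvolution":
        return cls(ExpressionMatrix.from_frame(df), **kwargs)

    @property
    def mode(self) -> str:
        return "semi" if self.markers is not None else "unsupervised"

    def select_k(self, **kwargs) -> MDLCurve:
        """MDL sweep for the number of types (unsupervised)."""
        kwargs.setdefault("seed", self.seed)
        return select_num_types(self.expr, **kwargs)

    def fit(self, stage: str = "auto", cluster_method: str = "kmeans",
            cluster_space: str = "linear", cluster_replicates: int = 500,
            subset_fraction: float = 10.0, nmf_config: NmfConfig | None = None,
            solver: str = "nnls", rank1_method: str = "multiplicative_normalized",
            estimate_s: bool = True, compute_se: bool | None = None,
            ) -> "DeconvolutionResults":
        """Run the pipeline and return a results object.

        ``stage``: "s1", "s1s2", or "auto" (s1, switching to the
        under-determined estimator when k > p).  Signature estimation
        (and, when p > k, standard errors) runs unless ``estimate_s``
        is false.
        """
        expr = self.expr
        clusters: ClusterResult | None = None
        curve: MDLCurve | None = None
        if self.markers is not None:
            sets: MarkerSets | ClusterResult = self.markers
            k = self.markers.k
        else:
            work = apply_filters(expr, self.filter_spec) if self.filter_spec else expr
            k = self.k
            if k == "auto":
                curve = self.select_k()
                k = curve.best_k
            clusters = cluster_genes(work, int(k), method=cluster_method,
                                     space=cluster_space,
                                     replicates=cluster_replicates,
                                     seed=self.seed)
            sets = clusters
        p = expr.n_samples

        underdetermined = int(k) > p
        stage_used = stage
        if stage == "auto":
            stage_used = "underdetermined" if underdetermined else "s1"
        elif underdetermined and stage in ("s1", "s1s2"):
            raise ValidationError(
                f"k={k} > p={p}: only the under-determined estimator applies")

        subsystems = None
        if stage_used == "underdetermined":
            if self.markers is not None:
                subset = self.markers
            else:
                subset = select_cluster_subsets(expr if self.filter_spec is None
                                                else work, clusters, subset_fraction)
            A, subsystems = estimate_proportions_underdetermined(
                expr, subset, method=rank1_method, seed=self.seed)
            stages_label = "underdetermined"
        else:
            meta = build_meta_profiles(expr if self.markers is not None else work, sets)
            A = estimate_proportions_stage1(meta, solver=solver)
            stages_label = "S1"
            if stage_used == "s1s2":
                if self.markers is not None:
                    subset = self.markers
                else:
                    subset = select_cluster_subsets(work, clusters, subset_fraction)
                cfg = nmf_config if nmf_config is not None else NmfConfig(seed=self.seed)
                nmf_expr = expr if self.markers is not None else work
                _, A = constrained_nmf(nmf_expr, subset, cfg, A0=A)
                stages_label = "S1S2"

        signatures = None
        if estimate_s:
            if compute_se is None:
                compute_se = p > int(k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                signatures = estimate_signatures(expr, A, compute_se=compute_se)

        result = DeconvolutionResult(
            proportions=A, signatures=signatures, mode=self.mode,
            stages=stages_label,
            provenance={"seed": self.seed, "stage": stage_used,
                        "solver": solver, "k": int(k)},
        )
        return DeconvolutionResults(self, result, clusters=clusters,
                                    subsystems=subsystems, mdl_curve=curve)


@dataclass
class DeconvolutionResults:
    """Fitted proportions/signatures plus diagnostics and a summary table."""

    model: Deconvolution
    result: DeconvolutionResult
    clusters: ClusterResult | None = None
    subsystems: list | None = None
    mdl_curve: MDLCurve | None = None

    @property
    def proportions(self) -> ProportionMatrix:
        return self.result.proportions

    @property
    def signatures(self) -> SignatureMatrix | None:
        return self.result.signatures

    @property
    def k(self) -> int:
        return self.result.k

    def rms_residual(self) -> float | None:
        """RMS of X - S A, the model's reconstruction error."""
        if self.signatures is None:
            return None
        X = self.model.expr.values
        R = X - self.signatures.values @ self.proportions.values
        return float(np.sqrt(np.mean(R ** 2)))

    def summary(self) -> str:
        res = self.result
        lines = [
            "Bulk expression deconvolution",
            "=" * 45,
            f"mode:            {res.mode}",
            f"stages:          {res.stages}",
            f"types (k):       {res.k}",
            f"genes x samples: {self.model.expr.n_genes} x {self.model.expr.n_samples}",
        ]
        rms = self.rms_residual()
        if rms is not None:
            lines.append(f"RMS residual:    {rms:.6g}")
        if self.mdl_curve is not None:
            lines.append(f"MDL best k:      {self.mdl_curve.best_k}")
        lines.append("")
        lines.append("Mean proportion per type (+/- sd across samples):")
        A = res.proportions
        for t, label in enumerate(A.type_labels):
            row = A.values[t]
            lines.append(f"  {label:<16s} {row.mean():.4f} +/- {row.std():.4f}")
        return "\n".join(lines)
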