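"""Stage I: mixing-proportion estimation from meta-marker profiles.

For each type ``t`` the marker (or cluster) genes are averaged per
sample into a meta-marker profile, giving a reduced k x p system
``X~ = S~ A`` in which ``S~`` is diagonal (each meta-marker expresses in
exactly one type, at unknown level m_t).  Writing ``d_t = 1 / m_t``,
the per-sample sum-to-one constraint on the proportions yields one
linear equation per sample,

    sum_t d_t * X~[t, j] = 1        for j = 1..p,

an over-determined system in the k unknowns ``d`` whenever p >= k.  It
is solved as a non-negative least-squares problem (squared-norm
objective, d >= 0); then ``A = diag(d) X~``, with each sample column
rescaled to sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterResult
from .datatypes import ExpressionMatrix, MarkerSets, ProportionMatrix, ValidationError
from .io import normalize_columns_sum_to_one
from . import solvers

__all__ = ["MetaProfiles", "build_meta_profiles", "estimate_proportions_stage1"]


@dataclass(frozen=True)
class MetaProfiles:
    """The reduced k x p system matrix X~ (one meta-profile row per type)."""

    values: np.ndarray
    type_labels: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.type_labels), len(self.sample_ids)):
            raise ValidationError("meta-profile shape does not match labels")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("meta-profiles must be finite and non-negative")
        zero_rows = np.where(~values.any(axis=1))[0]
        if zero_rows.size:
            raise ValidationError(
                f"meta-profile for type {self.type_labels[zero_rows[0]]!r} is all zero"
            )
        object.__setattr__(self, "values", values)

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def build_meta_profiles(expr: ExpressionMatrix,
                        sets: MarkerSets | ClusterResult) -> MetaProfiles:
    """Average each type's marker profiles (or pass cluster exemplars through).

    Given marker/cluster-subset gene lists, row ``t`` is the per-sample
    arithmetic mean of the linear mixed profiles of set ``t``'s genes.
    A :class:`ClusterResult` contributes its exemplars verbatim.
    """
    if isinstance(sets, ClusterResult):
        labels = [f"cluster_{t + 1}" for t in range(sets.k)]
        return MetaProfiles(sets.exemplars.copy(), labels, list(sets.sample_ids))
    sets.check_against(expr)
    idx = expr.gene_index()
    rows = np.vstack([
        expr.values[[idx[g] for g in genes]].mean(axis=0)
        for genes in sets.sets.values()
    ])
    return MetaProfiles(rows, sets.type_labels, list(expr.sample_ids))


def estimate_proportions_stage1(meta: MetaProfiles,
                                solver: str = "nnls") -> ProportionMatrix:
    """Solve the diagonal system for the proportions A.

    Minimizes ``|| X~^T d - 1 ||^2`` over ``d >= 0`` (one equation per
    sample), then forms ``A = diag(d) X~`` and rescales the columns to
    the simplex.  ``solver`` picks the route: "nnls" (active set),
    "bounded" (trust-region LS on [0, inf)), or "upso".
    """
    if meta.p < meta.k:
        raise ValidationError(
            f"Stage I needs at least as many samples as types (p={meta.p} < k={meta.k}); "
            "use the under-determined estimator instead"
        )
    if meta.p == meta.k:
        warnings.warn("p == k: system is exactly determined, no residual averaging",
                      stacklevel=2)
    M = meta.values.T                       # p x k
    b = np.ones(meta.p)
    if solver == "nnls":
        d = solvers.nnls(M, b)
    elif solver == "bounded":
        d = solvers.bounded_lsq(M, b, 0.0, np.inf)
    elif solver == "upso":
        # box upper bound: d_t cannot usefully exceed 1/min positive entry
        pos = np.where(meta.values > 0, meta.values, np.inf).min(axis=1)
        d = solvers.upso_minimize(lambda x: float(np.sum((M @ x - b) ** 2)),
                                  np.zeros(meta.k), 1.0 / pos)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if np.any(d == 0):
        t = int(np.argmin(d))
        warnings.warn(
            f"estimated marker level for type {meta.type_labels[t]!r} is infinite "
            "(d = 0); that type is assigned zero proportion everywhere",
            stacklevel=2,
        )
    A = d[:, None] * meta.values
    A = normalize_columns_sum_to_one(A)
    return ProportionMatrix(A, list(meta.type_labels), list(meta.sample_ids))
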