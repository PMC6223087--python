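"""Component-identity matching and accuracy metrics.

Unsupervised estimates carry arbitrary row (type) order, so before
comparison against reference proportions the rows are matched: for
small k every permutation is scored and the one maximizing the overall
Pearson correlation kept; beyond k = 8 the factorial search is replaced
by Hungarian assignment on per-pair row correlations.

Metrics follow the field's conventions: RMSE over the full k x p
matrix, RMSE per type row with their arithmetic mean reported as mRMSE,
and Pearson r on the flattened matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .clustering import ClusterResult
from .datatypes import ProportionMatrix, SignatureMatrix, ValidationError

__all__ = ["EvaluationReport", "match_components", "evaluate_proportions",
           "assign_clusters_by_reference"]


@dataclass(frozen=True)
class EvaluationReport:
    permutation: tuple[int, ...]        # estimated row -> reference row
    pearson_overall: float
    rmse_full: float
    rmse_per_type: tuple[float, ...]
    mrmse: float

    def as_dict(self) -> dict:
        return {
            "permutation": list(self.permutation),
            "pearson_overall": self.pearson_overall,
            "rmse_full": self.rmse_full,
            "rmse_per_type": list(self.rmse_per_type),
            "mrmse": self.mrmse,
        }


def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.ravel(), b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("correlation undefined: flattened matrix has zero variance")
    return float(pearsonr(a, b).statistic)


def match_components(A_est: ProportionMatrix | np.ndarray,
                     A_ref: ProportionMatrix | np.ndarray,
                     exhaustive: bool | None = None) -> tuple[int, ...]:
    """Row permutation of A_est maximizing overall Pearson r against A_ref.

    Element ``t`` of the result is the estimated row placed at reference
    position ``t``.  Exhaustive search up to k = 8 (the default);
    Hungarian assignment on the per-pair row-correlation matrix beyond.
    """
    E = A_est.values if isinstance(A_est, ProportionMatrix) else np.asarray(A_est, float)
    R = A_ref.values if isinstance(A_ref, ProportionMatrix) else np.asarray(A_ref, float)
    if E.shape != R.shape:
        raise ValidationError("estimate and reference shapes differ")
    k = E.shape[0]
    if exhaustive is None:
        exhaustive = k <= 8
    if exhaustive:
        if k > 10:
            raise ValidationError("exhaustive matching is limited to k <= 10")
        best_perm, best_r = None, -np.inf
        for perm in permutations(range(k)):
            r = _flat_corr(E[list(perm)], R)
            if r > best_r:
                best_r, best_perm = r, perm
        return tuple(best_perm)
    # Hungarian: maximize summed per-pair row correlations
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            ei, rj = E[i], R[j]
            if np.std(ei) == 0 or np.std(rj) == 0:
                C[i, j] = 0.0
            else:
                C[i, j] = pearsonr(ei, rj).statistic
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(k, dtype=int)
    perm[cols] = rows
    return tuple(int(i) for i in perm)


def evaluate_proportions(A_est: ProportionMatrix | np.ndarray,
                         A_ref: ProportionMatrix | np.ndarray,
                         permute: bool = False) -> EvaluationReport:
    """RMSE / mRMSE / Pearson r of an estimate against a reference.

    With ``permute`` the estimated rows are first matched to the
    reference by :func:`match_components`.
    """
    E = A_est.values if isinstance(A_est, ProportionMatrix) else np.asarray(A_est, float)
    R = A_ref.values if isinstance(A_ref, ProportionMatrix) else np.asarray(A_ref, float)
    if E.shape != R.shape:
        raise ValidationError("estimate and reference shapes differ")
    if permute:
        perm = match_components(E, R)
        E = E[list(perm)]
    else:
        perm = tuple(range(E.shape[0]))
    diff = E - R
    rmse_full = float(np.sqrt(np.mean(diff ** 2)))
    rmse_per_type = tuple(float(np.sqrt(np.mean(row ** 2))) for row in diff)
    return EvaluationReport(
        permutation=perm,
        pearson_overall=_flat_corr(E, R),
        rmse_full=rmse_full,
        rmse_per_type=rmse_per_type,
        mrmse=float(np.mean(rmse_per_type)),
    )


def assign_clusters_by_reference(clusters: ClusterResult,
                                 S_ref: SignatureMatrix) -> dict[int, int]:
    """Assign each cluster to the type where most of its genes peak.

    For every cluster, counts in which reference-signature column its
    member genes attain their row maximum; the majority type wins (ties
    -> lower type index).  The mapping need not be a bijection — two
    clusters landing on one type is reported, not an error.
    """
    gene_row = {g: i for i, g in enumerate(S_ref.gene_ids)}
    peak = np.argmax(S_ref.values, axis=1)
    out: dict[int, int] = {}
    for t in range(1, clusters.k + 1):
        counts = np.zeros(S_ref.values.shape[1], dtype=int)
        for g in clusters.members(t):
            if g in gene_row:
                counts[peak[gene_row[g]]] += 1
        out[t] = int(np.argmax(counts))
    return out
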