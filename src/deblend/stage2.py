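"""Stage II: marker-constrained NMF refinement of (S, A).

The mixing model ``X ~ S A`` is re-fit as a non-negative matrix
factorization in which rows of ``S`` belonging to a type's marker genes
(or cluster-subset genes) are pinned to zero in every other type's
column, both at initialization and after every iteration.  The
objective is the root-mean-squared residual between ``X`` and ``S A``,
minimized by the standard multiplicative updates; masked entries stay
exactly zero because a multiplicative update cannot revive them and the
mask is re-applied regardless.

Several random restarts are run and the lowest-residual one returned;
one restart is seeded with the Stage-I proportion estimate (and
optionally the signature estimate derived from it), which in practice
anchors the factorization to the Stage-I solution when that solution is
already good.  The per-sample sum-to-one constraint is imposed on the
final ``A`` by column rescaling (per-iteration projection would break
the monotonic-descent property of the updates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    MarkerSets,
    ProportionMatrix,
    SignatureMatrix,
    ValidationError,
)
from .io import normalize_columns_sum_to_one

__all__ = ["NmfConfig", "build_mask", "masked_update_step", "constrained_nmf", "rms_residual"]


@dataclass(frozen=True)
class NmfConfig:
    """Iteration controls for the constrained factorization.

    ``gene_scope`` chooses whether all genes or only the marker/subset
    genes enter the factorization.
    """

    replicates: int = 10
    max_iter: int = 1000
    tol: float = 1e-4
    eps: float = 1e-9
    gene_scope: str = "all_genes"           # or "subset_only"
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.tol <= 0 or self.eps <= 0:
            raise ValidationError("tol and eps must be positive")
        if self.gene_scope not in ("all_genes", "subset_only"):
            raise ValidationError(f"unknown gene_scope {self.gene_scope!r}")


def build_mask(gene_ids: list[str], sets: MarkerSets) -> np.ndarray:
    """n x k binary mask: marker rows are 1 only in their own type's column."""
    mask = np.ones((len(gene_ids), sets.k))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for j, genes in enumerate(sets.sets.values()):
        for g in genes:
            if g in idx:
                mask[idx[g], :] = 0.0
                mask[idx[g], j] = 1.0
    return mask


def rms_residual(X: np.ndarray, S: np.ndarray, A: np.ndarray) -> float:
    return float(np.sqrt(np.mean((X - S @ A) ** 2)))


def masked_update_step(X: np.ndarray, S: np.ndarray, A: np.ndarray,
                       mask: np.ndarray, eps: float = 1e-9) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update of S then A under the marker mask."""
    S = S * (X @ A.T) / (S @ (A @ A.T) + eps)
    S *= mask
    A = A * (S.T @ X) / ((S.T @ S) @ A + eps)
    return S, A


def constrained_nmf(expr: ExpressionMatrix, sets: MarkerSets,
                    config: NmfConfig | None = None,
                    A0: ProportionMatrix | None = None,
                    S0: SignatureMatrix | None = None,
                    return_info: bool = False,
                    ) -> tuple[SignatureMatrix, ProportionMatrix]:
    """Fit the masked factorization and return (signatures, proportions).

    Runs ``config.replicates`` initializations: uniform-random (seeded)
    non-negative S and simplex-column A, except that one replicate uses
    ``A0`` (and ``S0`` masked, when given).  Each run iterates
    :func:`masked_update_step` until the relative change of the RMS
    residual drops below ``config.tol`` or ``max_iter`` is reached; the
    lowest-residual replicate wins.  The returned A is column-rescaled
    to the simplex.
    """
    if config is None:
        config = NmfConfig()
    sets_labels = sets.type_labels
    k = sets.k
    if config.gene_scope == "subset_only":
        expr = expr.subset_genes(sets.all_genes())
    else:
        sets.check_against(expr)
    X = expr.values
    n, p = X.shape
    mask = build_mask(expr.gene_ids, sets)
    if A0 is not None and A0.values.shape != (k, p):
        raise ValidationError(
            f"A0 shape {A0.values.shape} does not match (k={k}, p={p})"
        )
    rng = np.random.default_rng(config.seed)
    scale = float(X.max()) or 1.0

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for rep in range(config.replicates):
        if rep == 0 and A0 is not None:
            A = A0.values.copy()
            A = np.maximum(A, config.eps)     # multiplicative updates need > 0
            if S0 is not None:
                S = np.maximum(S0.values.copy(), 0.0) * mask
                S = np.maximum(S, config.eps * mask)
            else:
                S = rng.uniform(0.0, scale, size=(n, k)) * mask
        else:
            S = rng.uniform(0.0, scale, size=(n, k)) * mask
            A = rng.uniform(0.0, 1.0, size=(k, p))
            A /= A.sum(axis=0, keepdims=True)
        prev = rms_residual(X, S, A)
        for _ in range(config.max_iter):
            S, A = masked_update_step(X, S, A, mask, config.eps)
            cur = rms_residual(X, S, A)
            if prev > 0 and abs(prev - cur) / prev < config.tol:
                prev = cur
                break
            prev = cur
        if best is None or prev < best[0]:
            best = (prev, S, A)

    rms, S, A = best
    A = normalize_columns_sum_to_one(np.maximum(A, 0.0))
    sig = SignatureMatrix(S, list(expr.gene_ids), list(sets_labels),
                          lb=0.0, ub=max(float(S.max()), float(X.max())))
    prop = ProportionMatrix(A, list(sets_labels), list(expr.sample_ids))
    if return_info:
        return sig, prop, {"rms_residual": rms}
    return sig, prop
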