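"""Type-specific expression profiles from known proportions, with SEs.

Once the mixing proportions ``A`` are known, each gene ``i`` is an
independent bounded least-squares regression: its mixed profile ``x_i``
(p observations) on the k rows of ``A``,

    S_i = argmin_{lb <= s <= ub} || x_i - A^T s ||^2 ,

where the box [lb, ub] reflects the minimum and maximum measurable
expression levels (the data range by default).  Standard errors follow
the usual multiple-linear-regression form: with residuals
``R = X - S A`` and per-gene mean squared error
``MSE_i = sum_j R_ij^2 / (p - k)``,

    SE(S_ij) = sqrt( MSE_i * [(A A^T)^{-1}]_jj ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, ProportionMatrix, SignatureMatrix, ValidationError
from .solvers import bounded_lsq

__all__ = ["ResidualStats", "estimate_signatures", "signature_standard_errors"]


@dataclass(frozen=True)
class ResidualStats:
    """Residual matrix R = X - S A and per-gene mean squared errors."""

    residuals: np.ndarray
    mse: np.ndarray
    dof: int


def estimate_signatures(expr: ExpressionMatrix, A: ProportionMatrix,
                        lb: float | None = None, ub: float | None = None,
                        compute_se: bool = False) -> SignatureMatrix:
    """Per-gene bounded least squares for the signature matrix S.

    ``lb``/``ub`` default to the data minimum/maximum.  Genes whose
    unconstrained normal-equation solution already lies inside the box
    take it directly; the rest are solved with a bounded trust-region
    least-squares routine.  With ``compute_se`` the returned matrix also
    carries :func:`signature_standard_errors` (requires p > k).
    """
    if expr.sample_ids != A.sample_ids:
        raise ValidationError("expression and proportion sample ids differ")
    X = expr.values
    n, p = X.shape
    k = A.k
    if lb is None:
        lb = float(X.min())
    if ub is None:
        ub = float(X.max())
    if lb > ub:
        raise ValidationError("lb must not exceed ub")
    M = A.values.T                          # p x k design
    rank = np.linalg.matrix_rank(A.values)
    if rank < k:
        warnings.warn(
            "proportion matrix is rank-deficient (collinear types); "
            "signature estimates are a non-unique optimum", stacklevel=2)
    # unconstrained solution for all genes at once, then bound-violators re-solved
    sol, *_ = np.linalg.lstsq(M, X.T, rcond=None)
    if rank == k:
        # one step of iterative refinement tightens recovery to ~eps
        sol = sol + np.linalg.lstsq(M, X.T - M @ sol, rcond=None)[0]
    S = sol.T                               # n x k
    bad = np.where(np.any((S < lb) | (S > ub), axis=1))[0]
    for i in bad:
        S[i] = bounded_lsq(M, X[i], lb, ub)
    S = np.clip(S, lb, ub)
    sig = SignatureMatrix(S, list(expr.gene_ids), list(A.type_labels), lb=lb, ub=ub)
    if compute_se:
        se = signature_standard_errors(expr, A, sig)
        sig = SignatureMatrix(S, list(expr.gene_ids), list(A.type_labels),
                              se=se, lb=lb, ub=ub)
    return sig


def residual_stats(expr: ExpressionMatrix, A: ProportionMatrix,
                   S: SignatureMatrix) -> ResidualStats:
    X = expr.values
    p, k = X.shape[1], A.k
    if p <= k:
        raise ValidationError(
            f"standard errors need more samples than types (p={p}, k={k})")
    R = X - S.values @ A.values
    mse = (R ** 2).sum(axis=1) / (p - k)
    return ResidualStats(R, mse, p - k)


def signature_standard_errors(expr: ExpressionMatrix, A: ProportionMatrix,
                              S: SignatureMatrix) -> np.ndarray:
    """Regression standard errors for every signature coefficient."""
    stats = residual_stats(expr, A, S)
    AAt = A.values @ A.values.T
    try:
        inv = np.linalg.inv(AAt)
    except np.linalg.LinAlgError:
        corr = np.corrcoef(A.values)
        i, j = divmod(int(np.nanargmax(np.abs(corr - np.eye(A.k)))), A.k)
        raise ValidationError(
            f"A A^T is singular; types {A.type_labels[i]!r} and "
            f"{A.type_labels[j]!r} are collinear") from None
    diag = np.diag(inv)
    if np.any(diag < 0):
        raise ValidationError("A A^T inverse has negative diagonal; A is ill-conditioned")
    return np.sqrt(np.outer(stats.mse, diag))
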