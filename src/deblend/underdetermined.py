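"""Proportion estimation when types outnumber samples (k > p).

Stage I needs at least as many samples as types.  When that fails, the
mixing system is split into one subsystem per type: the c marker (or
cluster-subset) genes of type ``t`` give a c x p sub-matrix ``X_t``
which, if those genes express only in type ``t``, is approximately
rank one,

    X_t ~ w h^T ,

with ``w`` the c type-specific expression levels and ``h`` the type's
proportions across the p samples.  Each subsystem is factorized
independently (multiplicative updates, optionally with per-iteration
normalization of ``h`` or a bound-constrained UPSO search); only the
``h`` vectors are kept, stacked into a k x p matrix and rescaled so
each sample column sums to one.

Each subsystem fixes its own scale only up to a constant (w h = (w/c)(c h));
the unit-maximum convention on ``h`` resolves it per type, and absolute
cross-type calibration comes solely from the final column sum-to-one.
Within-type proportion *ratios* are therefore the meaningful output,
which is why this regime is evaluated by per-type correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, MarkerSets, ProportionMatrix, ValidationError
from .io import normalize_columns_sum_to_one
from .solvers import UpsoConfig, upso_minimize

__all__ = ["Subsystem", "rank1_nmf", "estimate_proportions_underdetermined"]


@dataclass
class Subsystem:
    """One type's marker rows and its fitted rank-1 factors."""

    type_label: str
    X_sub: np.ndarray
    w: np.ndarray
    h: np.ndarray


def rank1_nmf(X_sub: np.ndarray, method: str = "multiplicative_normalized",
              bounds: tuple[float, float] | None = None, seed: int = 0,
              max_iter: int = 2000, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Best rank-1 non-negative factorization X_sub ~ w h^T.

    ``method``:

    - "multiplicative": plain multiplicative updates;
    - "multiplicative_normalized": h rescaled to unit maximum after each
      iteration, scale absorbed into w (the default);
    - "upso": particle-swarm search with ``lb <= w <= ub`` and
      ``0 <= h <= 1`` enforced throughout (``bounds`` defaults to the
      data range), followed by multiplicative polishing inside the box.
    """
    X = np.asarray(X_sub, dtype=float)
    if X.ndim != 2:
        raise ValidationError("subsystem matrix must be 2-D")
    if np.any(X < 0):
        raise ValidationError("subsystem matrix must be non-negative")
    if X.shape[1] < 2:
        raise ValidationError("under-determined estimation needs at least 2 samples")
    if not X.any():
        raise ValidationError("subsystem matrix is all zero")
    c, p = X.shape
    rng = np.random.default_rng(seed)

    if method == "upso":
        lb_w, ub_w = bounds if bounds is not None else (0.0, float(X.max()))
        lo = np.concatenate([np.full(c, lb_w), np.zeros(p)])
        hi = np.concatenate([np.full(c, ub_w), np.ones(p)])

        def objective(z):
            return float(np.sum((X - np.outer(z[:c], z[c:])) ** 2))

        z = upso_minimize(objective, lo, hi, UpsoConfig(seed=seed))
        w, h = z[:c].copy(), z[c:].copy()
        # polish with box-respecting multiplicative updates
        for _ in range(max_iter):
            prev = np.sum((X - np.outer(w, h)) ** 2)
            w = np.clip(w * (X @ h) / (w * (h @ h) + 1e-12), lb_w, ub_w)
            h = h * (X.T @ w) / (h * (w @ w) + 1e-12)
            m = h.max()
            if m > 0:
                h /= m
                w = np.clip(w * m, lb_w, ub_w)
            cur = np.sum((X - np.outer(w, h)) ** 2)
            if prev > 0 and abs(prev - cur) / prev < tol:
                break
        return w, h

    if method not in ("multiplicative", "multiplicative_normalized"):
        raise ValueError(f"unknown rank-1 method {method!r}")
    w = rng.uniform(0.1, 1.0, size=c) * float(X.max())
    h = rng.uniform(0.1, 1.0, size=p)
    prev = np.sum((X - np.outer(w, h)) ** 2)
    for _ in range(max_iter):
        w = w * (X @ h) / (w * (h @ h) + 1e-12)
        h = h * (X.T @ w) / (h * (w @ w) + 1e-12)
        if method == "multiplicative_normalized":
            m = h.max()
            if m > 0:
                h /= m
                w *= m
        cur = np.sum((X - np.outer(w, h)) ** 2)
        if prev > 0 and abs(prev - cur) / prev < tol:
            break
        prev = cur
    return w, h


def estimate_proportions_underdetermined(
        expr: ExpressionMatrix, sets: MarkerSets,
        method: str = "multiplicative_normalized", seed: int = 0,
        bounds: tuple[float, float] | None = None,
) -> tuple[ProportionMatrix, list[Subsystem]]:
    """Per-type rank-1 subsystems, stacked and simplex-rescaled.

    Returns the k x p proportion estimate together with the fitted
    subsystems (whose ``w`` vectors are the per-type expression levels
    of the marker genes, for inspection).
    """
    if expr.n_samples < 2:
        raise ValidationError("under-determined estimation needs at least 2 samples")
    sets.check_against(expr)
    idx = expr.gene_index()
    subsystems: list[Subsystem] = []
    H = np.zeros((sets.k, expr.n_samples))
    for t, (label, genes) in enumerate(sets.sets.items()):
        X_sub = expr.values[[idx[g] for g in genes]]
        w, h = rank1_nmf(X_sub, method=method, bounds=bounds,
                         seed=seed + t, max_iter=2000)
        if method == "multiplicative":
            m = h.max()
            if m > 0:       # harmless canonical scaling for the plain variant
                h, w = h / m, w * m
        subsystems.append(Subsystem(label, X_sub, w, h))
        H[t] = h
    A = normalize_columns_sum_to_one(H)
    return (ProportionMatrix(A, sets.type_labels, list(expr.sample_ids)),
            subsystems)
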