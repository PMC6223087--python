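"""Interchangeable constrained least-squares solvers.

The proportion and signature estimators all reduce to small box- or
non-negativity-constrained least-squares problems.  Three routes are
offered: active-set non-negative LS (`nnls`), bounded trust-region LS
(`bounded_lsq`, also covering the quadratic-programming formulation),
and a Unified Particle Swarm Optimization search (`upso_minimize`) for
users who want a stochastic global method with hard space bounds.

UPSO blends the global and local (ring-neighborhood) particle-swarm
variants: each particle's velocity is u * G + (1 - u) * L, where G and L
are constriction-form updates toward the swarm-best and the
neighborhood-best respectively, and u in [0, 1] is the unification
factor.  Defaults follow the canonical constriction analysis
(chi = 0.729, c1 = c2 = 2.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = ["UpsoConfig", "nnls", "bounded_lsq", "upso_minimize"]


@dataclass(frozen=True)
class UpsoConfig:
    swarm_size: int = 40
    iterations: int = 200
    unification_u: float = 0.5
    constriction_chi: float = 0.729
    c1: float = 2.05
    c2: float = 2.05
    neighborhood_radius: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.swarm_size < 3:
            raise ValueError("swarm_size must be >= 3")
        if not 0.0 <= self.unification_u <= 1.0:
            raise ValueError("unification_u must lie in [0, 1]")


def nnls(M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin ||M x - b||^2 subject to x >= 0 (active-set method)."""
    M = np.asarray(M, dtype=float)
    b = np.asarray(b, dtype=float)
    x, _ = scipy.optimize.nnls(M, b)
    return x


def bounded_lsq(M: np.ndarray, b: np.ndarray, lb, ub) -> np.ndarray:
    """argmin ||M x - b||^2 subject to lb <= x <= ub element-wise."""
    M = np.asarray(M, dtype=float)
    b = np.asarray(b, dtype=float)
    lb = np.broadcast_to(np.asarray(lb, dtype=float), (M.shape[1],))
    ub = np.broadcast_to(np.asarray(ub, dtype=float), (M.shape[1],))
    if np.any(lb > ub):
        raise ValueError("infeasible bounds: lb > ub")
    if np.all(lb == ub):
        return lb.copy()
    res = scipy.optimize.lsq_linear(M, b, bounds=(lb, ub), method="trf", tol=1e-14)
    x = np.clip(res.x, lb, ub)
    # active-set polish: pin near-bound coordinates, solve the rest exactly
    scale = max(np.max(np.abs(x), initial=0.0), 1.0)
    at_lb = np.isfinite(lb) & (x - lb <= 1e-7 * scale)
    at_ub = np.isfinite(ub) & (ub - x <= 1e-7 * scale)
    free = ~(at_lb | at_ub)
    if not free.all():
        cand = np.where(at_lb, lb, np.where(at_ub, ub, 0.0))
        if free.any():
            rhs = b - M[:, ~free] @ cand[~free]
            cand[free] = np.linalg.lstsq(M[:, free], rhs, rcond=None)[0]
        if (np.all(cand >= lb) and np.all(cand <= ub)
                and np.sum((M @ cand - b) ** 2) <= np.sum((M @ x - b) ** 2) + 1e-30):
            x = cand
    return x


def upso_minimize(objective, lb, ub, config: UpsoConfig | None = None) -> np.ndarray:
    """Minimize ``objective`` over the box [lb, ub] with a unified particle swarm.

    Deterministic given ``config.seed``; positions are clamped to the box
    and velocities to the box width.  Returns the best position found.
    """
    if config is None:
        config = UpsoConfig()
    lb = np.atleast_1d(np.asarray(lb, dtype=float))
    ub = np.atleast_1d(np.asarray(ub, dtype=float))
    r = lb.size
    width = ub - lb
    rng = np.random.default_rng(config.seed)
    n = config.swarm_size
    x = lb + rng.random((n, r)) * width
    v = (rng.random((n, r)) - 0.5) * width
    pbest = x.copy()
    pbest_f = np.array([objective(xi) for xi in x])
    chi, c1, c2, u = (config.constriction_chi, config.c1, config.c2,
                      config.unification_u)
    radius = config.neighborhood_radius
    for _ in range(config.iterations):
        g = int(np.argmin(pbest_f))
        # ring-topology neighborhood best for the local component
        nb = np.empty(n, dtype=int)
        for i in range(n):
            idx = [(i + d) % n for d in range(-radius, radius + 1)]
            nb[i] = idx[int(np.argmin(pbest_f[idx]))]
        r1, r2 = rng.random((n, r)), rng.random((n, r))
        r3, r4 = rng.random((n, r)), rng.random((n, r))
        G = chi * (v + c1 * r1 * (pbest - x) + c2 * r2 * (pbest[g] - x))
        L = chi * (v + c1 * r3 * (pbest - x) + c2 * r4 * (pbest[nb] - x))
        v = u * G + (1.0 - u) * L
        v = np.clip(v, -width, width)
        x = np.clip(x + v, lb, ub)
        f = np.array([objective(xi) for xi in x])
        improved = f < pbest_f
        pbest[improved] = x[improved]
        pbest_f[improved] = f[improved]
    return pbest[int(np.argmin(pbest_f))]
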