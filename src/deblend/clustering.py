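"""Gene clustering with correlation distance (k-means / k-medoids).

In unsupervised mode, gene clusters stand in for marker-gene lists: each
cluster is treated as a set of genes biased toward one underlying
cell/tissue type, its exemplar profile replaces the meta-marker profile
in Stage I, and the genes closest to the exemplar (the "cluster subset")
carry the zero-constraints in Stage II and the under-determined
subsystems.

Distance between gene profiles is 1 - Pearson correlation.  Writing
``u_i`` for a profile standardized to zero mean and unit Euclidean norm,
``corr(x_i, x_j) = u_i . u_j``, and the total within-cluster distance of
a k-means partition with correlation-standardized centroids is

    n - sum_t || sum_{i in cluster t} u_i ||,

which this module exploits: batch assignment is one matrix product and
the post-convergence online phase (single-gene moves accepted only when
they lower the exact objective) costs O(p) per candidate move.

Profiles may be clustered in linear or log2(x + offset) space; exemplars
are always reported in linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ExpressionMatrix, MarkerSets, ValidationError

__all__ = ["ClusterResult", "cluster_genes", "select_cluster_subsets"]


@dataclass
class ClusterResult:
    """A gene partition plus per-cluster exemplar profiles.

    ``assignment`` maps gene id -> cluster index in 1..k.  ``exemplars``
    is the k x p matrix of linear-scale exemplar profiles (mean profile
    for k-means; medoid or mean for k-medoids).  ``space_centroids``
    holds the cluster representatives in the clustering space and is
    what subset selection measures distances against.
    """

    assignment: dict[str, int]
    exemplars: np.ndarray
    sample_ids: list[str]
    method: str
    exemplar_kind: str
    space: str
    seed: int
    objective: float
    space_centroids: np.ndarray = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.exemplars.shape[0]

    def members(self, t: int) -> list[str]:
        return [g for g, c in self.assignment.items() if c == t]


def _standardize(profiles: np.ndarray, gene_ids) -> np.ndarray:
    z = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    flat = np.where(norms == 0)[0]
    if flat.size:
        raise ValidationError(
            f"gene {gene_ids[flat[0]]!r} has zero variance across samples; "
            "correlation distance is undefined — apply a CV pre-filter"
        )
    return z / norms[:, None]


def _to_space(values: np.ndarray, space: str, log_offset: float) -> np.ndarray:
    if space == "log":
        return np.log2(values + log_offset)
    if space == "linear":
        return values
    raise ValueError(f"unknown space {space!r}")


def _kmeans_once(U: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 100) -> tuple[np.ndarray, float] | None:
    """One seeded restart; returns (labels, objective) or None on collapse."""
    n = U.shape[0]
    centers = U[rng.choice(n, size=k, replace=False)]
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sim = U @ centers.T
        new = np.argmax(sim, axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        sums = np.zeros((k, U.shape[1]))
        np.add.at(sums, labels, U)
        norms = np.linalg.norm(sums, axis=1)
        if np.any(norms == 0):
            return None  # empty cluster: failed restart
        centers = sums / norms[:, None]
    if len(np.unique(labels)) < k:
        return None
    sums = np.zeros((k, U.shape[1]))
    np.add.at(sums, labels, U)
    return labels, n - float(np.linalg.norm(sums, axis=1).sum())


def _online_phase(U: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Greedy single-gene moves until none lowers the exact objective."""
    sums = np.zeros((k, U.shape[1]))
    np.add.at(sums, labels, U)
    counts = np.bincount(labels, minlength=k)
    norms = np.linalg.norm(sums, axis=1)
    improved = True
    sweeps = 0
    while improved and sweeps < 50:
        improved = False
        sweeps += 1
        for i in range(U.shape[0]):
            t = labels[i]
            if counts[t] == 1:
                continue
            src_norm = np.linalg.norm(sums[t] - U[i])
            # gain of moving gene i from t to t2 (objective decreases by gain)
            best_gain, best_t = 1e-12, -1
            for t2 in range(k):
                if t2 == t:
                    continue
                gain = (src_norm + np.linalg.norm(sums[t2] + U[i])
                        - norms[t] - norms[t2])
                if gain > best_gain:
                    best_gain, best_t = gain, t2
            if best_t >= 0:
                sums[t] -= U[i]
                sums[best_t] += U[i]
                counts[t] -= 1
                counts[best_t] += 1
                norms[t] = np.linalg.norm(sums[t])
                norms[best_t] = np.linalg.norm(sums[best_t])
                labels[i] = best_t
                improved = True
    return labels


def _kmedoids_once(G: np.ndarray, k: int, rng: np.random.Generator,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Alternating (k-means-style) k-medoids on a correlation Gram matrix."""
    n = G.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels = np.full(n, -1)
    for _ in range(max_iter):
        new = np.argmax(G[:, medoids], axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        if len(np.unique(labels)) < k:
            return None
        for t in range(k):
            idx = np.where(labels == t)[0]
            medoids[t] = idx[int(np.argmax(G[np.ix_(idx, idx)].sum(axis=1)))]
    obj = float(np.sum(1.0 - G[np.arange(n), medoids[labels]]))
    return labels, medoids, obj


def cluster_genes(expr: ExpressionMatrix, k: int, method: str = "kmeans",
                  space: str = "linear", log_offset: float = 1.0,
                  replicates: int = 500, seed: int = 0,
                  exemplar_kind: str | None = None) -> ClusterResult:
    """Partition genes into k clusters by correlation distance.

    The best of ``replicates`` seeded restarts (lowest total
    within-cluster distance) is kept; for k-means a final online phase
    then applies single-gene moves until no move improves the objective.
    Restarts that collapse a cluster are discarded.

    ``exemplar_kind`` defaults to "mean_profile" for k-means and
    "medoid" for k-medoids.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > expr.n_genes:
        raise ValidationError("k cannot exceed the number of genes")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if exemplar_kind is None:
        exemplar_kind = "mean_profile" if method == "kmeans" else "medoid"
    if method == "kmeans" and exemplar_kind != "mean_profile":
        raise ValidationError("k-means exemplars are mean profiles")

    profiles = _to_space(expr.values, space, log_offset)
    U = _standardize(profiles, expr.gene_ids)
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=replicates)

    best = None
    if method == "kmeans":
        for s in rep_seeds:
            out = _kmeans_once(U, k, np.random.default_rng(int(s)))
            if out is not None and (best is None or out[1] < best[1]):
                best = out
        if best is None:
            raise ValidationError("all clustering restarts produced an empty cluster")
        labels = _online_phase(U, best[0].copy(), k)
        sums = np.zeros((k, U.shape[1]))
        np.add.at(sums, labels, U)
        objective = U.shape[0] - float(np.linalg.norm(sums, axis=1).sum())
        medoids = None
    elif method == "kmedoids":
        G = U @ U.T
        for s in rep_seeds:
            out = _kmedoids_once(G, k, np.random.default_rng(int(s)))
            if out is not None and (best is None or out[2] < best[2]):
                best = out
        if best is None:
            raise ValidationError("all clustering restarts produced an empty cluster")
        labels, medoids, objective = best[0], best[1], best[2]
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # canonical cluster numbering: order of first gene appearance
    relabel = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    labels = np.array([relabel[lab] for lab in labels])
    if medoids is not None:
        medoids = medoids[np.argsort([relabel[t] for t in range(k)])]

    exemplars = np.zeros((k, expr.n_samples))
    space_centroids = np.zeros((k, expr.n_samples))
    for t in range(k):
        idx = np.where(labels == t)[0]
        if method == "kmedoids" and exemplar_kind == "medoid":
            exemplars[t] = expr.values[medoids[t]]
            space_centroids[t] = profiles[medoids[t]]
        else:
            exemplars[t] = expr.values[idx].mean(axis=0)
            space_centroids[t] = profiles[idx].mean(axis=0)

    assignment = {g: int(lab) + 1 for g, lab in zip(expr.gene_ids, labels)}
    return ClusterResult(assignment=assignment, exemplars=exemplars,
                         sample_ids=list(expr.sample_ids), method=method,
                         exemplar_kind=exemplar_kind, space=space, seed=seed,
                         objective=objective, space_centroids=space_centroids)


def select_cluster_subsets(expr: ExpressionMatrix, clusters: ClusterResult,
                           fraction: float, log_offset: float = 1.0) -> MarkerSets:
    """Pick the ``fraction`` % of each cluster closest to its exemplar.

    Distances are correlation distances in the clustering space;
    ``ceil(fraction/100 * cluster size)`` genes are kept per cluster,
    ties broken by input gene order.  The result is a marker-set
    container usable anywhere marker lists are.
    """
    if not 0 < fraction <= 100:
        raise ValidationError("fraction must lie in (0, 100]")
    profiles = _to_space(expr.values, clusters.space, log_offset)
    idx_of = expr.gene_index()
    sets: dict[str, list[str]] = {}
    for t in range(clusters.k):
        genes = [g for g, c in clusters.assignment.items() if c == t + 1]
        rows = np.array([idx_of[g] for g in genes])
        P = profiles[rows]
        c = clusters.space_centroids[t]
        Pz = P - P.mean(axis=1, keepdims=True)
        cz = c - c.mean()
        denom = np.linalg.norm(Pz, axis=1) * np.linalg.norm(cz)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, Pz @ cz / denom, 0.0)
        dist = 1.0 - corr
        n_keep = math.ceil(fraction / 100.0 * len(genes))
        order = np.argsort(dist, kind="stable")[:n_keep]
        sets[f"cluster_{t + 1}"] = [genes[i] for i in sorted(order)]
    return MarkerSets(sets)
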