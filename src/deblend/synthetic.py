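"""Seeded generator of ground-truth expression mixtures.

The generator emulates the structure the deconvolution model assumes:

- per-gene, per-type signature levels drawn log-normally, independently
  across types, so non-marker genes also carry globally type-dependent
  expression (the property gene clustering exploits);
- designated marker genes whose own-type level is forced to at least
  ``marker_fold`` times their highest off-type level (optionally
  exclusive: off-type levels exactly zero);
- per-sample mixing proportions drawn from a Dirichlet;
- the mixture X = S A corrupted by multiplicative log-normal noise,
  which keeps X non-negative without clipping.

It is deliberately not a realistic RNA-seq count simulator (no
library-size or dispersion modelling); it exercises exactly the
assumptions the estimators make.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datatypes import (
    ExpressionMatrix,
    MarkerSets,
    ProportionMatrix,
    SignatureMatrix,
    ValidationError,
)

__all__ = ["MixtureSpec", "generate_mixture", "standard_fixtures"]


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of one synthetic mixture.

    ``base_log_mean``/``base_log_sd`` parameterize the natural-log
    normal draw of signature levels (defaults put typical expression
    near e^5 ~ 150 linear units with roughly e-fold spread across
    types).  ``noise_sd`` is the standard deviation of the log-scale
    multiplicative noise on X.
    """

    n_genes: int = 2000
    k: int = 3
    p: int = 20
    markers_per_type: int = 30
    marker_fold: float = 5.0
    base_log_mean: float = 5.0
    base_log_sd: float = 1.0
    dirichlet_alpha: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    exclusive_markers: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_type * self.k > self.n_genes:
            raise ValidationError("markers_per_type * k exceeds n_genes")
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.k < 2 or self.p < 1:
            raise ValidationError("need k >= 2 and p >= 1")
        if self.dirichlet_alpha is not None and len(self.dirichlet_alpha) != self.k:
            raise ValidationError("dirichlet_alpha must have length k")


@dataclass
class MixtureBundle:
    """Everything a test needs: the mixture and its generating truth."""

    X: ExpressionMatrix
    S_true: SignatureMatrix
    A_true: ProportionMatrix
    markers: MarkerSets
    spec: MixtureSpec


def generate_mixture(spec: MixtureSpec) -> MixtureBundle:
    """Draw one seeded mixture with ground truth."""
    rng = np.random.default_rng(spec.seed)
    n, k, p = spec.n_genes, spec.k, spec.p
    gene_ids = [f"g{i + 1}" for i in range(n)]
    sample_ids = [f"s{j + 1}" for j in range(p)]
    type_labels = [f"type_{t + 1}" for t in range(k)]

    S = np.exp(rng.normal(spec.base_log_mean, spec.base_log_sd, size=(n, k)))

    marker_sets: dict[str, list[str]] = {}
    for t in range(k):
        rows = range(t * spec.markers_per_type, (t + 1) * spec.markers_per_type)
        marker_sets[type_labels[t]] = [gene_ids[i] for i in rows]
        for i in rows:
            if spec.exclusive_markers:
                off = np.ones(k, dtype=bool)
                off[t] = False
                S[i, off] = 0.0
            else:
                max_off = np.delete(S[i], t).max()
                if S[i, t] < spec.marker_fold * max_off:
                    S[i, t] = spec.marker_fold * max_off

    alpha = np.ones(k) if spec.dirichlet_alpha is None else np.asarray(spec.dirichlet_alpha)
    A = rng.dirichlet(alpha, size=p).T                # k x p, columns on simplex

    X = S @ A
    if spec.noise_sd > 0:
        X = X * np.exp(rng.normal(0.0, spec.noise_sd, size=X.shape))

    return MixtureBundle(
        X=ExpressionMatrix(X, gene_ids, sample_ids),
        S_true=SignatureMatrix(S, gene_ids, type_labels, lb=0.0, ub=float(S.max())),
        A_true=ProportionMatrix(A, type_labels, sample_ids),
        markers=MarkerSets(marker_sets),
        spec=spec,
    )


_FIXTURE_SPECS: dict[str, MixtureSpec] = {
    # over-determined benchmark: 3 types, 20 samples, 5-fold markers, 10 % noise
    "overdet": MixtureSpec(n_genes=2000, k=3, p=20, markers_per_type=30,
                           marker_fold=5.0, noise_sd=0.1, seed=101),
    # noiseless twin with exclusive markers: Stage I is exact here
    "overdet_noiseless": MixtureSpec(n_genes=2000, k=3, p=20, markers_per_type=30,
                                     marker_fold=5.0, noise_sd=0.0,
                                     exclusive_markers=True, seed=102),
    # under-determined: 4 types, 3 samples, exclusive markers, noiseless
    "underdet": MixtureSpec(n_genes=1000, k=4, p=3, markers_per_type=25,
                            marker_fold=5.0, noise_sd=0.0,
                            exclusive_markers=True, seed=103),
    # model-order selection family (k_true = 3); sweep seeds via with_seed
    "mdl": MixtureSpec(n_genes=2000, k=3, p=20, markers_per_type=30,
                       marker_fold=5.0, noise_sd=0.1, seed=104),
}


def standard_fixtures(names: list[str] | None = None) -> dict[str, MixtureBundle]:
    """The fixed-seed bundles used across the test suite."""
    names = list(_FIXTURE_SPECS) if names is None else names
    return {name: generate_mixture(_FIXTURE_SPECS[name]) for name in names}


def fixture_spec(name: str, seed: int | None = None) -> MixtureSpec:
    """A standard fixture's spec, optionally reseeded (for seed sweeps)."""
    spec = _FIXTURE_SPECS[name]
    return spec if seed is None else replace(spec, seed=seed)
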