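"""Core container types shared across the deconvolution pipeline.

The linear mixing model underlying everything here is ``X = S @ A``:
``X`` is the observed genes-by-samples bulk expression matrix in linear
(non-log) units, ``S`` the unknown genes-by-types signature matrix and
``A`` the unknown types-by-samples mixing-proportion matrix whose columns
live on the probability simplex.  Each container validates the invariants
its matrix must satisfy so that downstream numerics can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MarkerSets",
    "ProportionMatrix",
    "SignatureMatrix",
    "DeconvolutionResult",
    "ValidationError",
    "FormatError",
]


class ValidationError(ValueError):
    """An input value violates a container invariant."""


class FormatError(ValueError):
    """A file or table is structurally malformed."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative linear-scale expression matrix (genes x samples).

    Parameters
    ----------
    values : (n, p) ndarray
        Expression in linear units; all entries finite and >= 0.
    gene_ids, sample_ids : sequences of unique strings
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        n, p = values.shape
        if n < 1 or p < 1:
            raise ValidationError("expression matrix must be at least 1 x 1")
        gene_ids = _check_unique(self.gene_ids, "gene id")
        sample_ids = _check_unique(self.sample_ids, "sample id")
        if len(gene_ids) != n or len(sample_ids) != p:
            raise ValidationError(
                f"shape {values.shape} does not match {len(gene_ids)} gene ids "
                f"and {len(sample_ids)} sample ids"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression for gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        if np.any(values < 0):
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression {values[i, j]} for gene {gene_ids[i]!r}, "
                f"sample {sample_ids[j]!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving the requested order."""
        idx = self.gene_index()
        try:
            rows = [idx[g] for g in gene_ids]
        except KeyError as e:
            raise ValidationError(f"gene {e.args[0]!r} not present in matrix") from None
        return ExpressionMatrix(self.values[rows], list(gene_ids), list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass(frozen=True)
class MarkerSets:
    """Ordered mapping from cell/tissue-type label to its marker gene ids.

    The same container carries cluster subsets in unsupervised mode, where
    label ``t`` holds the genes closest to cluster ``t``'s exemplar.  Lists
    must be non-empty and pairwise disjoint; label order fixes the row
    order of every proportion matrix downstream.
    """

    sets: dict[str, list[str]]

    def __post_init__(self):
        sets = {str(k): [str(g) for g in v] for k, v in self.sets.items()}
        if len(sets) < 2:
            raise ValidationError("need at least 2 type labels")
        seen: dict[str, str] = {}
        for label, genes in sets.items():
            if not genes:
                raise ValidationError(f"type {label!r} has an empty gene list")
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"gene {g!r} listed under both {seen[g]!r} and {label!r}; "
                        "marker sets must be disjoint"
                    )
                seen[g] = label
        object.__setattr__(self, "sets", sets)

    @property
    def k(self) -> int:
        return len(self.sets)

    @property
    def type_labels(self) -> list[str]:
        return list(self.sets.keys())

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.sets.values())

    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.sets.values():
            out.extend(genes)
        return out

    def check_against(self, expr: ExpressionMatrix) -> None:
        present = set(expr.gene_ids)
        for label, genes in self.sets.items():
            missing = [g for g in genes if g not in present]
            if missing:
                raise ValidationError(
                    f"marker genes for type {label!r} absent from matrix: {missing[:5]}"
                )


@dataclass(frozen=True)
class ProportionMatrix:
    """Mixing proportions A (types x samples); columns on the simplex."""

    values: np.ndarray
    type_labels: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        type_labels = _check_unique(self.type_labels, "type label")
        sample_ids = _check_unique(self.sample_ids, "sample id")
        if values.shape != (len(type_labels), len(sample_ids)):
            raise ValidationError("proportion matrix shape does not match labels")
        if np.any(values < -1e-12) or np.any(values > 1 + 1e-12):
            raise ValidationError("proportions must lie in [0, 1]")
        sums = values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            j = int(np.argmax(np.abs(sums - 1.0)))
            raise ValidationError(
                f"proportions of sample {sample_ids[j]!r} sum to {sums[j]:.10g}, not 1"
            )
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))
        object.__setattr__(self, "type_labels", type_labels)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.type_labels, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProportionMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])


@dataclass(frozen=True)
class SignatureMatrix:
    """Type-specific expression S (genes x types) with optional standard errors.

    ``lb``/``ub`` are the expression bounds the estimates were constrained
    to (the minimum and maximum measurable levels by default).
    """

    values: np.ndarray
    gene_ids: list[str]
    type_labels: list[str]
    se: np.ndarray | None = None
    lb: float = -np.inf
    ub: float = np.inf

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        gene_ids = _check_unique(self.gene_ids, "gene id")
        type_labels = _check_unique(self.type_labels, "type label")
        if values.shape != (len(gene_ids), len(type_labels)):
            raise ValidationError("signature matrix shape does not match labels")
        if np.any(values < self.lb - 1e-9) or np.any(values > self.ub + 1e-9):
            raise ValidationError("signature values outside [lb, ub]")
        se = self.se
        if se is not None:
            se = np.asarray(se, dtype=float)
            if se.shape != values.shape:
                raise ValidationError("SE matrix shape must match signature shape")
            if not np.all(np.isfinite(se)) or np.any(se < 0):
                raise ValidationError("SEs must be finite and non-negative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "type_labels", type_labels)
        object.__setattr__(self, "se", se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.type_labels)

    def se_frame(self) -> pd.DataFrame | None:
        if self.se is None:
            return None
        return pd.DataFrame(self.se, index=self.gene_ids, columns=self.type_labels)


@dataclass
class DeconvolutionResult:
    """Bundle of a finished run: proportions, optional signatures, metadata."""

    proportions: ProportionMatrix
    signatures: SignatureMatrix | None = None
    mode: str = "semi"                      # {"semi", "unsupervised"}
    stages: str = "S1"                      # {"S1", "S1S2", "underdetermined"}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("semi", "unsupervised"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.stages not in ("S1", "S1S2", "underdetermined"):
            raise ValidationError(f"unknown stages {self.stages!r}")

    @property
    def k(self) -> int:
        return self.proportions.k
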