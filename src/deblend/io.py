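"""Readers and writers for the tool's tabular formats.

TSV is the canonical on-disk format: first column row labels, header row
column labels, numbers written with 10 significant digits so round-trips
are stable.  GCT 1.2 is accepted on read only.  Marker tables may be TSV
(columns ``gene_id``, ``type_label``) or a JSON mapping label -> gene list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    FormatError,
    MarkerSets,
    ProportionMatrix,
    SignatureMatrix,
    ValidationError,
)

__all__ = [
    "read_expression_tsv",
    "read_marker_table",
    "read_probe_map",
    "read_proportions_tsv",
    "normalize_columns_sum_to_one",
    "write_matrix_tsv",
    "write_proportions_tsv",
    "write_signatures_tsv",
]

_FLOAT_FMT = "%.10g"


def read_expression_tsv(path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-by-samples expression table.

    ``dialect`` is ``"tsv"`` (plain table, first column gene ids) or
    ``"gct"`` (GCT 1.2: two header lines, then Name/Description columns).
    Values must parse as finite non-negative reals.
    """
    path = Path(path)
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"{path}: not a GCT 1.2 file (first line {version!r})")
            fh.readline()  # dimensions line; shapes re-validated below
            df = pd.read_csv(fh, sep="\t", dtype=str)
        if df.columns[0].lower() not in ("name", "gene_id") or len(df.columns) < 3:
            raise FormatError(f"{path}: malformed GCT header")
        df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    elif dialect == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise FormatError(f"{path}: duplicated sample ids in header")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _to_expression(df, path)


def _to_expression(df: pd.DataFrame, path) -> ExpressionMatrix:
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicated sample ids in header")
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()][0]
        raise FormatError(f"{path}: duplicated gene id {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValidationError(
                f"{path}: non-numeric value for gene {bad!r}, sample {col!r}"
            ) from None
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"{path}: negative expression {values[i, j]} for gene "
            f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(values, gene_ids, sample_ids)


def read_marker_table(path) -> MarkerSets:
    """Read marker sets from TSV (gene_id, type_label) or JSON.

    Type labels keep first-appearance order; that order fixes the row
    order of the estimated proportion matrix.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: JSON marker file must map label -> gene list")
        return MarkerSets({str(k): list(v) for k, v in raw.items()})
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "gene_id" in cols and "type_label" in cols:
        gene_col = df.columns[cols.index("gene_id")]
        label_col = df.columns[cols.index("type_label")]
    elif len(df.columns) == 2:
        gene_col, label_col = df.columns
    else:
        raise FormatError(f"{path}: expected columns gene_id, type_label")
    sets: dict[str, list[str]] = {}
    for gene, label in zip(df[gene_col], df[label_col]):
        sets.setdefault(str(label), []).append(str(gene))
    return MarkerSets(sets)


def read_probe_map(path) -> dict[str, str]:
    """Read a probe -> gene map (TSV columns probe_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "probe_id" in cols and "gene_id" in cols:
        pc = df.columns[cols.index("probe_id")]
        gc = df.columns[cols.index("gene_id")]
    elif len(df.columns) == 2:
        pc, gc = df.columns
    else:
        raise FormatError(f"{path}: expected columns probe_id, gene_id")
    return dict(zip(df[pc].astype(str), df[gc].astype(str)))


def read_proportions_tsv(path) -> ProportionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProportionMatrix.from_frame(df)


def normalize_columns_sum_to_one(values: np.ndarray) -> np.ndarray:
    """Rescale each column of a non-negative matrix to sum to one.

    This is the calibration applied to every estimated proportion matrix:
    whenever a sample's proportions do not already total one they are
    scaled accordingly.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("cannot normalize a matrix with negative entries")
    sums = values.sum(axis=0)
    zero = np.where(sums == 0)[0]
    if zero.size:
        raise ValidationError(
            f"sample column {int(zero[0])} is all zero; proportions undefined"
        )
    return values / sums


def write_matrix_tsv(frame: pd.DataFrame, path, index_label: str | None = None) -> None:
    """Write a labeled matrix as TSV (row labels first, 10 sig. digits)."""
    for label in list(frame.index) + list(frame.columns):
        if "\t" in str(label) or "\n" in str(label):
            raise FormatError(f"label {label!r} contains a tab/newline; refusing to write")
    frame.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def write_proportions_tsv(prop: ProportionMatrix, path) -> None:
    write_matrix_tsv(prop.to_frame(), path, index_label="type_label")


def write_signatures_tsv(sig: SignatureMatrix, path) -> None:
    """Write signatures; SEs, when present, go to a sibling ``.se.tsv`` file."""
    path = Path(path)
    write_matrix_tsv(sig.to_frame(), path, index_label="gene_id")
    if sig.se is not None:
        se_path = path.with_suffix(path.suffix + ".se.tsv") if path.suffix != ".tsv" \
            else path.with_name(path.stem + ".se.tsv")
        write_matrix_tsv(sig.se_frame(), se_path, index_label="gene_id")


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    write_matrix_tsv(expr.to_frame(), path, index_label="gene_id")
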