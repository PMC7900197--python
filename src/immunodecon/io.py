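"""Readers and writers for expression matrices, clinical tables and results.

File dialect: expression matrices are tab-delimited UTF-8 text, genes as
rows, first column gene identifiers, first row column labels (the LM22 /
UCSC Xena convention). Clinical tables are CSV. Fitted models and test
results are JSON.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    MixtureProfile,
    ProportionEstimate,
    SignatureMatrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_expression_matrix",
    "read_clinical",
    "write_clinical",
    "align_genes",
    "write_proportions",
    "read_proportions",
    "write_json",
    "read_json",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending row/column."""


_DIAG_COLS = ["rmse", "pearson_r", "p_value", "nu_selected", "degenerate"]


def _parse_numeric(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce every cell to float, raising ParseError with coordinates."""
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if out.isna().to_numpy().any():
        rows, cols = np.nonzero(out.isna().to_numpy())
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return out


def read_expression_matrix(
    path: Union[str, os.PathLike], kind: str
) -> Union[SignatureMatrix, MixtureProfile]:
    """Read a tab-delimited genes-by-columns expression matrix.

    ``kind`` is ``"signature"`` or ``"mixture"``. Duplicate gene rows are
    collapsed by their arithmetic mean with a logged warning; file order is
    preserved otherwise.
    """
    if kind not in ("signature", "mixture"):
        raise ValueError(f"kind must be 'signature' or 'mixture', got {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ParseError(f"{path}: matrix has no data columns or rows")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate column labels in header")
    df = _parse_numeric(df, str(path))
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene row(s) collapsed by mean", path, n_dup
        )
        df = df.groupby(level=0, sort=False).mean()
    cls = SignatureMatrix if kind == "signature" else MixtureProfile
    return cls(df)


def read_clinical(path: Union[str, os.PathLike]) -> ClinicalTable:
    """Read the clinical covariate CSV (first column sample_id)."""
    df = pd.read_csv(path, index_col=0)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: Union[str, os.PathLike]) -> None:
    table.data.to_csv(path, index_label="sample_id")


def align_genes(
    sig: SignatureMatrix, mix: MixtureProfile
) -> tuple[SignatureMatrix, MixtureProfile]:
    """Restrict both matrices to their shared genes, in signature order.

    Idempotent; raises on an empty intersection. The intersection size is
    logged so sample/gene attrition is always visible.
    """
    shared = sig.gene_ids[sig.gene_ids.isin(mix.gene_ids)]
    if len(shared) == 0:
        raise ValueError("signature and mixture share no genes")
    logger.info(
        "align_genes: %d shared genes (signature %d, mixture %d)",
        len(shared), len(sig.gene_ids), len(mix.gene_ids),
    )
    return (
        SignatureMatrix(sig.data.loc[shared]),
        MixtureProfile(mix.data.loc[shared]),
    )


def write_proportions(
    est: ProportionEstimate, path: Union[str, os.PathLike]
) -> None:
    """Write a ProportionEstimate as one tab-delimited table.

    Fraction columns come first, diagnostic columns last; round-trips via
    :func:`read_proportions` to full float precision.
    """
    out = pd.concat([est.fractions, est.diagnostics[_DIAG_COLS]], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id", float_format="%.17g")


def read_proportions(path: Union[str, os.PathLike]) -> ProportionEstimate:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in _DIAG_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing diagnostic columns {missing}")
    diag = df[_DIAG_COLS].copy()
    diag["degenerate"] = diag["degenerate"].astype(bool)
    fractions = df.drop(columns=_DIAG_COLS)
    return ProportionEstimate(fractions=fractions, diagnostics=diag)


def write_json(obj, path: Union[str, os.PathLike]) -> None:
    """Write a model/result object (anything with ``to_dict``) as JSON."""
    payload = obj.to_dict() if hasattr(obj, "to_dict") else obj
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_json(path: Union[str, os.PathLike]):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
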