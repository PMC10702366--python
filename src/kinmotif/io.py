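"""Delimited-text readers/writers and input validation.

All tables are tab-separated with headers.  Quantification tables carry row
ids in the first column and one column per reporter channel; missing values
are empty cells.  The impurity matrix is a square table with channel headers.
"""

from __future__ import annotations

import os
from collections.abc import Mapping

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A delimited input violates its documented schema."""


def _read(path, **kwargs) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse as TSV ({exc})") from exc


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_quant_table(path) -> pd.DataFrame:
    df = _read(path, index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"{path}: duplicate row ids, e.g. {dups}")
    if (df.fillna(0).to_numpy(dtype=float) < 0).any():
        raise SchemaError(f"{path}: negative abundances")
    return df


def write_quant_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    df = _read(path)
    _require_columns(df, ["channel", "genotype", "treatment"], path)
    if df["channel"].duplicated().any():
        lines = (df.index[df["channel"].duplicated()] + 2).tolist()
        raise SchemaError(f"{path}: duplicate channel ids at line(s) {lines}")
    return df


def read_sites(path) -> pd.DataFrame:
    df = _read(path, keep_default_na=False)
    _require_columns(df, ["site_id", "protein_id", "position", "flank"], path)
    if df["site_id"].duplicated().any():
        lines = (df.index[df["site_id"].duplicated()] + 2).tolist()
        raise SchemaError(f"{path}: duplicate site ids at line(s) {lines}")
    return df


def read_records(path) -> pd.DataFrame:
    df = _read(path)
    _require_columns(df, ["record_id", "site_id", "isolation_specificity",
                          "summed_sn", "n_missing_channels"], path)
    return df


def read_impurity(path) -> np.ndarray:
    df = _read(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SchemaError(f"{path}: impurity matrix must be square, got {df.shape}")
    return df.to_numpy(dtype=float)


def write_impurity(matrix: np.ndarray, channels, path) -> None:
    pd.DataFrame(matrix, index=list(channels), columns=list(channels)).to_csv(path, sep="\t")


def validate_inputs(paths: Mapping[str, str]) -> list[str]:
    """Cross-check a set of input files without mutating anything.

    Recognised keys: quant, records, sites, design, library, impurity,
    protein.  Returns a list of human-readable diagnostics (empty = clean).
    """
    diagnostics: list[str] = []
    loaded: dict[str, object] = {}
    readers = {
        "quant": read_quant_table, "protein": read_quant_table,
        "records": read_records, "sites": read_sites,
        "design": read_design, "impurity": read_impurity,
    }
    for key, path in paths.items():
        if key == "library":
            from .library import KinaseLibrary
            reader = KinaseLibrary.from_tsv
        else:
            reader = readers.get(key)
        if reader is None:
            diagnostics.append(f"unrecognised input kind {key!r}")
            continue
        try:
            loaded[key] = reader(path)
        except (OSError, ValueError) as exc:
            diagnostics.append(f"{key}: {exc}")

    design = loaded.get("design")
    quant = loaded.get("quant")
    if design is not None and quant is not None:
        missing = [c for c in design["channel"] if c not in quant.columns]
        if missing:
            diagnostics.append(f"design channels absent from quant table: {missing}")
    prot = loaded.get("protein")
    if prot is not None and quant is not None:
        if list(prot.columns) != list(quant.columns):
            diagnostics.append("protein and quant tables have different channel sets")
    sites = loaded.get("sites")
    if sites is not None and quant is not None:
        unknown = [s for s in quant.index if s not in set(sites["site_id"])]
        if unknown:
            diagnostics.append(
                f"{len(unknown)} quant row id(s) missing from site table, e.g. {unknown[:3]}")
    return diagnostics
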