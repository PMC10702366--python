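"""TMT reporter-level quantification processing.

The cascade mirrors standard isobaric-labelling practice: invert the reagent
isotopic-impurity mixing to recover per-channel signal, reject PSMs failing
quality thresholds (co-isolation, summed signal-to-noise, missing channels,
phosphosite localization confidence), sum records to protein or site rows,
scale channels to equal total loading, optionally divide phosphosite profiles
by the parent protein's relative profile, and median-center log2 columns.

Quantification tables are plain pandas DataFrames: rows = site/protein ids,
columns = channel ids, NaN = missing.  Missing values are never imputed.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from collections.abc import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fixed audit order in which rejection reasons are reported
REJECT_REASONS = ("missing_channels", "isolation_specificity", "summed_sn",
                  "localization", "no_quant")


def channel_columns(df: pd.DataFrame) -> list[str]:
    """Columns named like reporter channels (ch01, ch02, ...)."""
    return [c for c in df.columns if re.fullmatch(r"ch\d+", str(c))]


@dataclasses.dataclass(frozen=True)
class FilterPolicy:
    """PSM quality thresholds.

    max_missing_channels is the largest number of missing reporter channels
    still kept (phospho: 11 of 16, i.e. reject >= 12 missing; total proteome:
    7, i.e. reject >= 8).  min_localization_score of None disables the
    site-localization filter (protein-level data).
    """

    min_isolation_specificity: float = 0.8
    min_summed_sn: float = 160.0
    max_missing_channels: int = 11
    min_localization_score: float | None = 13.0
    require_single_phospho: bool = False

    def __post_init__(self):
        if not 0.0 <= self.min_isolation_specificity <= 1.0:
            raise ValueError("min_isolation_specificity must be in [0, 1]")
        if not np.isfinite(self.min_summed_sn):
            raise ValueError("min_summed_sn must be finite")

    @classmethod
    def phospho(cls) -> "FilterPolicy":
        return cls(min_isolation_specificity=0.8, min_summed_sn=160.0,
                   max_missing_channels=11, min_localization_score=13.0,
                   require_single_phospho=True)

    @classmethod
    def total_proteome(cls) -> "FilterPolicy":
        return cls(min_isolation_specificity=0.7, min_summed_sn=160.0,
                   max_missing_channels=7, min_localization_score=None)


def validate_impurity(matrix: np.ndarray) -> np.ndarray:
    """Check an impurity matrix: square, nonnegative, positive diagonal,
    columns summing to <= 1 (each column = where one reagent's signal lands)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"impurity matrix must be square, got shape {m.shape}")
    if (m < 0).any():
        raise ValueError("impurity matrix entries must be nonnegative")
    if (np.diag(m) <= 0).any():
        raise ValueError("impurity matrix diagonal must be positive")
    if (m.sum(axis=0) > 1.0 + 1e-9).any():
        raise ValueError("impurity matrix columns must sum to <= 1")
    return m


def correct_impurities(raw: Sequence[float], impurity: np.ndarray,
                       clamp_tol: float = 1e-6) -> np.ndarray:
    """Invert the impurity mixing model: solve impurity @ x = raw.

    Small negative solutions (numerical noise, > -clamp_tol relative to the
    total signal) are clamped to 0; larger negatives are left for the caller
    to inspect.  NaN (missing) entries propagate as NaN in the result mask.
    """
    m = validate_impurity(impurity)
    raw = np.asarray(raw, dtype=float)
    if raw.shape[-1] != m.shape[0]:
        raise ValueError(f"vector length {raw.shape[-1]} != matrix dimension {m.shape[0]}")
    missing = np.isnan(raw)
    filled = np.where(missing, 0.0, raw)
    x = np.linalg.solve(m, filled.T).T  # LinAlgError propagates on singular matrices
    scale = max(1.0, float(np.abs(filled).sum(axis=-1).max() if filled.size else 1.0))
    tiny = (x < 0) & (x > -clamp_tol * scale)
    x[tiny] = 0.0
    x[missing] = np.nan
    return x


def correct_record_table(records: pd.DataFrame, impurity: np.ndarray) -> pd.DataFrame:
    """Apply impurity correction to every record's channel columns; recomputes
    summed_sn from the corrected intensities."""
    cols = channel_columns(records)
    out = records.copy()
    out[cols] = correct_impurities(records[cols].to_numpy(dtype=float), impurity)
    if "summed_sn" in out.columns:
        out["summed_sn"] = np.nansum(out[cols].to_numpy(dtype=float), axis=1)
    return out


def filter_records(records: pd.DataFrame, policy: FilterPolicy
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (kept, rejected-with-reason).

    Exclusion rules are strict as stated: isolation specificity < threshold,
    summed S:N < threshold (exactly 160 is kept), missing channels exceeding
    the kept maximum, localization score < threshold.  A record failing
    several rules is tagged with the first failing reason in REJECT_REASONS
    order.  ``no_quant`` marks records with no reporter quantification at all.
    """
    if records.empty:
        empty = records.copy()
        rej = records.copy()
        rej["reject_reason"] = pd.Series(dtype=object)
        return empty, rej
    cols = channel_columns(records)
    n_missing = records["n_missing_channels"] if "n_missing_channels" in records.columns \
        else records[cols].isna().sum(axis=1)

    reason = pd.Series("", index=records.index, dtype=object)

    def tag(mask: pd.Series, why: str) -> None:
        reason[(reason == "") & mask.astype(bool)] = why

    tag(n_missing > policy.max_missing_channels, "missing_channels")
    tag(records["isolation_specificity"] < policy.min_isolation_specificity,
        "isolation_specificity")
    tag(records["summed_sn"] < policy.min_summed_sn, "summed_sn")
    if policy.min_localization_score is not None and "localization_score" in records.columns:
        tag(records["localization_score"] < policy.min_localization_score, "localization")
    if cols:
        tag(records[cols].isna().all(axis=1) | records["summed_sn"].isna(), "no_quant")

    kept = records[reason == ""].copy()
    rejected = records[reason != ""].copy()
    rejected["reject_reason"] = reason[reason != ""]
    return kept, rejected


def collapse_records(records: pd.DataFrame, key: str) -> pd.DataFrame:
    """Sum record reporter intensities into one row per ``key`` value.

    Missing channels contribute 0; a cell is missing only when every
    contributing record was missing there (pandas min_count semantics).
    Records with no key assignment are skipped with a logged warning.
    """
    cols = channel_columns(records)
    has_key = records[key].notna() & (records[key] != "")
    n_skipped = int((~has_key).sum())
    if n_skipped:
        logger.warning("collapse: skipped %d records with no %s assignment", n_skipped, key)
    grouped = records.loc[has_key].groupby(key, sort=True)[cols].sum(min_count=1)
    grouped.index.name = key
    return grouped


def collapse_to_protein(records: pd.DataFrame) -> pd.DataFrame:
    """Protein rows = elementwise sums of matching records' intensities."""
    return collapse_records(records, "protein_id")


def collapse_to_site(records: pd.DataFrame) -> pd.DataFrame:
    """Phosphosite rows = elementwise sums of matching records' intensities."""
    return collapse_records(records, "site_id")


def normalize_equal_loading(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each channel so all column sums equal their mean (equal loading).

    Scale-preserving: the grand total of the matrix is unchanged.
    """
    sums = table.sum(axis=0, skipna=True)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for channel(s): {list(zero.index)}")
    return table * (sums.mean() / sums)


def normalize_phospho_to_protein(phospho: pd.DataFrame, protein: pd.DataFrame,
                                 site_to_protein: pd.Series | None = None
                                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each phosphosite profile by its protein's relative channel profile.

    The relative profile is the protein row divided by its (non-missing) row
    mean, so a flat protein leaves the site unchanged.  Sites whose protein is
    absent (or has zero/undefined mean) pass through unchanged and are flagged.
    Channels where the protein value is missing use a neutral factor of 1.
    Returns (normalized table, boolean 'no protein match' flags).
    """
    if list(phospho.columns) != list(protein.columns):
        raise ValueError("phospho and protein tables must share the channel set")
    if site_to_protein is None:
        site_to_protein = pd.Series(
            [str(s).split("_", 1)[0] for s in phospho.index], index=phospho.index)
    out = phospho.copy()
    flagged = pd.Series(False, index=phospho.index)
    prot_means = protein.mean(axis=1, skipna=True)
    for site in phospho.index:
        prot = site_to_protein.get(site)
        if prot not in protein.index or not prot_means[prot] > 0:
            flagged[site] = True
            continue
        rel = (protein.loc[prot] / prot_means[prot]).fillna(1.0)
        out.loc[site] = phospho.loc[site] / rel
    return out, flagged


def median_center(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each column's median (table assumed on log2 scale)."""
    medians = table.median(axis=0, skipna=True)
    bad = medians[medians.isna()]
    if len(bad):
        raise ValueError(f"all-missing column(s): {list(bad.index)}")
    return table - medians


def log2_table(table: pd.DataFrame) -> pd.DataFrame:
    """log2-transform a linear-scale table; nonpositive entries become missing."""
    vals = table.to_numpy(dtype=float)
    out = np.full(vals.shape, np.nan)
    np.log2(vals, out=out, where=vals > 0)
    return pd.DataFrame(out, index=table.index, columns=table.columns)
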