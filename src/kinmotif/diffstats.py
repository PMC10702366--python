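"""Per-site differential statistics between sample groups.

Each phosphosite is contrasted between two channel groups defined over the
experimental design (genotype x treatment): log2 fold change is the
difference of group means on the log2 scale, the P value comes from a Welch
(unequal-variance) two-sample t-test on log2 values, and Benjamini-Hochberg
adjustment gives per-contrast FDRs.  Sites are then classified into the
strata used by the kinase-motif enrichment: down/up-regulated
(|log2fc| >= 1 and FDR <= 0.1), unregulated (|log2fc| < 1 and FDR > 0.1),
and an intermediate remainder that belongs to neither enrichment stratum.
Tiers follow the P-value conventions of the volcano plots (tier 1: P < 0.01,
tier 2: P < 0.05, both at the twofold cutoff).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REGULATION_LEVELS = ("down", "up", "unregulated", "intermediate")
TIER_LEVELS = ("tier1", "tier2", "none")

#: smallest representable positive p, assigned to zero-variance unequal-mean sites
P_FLOOR = float(np.nextafter(0, 1))


@dataclasses.dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint channel-group selectors over design factors.

    Each selector maps a design column (genotype / treatment) to a required
    value or collection of values; channels matching every entry are selected.
    """

    numerator: Mapping[str, object]
    denominator: Mapping[str, object]
    name: str = "contrast"

    def _select(self, design: pd.DataFrame, selector: Mapping[str, object]) -> list[str]:
        mask = pd.Series(True, index=design.index)
        for factor, value in selector.items():
            if factor not in design.columns:
                raise ValueError(f"unknown design factor {factor!r}")
            values = value if isinstance(value, (list, tuple, set, frozenset)) else [value]
            mask &= design[factor].isin(list(values))
        return list(design.loc[mask, "channel"])

    def channels(self, design: pd.DataFrame) -> tuple[list[str], list[str]]:
        num = self._select(design, self.numerator)
        den = self._select(design, self.denominator)
        if not num or not den:
            raise ValueError(f"contrast {self.name!r}: empty channel group")
        if set(num) & set(den):
            raise ValueError(f"contrast {self.name!r}: overlapping channel groups")
        return num, den


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    required = {"channel", "genotype", "treatment"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["channel"].duplicated().any():
        dups = design.loc[design["channel"].duplicated(), "channel"].tolist()
        raise ValueError(f"duplicate design channels: {dups}")
    return design


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised NaN-aware Welch t-test over rows. Returns (t, p, zero_var)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = np.sum(~np.isnan(x), axis=1)
        n2 = np.sum(~np.isnan(y), axis=1)
        m1 = np.nanmean(x, axis=1)
        m2 = np.nanmean(y, axis=1)
        v1 = np.nanvar(x, axis=1, ddof=1)
        v2 = np.nanvar(y, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        d = m1 - m2
        t = d / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = se2 == 0
    # degenerate variance: identical means -> no evidence; unequal -> floor p
    signed_inf = np.where(d > 0, np.inf, np.where(d < 0, -np.inf, 0.0))
    t = np.where(zero_var, signed_inf, t)
    p = np.where(zero_var, np.where(d == 0, 1.0, P_FLOOR), p)
    return t, p, zero_var


def contrast_stats(table: pd.DataFrame, design: pd.DataFrame, contrast: ContrastSpec,
                   log2_input: bool = False, flanks: pd.Series | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-site log2fc and Welch-t P values for one contrast.

    ``table`` is sites x channels; linear scale by default (log2 applied here,
    nonpositive values treated as missing), or already-log2 with
    ``log2_input=True``.  Sites with fewer than two non-missing values on
    either side are skipped; returns (records, skipped-with-reason).
    """
    design = validate_design(design)
    num, den = contrast.channels(design)
    for ch in num + den:
        if ch not in table.columns:
            raise ValueError(f"design channel {ch!r} absent from quant table")
    if log2_input:
        vals = table
    else:
        from .quant import log2_table
        vals = log2_table(table)
    x = vals[num].to_numpy(dtype=float)
    y = vals[den].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(x), axis=1)
    n2 = np.sum(~np.isnan(y), axis=1)
    valid = (n1 >= 2) & (n2 >= 2)

    t, p, zero_var = _welch(x[valid], y[valid])
    with np.errstate(invalid="ignore"):
        log2fc = np.nanmean(x[valid], axis=1) - np.nanmean(y[valid], axis=1)
    records = pd.DataFrame({
        "log2fc": log2fc,
        "t_stat": t,
        "p_value": p,
        "n_num": n1[valid],
        "n_den": n2[valid],
        "zero_variance": zero_var,
    }, index=table.index[valid])
    records.index.name = "site_id"
    if flanks is not None:
        records.insert(0, "flank", flanks.reindex(records.index))

    skipped = pd.DataFrame({
        "n_num": n1[~valid], "n_den": n2[~valid],
        "reason": "insufficient_replicates",
    }, index=table.index[~valid])
    skipped.index.name = "site_id"
    return records, skipped


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_fdr(records: pd.DataFrame) -> pd.DataFrame:
    """Append a BH-adjusted ``fdr`` column for the contrast's p-values."""
    out = records.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out


def classify_sites(records: pd.DataFrame, down_up_fc_min: float = 1.0,
                   reg_fdr_max: float = 0.1, unreg_fc_max: float = 1.0,
                   unreg_fdr_min: float = 0.1, tier1_p: float = 0.01,
                   tier2_p: float = 0.05) -> pd.DataFrame:
    """Assign regulation strata and significance tiers.

    down: log2fc <= -fc_min and fdr <= reg_fdr_max;  up symmetric;
    unregulated: |log2fc| < unreg_fc_max and fdr > unreg_fdr_min;
    everything else is intermediate (member of neither enrichment stratum).
    Boundary conventions are exactly the printed inequalities.
    """
    out = records.copy()
    fc = out["log2fc"]
    fdr = out["fdr"]
    p = out["p_value"]

    regulation = pd.Series("intermediate", index=out.index, dtype=object)
    regulation[(fc <= -down_up_fc_min) & (fdr <= reg_fdr_max)] = "down"
    regulation[(fc >= down_up_fc_min) & (fdr <= reg_fdr_max)] = "up"
    regulation[(fc.abs() < unreg_fc_max) & (fdr > unreg_fdr_min)] = "unregulated"
    out["regulation"] = regulation

    tier = pd.Series("none", index=out.index, dtype=object)
    tier[(fc.abs() >= down_up_fc_min) & (p < tier2_p)] = "tier2"
    tier[(fc.abs() >= down_up_fc_min) & (p < tier1_p)] = "tier1"
    out["tier"] = tier
    return out


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """log2fc vs -log10 P table for volcano plotting."""
    out = records[["log2fc", "p_value"]].copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p_value"])
    return out
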