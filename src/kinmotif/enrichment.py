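"""Kinase-motif enrichment and position-residue motif statistics.

For every kinase, a 2x2 table counts how often it is among the predicted
(top-k) kinases for down- (or up-) regulated sites versus unregulated sites.
Over-representation among regulated sites is tested with a one-sided Fisher
exact test (hypergeometric upper tail), BH-adjusted across kinases within
each side.  Kinases significant on both sides are excluded; for the rest the
more significant side is selected and plotted as log2 predicted-fraction
ratio vs -log10 adjusted P.

pLogo-style motif statistics: for each flank position and residue, the signed
log10 binomial tail probability of the foreground count given the background
residue frequency (positive = over-represented, negative = depleted).
"""

from __future__ import annotations

import math
from collections.abc import Collection, Mapping
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust
from .library import AMINO_ACIDS, CENTER_INDEX, FLANK_POSITIONS, PAD, validate_flank

_LN10 = math.log(10.0)


class ContingencyTable(NamedTuple):
    """a/b: regulated sites predicted / not; c/d: unregulated predicted / not."""

    a: int
    b: int
    c: int
    d: int


def _predicted_sites(predictions, kinase: str) -> set:
    """Sites for which ``kinase`` is in the prediction set.

    ``predictions`` is either a boolean sites x kinases DataFrame or a
    mapping site -> collection of predicted kinase ids.
    """
    if isinstance(predictions, pd.DataFrame):
        if kinase not in predictions.columns:
            raise ValueError(f"unknown kinase id {kinase!r}")
        col = predictions[kinase].astype(bool)
        return set(predictions.index[col])
    return {site for site, kins in predictions.items() if kinase in kins}


def build_table(kinase: str, predictions, regulated: Collection,
                unregulated: Collection) -> ContingencyTable:
    """Count predicted/not-predicted sites within the two strata."""
    reg = set(regulated)
    unreg = set(unregulated)
    overlap = reg & unreg
    if overlap:
        raise ValueError(f"regulated and unregulated strata overlap: {sorted(overlap)[:5]}")
    hits = _predicted_sites(predictions, kinase)
    a = len(reg & hits)
    c = len(unreg & hits)
    return ContingencyTable(a, len(reg) - a, c, len(unreg) - c)


def fisher_greater(table: ContingencyTable) -> float:
    """One-sided Fisher exact P of over-representation among regulated sites.

    P(X >= a) for X hypergeometric with the table's margins; degenerate
    margins (empty stratum or no predictions) give p = 1 by convention.
    """
    a, b, c, d = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be nonnegative")
    n_reg = a + b
    n_pred = a + c
    total = a + b + c + d
    if n_reg == 0 or n_pred == 0 or a == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, total, n_pred, n_reg))


def enrich_kinases(predictions: pd.DataFrame | Mapping, kinases: Collection[str],
                   down: Collection, up: Collection, unregulated: Collection,
                   alpha: float = 0.1) -> pd.DataFrame:
    """Full per-kinase enrichment table for both regulation sides.

    BH adjustment is applied across kinases separately within the down and up
    analyses.  Kinases significant (q <= alpha) on both sides are excluded;
    otherwise the side with the smaller adjusted P is selected (tie -> down)
    and the scatter coordinates are emitted for it.
    """
    kinases = sorted(kinases)
    rows = []
    for kin in kinases:
        t_down = build_table(kin, predictions, down, unregulated)
        t_up = build_table(kin, predictions, up, unregulated)
        rows.append((kin, *t_down, *t_up, fisher_greater(t_down), fisher_greater(t_up)))
    table = pd.DataFrame(rows, columns=[
        "kinase", "a_down", "b_down", "c_down", "d_down",
        "a_up", "b_up", "c_up", "d_up", "p_down", "p_up",
    ]).set_index("kinase")
    table["q_down"] = bh_adjust(table["p_down"].to_numpy())
    table["q_up"] = bh_adjust(table["p_up"].to_numpy())
    excluded, side, final_q = select_side(
        table["q_down"].to_numpy(), table["q_up"].to_numpy(), alpha)
    table["excluded"] = excluded
    table["side"] = side
    table["final_q"] = final_q

    ratios = []
    for kin in table.index:
        r = table.loc[kin]
        if r["side"] == "up":
            ct = ContingencyTable(r["a_up"], r["b_up"], r["c_up"], r["d_up"])
        else:
            ct = ContingencyTable(r["a_down"], r["b_down"], r["c_down"], r["d_down"])
        ratios.append(log2_frequency_ratio(ct))
    table["log2_freq_ratio"] = ratios
    with np.errstate(divide="ignore"):
        table["neg_log10_final_q"] = -np.log10(table["final_q"])
    return table


def select_side(q_down: np.ndarray, q_up: np.ndarray, alpha: float = 0.1
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dual-side exclusion and most-significant-side selection.

    A kinase significant (q <= alpha) on both sides is excluded (side
    'none', final_q NaN); otherwise the side with the smaller adjusted P is
    selected, ties resolving to 'down'.  Returns (excluded, side, final_q).
    """
    q_down = np.asarray(q_down, dtype=float)
    q_up = np.asarray(q_up, dtype=float)
    excluded = (q_down <= alpha) & (q_up <= alpha)
    side = np.where(excluded, "none", np.where(q_down <= q_up, "down", "up"))
    final_q = np.where(excluded, np.nan, np.minimum(q_down, q_up))
    return excluded, side, final_q


def log2_frequency_ratio(table: ContingencyTable) -> float:
    """log2 of predicted-fraction ratio (regulated vs unregulated).

    A 0.5 pseudo-count (Haldane style, all four cells) is used whenever any
    cell or margin is zero, keeping the ratio finite.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, c) == 0 or a + b == 0 or c + d == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log2((a / (a + b)) / (c / (c + d))))


def finalize_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Scatter table (Fig-style) of non-excluded kinases: effect size vs
    -log10 adjusted P for the selected side."""
    keep = table[~table["excluded"]]
    return keep[["side", "final_q", "log2_freq_ratio", "neg_log10_final_q"]].copy()


def plogo_stats(foreground, background, pseudocount: float = 0.5) -> pd.DataFrame:
    """Signed log10 binomial tail statistic per flank position and residue.

    Background probability p of residue r at position j is its background
    frequency with ``pseudocount`` added per residue.  With k foreground
    occurrences among n foreground flanks (non-pad at that position):
    height = -log10 P(Bin(n, p) >= k) when enriched (k/n > p), else
    +log10 P(Bin(n, p) <= k) (negative, depletion).
    """
    fg = [validate_flank(f) for f in foreground]
    bg = [validate_flank(f) for f in background]
    if not fg:
        raise ValueError("empty foreground set")
    if not bg:
        raise ValueError("empty background set")
    if not 0.0 < pseudocount:
        raise ValueError("pseudocount must be positive")

    rows = []
    for pos in FLANK_POSITIONS:
        col = pos + CENTER_INDEX
        fg_res = [f[col] for f in fg if f[col] != PAD]
        bg_res = [f[col] for f in bg if f[col] != PAD]
        n = len(fg_res)
        denom = len(bg_res) + pseudocount * len(AMINO_ACIDS)
        for aa in AMINO_ACIDS:
            p = (bg_res.count(aa) + pseudocount) / denom
            k = fg_res.count(aa)
            if n == 0:
                height = 0.0
            elif k / n > p:
                height = -stats.binom.logsf(k - 1, n, p) / _LN10
            else:
                height = stats.binom.logcdf(k, n, p) / _LN10
            rows.append((pos, aa, k, n, p, float(height)))
    return pd.DataFrame(rows, columns=["position", "residue", "k", "n", "p", "height"])
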