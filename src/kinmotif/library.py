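"""Kinase substrate-motif scoring with position-specific scoring matrices (PSSMs).

A serine/threonine kinase's substrate preference is summarised as a PSSM: for
each flanking position -5..-1,+1..+5 around the phosphoacceptor, a probability
distribution over the 20 amino acids.  A candidate phosphosite is represented
by its 11-residue flank (center = phosphorylated S/T) and scored against each
kinase as the log2-odds of the observed flanking residues relative to a uniform
1/20 background.  Raw scores are converted to percentiles against a per-kinase
background score distribution, kinases are ranked per site, and the top-k
kinases are called "biochemically predicted" for that site.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
FLANK_POSITIONS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
FLANK_LENGTH = 11
CENTER_INDEX = 5

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_N_AA = len(AMINO_ACIDS)


class NotScoreableError(ValueError):
    """Raised for sites whose central residue is not a phospho-accepting S/T."""


def validate_flank(flank: str) -> str:
    """Validate an 11-mer flank string; returns the uppercased flank.

    Rules: length exactly 11; center in {S, T}; characters drawn from the
    20-letter amino-acid alphabet plus ``_`` padding; padding only contiguous
    at the ends (an interior ``_`` indicates a malformed window).
    """
    if not isinstance(flank, str) or len(flank) != FLANK_LENGTH:
        raise ValueError(f"flank must be a string of length {FLANK_LENGTH}, got {flank!r}")
    flank = flank.upper()
    if flank[CENTER_INDEX] not in "ST":
        raise NotScoreableError(
            f"central residue {flank[CENTER_INDEX]!r} is not S/T; only Ser/Thr sites are scoreable"
        )
    for ch in flank:
        if ch != PAD and ch not in _AA_INDEX:
            raise ValueError(f"residue {ch!r} outside the amino-acid alphabet")
    if PAD in flank.strip(PAD):
        raise ValueError(f"interior padding in flank {flank!r}")
    return flank


def extract_flank(sequence: str, position: int) -> str:
    """Extract the +/-5 flank around a 1-based S/T position of a protein sequence.

    Out-of-range positions at the termini are padded with ``_``.
    """
    sequence = sequence.upper()
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] not in "ST":
        raise NotScoreableError(
            f"residue {sequence[position - 1]!r} at position {position} is not S/T"
        )
    i = position - 1
    left = sequence[max(0, i - 5): i]
    right = sequence[i + 1: i + 6]
    flank = PAD * (5 - len(left)) + left + sequence[i] + right + PAD * (5 - len(right))
    return validate_flank(flank)


@dataclasses.dataclass
class PSSM:
    """Per-kinase residue preference matrix over flank positions -5..+5 (no 0).

    matrix: DataFrame indexed by FLANK_POSITIONS with one column per residue;
    each row is a probability distribution (all entries > 0, sums to 1).
    background: optional sample of raw scores used for percentile conversion.
    """

    kinase: str
    matrix: pd.DataFrame
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = self.matrix.reindex(index=list(FLANK_POSITIONS), columns=list(AMINO_ACIDS))
        if m.isna().any().any():
            raise ValueError(
                f"PSSM {self.kinase!r}: matrix must cover positions {FLANK_POSITIONS} "
                f"and residues {AMINO_ACIDS}"
            )
        vals = m.to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError(f"PSSM {self.kinase!r}: all probabilities must be > 0")
        sums = vals.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError(f"PSSM {self.kinase!r}: position rows must sum to 1")
        m.index.name = "position"
        m.columns.name = "residue"
        self.matrix = m
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / (1/20)) as a (10 positions, 20 residues) array."""
        return np.log2(self.matrix.to_numpy(dtype=float) * _N_AA)


class KinaseLibrary(Mapping):
    """Ordered collection of PSSMs, keyed by kinase id (sorted)."""

    def __init__(self, pssms: Iterable[PSSM]):
        self._pssms: dict[str, PSSM] = {}
        for p in pssms:
            if p.kinase in self._pssms:
                raise ValueError(f"duplicate kinase id {p.kinase!r}")
            self._pssms[p.kinase] = p
        self._pssms = dict(sorted(self._pssms.items()))

    def __getitem__(self, kinase: str) -> PSSM:
        return self._pssms[kinase]

    def __iter__(self):
        return iter(self._pssms)

    def __len__(self) -> int:
        return len(self._pssms)

    @property
    def kinases(self) -> list[str]:
        return list(self._pssms)

    # -- delimited-text round trip (long format: kinase, position, residue, probability)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for kin, p in self._pssms.items():
            for pos in FLANK_POSITIONS:
                for aa in AMINO_ACIDS:
                    rows.append((kin, pos, aa, p.matrix.at[pos, aa]))
        return pd.DataFrame(rows, columns=["kinase", "position", "residue", "probability"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "KinaseLibrary":
        required = {"kinase", "position", "residue", "probability"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"PSSM table missing columns: {sorted(missing)}")
        pssms = []
        for kin, grp in frame.groupby("kinase", sort=True):
            mat = grp.pivot_table(
                index="position", columns="residue", values="probability", aggfunc="first"
            )
            pssms.append(PSSM(str(kin), mat))
        return cls(pssms)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "KinaseLibrary":
        try:
            frame = pd.read_csv(path, sep="\t")
        except Exception as exc:  # surface the offending path
            raise ValueError(f"cannot read PSSM library {path}: {exc}") from exc
        return cls.from_frame(frame)


def score_flank(pssm: PSSM, flank: str) -> float:
    """Raw motif score: sum of log2(p/ (1/20)) over off-center, non-pad positions.

    Padding contributes 0 (neutral); the central S/T does not contribute.
    """
    flank = validate_flank(flank)
    lo = pssm.log_odds
    total = 0.0
    for row, pos in enumerate(FLANK_POSITIONS):
        ch = flank[pos + CENTER_INDEX]
        if ch == PAD:
            continue
        total += lo[row, _AA_INDEX[ch]]
    return float(total)


def encode_flanks(flanks: Sequence[str]) -> np.ndarray:
    """Encode flanks to an (n, 10) int array of residue indices; pad -> -1."""
    out = np.empty((len(flanks), len(FLANK_POSITIONS)), dtype=np.int64)
    for i, flank in enumerate(flanks):
        flank = validate_flank(flank)
        for row, pos in enumerate(FLANK_POSITIONS):
            ch = flank[pos + CENTER_INDEX]
            out[i, row] = -1 if ch == PAD else _AA_INDEX[ch]
    return out


def score_sites(flanks: Sequence[str], library: KinaseLibrary,
                index: pd.Index | None = None) -> pd.DataFrame:
    """Score every flank against every kinase; returns sites x kinases raw scores."""
    if len(library) == 0:
        raise ValueError("empty kinase library")
    codes = encode_flanks(list(flanks))
    rows = np.arange(len(FLANK_POSITIONS))
    scores = np.empty((codes.shape[0], len(library)))
    for j, kin in enumerate(library.kinases):
        lo = np.concatenate([library[kin].log_odds, np.zeros((len(rows), 1))], axis=1)
        scores[:, j] = lo[rows[None, :], codes].sum(axis=1)
    return pd.DataFrame(scores, index=index, columns=library.kinases)


def percentile_of(score: float, background: Sequence[float]) -> float:
    """Percentile of a score within a background sample: 100 * #(bg <= score)/|bg|."""
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background sample")
    return 100.0 * float(np.count_nonzero(bg <= score)) / bg.size


def score_percentiles(scores: pd.DataFrame, library: KinaseLibrary | None = None,
                      background: str = "dataset") -> pd.DataFrame:
    """Convert raw scores to per-kinase percentiles in [0, 100].

    background="dataset": each kinase's background is its own empirical score
    distribution over all scored sites (self-contained default).
    background="library": use each PSSM's stored background sample; kinases
    without one fall back to the dataset distribution.
    """
    if background not in {"dataset", "library"}:
        raise ValueError(f"unknown background mode {background!r}")
    out = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=float)
    for kin in scores.columns:
        col = scores[kin].to_numpy(dtype=float)
        bg = None
        if background == "library" and library is not None:
            bg = library[kin].background
        if bg is None:
            bg = col
        srt = np.sort(np.asarray(bg, dtype=float))
        out[kin] = 100.0 * np.searchsorted(srt, col, side="right") / srt.size
    return out


def rank_kinases(percentiles: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-site kinase ranks (1 = best).

    Ordering key: percentile descending, raw score descending, kinase id
    ascending as the final deterministic tie-break.
    """
    kin_idx = np.arange(percentiles.shape[1])
    pct = percentiles.to_numpy(dtype=float)
    raw = scores.to_numpy(dtype=float)
    ranks = np.empty_like(pct, dtype=np.int64)
    for i in range(pct.shape[0]):
        order = np.lexsort((kin_idx, -raw[i], -pct[i]))
        ranks[i, order] = np.arange(1, len(kin_idx) + 1)
    return pd.DataFrame(ranks, index=percentiles.index, columns=percentiles.columns)


def predict_top_k(ranks: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """Boolean sites x kinases table: kinase is 'predicted' when rank <= k."""
    if not 1 <= k <= ranks.shape[1]:
        raise ValueError(f"k={k} out of range 1..{ranks.shape[1]}")
    return ranks <= k


@dataclasses.dataclass
class SiteKinaseScores:
    """Kinase scoring result for a single site."""

    site_id: str | None
    scores: pd.Series
    percentiles: pd.Series
    ranks: pd.Series
    predicted: frozenset


def rank_and_predict(flank: str, library: KinaseLibrary, k: int = 15,
                     background_scores: pd.DataFrame | None = None,
                     site_id: str | None = None) -> SiteKinaseScores:
    """Score one flank against the library and call its top-k predicted kinases.

    Percentiles use the PSSM-stored backgrounds when present, otherwise the
    columns of ``background_scores`` (raw scores of a reference site set).
    With neither available, percentiles are computed against the singleton
    score itself (every percentile 100), so ranking falls back to raw score.
    """
    if len(library) == 0:
        raise ValueError("empty kinase library")
    if not 1 <= k <= len(library):
        raise ValueError(f"k={k} out of range 1..{len(library)}")
    raw = score_sites([flank], library).iloc[0]
    pct = {}
    for kin in library.kinases:
        bg = library[kin].background
        if bg is None and background_scores is not None:
            bg = background_scores[kin].to_numpy(dtype=float)
        if bg is None:
            bg = np.array([raw[kin]])
        pct[kin] = percentile_of(raw[kin], bg)
    pct = pd.Series(pct)[library.kinases]
    ranks = rank_kinases(pct.to_frame().T, raw.to_frame().T).iloc[0]
    predicted = frozenset(ranks.index[ranks <= k])
    return SiteKinaseScores(site_id, raw, pct, ranks, predicted)


def putative_substrates(percentiles: pd.DataFrame, kinase: str,
                        percentile_min: float = 95.0) -> pd.Index:
    """Sites whose percentile for ``kinase`` strictly exceeds ``percentile_min``."""
    if kinase not in percentiles.columns:
        raise ValueError(f"unknown kinase id {kinase!r}")
    if not 0.0 <= percentile_min <= 100.0:
        raise ValueError("percentile_min must be in [0, 100]")
    col = percentiles[kinase]
    return percentiles.index[col > percentile_min]


def select_scoreable(sites: pd.DataFrame, protein_col: str = "protein_id",
                     position_col: str = "position") -> pd.DataFrame:
    """Restrict to non-duplicate, singly phosphorylated S/T sites.

    Duplicates by (protein, position) collapse to the first occurrence; rows
    with an ``n_phospho`` column != 1 are dropped.
    """
    out = sites
    if "n_phospho" in out.columns:
        out = out[out["n_phospho"] == 1]
    out = out.drop_duplicates(subset=[protein_col, position_col], keep="first")
    return out
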