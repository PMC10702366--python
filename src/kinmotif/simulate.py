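"""Synthetic multiplexed phosphoproteomics with a known spiked kinase effect.

Emulates a 16-channel TMTpro experiment run on {WT, KO} x {untreated,
inhibitor} groups in quadruplicate: a PSSM library of artificial kinase
motifs, phosphosites whose flanks are either uniform-random or sampled from
one kinase's motif, lognormal reporter noise, and a log2 down-shift applied to
the target kinase's substrate sites in the affected (KO) channels.  A PSM
layer adds the quality defects the processing filters are designed to catch
(co-isolation, low summed signal-to-noise, missing channels, poor site
localization).  The generator returns the ground truth (which sites were
shifted, by how much) so the whole downstream pipeline can be scored on
recovery.

Randomness: one root seed; each operation draws from its own documented
substream (spawn keys: library=0, sites=1, quant=2, psm=3), so sub-steps are
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import AMINO_ACIDS, FLANK_POSITIONS, KinaseLibrary, PSSM

_STREAMS = {"library": 0, "sites": 1, "quant": 2, "psm": 3}
# floor on Dirichlet-sampled probabilities: keeps every PSSM entry positive
# and log-odds bounded even at very small concentration parameters
_PROB_FLOOR = 1e-6


def _rng(seed: int, stream: str) -> np.random.Generator:
    seq = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(seq)


def default_groups(n_channels: int = 16) -> tuple[tuple[str, tuple[int, ...]], ...]:
    """Quadruplicate 16plex layout: 4 groups x 4 consecutive channels."""
    if n_channels % 4 != 0:
        raise ValueError("default layout needs a multiple of 4 channels")
    per = n_channels // 4
    labels = ["WT_untreated", "WT_inhibitor", "KO_untreated", "KO_inhibitor"]
    return tuple(
        (lab, tuple(range(i * per + 1, (i + 1) * per + 1))) for i, lab in enumerate(labels)
    )


@dataclasses.dataclass(frozen=True)
class ArtifactRates:
    """Per-record probabilities of PSM-level quality defects."""

    low_isolation: float = 0.0
    low_sn: float = 0.0
    missing_channels: float = 0.0
    low_localization: float = 0.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"artifact rate {f.name}={v} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    groups maps group labels to 1-based channel indices; the labels' channel
    sets must partition 1..n_channels.  ``affected_groups`` designates the
    channels (default: the TBK1-null genotype groups) where the target
    kinase's substrate sites receive ``effect_log2``.
    """

    n_sites: int
    n_kinases: int
    n_channels: int = 16
    groups: tuple[tuple[str, tuple[int, ...]], ...] | None = None
    affected_groups: tuple[str, ...] | None = None
    target_kinase: str | None = None
    effect_log2: float = 0.0
    motif_fraction: float = 0.0
    noise_sd: float = 0.25
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    sharpness: float = 4.0
    artifact_rates: ArtifactRates = dataclasses.field(default_factory=ArtifactRates)
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1 or self.n_kinases < 1 or self.n_channels < 1:
            raise ValueError("n_sites, n_kinases, n_channels must be positive")
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be > 0")
        if self.groups is None:
            object.__setattr__(self, "groups", default_groups(self.n_channels))
        covered = sorted(i for _, idx in self.groups for i in idx)
        if covered != list(range(1, self.n_channels + 1)):
            raise ValueError("group channel indices must partition 1..n_channels")
        labels = [lab for lab, _ in self.groups]
        if self.affected_groups is None:
            ko = tuple(lab for lab in labels if lab.startswith("KO"))
            object.__setattr__(self, "affected_groups", ko)
        for lab in self.affected_groups:
            if lab not in labels:
                raise ValueError(f"affected group {lab!r} not among group labels {labels}")

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(1, self.n_channels + 1)]

    def group_channels(self, label: str) -> list[str]:
        for lab, idx in self.groups:
            if lab == label:
                return [f"ch{i:02d}" for i in idx]
        raise KeyError(label)

    def design_table(self) -> pd.DataFrame:
        """Channel -> (genotype, treatment, replicate), parsed from group labels."""
        rows = []
        for lab, idx in self.groups:
            genotype, _, treatment = lab.partition("_")
            for rep, i in enumerate(sorted(idx), start=1):
                rows.append((f"ch{i:02d}", genotype, treatment or "none", rep))
        rows.sort()
        return pd.DataFrame(rows, columns=["channel", "genotype", "treatment", "replicate"])


@dataclasses.dataclass
class GroundTruth:
    """Which sites were truly shifted and by how much (log2)."""

    target_kinase: str | None
    affected_sites: frozenset
    effects: dict

    def __post_init__(self):
        assert set(self.effects) == set(self.affected_sites)


def make_library(n_kinases: int, sharpness: float, seed: int) -> KinaseLibrary:
    """Sample a library of artificial kinase PSSMs.

    Each flank-position row is a symmetric Dirichlet draw over the 20
    residues with concentration 1/sharpness, so larger sharpness gives more
    peaked (informative) motifs and sharpness -> 0 approaches the uniform,
    uninformative motif.  A single parameter thus controls motif information
    content.
    """
    if n_kinases < 1:
        raise ValueError("n_kinases must be >= 1")
    if sharpness <= 0:
        raise ValueError("sharpness must be > 0")
    rng = _rng(seed, "library")
    alpha = 1.0 / sharpness
    pssms = []
    for j in range(n_kinases):
        rows = rng.dirichlet(np.full(len(AMINO_ACIDS), alpha), size=len(FLANK_POSITIONS))
        rows = np.clip(rows, _PROB_FLOOR, None)
        rows /= rows.sum(axis=1, keepdims=True)
        mat = pd.DataFrame(rows, index=list(FLANK_POSITIONS), columns=list(AMINO_ACIDS))
        pssms.append(PSSM(f"KIN{j + 1:03d}", mat))
    return KinaseLibrary(pssms)


def make_sites(n_sites: int, library: KinaseLibrary, motif_fraction: float,
               seed: int) -> pd.DataFrame:
    """Generate a phosphosite table with +/-5 flanks.

    A ``motif_fraction`` of sites draw their off-center flank residues from a
    uniformly chosen kinase's PSSM rows (the generating kinase is recorded in
    ``source_kinase``); the rest are uniform over the 20 residues and carry no
    label.  Centers are S or T with equal probability.
    """
    if not 0.0 <= motif_fraction <= 1.0:
        raise ValueError("motif_fraction must be in [0, 1]")
    if motif_fraction > 0 and len(library) == 0:
        raise ValueError("motif_fraction > 0 requires a non-empty library")
    rng = _rng(seed, "sites")
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    is_motif = rng.random(n_sites) < motif_fraction
    kinases = np.array(library.kinases) if len(library) else np.array([], dtype="U1")
    source = np.full(n_sites, "", dtype=object)
    if is_motif.any():
        source[is_motif] = rng.choice(kinases, size=int(is_motif.sum()))

    codes = rng.integers(0, len(AMINO_ACIDS), size=(n_sites, len(FLANK_POSITIONS)))
    for kin in kinases:
        mask = source == kin
        m = int(mask.sum())
        if m == 0:
            continue
        mat = library[kin].matrix.to_numpy()
        cols = np.empty((m, len(FLANK_POSITIONS)), dtype=np.int64)
        for row in range(len(FLANK_POSITIONS)):
            cols[:, row] = rng.choice(len(AMINO_ACIDS), size=m, p=mat[row])
        codes[mask] = cols

    centers = rng.choice(np.array(["S", "T"]), size=n_sites)
    positions = rng.integers(6, 800, size=n_sites)
    rows = []
    for i in range(n_sites):
        left = "".join(aa[codes[i, :5]])
        right = "".join(aa[codes[i, 5:]])
        flank = left + centers[i] + right
        protein = f"P{i + 1:05d}"
        rows.append((
            f"{protein}_{centers[i]}{positions[i]}", protein, int(positions[i]),
            centers[i], flank, source[i], 1,
        ))
    return pd.DataFrame(rows, columns=[
        "site_id", "protein_id", "position", "residue", "flank", "source_kinase", "n_phospho",
    ])


def simulate_quant(sites: pd.DataFrame, config: SimulationConfig
                   ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a sites x channels reporter quantification table (linear scale).

    log2 abundance = per-site baseline + effect (target-kinase sites in
    affected-group channels only) + N(0, noise_sd) noise.  Returns the linear
    (signal-to-noise-like, strictly positive) table and the ground truth.
    """
    if config.target_kinase is not None:
        labels = set(sites["source_kinase"])
        if config.target_kinase not in labels:
            raise ValueError(
                f"target kinase {config.target_kinase!r} generated no sites "
                "(not among site source labels)"
            )
    rng = _rng(config.seed, "quant")
    n = len(sites)
    channels = config.channel_names
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    log2 = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n, len(channels)))

    affected = frozenset()
    effects: dict = {}
    if config.target_kinase is not None and config.effect_log2 != 0.0:
        hit = (sites["source_kinase"] == config.target_kinase).to_numpy()
        cols = sorted({c for g in config.affected_groups for c in config.group_channels(g)})
        col_idx = [channels.index(c) for c in cols]
        log2[np.ix_(hit, col_idx)] += config.effect_log2
        affected = frozenset(sites.loc[hit, "site_id"])
        effects = {s: config.effect_log2 for s in affected}

    quant = pd.DataFrame(np.exp2(log2), index=pd.Index(sites["site_id"], name="site_id"),
                         columns=channels)
    return quant, GroundTruth(config.target_kinase, affected, effects)


def default_impurity(n_channels: int, leak: float = 0.02) -> np.ndarray:
    """Simple tridiagonal reagent-impurity matrix: each reagent leaks ``leak``
    of its signal into each adjacent channel."""
    m = np.eye(n_channels) * (1.0 - 2.0 * leak)
    m[0, 0] = m[-1, -1] = 1.0 - leak
    for j in range(n_channels):
        if j > 0:
            m[j - 1, j] = leak
        if j < n_channels - 1:
            m[j + 1, j] = leak
    return m


def simulate_psm_table(quant: pd.DataFrame, impurity: np.ndarray,
                       artifact_rates: ArtifactRates | Mapping | None,
                       seed: int) -> tuple[pd.DataFrame, dict]:
    """Degrade a true quant table into PSM-like reporter records.

    Applies the reagent impurity mixing (observed = impurity @ true), then
    injects independent Bernoulli quality defects per record.  Returns the
    record table plus per-defect injection counts (keyed by the filter reason
    each defect should trigger) as a ground-truth side channel.
    """
    impurity = np.asarray(impurity, dtype=float)
    n_ch = quant.shape[1]
    if impurity.shape != (n_ch, n_ch):
        raise ValueError(f"impurity matrix must be {n_ch}x{n_ch}, got {impurity.shape}")
    if (np.diag(impurity) <= 0).any():
        raise ValueError("impurity matrix diagonal must be positive")
    if artifact_rates is None:
        artifact_rates = ArtifactRates()
    elif isinstance(artifact_rates, Mapping):
        artifact_rates = ArtifactRates(**artifact_rates)

    rng = _rng(seed, "psm")
    n = quant.shape[0]
    mixed = quant.to_numpy(dtype=float) @ impurity.T

    iso = rng.uniform(0.85, 1.0, size=n)
    loc = rng.uniform(20.0, 60.0, size=n)
    flags = {
        "isolation_specificity": rng.random(n) < artifact_rates.low_isolation,
        "summed_sn": rng.random(n) < artifact_rates.low_sn,
        "missing_channels": rng.random(n) < artifact_rates.missing_channels,
        "localization": rng.random(n) < artifact_rates.low_localization,
    }
    iso[flags["isolation_specificity"]] = rng.uniform(
        0.30, 0.79, size=int(flags["isolation_specificity"].sum()))
    loc[flags["localization"]] = rng.uniform(
        0.0, 12.9, size=int(flags["localization"].sum()))

    for i in np.flatnonzero(flags["summed_sn"]):
        target = rng.uniform(10.0, 159.0)
        mixed[i] *= target / mixed[i].sum()

    missing_min = min(12, n_ch)
    for i in np.flatnonzero(flags["missing_channels"]):
        k = int(rng.integers(missing_min, n_ch + 1))
        drop = rng.choice(n_ch, size=k, replace=False)
        mixed[i, drop] = np.nan

    records = pd.DataFrame(mixed, columns=list(quant.columns))
    records.insert(0, "record_id", [f"R{i + 1:06d}" for i in range(n)])
    records.insert(1, "site_id", list(quant.index))
    records["isolation_specificity"] = iso
    records["summed_sn"] = np.nansum(mixed, axis=1)
    records["n_missing_channels"] = np.isnan(mixed).sum(axis=1)
    records["localization_score"] = loc
    records["n_phospho"] = 1
    counts = {k: int(v.sum()) for k, v in flags.items()}
    return records, counts
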