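"""End-to-end pipeline: simulate -> process -> differential -> score -> enrich.

A run is driven by a RunConfig (usually loaded from a YAML file): it either
simulates a complete experiment from a seed or reads the documented
delimited-text inputs, then applies the reporter-processing cascade, the
per-site contrast statistics, PSSM kinase scoring, and kinase-motif
enrichment, writing every analysis table plus a machine-readable run report.
Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from collections.abc import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffstats, enrichment, io, library, quant, simulate

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    mode: str = "simulate"
    out_dir: str = "kinmotif_out"
    seed: int = 0
    # simulate mode
    sim: simulate.SimulationConfig | None = None
    impurity_leak: float = 0.02
    # real mode input paths
    paths: dict = dataclasses.field(default_factory=dict)
    # processing / analysis parameters
    policy: quant.FilterPolicy = dataclasses.field(default_factory=quant.FilterPolicy.phospho)
    contrast: diffstats.ContrastSpec = dataclasses.field(
        default_factory=lambda: diffstats.ContrastSpec(
            {"genotype": "KO"}, {"genotype": "WT"}, name="KO_vs_WT"))
    classify: dict = dataclasses.field(default_factory=dict)
    k: int = 15
    percentile_min: float = 95.0
    alpha: float = 0.1
    background: str = "dataset"

    def __post_init__(self):
        if self.mode not in {"simulate", "real"}:
            raise ValueError(f"mode must be 'simulate' or 'real', got {self.mode!r}")
        if self.mode == "real":
            for key, path in self.paths.items():
                if not os.path.exists(path):
                    raise FileNotFoundError(f"{key} input not found: {path}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        sim = None
        if "simulate" in raw:
            s = dict(raw.pop("simulate"))
            groups = s.pop("groups", None)
            if groups is not None:
                s["groups"] = tuple((lab, tuple(idx)) for lab, idx in dict(groups).items())
            if "affected_groups" in s and s["affected_groups"] is not None:
                s["affected_groups"] = tuple(s["affected_groups"])
            if "artifact_rates" in s and s["artifact_rates"] is not None:
                s["artifact_rates"] = simulate.ArtifactRates(**dict(s["artifact_rates"]))
            sim = simulate.SimulationConfig(seed=seed, **s)
        policy = quant.FilterPolicy.phospho()
        if "filter" in raw:
            f = dict(raw.pop("filter"))
            preset = f.pop("policy", "phospho")
            base = (quant.FilterPolicy.phospho() if preset == "phospho"
                    else quant.FilterPolicy.total_proteome())
            policy = dataclasses.replace(base, **f)
        contrast = cls().contrast
        if "contrast" in raw:
            c = dict(raw.pop("contrast"))
            contrast = diffstats.ContrastSpec(
                c["numerator"], c["denominator"], name=c.get("name", "contrast"))
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known and k not in
                  {"sim", "policy", "contrast", "seed"}}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(sim=sim, policy=policy, contrast=contrast, seed=seed, **kwargs)


@dataclasses.dataclass
class RunReport:
    """Stage-by-stage counts plus the config echo, for auditability."""

    seed: int
    counts: dict
    config: dict
    version: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _simulate_inputs(cfg: RunConfig):
    sim = cfg.sim
    if sim is None:
        raise ValueError("simulate mode requires a 'simulate' config section")
    lib = simulate.make_library(sim.n_kinases, sim.sharpness, sim.seed)
    sites = simulate.make_sites(sim.n_sites, lib, sim.motif_fraction, sim.seed)
    quant_true, truth = simulate.simulate_quant(sites, sim)
    impurity = simulate.default_impurity(sim.n_channels, cfg.impurity_leak)
    records, artifact_counts = simulate.simulate_psm_table(
        quant_true, impurity, sim.artifact_rates, sim.seed)
    records = records.merge(sites[["site_id", "protein_id"]], on="site_id", how="left")
    design = sim.design_table()
    return lib, sites, design, impurity, records, truth, artifact_counts


def _load_inputs(cfg: RunConfig):
    paths = cfg.paths
    lib = library.KinaseLibrary.from_tsv(paths["library"])
    sites = io.read_sites(paths["sites"])
    design = io.read_design(paths["design"])
    impurity = io.read_impurity(paths["impurity"]) if "impurity" in paths else None
    records = io.read_records(paths["records"]) if "records" in paths else None
    quant_table = io.read_quant_table(paths["quant"]) if "quant" in paths else None
    if records is None and quant_table is None:
        raise ValueError("real mode requires a 'records' or 'quant' input path")
    return lib, sites, design, impurity, records, quant_table


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured analysis and write all output tables."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    counts: dict = {}
    truth = None
    quant_table = None

    if cfg.mode == "simulate":
        lib, sites, design, impurity, records, truth, artifact_counts = _simulate_inputs(cfg)
        counts["artifacts_injected"] = artifact_counts
        lib.to_tsv(os.path.join(cfg.out_dir, "pssm_library.tsv"))
        sites.to_csv(os.path.join(cfg.out_dir, "sites.tsv"), sep="\t", index=False)
        design.to_csv(os.path.join(cfg.out_dir, "design.tsv"), sep="\t", index=False)
        io.write_impurity(impurity, [f"ch{i:02d}" for i in range(1, cfg.sim.n_channels + 1)],
                          os.path.join(cfg.out_dir, "impurity.tsv"))
        truth_df = pd.DataFrame({
            "site_id": sorted(truth.affected_sites),
            "effect_log2": [truth.effects[s] for s in sorted(truth.affected_sites)],
        })
        truth_df.to_csv(os.path.join(cfg.out_dir, "ground_truth.tsv"), sep="\t", index=False)
    else:
        lib, sites, design, impurity, records, quant_table = _load_inputs(cfg)

    # --- reporter processing cascade
    if records is not None:
        counts["records_in"] = int(len(records))
        if impurity is not None:
            records = quant.correct_record_table(records, impurity)
        kept, rejected = quant.filter_records(records, cfg.policy)
        counts["records_kept"] = int(len(kept))
        counts["records_rejected"] = {
            r: int((rejected["reject_reason"] == r).sum()) for r in quant.REJECT_REASONS}
        rejected.to_csv(os.path.join(cfg.out_dir, "rejected_records.tsv"),
                        sep="\t", index=False)
        quant_table = quant.collapse_to_site(kept)
    counts["sites_quantified"] = int(len(quant_table))
    quant_table = quant.normalize_equal_loading(quant_table)
    io.write_quant_table(quant_table, os.path.join(cfg.out_dir, "quant_sites.tsv"))

    prot_path = cfg.paths.get("protein")
    log2 = quant.log2_table(quant_table)
    if prot_path:
        protein = io.read_quant_table(prot_path)
        protein = quant.normalize_equal_loading(protein)
        normalized, flagged = quant.normalize_phospho_to_protein(quant_table, protein)
        counts["sites_no_protein_match"] = int(flagged.sum())
        log2 = quant.log2_table(normalized)
    log2 = quant.median_center(log2)
    io.write_quant_table(log2, os.path.join(cfg.out_dir, "quant_processed_log2.tsv"))

    # --- differential statistics
    flanks = sites.set_index("site_id")["flank"]
    records_df, skipped = diffstats.contrast_stats(
        log2, design, cfg.contrast, log2_input=True, flanks=flanks)
    counts["sites_tested"] = int(len(records_df))
    counts["sites_skipped"] = int(len(skipped))
    records_df = diffstats.adjust_fdr(records_df)
    records_df = diffstats.classify_sites(records_df, **cfg.classify)
    records_df.to_csv(os.path.join(cfg.out_dir, "differential.tsv"), sep="\t")
    diffstats.volcano_table(records_df).to_csv(
        os.path.join(cfg.out_dir, "volcano.tsv"), sep="\t")
    counts["sites_per_stratum"] = {
        lev: int((records_df["regulation"] == lev).sum())
        for lev in diffstats.REGULATION_LEVELS}

    # --- kinase scoring (non-duplicate, singly phosphorylated sites only)
    scoreable = library.select_scoreable(sites)
    scoreable = scoreable[scoreable["site_id"].isin(records_df.index)]
    idx = pd.Index(scoreable["site_id"], name="site_id")
    scores = library.score_sites(list(scoreable["flank"]), lib, index=idx)
    percentiles = library.score_percentiles(scores, lib, background=cfg.background)
    ranks = library.rank_kinases(percentiles, scores)
    predicted = library.predict_top_k(ranks, cfg.k)
    counts["sites_scored"] = int(len(scores))
    percentiles.round(4).to_csv(os.path.join(cfg.out_dir, "site_kinase_percentiles.tsv"),
                                sep="\t")

    # --- enrichment
    reg = records_df.loc[records_df.index.isin(idx), "regulation"]
    down = set(reg.index[reg == "down"])
    up = set(reg.index[reg == "up"])
    unreg = set(reg.index[reg == "unregulated"])
    counts["sites_intermediate_excluded"] = int((reg == "intermediate").sum())
    enr = enrichment.enrich_kinases(predicted, lib.kinases, down, up, unreg, cfg.alpha)
    counts["kinases_tested"] = int(len(enr))
    counts["kinases_excluded_dual_side"] = int(enr["excluded"].sum())
    enr.to_csv(os.path.join(cfg.out_dir, "enrichment.tsv"), sep="\t")
    enrichment.finalize_enrichment(enr).to_csv(
        os.path.join(cfg.out_dir, "enrichment_scatter.tsv"), sep="\t")

    # --- motif statistics: downregulated foreground vs unregulated background
    fg = flanks.reindex(sorted(down)).dropna().tolist()
    bg = flanks.reindex(sorted(unreg)).dropna().tolist()
    if fg and bg:
        motif = enrichment.plogo_stats(fg, bg)
        motif.to_csv(os.path.join(cfg.out_dir, "motif_stats.tsv"), sep="\t", index=False)
        counts["motif_foreground_size"] = len(fg)
    else:
        logger.warning("motif statistics skipped: empty foreground or background stratum")
        counts["motif_foreground_size"] = 0

    if truth is not None:
        recovered = down & set(truth.affected_sites)
        counts["truth_affected_sites"] = len(truth.affected_sites)
        counts["truth_recovered_down"] = len(recovered)

    from . import __version__
    report = RunReport(seed=cfg.seed, counts=counts,
                       config=_config_echo(cfg), version=__version__)
    report.to_json(os.path.join(cfg.out_dir, "run_report.json"))
    return report


def _config_echo(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


# ---------------------------------------------------------------------------
# convenience experiment drivers (also used by the acceptance machinery)

def spike_recovery_config(seed: int, n_sites: int = 2000, n_kinases: int = 50,
                          effect_log2: float = -2.0, noise_sd: float = 0.25,
                          motif_fraction: float = 0.5, sharpness: float = 4.0,
                          target_kinase: str = "KIN001") -> simulate.SimulationConfig:
    """Study conditions for the 4-vs-4 spiked-kinase recovery experiment."""
    return simulate.SimulationConfig(
        n_sites=n_sites, n_kinases=n_kinases, n_channels=8,
        groups=(("WT", (1, 2, 3, 4)), ("KO", (5, 6, 7, 8))),
        affected_groups=("KO",), target_kinase=target_kinase,
        effect_log2=effect_log2, motif_fraction=motif_fraction,
        noise_sd=noise_sd, sharpness=sharpness, seed=seed)


def run_spike_recovery(sim: simulate.SimulationConfig, k: int = 15,
                       alpha: float = 0.1, permute_labels: bool = False) -> dict:
    """Simulate one experiment and run the core analysis in memory.

    Returns the per-kinase enrichment table plus summary quantities: the
    target kinase's rank among downregulated-enriched kinases (by adjusted P),
    its final_q, and stratum-recovery counts.  ``permute_labels`` shuffles the
    regulation labels across sites before enrichment (null calibration).
    """
    lib = simulate.make_library(sim.n_kinases, sim.sharpness, sim.seed)
    sites = simulate.make_sites(sim.n_sites, lib, sim.motif_fraction, sim.seed)
    quant_true, truth = simulate.simulate_quant(sites, sim)

    table = quant.normalize_equal_loading(quant_true)
    log2 = quant.median_center(quant.log2_table(table))
    design = sim.design_table()
    labels = [lab for lab, _ in sim.groups]
    contrast = diffstats.ContrastSpec({"genotype": labels[1].partition("_")[0]},
                                      {"genotype": labels[0].partition("_")[0]},
                                      name="KO_vs_WT")
    recs, _ = diffstats.contrast_stats(log2, design, contrast, log2_input=True)
    recs = diffstats.classify_sites(diffstats.adjust_fdr(recs))

    if permute_labels:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(sim.seed), spawn_key=(17,)))
        recs["regulation"] = rng.permutation(recs["regulation"].to_numpy())

    idx = pd.Index(sites["site_id"], name="site_id")
    scores = library.score_sites(list(sites["flank"]), lib, index=idx)
    percentiles = library.score_percentiles(scores)
    predicted = library.predict_top_k(library.rank_kinases(percentiles, scores), k)

    reg = recs["regulation"]
    down = set(reg.index[reg == "down"])
    up = set(reg.index[reg == "up"])
    unreg = set(reg.index[reg == "unregulated"])
    enr = enrichment.enrich_kinases(predicted, lib.kinases, down, up, unreg, alpha)

    down_enr = enr[(enr["side"] == "down") & (enr["final_q"] <= alpha)]
    order = down_enr.sort_values(["final_q", "p_down"]).index.tolist()
    target = sim.target_kinase
    return {
        "enrichment": enr,
        "truth": truth,
        "differential": recs,
        "target_down_rank": order.index(target) + 1 if target in order else None,
        "target_final_q": float(enr.loc[target, "final_q"]) if target in enr.index
                          and not enr.loc[target, "excluded"] else float("nan"),
        "n_down": len(down),
        "n_up": len(up),
        "n_unregulated": len(unreg),
        "recovered_down": len(down & set(truth.affected_sites)),
        "frac_q_le_alpha": float((enr["final_q"] <= alpha).mean()),
    }
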