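"""End-to-end orchestration: simulate (or load) a phased panel, run QC,
per-group iHS / F_ST / DRC scans, merge and filter loci, and write a
machine-readable run log.

All randomness flows from one global seed; rerunning a config reproduces
every output table byte-for-byte (the JSON log carries a timestamp, the
tables do not).
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import __version__
from .genio import (
    GeneticMap,
    HaplotypePanel,
    interpolate_cM,
    read_ancestral_table,
    read_genetic_map,
    read_labels,
    read_phased_vcf,
    read_sv_bed,
    write_scan_table,
)
from .haplostats import ihs_pvalue, ihs_scan, normalize_ihs
from .ibddrc import detect_ibd, drc_bins, drc_pvalues, fit_gamma_null, segments_to_table
from .fststats import fst_pvalues, hudson_fst_table, weighted_mean_fst
from .postfilter import bonferroni_threshold, loci_table, merge_to_loci, sv_overlap_filter
from .qc import filter_related, filter_variants_two_stage, ld_prune, pc_outlier_filter, pca_top_k
from .synth import SimulationConfig, SweepConfig, emit_dataset, simulate_panel

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Either ``vcf``/``genetic_map``/``ancestral``/``labels`` point at input
    files, or ``simulate`` holds keyword arguments for the synthetic
    generator (then inputs are produced in the run directory first).
    """

    out_dir: str = "popscan_run"
    seed: int = 0
    vcf: str | None = None
    genetic_map: str | None = None
    ancestral: str | None = None
    labels: str | None = None
    sv_bed: str | None = None
    simulate: dict | None = None
    groups: list[str] = field(default_factory=list)
    # stage parameters (defaults match the scan conventions documented
    # throughout the package)
    call_rate_min: float = 0.97
    hwe_alpha: float = 1e-6
    pihat_max: float = 0.25
    prune_window: int = 100
    prune_step: int = 10
    prune_r2: float = 0.2
    prune_maf: float = 0.05
    pca_k: int = 20
    pc_outlier_sd: float = 3.0
    ihs_maf_min: float = 0.01
    ihs_bins: int = 100
    ehh_cutoff: float = 0.05
    fst_maf_min: float = 0.01
    ibd_min_length_cM: float = 1.0
    ibd_seed_snps: int = 64
    drc_bin_cM: float = 0.05
    drc_timescales: tuple = (20, 50, 150)
    merge_gap_cM: float = 0.1
    alpha: float = 0.05
    run_qc: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _load_inputs(cfg: PipelineConfig) -> tuple[HaplotypePanel, pd.Series, GeneticMap]:
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sweep = sim_kwargs.pop("sweep", None)
        if sweep is not None:
            sweep = SweepConfig(**{**sweep, "target_subpops": tuple(sweep.get("target_subpops", ("pop1", "pop2")))})
        sim_cfg = SimulationConfig(**sim_kwargs, sweep=sweep, seed=cfg.seed)
        panel, truth = simulate_panel(sim_cfg)
        emit_dataset(panel, truth, os.path.join(cfg.out_dir, "synthetic_input"))
        labels = truth.subpop_labels
        knots = {
            str(chrom): sub[["bp", "cM"]].reset_index(drop=True)
            for chrom, sub in panel.variants.groupby("chrom", sort=False)
        }
        gmap = GeneticMap(knots)
        return panel, labels, gmap
    for key in ("vcf", "genetic_map", "ancestral", "labels"):
        path = getattr(cfg, key)
        if path is None:
            raise ConfigError(f"config needs {key!r} (or a simulate block)")
        if not os.path.exists(path):
            raise ConfigError(f"{key} file not found: {path}")
    panel = read_phased_vcf(cfg.vcf, read_ancestral_table(cfg.ancestral))
    gmap = read_genetic_map(cfg.genetic_map)
    cm = np.concatenate(
        [
            np.atleast_1d(interpolate_cM(gmap, chrom, sub["bp"].to_numpy()))
            for chrom, sub in panel.variants.groupby("chrom", sort=False)
        ]
    )
    panel.variants["cM"] = cm
    labels = read_labels(cfg.labels)
    return panel, labels, gmap


def run_pipeline(cfg: PipelineConfig) -> str:
    """Run every stage; returns the run directory path."""
    t0 = time.time()
    os.makedirs(cfg.out_dir, exist_ok=True)
    panel, labels, gmap = _load_inputs(cfg)
    log: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "n_samples_in": panel.n_samples,
        "n_variants_in": panel.n_variants,
    }

    if cfg.run_qc:
        panel, report = filter_variants_two_stage(
            panel, labels, cfg.call_rate_min, cfg.hwe_alpha
        )
        pruned_idx = ld_prune(
            panel, cfg.prune_window, cfg.prune_step, cfg.prune_r2, cfg.prune_maf
        )
        pruned = panel.subset_variants(pruned_idx)
        panel_rel, removed_rel, _ = filter_related(pruned, cfg.pihat_max)
        keep_rel = [s for s in panel.sample_ids if s not in set(removed_rel)]
        panel = panel.subset_samples(keep_rel)
        scores, _ = pca_top_k(
            panel.subset_variants(
                ld_prune(panel, cfg.prune_window, cfg.prune_step, cfg.prune_r2, cfg.prune_maf)
            ),
            min(cfg.pca_k, panel.n_samples - 1),
        )
        outliers = pc_outlier_filter(scores, cfg.pc_outlier_sd)
        keep_mask = np.ones(panel.n_samples, dtype=bool)
        keep_mask[outliers] = False
        panel = panel.subset_samples(keep_mask)
        report.removed_samples_relatedness = len(removed_rel)
        report.removed_samples_pc_outlier = int(len(outliers))
        log["qc"] = {
            "initial_variants": report.initial_variants,
            "removed_call_rate": report.removed_call_rate,
            "removed_hwe": report.removed_hwe,
            "recovered_variants": report.recovered_variants,
            "final_variants": report.final_variants,
            "removed_samples_relatedness": report.removed_samples_relatedness,
            "removed_samples_pc_outlier": report.removed_samples_pc_outlier,
            "reconciles": report.reconciles(),
        }
        labels = labels.loc[[s for s in panel.sample_ids]]

    groups = cfg.groups or list(pd.unique(labels))
    svs = read_sv_bed(cfg.sv_bed) if cfg.sv_bed else []
    all_loci: dict[str, pd.DataFrame] = {}

    # --- per-group iHS scan
    ihs_n_scored = {}
    ihs_tables = {}
    for g in groups:
        sub = panel.subset_samples(list(labels.index[labels == g]))
        rec = ihs_scan(sub, cfg.ihs_maf_min, cfg.ehh_cutoff)
        rec = ihs_pvalue(normalize_ihs(rec, cfg.ihs_bins))
        ihs_tables[g] = rec
        ihs_n_scored[g] = int((~rec["undefined"]).sum())
        write_scan_table(rec, os.path.join(cfg.out_dir, f"ihs_{g}.tsv"))
    n_scored = max(max(ihs_n_scored.values(), default=1), 1)
    ihs_thr, _ = bonferroni_threshold(cfg.alpha, n_scored, len(groups))
    for g in groups:
        loci = merge_to_loci(
            ihs_tables[g], ihs_thr, cfg.merge_gap_cM, p_col="p_ihs", stat_col="ihs_norm"
        )
        loci = sv_overlap_filter(loci, svs)
        all_loci[f"ihs_{g}"] = loci_table(loci)

    # --- between-group FST scan (first two groups)
    if len(groups) >= 2:
        a, b = groups[0], groups[1]
        pa = panel.subset_samples(list(labels.index[labels == a]))
        pb = panel.subset_samples(list(labels.index[labels == b]))
        pooled_maf = panel.maf()
        use = pooled_maf >= cfg.fst_maf_min
        tab = hudson_fst_table(
            pa.derived_freq()[use], pa.n_haplotypes, pb.derived_freq()[use], pb.n_haplotypes
        )
        tab.insert(0, "chrom", panel.variants.loc[use, "chrom"].to_numpy())
        tab.insert(1, "bp", panel.variants.loc[use, "bp"].to_numpy())
        tab.insert(2, "cM", panel.variants.loc[use, "cM"].to_numpy())
        tab = fst_pvalues(tab)
        fst_mean, fst_se = weighted_mean_fst(tab)
        write_scan_table(tab, os.path.join(cfg.out_dir, f"fst_{a}_vs_{b}.tsv"))
        fst_thr, _ = bonferroni_threshold(cfg.alpha, int(use.sum()))
        loci = sv_overlap_filter(
            merge_to_loci(tab, fst_thr, cfg.merge_gap_cM, p_col="p_fst", stat_col="fst"), svs
        )
        all_loci["fst"] = loci_table(loci)
        log["fst"] = {"weighted_mean": fst_mean, "se": fst_se, "n_snps": int(use.sum())}

    # --- per-group DRC scan
    for g in groups:
        sub = panel.subset_samples(list(labels.index[labels == g]))
        segs = detect_ibd(sub, cfg.ibd_min_length_cM, seed_snps=cfg.ibd_seed_snps)
        write_scan_table(
            segments_to_table(segs), os.path.join(cfg.out_dir, f"ibd_{g}.tsv")
        )
        cm = sub.variants["cM"].to_numpy(dtype=float)
        bins = drc_bins(
            segs, cm[0], cm[-1], sub.n_haplotypes,
            tuple(float(t) for t in cfg.drc_timescales), cfg.drc_bin_cM,
            chrom=str(sub.variants["chrom"].iloc[0]),
        )
        n_bins = len(bins)
        drc_thr, _ = bonferroni_threshold(
            cfg.alpha, n_bins, len(groups), len(cfg.drc_timescales)
        )
        nulls = {}
        for T in cfg.drc_timescales:
            try:
                nulls[T] = fit_gamma_null(bins[f"drc_{int(T)}"].to_numpy(), drc_thr)
            except ValueError:
                nulls[T] = None
        usable = {T: n for T, n in nulls.items() if n is not None}
        bins = drc_pvalues(bins, usable, tuple(usable)) if usable else bins
        write_scan_table(bins, os.path.join(cfg.out_dir, f"drc_{g}.tsv"))
        for T in usable:
            loci = sv_overlap_filter(
                merge_to_loci(
                    bins, drc_thr, cfg.merge_gap_cM,
                    p_col=f"p_drc_{int(T)}", stat_col=f"drc_{int(T)}",
                ),
                svs,
            )
            all_loci[f"drc_{int(T)}_{g}"] = loci_table(loci)

    for name, tab in all_loci.items():
        write_scan_table(tab, os.path.join(cfg.out_dir, f"loci_{name}.tsv"))
    log["loci_counts"] = {k: int(len(v)) for k, v in all_loci.items()}
    log["runtime_s"] = round(time.time() - t0, 3)
    log["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(cfg.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return cfg.out_dir
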