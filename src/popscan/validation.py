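"""Validation studies: the simulation experiments that check calibration,
parameter recovery, population-structure resolution, and sweep-detection
power of the scan statistics under controlled conditions.

Each study is a deterministic function of a seed and returns a flat dict of
named metrics.  The study conditions (population sizes, map lengths, sweep
parameters) are fixed design choices documented in the methods note; they
are chosen so each study runs in minutes on one CPU while staying inside
the regime where the statistics' distributional assumptions apply.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .fststats import fst_pvalues, hudson_fst_table, weighted_mean_fst
from .haplostats import ihs_pvalue, ihs_scan, normalize_ihs
from .ibddrc import detect_ibd, drc_bins, drc_pvalues, fit_gamma_null
from .qc import ld_prune, pca_top_k
from .synth import SimulationConfig, SweepConfig, simulate_conditioned, simulate_panel

__all__ = [
    "neutral_ihs_calibration",
    "fst_pvalue_uniformity",
    "drc_null_uniformity",
    "gamma_null_recovery",
    "sweep_power",
    "population_structure",
    "panmictic_fst",
]


def _seed(base: int, k: int) -> int:
    return int((base + 99_991 * k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# null calibration


def neutral_ihs_calibration(seed: int = 0) -> dict:
    """Fraction of neutral variants with two-sided iHS p < 0.01.

    One panmictic population of 1,000 haplotypes, 2 x 10^4 markers on a
    200 cM map: large enough for the normal approximation behind the iHS
    p-values (asymptotic in haplotype count) to be applicable.
    """
    cfg = SimulationConfig(
        seed=_seed(seed, 1), n_founders=50, pop_size=500, n_generations_burnin=60,
        split_generation=0, migration_rate=0.5, chrom_length_cM=200.0, n_variants=20_000,
    )
    panel, _ = simulate_panel(cfg)
    rec = ihs_pvalue(normalize_ihs(ihs_scan(panel)))
    p = rec["p_ihs"].dropna().to_numpy()
    frac = float((p < 0.01).mean())
    ci_half = float(2.5758 * np.sqrt(0.01 * 0.99 / len(p)))
    return {
        "ihs_tail_fraction": frac,
        "ihs_tail_nominal": 0.01,
        "ihs_tail_ci_halfwidth": ci_half,
        "n_scored": int(len(p)),
    }


def fst_pvalue_uniformity(seed: int = 0, n: int = 100_000, c: float = 0.003) -> dict:
    """KS distance from U(0,1) of the scaled-chi-square F_ST p-values when
    the statistics really are c * chi2(1)."""
    rng = np.random.default_rng(_seed(seed, 2))
    vals = c * rng.chisquare(1.0, size=n)
    records = pd.DataFrame({"fst": vals, "monomorphic": False})
    out = fst_pvalues(records)
    ks = stats.kstest(out["p_fst"].to_numpy(), "uniform").statistic
    return {"fst_p_ks": float(ks), "n": n}


def drc_null_uniformity(seed: int = 0, n: int = 10_000) -> dict:
    """KS distance from U(0,1) of DRC p-values under the fitted Gamma null
    (values drawn from Gamma(shape 2, rate 3))."""
    rng = np.random.default_rng(_seed(seed, 3))
    vals = rng.gamma(2.0, 1.0 / 3.0, size=n)
    null = fit_gamma_null(vals, alpha_exclude=1e-6)
    p = stats.gamma.sf(vals, null.shape, scale=1.0 / null.rate)
    ks = stats.kstest(p, "uniform").statistic
    return {"drc_p_ks": float(ks), "n": n}


# ---------------------------------------------------------------------------
# parameter recovery


def gamma_null_recovery(seed: int = 0, n: int = 10_000) -> dict:
    """Gamma-null MLE recovery of (shape 2, rate 3), with and without 0.2%
    injected outliers at 50x the mean (testing the iterative exclusion)."""
    rng = np.random.default_rng(_seed(seed, 4))
    clean = rng.gamma(2.0, 1.0 / 3.0, size=n)
    fit_clean = fit_gamma_null(clean, alpha_exclude=1e-6)
    outliers = np.full(20, 50.0 * clean.mean())
    contaminated = np.concatenate([clean, outliers])
    fit_dirty = fit_gamma_null(contaminated, alpha_exclude=1e-4)
    return {
        "gamma_shape_clean": float(fit_clean.shape),
        "gamma_rate_clean": float(fit_clean.rate),
        "gamma_shape_contaminated": float(fit_dirty.shape),
        "gamma_rate_contaminated": float(fit_dirty.rate),
        "n_outliers_excluded": int(len(fit_dirty.excluded_bins)),
        "shape_error": float(abs(fit_clean.shape - 2.0)),
        "contaminated_vs_clean_shape_reldiff": float(
            abs(fit_dirty.shape - fit_clean.shape) / fit_clean.shape
        ),
        "contaminated_vs_clean_rate_reldiff": float(
            abs(fit_dirty.rate - fit_clean.rate) / fit_clean.rate
        ),
    }


# ---------------------------------------------------------------------------
# sweep power


_POWER_M = 6000
_POWER_FOCAL = _POWER_M // 2
_POWER_L = 60.0
_POWER_TIMESCALES = 3  # DRC_20/50/150 family size for the Bonferroni alpha


def _power_config(seed: int, s: float = 0.05) -> SimulationConfig:
    """Hard-sweep study condition: one derived copy among 600 founder
    haplotypes, selected (s per copy) through a 150-generation expansion
    to 3,000 haplotypes; 0.01 cM marker spacing."""
    sweep = None
    if s > 0:
        sweep = SweepConfig(
            _POWER_FOCAL, s, sweep_start_generation=150, focal_initial_freq=1 / 600
        )
    return SimulationConfig(
        seed=seed, n_founders=300, pop_size=2250, n_generations_burnin=150,
        split_generation=0, migration_rate=0.5, chrom_length_cM=_POWER_L,
        n_variants=_POWER_M, sweep=sweep, sample_size=150,
    )


def _drc150_scan(panel) -> tuple[pd.DataFrame, float]:
    segs = detect_ibd(panel, min_length_cM=50.0 / 150.0, seed_snps=24)
    cm = panel.variants["cM"].to_numpy(dtype=float)
    bins = drc_bins(segs, cm[0], cm[-1], panel.n_haplotypes, timescales=(150.0,))
    thr = 0.05 / len(bins) / _POWER_TIMESCALES
    null = fit_gamma_null(bins["drc_150"].to_numpy(), alpha_exclude=thr)
    return drc_pvalues(bins, null, (150,)), thr


def sweep_power(seed: int = 0, n_reps: int = 20) -> dict:
    """Detection rates for a hard sweep with s = 0.05 conditioned on focal
    DAF in [0.4, 0.8] at sampling.

    Reports: the fraction of replicates where the focal variant's |iHS_norm|
    exceeds the neutral 99th percentile; where the genome-wide minimum
    DRC_150 p-value falls within the sweep footprint (+/- 0.25 cM of the
    focal site — carrier tracts tile several 0.05-cM bins, so the exact
    top bin wobbles inside the footprint; the strict same-bin rate is also
    reported); and where the focal bin stays Bonferroni-significant after
    halving the sample.
    """
    zs = []
    for k in range(3):
        panel, _ = simulate_panel(_power_config(_seed(seed, 10 + k), s=0.0))
        rec = ihs_pvalue(normalize_ihs(ihs_scan(panel)))
        zs.append(rec["ihs_norm"].dropna().abs().to_numpy())
    q99 = float(np.quantile(np.concatenate(zs), 0.99))

    ihs_hits = top_locus_hits = top_bin_hits = half_hits = 0
    focal_zs = []
    for rep in range(n_reps):
        cfg = _power_config(_seed(seed, 100 + rep))
        panel, truth, _ = simulate_conditioned(cfg, (0.4, 0.8))
        rec = ihs_pvalue(normalize_ihs(ihs_scan(panel)))
        row = rec.loc[rec["variant"] == _POWER_FOCAL]
        z = float(row["ihs_norm"].iloc[0]) if len(row) else np.nan
        focal_zs.append(z)
        ihs_hits += bool(np.isfinite(z) and abs(z) > q99)

        bins, thr = _drc150_scan(panel)
        cm = panel.variants["cM"].to_numpy(dtype=float)
        focal_cm = cm[_POWER_FOCAL]
        fbi = int(
            np.flatnonzero((bins["start_cM"] <= focal_cm) & (bins["end_cM"] > focal_cm))[0]
        )
        p = bins["p_drc_150"].to_numpy()
        top = int(np.argmin(p))
        top_bin_hits += bool(p[fbi] <= p.min() * (1 + 1e-9))
        top_locus_hits += bool(
            abs((bins["start_cM"].iloc[top] + bins["end_cM"].iloc[top]) / 2 - focal_cm)
            <= 0.25
        )

        half = panel.subset_samples(panel.sample_ids[::2])
        half_bins, half_thr = _drc150_scan(half)
        half_hits += bool(half_bins["p_drc_150"].iloc[fbi] < half_thr)

    return {
        "n_replicates": n_reps,
        "neutral_q99_abs_z": q99,
        "mean_focal_abs_z": float(np.nanmean(np.abs(focal_zs))),
        "ihs_detection_rate": ihs_hits / n_reps,
        "drc_top_locus_rate": top_locus_hits / n_reps,
        "drc_top_bin_strict_rate": top_bin_hits / n_reps,
        "drc_downsampled_significance_rate": half_hits / n_reps,
    }


# ---------------------------------------------------------------------------
# population structure


def population_structure(seed: int = 0) -> dict:
    """Two subpopulations split 60 generations ago (expected F_ST ~ 0.06,
    comfortably above the 0.01 detectability condition): PC1 must separate
    the sampled cohorts with zero overlap."""
    cfg = SimulationConfig(
        seed=_seed(seed, 5), n_founders=150, pop_size=500, n_generations_burnin=90,
        split_generation=60, migration_rate=0.0, chrom_length_cM=75.0, n_variants=3000,
        sample_size=100,
    )
    panel, truth = simulate_panel(cfg)
    labels = truth.subpop_labels
    n1 = int((labels == "pop1").sum())
    kept = ld_prune(panel)
    scores, _ = pca_top_k(panel.subset_variants(kept), k=10)
    g1 = scores[:n1, 0]
    g2 = scores[n1:, 0]
    lo, hi = max(g1.min(), g2.min()), min(g1.max(), g2.max())
    # samples falling inside the other group's PC1 range; 0 = clean split
    overlap = 0 if hi < lo else int(
        ((g1 >= lo) & (g1 <= hi)).sum() + ((g2 >= lo) & (g2 <= hi)).sum()
    )
    a = panel.subset_samples(list(labels.index[labels == "pop1"]))
    b = panel.subset_samples(list(labels.index[labels == "pop2"]))
    tab = hudson_fst_table(a.derived_freq(), a.n_haplotypes, b.derived_freq(), b.n_haplotypes)
    fst, se = weighted_mean_fst(tab)
    return {
        "pc1_overlap_count": overlap,
        "realized_fst": float(fst),
        "expected_fst": float(truth.expected_fst),
    }


def panmictic_fst(seed: int = 0) -> dict:
    """Weighted Hudson F_ST between two cohorts sampled from one panmictic
    population over >= 10^4 SNPs: must sit within 3 jackknife SE of 0.

    Cohorts are subsamples (100 of 1,000 diploids each) so sib-clustering
    noise, which SNP-block jackknives cannot see, stays below the SE scale;
    20 jackknife blocks (6 cM each) stay well above the ~1 cM LD scale.
    """
    cfg = SimulationConfig(
        seed=_seed(seed, 6), n_founders=300, pop_size=1000, n_generations_burnin=100,
        split_generation=0, migration_rate=0.5, chrom_length_cM=120.0, n_variants=15_000,
        sample_size=100,
    )
    panel, truth = simulate_panel(cfg)
    labels = truth.subpop_labels
    a = panel.subset_samples(list(labels.index[labels == "pop1"]))
    b = panel.subset_samples(list(labels.index[labels == "pop2"]))
    tab = hudson_fst_table(a.derived_freq(), a.n_haplotypes, b.derived_freq(), b.n_haplotypes)
    fst, se = weighted_mean_fst(tab, n_blocks=20)
    return {
        "panmictic_fst": float(fst),
        "panmictic_fst_se": float(se),
        "abs_fst_over_se": float(abs(fst) / se),
        "n_snps": int((~tab["monomorphic"]).sum()),
    }
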