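"""Forward-in-time simulator for phased two-subpopulation haplotype panels.

A founder pool of diploids carries haplotypes drawn site-wise from a neutral
frequency spectrum (density proportional to 1/x, truncated so every site is
polymorphic among founders).  The population then evolves as a discrete
Wright-Fisher process with recombination: each child draws two parents
(fitness-weighted under a sweep) and each gamete recombines the parent's two
haplotypes with a Poisson number of crossovers (mean = map length in
Morgans).  The population is panmictic until ``split_generation`` before
present, after which two subpopulations of ``pop_size`` diploids evolve
independently except for symmetric migration.

The founder bottleneck, not mutation, is the source of linkage
disequilibrium: descendant haplotypes are mosaics of the small founder set,
so nearby sites stay correlated while distant ones decay — enough LD
structure for EHH/iHS and IBD detection to have something real to find.

A selective sweep is modelled as genic selection: parents are sampled with
weight (1+s) per derived allele at the focal site, within the target
subpopulations, from ``sweep_start_generation`` before present onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

try:  # fast gamete assembly when numba is available; same semantics without
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _assemble_gametes(big, out, row_a, row_b, cut_sites, cut_offsets):  # pragma: no cover
    """Copy alternating parental segments into each gamete row.

    ``row_a`` is the starting haplotype row in ``big``; crossovers happen
    before the site indices in ``cut_sites[cut_offsets[g]:cut_offsets[g+1]]``
    (sorted per gamete)."""
    n_g, m = out.shape
    for g in range(n_g):
        cur = row_a[g]
        other = row_b[g]
        start = 0
        for c in range(cut_offsets[g], cut_offsets[g + 1]):
            idx = cut_sites[c]
            for t in range(start, idx):
                out[g, t] = big[cur, t]
            start = idx
            cur, other = other, cur
        for t in range(start, m):
            out[g, t] = big[cur, t]

from .genio import GeneticMap, HaplotypePanel, write_ancestral_table, write_genetic_map, write_labels, write_phased_vcf

__all__ = ["SweepConfig", "SimulationConfig", "SimulationTruth", "simulate_panel", "emit_dataset"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SweepConfig:
    """Additive selection at one focal biallelic site.

    ``focal_initial_freq``, when set, pins the founder derived-allele
    frequency at the focal site to an exact copy count (otherwise it is
    drawn from the neutral spectrum like every other site).

    ``de_novo`` models the textbook hard sweep: at ``sweep_start_generation``
    before present the focal column is reset to a single derived copy on a
    random haplotype, so every eventual carrier descends from one recent
    ancestor.  Without it, selection acts on standing variation, whose
    carriers keep their older, diverse haplotype backgrounds — a much
    weaker haplotype signature by construction.
    """

    focal_variant_index: int
    selection_coefficient: float
    sweep_start_generation: int
    target_subpops: tuple[str, ...] = ("pop1", "pop2")
    focal_initial_freq: float | None = None
    de_novo: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    n_founders: int = 50
    pop_size: int = 150
    n_generations_burnin: int = 100
    split_generation: int = 30
    migration_rate: float = 0.0
    chrom_length_cM: float = 50.0
    n_variants: int = 2000
    sweep: SweepConfig | None = None
    seed: int = 0
    chrom: str = "1"
    #: diploids per subpopulation placed in the emitted panel (defaults to
    #: pop_size); a cohort samples far fewer individuals than exist
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_founders, self.pop_size, self.n_variants) <= 0:
            raise ConfigurationError("counts must be positive")
        if self.n_generations_burnin < 0 or self.split_generation < 0:
            raise ConfigurationError("generation counts must be non-negative")
        if self.split_generation > self.n_generations_burnin:
            raise ConfigurationError("split_generation cannot exceed total generations")
        if not 0.0 <= self.migration_rate <= 0.5:
            raise ConfigurationError("migration_rate must be in [0, 0.5]")
        if self.chrom_length_cM <= 0:
            raise ConfigurationError("chrom_length_cM must be positive")
        if self.sweep is not None:
            if self.sweep.selection_coefficient < 0:
                raise ConfigurationError("selection coefficient must be >= 0")
            if not 0 <= self.sweep.focal_variant_index < self.n_variants:
                raise ConfigurationError("focal_variant_index out of range")
            if self.sweep.focal_initial_freq is not None and not (
                0.0 < self.sweep.focal_initial_freq < 1.0
            ):
                raise ConfigurationError("focal_initial_freq must be in (0, 1)")


@dataclass
class SimulationTruth:
    subpop_labels: pd.Series
    sweep_site: int | None
    expected_fst: float
    seed: int


def _founder_haplotypes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n_hap = 2 * cfg.n_founders
    lo = 1.0 / n_hap
    # inverse-CDF draw from density 1/x on [lo, 1]
    u = rng.random(cfg.n_variants)
    freqs = lo ** (1.0 - u)  # == exp(log(lo) * (1-u)); CDF log(x/lo)/log(1/lo)
    H = (rng.random((n_hap, cfg.n_variants)) < freqs[None, :]).astype(np.uint8)
    # keep every site polymorphic among founders (the truncation's intent)
    daf = H.mean(axis=0)
    for j in np.flatnonzero((daf == 0) | (daf == 1)):
        H[:, j] = 0
        H[rng.integers(n_hap), j] = 1
    if cfg.sweep is not None and cfg.sweep.focal_initial_freq is not None:
        # pin the focal site to an exact founder copy count so conditioning
        # on the sweep's starting state is reproducible even at 1-2 copies
        j = cfg.sweep.focal_variant_index
        count = max(int(round(cfg.sweep.focal_initial_freq * n_hap)), 1)
        H[:, j] = 0
        H[rng.choice(n_hap, size=count, replace=False), j] = 1
    return H


def _next_generation(
    H: np.ndarray,
    n_children: int,
    cm: np.ndarray,
    length_cM: float,
    fitness: np.ndarray | None,
    rng: np.random.Generator,
    migrant_pool: np.ndarray | None = None,
    migration_rate: float = 0.0,
) -> np.ndarray:
    """One Wright-Fisher generation; returns 2*n_children haplotype rows.

    ``fitness`` is per-diploid-parent sampling weight.  With migration, each
    gamete independently comes from a migrant-pool parent with probability
    ``migration_rate`` (per-haplotype semantics).  Per-gamete randomness
    (crossover counts, positions, starting haplotype) is drawn vectorized
    up front; gamete assembly is a short per-row loop.
    """
    n_parents = H.shape[0] // 2
    probs = None if fitness is None else fitness / fitness.sum()
    n_g = 2 * n_children
    out = np.empty((n_g, H.shape[1]), dtype=np.uint8)
    parent_draws = rng.choice(n_parents, size=(n_children, 2), p=probs).ravel()
    if migrant_pool is not None and migration_rate > 0.0:
        big = np.vstack([H, migrant_pool])
        mig = (rng.random((n_children, 2)) < migration_rate).ravel()
        mig_parents = rng.integers(migrant_pool.shape[0] // 2, size=n_g)
        base = np.where(mig, H.shape[0] + 2 * mig_parents, 2 * parent_draws)
    else:
        big = H
        base = 2 * parent_draws
    k = rng.poisson(length_cM / 100.0, size=n_g)
    first = rng.integers(0, 2, size=n_g)
    cuts_flat = rng.random(int(k.sum())) * length_cM
    # sort crossover positions within each gamete, then map to site indices
    gamete_of_cut = np.repeat(np.arange(n_g), k)
    order = np.lexsort((cuts_flat, gamete_of_cut))
    cut_sites = np.searchsorted(cm, cuts_flat[order]).astype(np.int64)
    cut_offsets = np.zeros(n_g + 1, dtype=np.int64)
    np.cumsum(k, out=cut_offsets[1:])
    row_a = (base + first).astype(np.int64)
    row_b = (base + 1 - first).astype(np.int64)
    _assemble_gametes(big, out, row_a, row_b, cut_sites, cut_offsets)
    return out


def _sweep_fitness(
    H: np.ndarray, cfg: SimulationConfig, pop_name: str, gens_before_present: int
) -> np.ndarray | None:
    sw = cfg.sweep
    if sw is None or sw.selection_coefficient == 0.0:
        return None
    if gens_before_present > sw.sweep_start_generation:
        return None
    if pop_name != "pre-split" and pop_name not in sw.target_subpops:
        return None
    copies = H[0::2, sw.focal_variant_index].astype(float) + H[1::2, sw.focal_variant_index]
    return (1.0 + sw.selection_coefficient) ** copies


def _maybe_inject_de_novo(
    H: np.ndarray, cfg: SimulationConfig, before_present: int, rng: np.random.Generator
) -> None:
    sw = cfg.sweep
    if sw is not None and sw.de_novo and before_present == sw.sweep_start_generation:
        H[:, sw.focal_variant_index] = 0
        H[rng.integers(H.shape[0]), sw.focal_variant_index] = 1


def _evolve(
    cfg: SimulationConfig, rng: np.random.Generator, focal_abort: tuple[float, float] | None = None
) -> np.ndarray | None:
    """Run the forward phases; returns the final haplotype matrix.

    ``focal_abort`` = (lo, hi): once selection is active, return None as
    soon as the focal derived frequency can no longer end inside [lo, hi]
    (allele lost, or fixed with hi < 1) — cheap early rejection for
    conditioned simulation.
    """
    cm = np.linspace(
        cfg.chrom_length_cM / cfg.n_variants, cfg.chrom_length_cM, cfg.n_variants
    )
    H = _founder_haplotypes(cfg, rng)
    sw = cfg.sweep

    def aborts(H: np.ndarray, before_present: int) -> bool:
        if focal_abort is None or sw is None:
            return False
        if before_present > sw.sweep_start_generation:
            return False
        f = H[:, sw.focal_variant_index].mean()
        return f == 0.0 or (f == 1.0 and focal_abort[1] < 1.0)

    n_pan = cfg.n_generations_burnin - cfg.split_generation
    pan_size = 2 * cfg.pop_size
    for g in range(n_pan):
        before_present = cfg.n_generations_burnin - g
        _maybe_inject_de_novo(H, cfg, before_present, rng)
        fit = _sweep_fitness(H, cfg, "pre-split", before_present)
        H = _next_generation(H, pan_size, cm, cfg.chrom_length_cM, fit, rng)
        if aborts(H, before_present - 1):
            return None

    if cfg.split_generation > 0:
        pops = {"pop1": H[: 2 * cfg.pop_size], "pop2": H[2 * cfg.pop_size :]}
        if pops["pop1"].shape[0] < 2 * cfg.pop_size or pops["pop2"].shape[0] < 2 * cfg.pop_size:
            # founder phase shorter than split: replicate founders to size
            idx = rng.integers(H.shape[0], size=4 * cfg.pop_size)
            pops = {
                "pop1": H[idx[: 2 * cfg.pop_size]],
                "pop2": H[idx[2 * cfg.pop_size :]],
            }
        for g in range(cfg.split_generation):
            before_present = cfg.split_generation - g
            if cfg.sweep is not None and cfg.sweep.de_novo:
                # a de novo mutation arises once, in the first target deme
                tgt = cfg.sweep.target_subpops[0]
                if tgt in pops:
                    _maybe_inject_de_novo(pops[tgt], cfg, before_present, rng)
            new = {}
            for name, other in (("pop1", "pop2"), ("pop2", "pop1")):
                fit = _sweep_fitness(pops[name], cfg, name, before_present)
                new[name] = _next_generation(
                    pops[name],
                    cfg.pop_size,
                    cm,
                    cfg.chrom_length_cM,
                    fit,
                    rng,
                    migrant_pool=pops[other],
                    migration_rate=cfg.migration_rate,
                )
            pops = new
            if aborts(np.vstack([pops["pop1"], pops["pop2"]]), before_present - 1):
                return None
        H = np.vstack([pops["pop1"], pops["pop2"]])
    # split_generation == 0: a single panmictic deme, halved into two labels
    if H.shape[0] != 4 * cfg.pop_size:
        # degenerate timing (no reproduction step ran): resample founders
        idx = rng.integers(H.shape[0], size=4 * cfg.pop_size)
        H = H[idx]
    return H


def simulate_panel(cfg: SimulationConfig) -> tuple[HaplotypePanel, SimulationTruth]:
    """Run the forward model and return a phased panel plus ground truth.

    Deterministic given ``cfg.seed``.  Sites are evenly spaced on the
    genetic map (1 cM per Mb); alleles are ancestral(0)/derived(1) with
    REF fixed as the ancestral allele.
    """
    rng = np.random.default_rng(cfg.seed)
    H = _evolve(cfg, rng)
    return _finalize(cfg, H)


def _finalize(cfg: SimulationConfig, H: np.ndarray) -> tuple[HaplotypePanel, SimulationTruth]:
    cm = np.linspace(
        cfg.chrom_length_cM / cfg.n_variants, cfg.chrom_length_cM, cfg.n_variants
    )
    n_per = cfg.pop_size
    if cfg.sample_size is not None and cfg.sample_size < cfg.pop_size:
        # children within a generation are exchangeable, so the leading rows
        # of each deme are already a uniform sample
        n_per = cfg.sample_size
        pop2_start = 2 * cfg.pop_size
        H = np.vstack([H[: 2 * n_per], H[pop2_start : pop2_start + 2 * n_per]])
    sample_ids = [f"pop1_{i:04d}" for i in range(n_per)] + [
        f"pop2_{i:04d}" for i in range(n_per)
    ]
    labels = pd.Series(
        ["pop1"] * n_per + ["pop2"] * n_per, index=sample_ids, name="group"
    )
    bp = np.round(cm * 1_000_000).astype(int)
    variants = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "bp": bp,
            "cM": cm,
            "ref": "A",
            "alt": "G",
            "ancestral_is_ref": True,
            "ancestral_ok": True,
        }
    )
    panel = HaplotypePanel(H, sample_ids, variants)
    expected_fst = 1.0 - (1.0 - 1.0 / (2.0 * cfg.pop_size)) ** cfg.split_generation
    truth = SimulationTruth(
        subpop_labels=labels,
        sweep_site=None if cfg.sweep is None else cfg.sweep.focal_variant_index,
        expected_fst=expected_fst,
        seed=cfg.seed,
    )
    return panel, truth


def simulate_conditioned(
    cfg: SimulationConfig,
    focal_freq_window: tuple[float, float],
    max_tries: int = 500,
) -> tuple[HaplotypePanel, SimulationTruth, int]:
    """Simulate until the focal derived frequency at sampling falls inside
    ``focal_freq_window``; sub-seed k of try k derives from ``cfg.seed``.

    Hard sweeps from one copy are usually lost to drift, so power studies
    condition on the sweep succeeding; lost/fixed trajectories are aborted
    early.  Returns (panel, truth, n_tries).  Raises RuntimeError when
    ``max_tries`` is exhausted.
    """
    if cfg.sweep is None:
        raise ValueError("conditioned simulation needs a sweep config")
    lo, hi = focal_freq_window
    focal = cfg.sweep.focal_variant_index
    for k in range(max_tries):
        sub_cfg = replace(cfg, seed=(cfg.seed + 1_000_003 * k) % (2**31 - 1))
        rng = np.random.default_rng(sub_cfg.seed)
        H = _evolve(sub_cfg, rng, focal_abort=(lo, hi))
        if H is None:
            continue
        f = H[:, focal].mean()
        if lo <= f <= hi:
            panel, truth = _finalize(sub_cfg, H)
            return panel, truth, k + 1
    raise RuntimeError(f"no accepted sweep trajectory in {max_tries} tries")


def emit_dataset(panel: HaplotypePanel, truth: SimulationTruth, out_dir) -> dict[str, str]:
    """Write VCF, genetic map, ancestral table and labels; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "panel.vcf"),
        "map": os.path.join(out_dir, "genetic_map.tsv"),
        "ancestral": os.path.join(out_dir, "ancestral.tsv"),
        "labels": os.path.join(out_dir, "labels.tsv"),
    }
    write_phased_vcf(panel, paths["vcf"])
    knots = {
        str(chrom): sub[["bp", "cM"]].reset_index(drop=True)
        for chrom, sub in panel.variants.groupby("chrom", sort=False)
    }
    write_genetic_map(GeneticMap(knots), paths["map"])
    anc = panel.variants.apply(
        lambda v: v["ref"] if v["ancestral_is_ref"] else v["alt"], axis=1
    )
    tab = panel.variants[["chrom", "bp"]].copy()
    tab["ancestral_allele"] = np.where(
        panel.variants["ancestral_ok"], anc, "N"
    )
    write_ancestral_table(tab, paths["ancestral"])
    write_labels(truth.subpop_labels, paths["labels"])
    return paths
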