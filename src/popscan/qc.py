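"""Variant/sample quality control and population-structure stratification.

The stages mirror standard array-QC practice for a stratified cohort:

1. variant filters — call rate >= 97% and an exact Hardy-Weinberg test at
   alpha = 1e-6 on the pooled sample, with a second stage that *recovers*
   variants failing only because of population stratification (they pass
   HWE within every subgroup separately: the Wahlund effect, not genotyping
   error, explains the pooled deviation);
2. sample filters — call rate, then method-of-moments relatedness (pi-hat
   >= 0.25 removes one member of each close pair);
3. structure — LD pruning (sliding-window r^2), top-k PCA on standardized
   dosages, and a 3-SD PC1/PC2 outlier rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .genio import HaplotypePanel

__all__ = [
    "hwe_exact_test",
    "filter_variants_two_stage",
    "relatedness_pihat",
    "filter_related",
    "ld_prune",
    "pca_top_k",
    "pc_outlier_filter",
    "QcReport",
]


@dataclass
class QcReport:
    initial_variants: int = 0
    removed_call_rate: int = 0
    removed_hwe: int = 0
    recovered_variants: int = 0
    final_variants: int = 0
    removed_samples_call_rate: int = 0
    removed_samples_relatedness: int = 0
    removed_samples_pc_outlier: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def removed_variants(self) -> int:
        return self.removed_call_rate + self.removed_hwe

    def reconciles(self) -> bool:
        return (
            self.final_variants
            == self.initial_variants - self.removed_variants + self.recovered_variants
        )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


@lru_cache(maxsize=100_000)
def _hwe_het_probs(n_a: int, n: int) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Conditional distribution of the heterozygote count given minor-allele
    count ``n_a`` among ``n`` diploids (log-space weights for stability)."""
    from math import lgamma

    def logw(h: int) -> float:
        n_aa = (n_a - h) // 2
        n_AA = n - n_aa - h
        return h * np.log(2.0) - lgamma(n_AA + 1) - lgamma(h + 1) - lgamma(n_aa + 1)

    hets = tuple(range(n_a % 2, n_a + 1, 2))
    hets = tuple(h for h in hets if n - (n_a - h) // 2 - h >= 0)
    lw = np.array([logw(h) for h in hets])
    w = np.exp(lw - lw.max())
    return hets, tuple(w / w.sum())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p-value: total probability of heterozygote counts
    no more likely than the observed one, conditional on allele counts.

    Monomorphic sites return p = 1 (no test possible)."""
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa == 0:
        raise ValueError("genotype counts must be non-negative, not all zero")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # 'a' allele count
    n_a = min(n_a, 2 * n - n_a)  # fold to minor allele
    if n_a == 0:
        return 1.0
    hets, probs = _hwe_het_probs(n_a, n)
    p_obs = probs[hets.index(n_Aa)]
    p = sum(q for q in probs if q <= p_obs * (1 + 1e-12))
    return float(min(p, 1.0))


def _geno_counts(g: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) counts from a dosage vector with NaN missing."""
    g = g[~np.isnan(g)]
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def filter_variants_two_stage(
    panel: HaplotypePanel,
    subpop_labels: pd.Series,
    call_rate_min: float = 0.97,
    hwe_alpha: float = 1e-6,
) -> tuple[HaplotypePanel, QcReport]:
    """Call-rate and pooled-HWE variant filter with per-subgroup recovery.

    A variant failing pooled HWE is recovered iff it passes HWE at the same
    alpha in *every* subgroup separately (subgroups with < 2 samples are
    skipped with a warning).  Call-rate failures are never recovered.
    """
    report = QcReport(
        initial_variants=panel.n_variants,
        thresholds={"call_rate_min": call_rate_min, "hwe_alpha": hwe_alpha},
    )
    G = panel.genotypes()
    cr = panel.call_rate()
    fail_cr = cr < call_rate_min
    hwe_p = np.array([hwe_exact_test(*_geno_counts(G[:, j])) for j in range(G.shape[1])])
    fail_hwe = (hwe_p < hwe_alpha) & ~fail_cr

    groups = []
    for g in pd.unique(subpop_labels):
        members = np.asarray(
            [subpop_labels.get(s) == g for s in panel.sample_ids]
        )
        if members.sum() < 2:
            warnings.warn(f"subgroup {g!r} has < 2 samples; skipped in HWE recovery")
            continue
        groups.append(members)

    recovered = np.zeros(panel.n_variants, dtype=bool)
    for j in np.flatnonzero(fail_hwe):
        ok = bool(groups)
        for members in groups:
            if hwe_exact_test(*_geno_counts(G[members, j])) < hwe_alpha:
                ok = False
                break
        recovered[j] = ok

    keep = ~(fail_cr | (fail_hwe & ~recovered))
    report.removed_call_rate = int(fail_cr.sum())
    report.removed_hwe = int(fail_hwe.sum())
    report.recovered_variants = int(recovered.sum())
    report.final_variants = int(keep.sum())
    return panel.subset_variants(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# relatedness


def relatedness_pihat(panel: HaplotypePanel) -> pd.DataFrame:
    """Method-of-moments pi-hat for every sample pair.

    Expected identity-by-state probabilities given IBD state are computed
    from sample allele frequencies; the observed genome-wide IBS profile is
    inverted for P(IBD=0/1/2) and pi-hat = P(IBD=1)/2 + P(IBD=2), clipped
    to [0, 1].
    """
    G = panel.genotypes()
    p = panel.derived_freq()
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic variants: pi-hat uninformative")
    G = G[:, poly]
    p = p[poly]
    q = 1.0 - p
    # per-site expected IBS-state probabilities for unrelated / one-shared /
    # identical pairs (Purcell-style method of moments, known frequencies)
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    E00, E01 = e0_ibs0.sum(), e0_ibs1.sum()
    E11 = e1_ibs1.sum()

    rows = []
    n = panel.n_samples
    for i in range(n):
        gi = G[i]
        for j in range(i + 1, n):
            gj = G[j]
            ok = ~(np.isnan(gi) | np.isnan(gj))
            diff = np.abs(gi[ok] - gj[ok])
            ibs0 = float((diff == 2).sum())
            ibs1 = float((diff == 1).sum())
            scale = ok.sum() / len(p) if len(p) else 1.0  # missingness rescale
            P0 = ibs0 / (E00 * scale) if E00 > 0 else 0.0
            P1 = (ibs1 - P0 * E01 * scale) / (E11 * scale) if E11 > 0 else 0.0
            P0 = min(max(P0, 0.0), 1.0)
            P1 = min(max(P1, 0.0), 1.0 - P0)
            P2 = 1.0 - P0 - P1
            pihat = min(max(P1 / 2.0 + P2, 0.0), 1.0)
            rows.append(
                {
                    "sample_i": panel.sample_ids[i],
                    "sample_j": panel.sample_ids[j],
                    "pihat": pihat,
                }
            )
    return pd.DataFrame(rows)


def filter_related(
    panel: HaplotypePanel, pihat_max: float = 0.25
) -> tuple[HaplotypePanel, list[str], pd.DataFrame]:
    """Drop one member of each pair with pi-hat >= threshold.

    Greedy: repeatedly remove the sample in the most flagged pairs, breaking
    ties by lower call rate, then by input order.
    """
    table = relatedness_pihat(panel)
    flagged = table.loc[table["pihat"] >= pihat_max]
    pairs = {frozenset((r.sample_i, r.sample_j)) for r in flagged.itertuples()}
    if panel.missing is None:
        sample_cr = {s: 1.0 for s in panel.sample_ids}
    else:
        ok = ~(panel.missing[0::2] | panel.missing[1::2])
        sample_cr = dict(zip(panel.sample_ids, ok.mean(axis=1)))
    order = {s: i for i, s in enumerate(panel.sample_ids)}
    removed: list[str] = []
    pairs = set(pairs)
    while pairs:
        degree: dict[str, int] = {}
        for pr in pairs:
            for s in pr:
                degree[s] = degree.get(s, 0) + 1
        victim = min(
            degree, key=lambda s: (-degree[s], sample_cr[s], -order[s])
        )
        # tie-break: most pairs first, then lower call rate, then later input
        removed.append(victim)
        pairs = {pr for pr in pairs if victim not in pr}
    keep = [s for s in panel.sample_ids if s not in set(removed)]
    return panel.subset_samples(keep), removed, table


# ---------------------------------------------------------------------------
# LD pruning and PCA


def ld_prune(
    panel: HaplotypePanel,
    window_snps: int = 100,
    step_snps: int = 10,
    r2_max: float = 0.2,
    maf_min: float = 0.05,
) -> np.ndarray:
    """Sliding-window greedy LD pruning on genotype r^2.

    Within each window, for every pair exceeding ``r2_max`` the later-indexed
    variant is removed; the window then advances by ``step_snps``.  Variants
    below ``maf_min`` are excluded up front.  Missing genotypes are
    mean-imputed for the correlation.  Returns surviving variant indices
    (into the input panel).
    """
    candidates = np.flatnonzero(panel.maf() >= maf_min)
    G = panel.genotypes()
    mu = np.nanmean(G, axis=0)
    Z = np.where(np.isnan(G), mu, G) - mu
    norms = np.sqrt((Z**2).sum(axis=0))
    norms[norms == 0] = 1.0
    Z = Z / norms  # unit columns: r = dot product
    alive = {int(c) for c in candidates}
    cand = list(map(int, candidates))
    start = 0
    while start < len(cand):
        window = [c for c in cand[start : start + window_snps] if c in alive]
        if len(window) > 1:
            C = Z[:, window].T @ Z[:, window]
            r2 = C * C
            for x in range(len(window)):
                if window[x] not in alive:
                    continue
                for y in range(x + 1, len(window)):
                    if window[y] in alive and r2[x, y] > r2_max:
                        alive.discard(window[y])
        start += step_snps
    return np.array(sorted(alive), dtype=int)


def pca_top_k(
    panel: HaplotypePanel, k: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """PCA on centered, frequency-standardized dosages.

    Returns (scores, loadings): scores is (n_samples, k); loadings columns
    are orthonormal.  If the matrix rank is below ``k`` the returned
    components are truncated with a warning.
    """
    G = panel.genotypes()
    p = np.nanmean(G, axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    G = G[:, keep]
    p = p[keep]
    X = (np.nan_to_num(G, nan=0.0) - 2 * p) / np.sqrt(2 * p * (1 - p))
    if k > min(X.shape):
        warnings.warn(f"k={k} exceeds rank bound; truncating")
        k = min(X.shape)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum()) if len(S) else 0
    if rank < k:
        warnings.warn(f"matrix rank {rank} < k={k}; truncating components")
        k = rank
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T
    return scores, loadings


def pc_outlier_filter(scores: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    """Indices of samples more than ``n_sd`` SD from the mean on PC1 or PC2
    (single pass, no recomputation)."""
    out = np.zeros(scores.shape[0], dtype=bool)
    for pc in range(min(2, scores.shape[1])):
        col = scores[:, pc]
        out |= np.abs(col - col.mean()) > n_sd * col.std()
    return np.flatnonzero(out)
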