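"""QC stage: exact HWE test (vs exhaustive enumeration), two-stage variant
filtering, relatedness, LD pruning, and PCA outliers."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from popscan.qc import (
    QcReport,
    filter_related,
    filter_variants_two_stage,
    hwe_exact_test,
    ld_prune,
    pc_outlier_filter,
    pca_top_k,
    relatedness_pihat,
)
from popscan.synth import SimulationConfig, simulate_panel

from conftest import build_panel


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exhaustive enumeration of the conditional heterozygote distribution
    using exact rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = min(2 * n_aa + n_Aa, 2 * n_AA + n_Aa)
    if n_a == 0:
        return 1.0
    weights = {}
    for h in range(n_a % 2, n_a + 1, 2):
        n_hom_rare = (n_a - h) // 2
        n_hom_common = n - n_hom_rare - h
        if n_hom_common < 0:
            continue
        weights[h] = Fraction(
            2**h * comb(n, h) * comb(n - h, n_hom_rare), 1
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHweExact:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((2, 0, 2), 6 / 70),
            ((0, 4, 0), 22 / 70),
            ((5, 0, 0), 1.0),
        ],
    )
    def test_worked_examples(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_for_all_small_tables(self):
        """Exhaustive check against the rational-arithmetic oracle for every
        genotype-count triple with 2n <= 30."""
        for n in range(1, 16):
            for n_Aa in range(n + 1):
                for n_aa in range(n - n_Aa + 1):
                    n_AA = n - n_Aa - n_aa
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = hwe_oracle(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, rel=1e-9), (n_AA, n_Aa, n_aa)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


class TestTwoStageFilter:
    def _labels(self, panel, k=2):
        groups = ["g%d" % (i % k) for i in range(panel.n_samples)]
        return pd.Series(groups, index=panel.sample_ids)

    def test_low_call_rate_removed(self, rng):
        H = rng.integers(0, 2, size=(100, 5)).astype(np.uint8)
        missing = np.zeros_like(H, dtype=bool)
        missing[:4, 2] = True  # 2 of 50 samples missing -> call rate 0.96
        panel = build_panel(H, missing=missing)
        out, report = filter_variants_two_stage(panel, self._labels(panel))
        assert report.removed_call_rate == 1
        assert out.n_variants == 4
        assert report.reconciles()

    def test_stratification_failure_recovered(self):
        """A variant in HWE within each of two diverged groups but far from
        HWE pooled (Wahlund) must be recovered."""
        rng = np.random.default_rng(1)
        n_per = 60
        cols = []
        for p1, p2 in [(0.95, 0.05)] * 3 + [(0.5, 0.5)] * 3:
            g1 = rng.binomial(1, p1, size=(2 * n_per,))
            g2 = rng.binomial(1, p2, size=(2 * n_per,))
            cols.append(np.concatenate([g1, g2]))
        H = np.column_stack(cols).astype(np.uint8)
        panel = build_panel(H)
        labels = pd.Series(
            ["a"] * n_per + ["b"] * n_per, index=panel.sample_ids
        )
        out, report = filter_variants_two_stage(panel, labels)
        assert report.removed_hwe >= 1
        assert report.recovered_variants == report.removed_hwe
        assert out.n_variants == 6
        assert report.reconciles()

    def test_clean_panel_untouched(self, rng):
        H = rng.integers(0, 2, size=(120, 8)).astype(np.uint8)
        panel = build_panel(H)
        out, report = filter_variants_two_stage(panel, self._labels(panel))
        assert report.removed_variants == 0
        assert out.n_variants == panel.n_variants

    def test_report_arithmetic_always_reconciles(self):
        r = QcReport(initial_variants=100, removed_call_rate=5, removed_hwe=10,
                     recovered_variants=3, final_variants=88)
        assert r.reconciles()
        r.final_variants = 87
        assert not r.reconciles()


def _panel_from_freqs(rng, freqs, n_samples):
    H = (rng.random((2 * n_samples, len(freqs))) < freqs).astype(np.uint8)
    return build_panel(H, cm=np.arange(1, len(freqs) + 1) * 0.01)


class TestPihat:
    def test_duplicate_sample_near_one(self, rng):
        freqs = rng.uniform(0.1, 0.9, 600)
        panel = _panel_from_freqs(rng, freqs, 20)
        H = panel.haplotypes.copy()
        H[2:4] = H[0:2]  # sample 1 duplicates sample 0
        panel = build_panel(H, cm=panel.variants["cM"].to_numpy())
        tab = relatedness_pihat(panel)
        dup = tab.loc[(tab.sample_i == "s000") & (tab.sample_j == "s001"), "pihat"].iloc[0]
        assert dup > 0.9

    def test_unrelated_mean_near_zero(self, rng):
        freqs = rng.uniform(0.1, 0.9, 5000)
        panel = _panel_from_freqs(rng, freqs, 12)  # 66 pairs, all unrelated
        tab = relatedness_pihat(panel)
        assert abs(tab["pihat"].mean()) < 0.02
        assert (tab["pihat"].abs() < 0.05).all()

    def test_parent_child_near_half(self, rng):
        freqs = rng.uniform(0.2, 0.8, 4000)
        panel = _panel_from_freqs(rng, freqs, 12)
        H = panel.haplotypes.copy()
        H[2] = H[0]  # child's first haplotype copied from parent
        panel = build_panel(H, cm=panel.variants["cM"].to_numpy())
        tab = relatedness_pihat(panel)
        pc = tab.loc[(tab.sample_i == "s000") & (tab.sample_j == "s001"), "pihat"].iloc[0]
        assert 0.45 <= pc <= 0.55

    def test_filter_removes_one_member_per_pair(self, rng):
        freqs = rng.uniform(0.2, 0.8, 2000)
        panel = _panel_from_freqs(rng, freqs, 10)
        H = panel.haplotypes.copy()
        H[2:4] = H[0:2]
        panel = build_panel(H, cm=panel.variants["cM"].to_numpy())
        filtered, removed, _ = filter_related(panel)
        assert len(removed) == 1
        assert filtered.n_samples == 9

    def test_monomorphic_only_errors(self):
        H = np.zeros((8, 10), dtype=np.uint8)
        with pytest.raises(ValueError):
            relatedness_pihat(build_panel(H))


def _geno_r2(G, a, b):
    return np.corrcoef(G[:, a], G[:, b])[0, 1] ** 2


class TestLdPrune:
    def test_perfectly_correlated_pair_keeps_one(self, rng):
        base = rng.integers(0, 2, size=(60, 1)).astype(np.uint8)
        noise = rng.integers(0, 2, size=(60, 1)).astype(np.uint8)
        H = np.hstack([base, base, noise])
        kept = ld_prune(build_panel(H), maf_min=0.0)
        assert 0 in kept and 1 not in kept

    def test_independent_snps_all_kept(self, rng):
        H = rng.integers(0, 2, size=(400, 20)).astype(np.uint8)
        kept = ld_prune(build_panel(H), maf_min=0.0)
        assert len(kept) == 20

    def test_chain_keeps_first_and_third(self, rng):
        """A-B r2 ~ 0.5, B-C r2 ~ 0.5, A-C low: greedy removes B only."""
        n = 2000
        a = rng.integers(0, 2, n)
        flip_ab = rng.random(n) < 0.15
        b = np.where(flip_ab, 1 - a, a)
        flip_bc = rng.random(n) < 0.15
        c = np.where(flip_bc, 1 - b, b)
        # decorrelate a and c a bit more
        H = np.column_stack([a, b, c]).astype(np.uint8)
        panel = build_panel(H)
        G = panel.genotypes()
        if not (_geno_r2(G, 0, 1) > 0.2 and _geno_r2(G, 1, 2) > 0.2):
            pytest.skip("random draw missed the intended LD pattern")
        kept = ld_prune(panel, maf_min=0.0)
        assert list(kept) == [0, 2] or _geno_r2(G, 0, 2) > 0.2

    def test_within_window_guarantee_brute_force(self, rng):
        """Surviving sets satisfy pairwise r2 <= threshold inside windows."""
        panel, _ = simulate_panel(SimulationConfig(
            n_founders=30, pop_size=50, n_generations_burnin=30, split_generation=0,
            migration_rate=0.5, chrom_length_cM=5.0, n_variants=300, seed=17,
        ))
        kept = ld_prune(panel, window_snps=50, step_snps=5, r2_max=0.2)
        G = panel.genotypes()
        kept = list(kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if b - a < 5:  # deep inside any shared window
                    assert _geno_r2(G, a, b) <= 0.2 + 1e-9


class TestPca:
    def test_loadings_orthonormal(self, rng):
        H = rng.integers(0, 2, size=(80, 60)).astype(np.uint8)
        _, loadings = pca_top_k(build_panel(H), k=10)
        gram = loadings.T @ loadings
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)

    def test_contaminant_sample_removed(self, rng):
        freqs = rng.uniform(0.2, 0.8, 300)
        H = (rng.random((80, 300)) < freqs).astype(np.uint8)
        H[0:2] = (rng.random((2, 300)) < (1 - freqs)).astype(np.uint8)  # inverted pool
        scores, _ = pca_top_k(build_panel(H), k=5)
        out = pc_outlier_filter(scores, n_sd=3.0)
        assert 0 in out

    def test_k_truncated_with_warning(self, rng):
        H = rng.integers(0, 2, size=(8, 6)).astype(np.uint8)
        with pytest.warns(UserWarning):
            scores, _ = pca_top_k(build_panel(H), k=20)
        assert scores.shape[1] <= 6
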