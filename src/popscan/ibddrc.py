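"""Identity-by-descent segment detection and the density-of-recent-
coalescence (DRC) scan with an empirical Gamma null.

IBD detection is a hash-seeded exact-match-and-extend heuristic in the
GERMLINE family: haplotype pairs sharing an identical run of ``seed_snps``
consecutive alleles are candidate relatives; each seed is extended outward,
tolerating isolated mismatches (genotyping error) but stopping where
mismatches cluster — two mismatches closer than 1/max_mismatch_per_cM cM
indicate the shared tract has ended.  Segment age in generations is the
length-based heuristic g-hat = 50 / length_cM: an IBD tract inherited from
a common ancestor g generations back has expected genetic length 100/(2g)
cM, since recombination in either lineage breaks it.

DRC_T for a 0.05-cM bin sums the quality scores of segments whose estimated
age is at most T generations and which overlap the bin, normalized by the
number of haplotype pairs, so it is a bounded per-pair density in [0, 1].
Under neutrality most bins carry little recent sharing; a sweep concentrates
many long (young) shared haplotypes at one place.  A Gamma null is fitted to
the bin values on putatively neutral regions, defined iteratively by
excluding bins that reject under the current fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import HaplotypePanel

__all__ = [
    "IbdSegment",
    "DrcBin",
    "GammaNull",
    "detect_ibd",
    "estimate_age",
    "drc_bins",
    "fit_gamma_null",
    "drc_pvalues",
]

#: expected IBD tract length (cM) from an ancestor 1 generation back;
#: age_hat = AGE_LENGTH_CONST / length_cM
AGE_LENGTH_CONST = 50.0


@dataclass(frozen=True)
class IbdSegment:
    hap_i: int
    hap_j: int
    chrom: str
    start_cM: float
    end_cM: float
    quality: float

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM

    @property
    def age_hat(self) -> float:
        return estimate_age(self.length_cM)


@dataclass
class GammaNull:
    shape: float
    rate: float
    excluded_bins: np.ndarray
    n_iterations: int
    converged: bool
    zero_fraction: float


def estimate_age(length_cM: float) -> float:
    """Heuristic TMRCA in generations from IBD tract length: 50 / length."""
    if length_cM <= 0:
        raise ValueError("IBD length must be positive")
    return AGE_LENGTH_CONST / length_cM


def _extend_pair(
    mismatch_cm: np.ndarray,
    seed_lo: float,
    seed_hi: float,
    chrom_lo: float,
    chrom_hi: float,
    min_gap_cM: float,
) -> tuple[float, float]:
    """Maximal interval around a clean seed obeying the local mismatch rule.

    The interval may absorb isolated mismatches; it ends just inside the
    first pair of mismatches separated by less than ``min_gap_cM``, or at a
    chromosome end."""
    left = np.searchsorted(mismatch_cm, seed_lo)  # mismatches below seed
    right = np.searchsorted(mismatch_cm, seed_hi)  # first mismatch above seed
    # walk right: absorb mismatch k if the next one is at least min_gap away
    k = right
    while k < len(mismatch_cm):
        nxt = mismatch_cm[k + 1] if k + 1 < len(mismatch_cm) else np.inf
        if nxt - mismatch_cm[k] < min_gap_cM:
            break
        k += 1
    hi = chrom_hi if k == len(mismatch_cm) else mismatch_cm[k]
    k = left - 1
    while k >= 0:
        prv = mismatch_cm[k - 1] if k - 1 >= 0 else -np.inf
        if mismatch_cm[k] - prv < min_gap_cM:
            break
        k -= 1
    lo = chrom_lo if k < 0 else mismatch_cm[k]
    return lo, hi


def detect_ibd(
    panel: HaplotypePanel,
    min_length_cM: float = 1.0,
    max_mismatch_per_cM: float = 1.0,
    seed_snps: int = 64,
    seed_step: int | None = None,
    maf_min: float = 0.05,
) -> list[IbdSegment]:
    """Hash-seeded IBD detection over all haplotype pairs of a phased panel.

    Windows of ``seed_snps`` consecutive *informative* sites (sample MAF >=
    ``maf_min``; rare-allele stretches match between any two haplotypes and
    would seed spurious segments), starting every ``seed_step`` sites
    (default seed_snps // 2, so tracts barely longer than one window still
    contain an aligned window), are hashed; pairs identical across a window
    are extended in both directions under the local mismatch-density rule,
    overlapping extensions of one pair are merged, and segments of at least
    ``min_length_cM`` are reported with quality = fraction of matching
    informative sites inside the segment.  Genetic lengths are on the
    panel's cM map regardless of the filter.
    """
    if "cM" not in panel.variants or panel.variants["cM"].isna().any():
        raise ValueError("panel lacks cM positions; interpolate a genetic map first")
    if seed_step is None:
        seed_step = max(seed_snps // 2, 1)
    keep = panel.maf() >= maf_min
    if keep.sum() < seed_snps:
        raise ValueError("too few informative markers for one seed window")
    H = np.ascontiguousarray(panel.haplotypes[:, keep])
    cm = panel.variants["cM"].to_numpy(dtype=float)[keep]
    chrom = str(panel.variants["chrom"].iloc[0])
    n, m = H.shape
    min_gap = 1.0 / max_mismatch_per_cM
    chrom_lo, chrom_hi = cm[0], cm[-1]

    # candidate pairs: share at least one exact seed window
    pair_seeds: dict[tuple[int, int], list[int]] = {}
    for w0 in range(0, m - seed_snps + 1, seed_step):
        window = H[:, w0 : w0 + seed_snps]
        buckets: dict[bytes, list[int]] = {}
        for h in range(n):
            buckets.setdefault(window[h].tobytes(), []).append(h)
        for rows in buckets.values():
            for a in range(len(rows)):
                for b in range(a + 1, len(rows)):
                    pair_seeds.setdefault((rows[a], rows[b]), []).append(w0)

    segments: list[IbdSegment] = []
    for (i, j), seeds in pair_seeds.items():
        mismatch_cm = cm[H[i] != H[j]]
        intervals: list[tuple[float, float]] = []
        for w0 in seeds:  # ascending; skip seeds inside the last extension
            hi_seed = cm[w0 + seed_snps - 1]
            if intervals and hi_seed <= intervals[-1][1]:
                continue
            lo, hi = _extend_pair(
                mismatch_cm, cm[w0], hi_seed, chrom_lo, chrom_hi, min_gap
            )
            intervals.append((lo, hi))
        intervals.sort()
        merged: list[list[float]] = []
        for lo, hi in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            if hi - lo < min_length_cM:
                continue
            n_inside = int(
                np.searchsorted(cm, hi, "right") - np.searchsorted(cm, lo, "left")
            )
            n_bad = int(
                np.searchsorted(mismatch_cm, hi, "right")
                - np.searchsorted(mismatch_cm, lo, "left")
            )
            quality = 1.0 - n_bad / n_inside if n_inside else 1.0
            segments.append(IbdSegment(i, j, chrom, float(lo), float(hi), quality))
    segments.sort(key=lambda s: (s.hap_i, s.hap_j, s.start_cM))
    return segments


def segments_to_table(segments: list[IbdSegment]) -> pd.DataFrame:
    """GERMLINE-like TSV shape for exporting detected segments."""
    return pd.DataFrame(
        [
            {
                "hap_i": s.hap_i,
                "hap_j": s.hap_j,
                "chrom": s.chrom,
                "start_cM": s.start_cM,
                "end_cM": s.end_cM,
                "length_cM": s.length_cM,
                "quality": s.quality,
                "age_hat": s.age_hat,
            }
            for s in segments
        ],
        columns=[
            "hap_i", "hap_j", "chrom", "start_cM", "end_cM",
            "length_cM", "quality", "age_hat",
        ],
    )


def drc_bins(
    segments: list[IbdSegment],
    chrom_start_cM: float,
    chrom_end_cM: float,
    n_haplotypes: int,
    timescales: tuple[float, ...] = (20.0, 50.0, 150.0),
    bin_size_cM: float = 0.05,
    chrom: str = "1",
) -> pd.DataFrame:
    """Per-bin DRC_T for each timescale T.

    Bins tile [chrom_start_cM, chrom_end_cM) without overlap.  A bin's
    DRC_T sums the quality of segments with age_hat <= T overlapping the
    bin (each haplotype pair counted once per bin), divided by the number
    of haplotype pairs C(n_haplotypes, 2).
    """
    if n_haplotypes < 2:
        raise ValueError("need >= 2 haplotypes")
    n_pairs = n_haplotypes * (n_haplotypes - 1) / 2.0
    edges = np.arange(chrom_start_cM, chrom_end_cM + bin_size_cM, bin_size_cM)
    n_bins = len(edges) - 1
    if n_bins < 1:
        raise ValueError("chromosome shorter than one bin")
    # difference-array accumulation: segment covering bins [b0, b1] adds its
    # quality at b0 and removes it past b1; the bin profile is the cumsum.
    # Segments of one pair are disjoint in cM, so the same pair can touch a
    # bin twice only when consecutive segments fall in one bin — corrected
    # to count the pair once (with the larger quality).
    acc = {T: np.zeros(n_bins + 1) for T in timescales}
    last: dict[tuple[int, int], tuple[int, float]] = {}
    for s in segments:  # sorted by (hap_i, hap_j, start_cM)
        age = s.age_hat
        b0 = max(int(np.floor((s.start_cM - chrom_start_cM) / bin_size_cM)), 0)
        b1 = min(int(np.floor((s.end_cM - chrom_start_cM) / bin_size_cM)), n_bins - 1)
        if b1 < 0 or b0 > n_bins - 1:
            continue
        for T in timescales:
            if age > T:
                continue
            key = (s.hap_i, s.hap_j, T)
            prev = last.get(key)
            acc[T][b0] += s.quality
            acc[T][b1 + 1] -= s.quality
            carry = s.quality
            if prev is not None and prev[0] == b0:
                # collision bin: keep the max quality, not the sum
                overlap = min(prev[1], s.quality)
                acc[T][b0] -= overlap
                acc[T][b0 + 1] += overlap
                carry = max(prev[1], s.quality)
            last[key] = (b1, carry if b1 == b0 else s.quality)
    drc = {T: np.cumsum(acc[T][:-1]) / n_pairs for T in timescales}
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start_cM": edges[:-1][:n_bins],
            "end_cM": edges[1:][:n_bins],
        }
    )
    for T in timescales:
        out[f"drc_{int(T)}"] = drc[T]
    return out


def fit_gamma_null(
    drc_values: np.ndarray,
    alpha_exclude: float = 1e-4,
    max_iter: int = 20,
) -> GammaNull:
    """Iteratively fit a Gamma null to DRC values on neutral-looking bins.

    Each round fits shape/rate by maximum likelihood (moment initialization,
    location fixed at 0) on currently included positive bins, computes
    upper-tail p-values for all bins, and excludes bins with p <
    ``alpha_exclude``; iteration stops when the exclusion set is stable.
    Zero-valued bins never enter the likelihood; their mass is recorded in
    ``zero_fraction``.
    """
    x = np.asarray(drc_values, dtype=float)
    pos = x[x > 0]
    if len(pos) < 2 or np.ptp(pos) == 0.0:
        raise ValueError("degenerate DRC values: cannot fit a Gamma null")
    zero_fraction = 1.0 - len(pos) / len(x)
    included = np.ones(len(pos), dtype=bool)
    shape = rate = None
    converged = False
    for it in range(1, max_iter + 1):
        sample = pos[included]
        if len(sample) < 2 or np.ptp(sample) == 0.0:
            raise ValueError("exclusion removed too many bins to fit")
        mean, var = sample.mean(), sample.var()
        k0 = mean**2 / var if var > 0 else 1.0
        shape, _, scale = stats.gamma.fit(sample, k0, floc=0.0, scale=mean / max(k0, 1e-12))
        rate = 1.0 / scale
        p = stats.gamma.sf(pos, shape, scale=scale)
        new_included = p >= alpha_exclude
        if (new_included == included).all():
            converged = True
            included = new_included
            break
        included = new_included
    return GammaNull(
        shape=float(shape),
        rate=float(rate),
        excluded_bins=np.flatnonzero(~included),
        n_iterations=it,
        converged=converged,
        zero_fraction=float(zero_fraction),
    )


def drc_pvalues(
    bins: pd.DataFrame, null: "GammaNull | dict", timescales=(20, 50, 150)
) -> pd.DataFrame:
    """One-sided upper-tail Gamma p-values for each bin and timescale.

    ``null`` is a single fitted :class:`GammaNull` applied to every
    timescale, or a mapping timescale -> GammaNull (each statistic has its
    own empirical null in a full scan).
    """
    out = bins.copy()
    for T in timescales:
        col = f"drc_{int(T)}"
        if col not in out:
            continue
        nl = null[T] if isinstance(null, dict) else null
        out[f"p_{col}"] = stats.gamma.sf(
            out[col].to_numpy(dtype=float), nl.shape, scale=1.0 / nl.rate
        )
    return out
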