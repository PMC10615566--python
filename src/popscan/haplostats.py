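"""Extended haplotype homozygosity (EHH), integrated haplotype homozygosity
(iHH), the integrated haplotype score (iHS), frequency-bin normalization,
and approximate normal p-values.

At a core SNP, EHH(x) for one allele is the probability that two randomly
drawn carrier haplotypes are identical at every marker between the core and
distance x.  iHH integrates EHH over genetic distance (trapezoid rule) out
to the first marker where EHH drops below a cutoff (default 0.05; the
crossing trapezoid is included).  The raw score

    iHS_raw = ln(iHH_ancestral / iHH_derived)

is standardized within derived-allele-frequency bins (100 equal-width bins
on (0, 1)), because the expected haplotype length depends strongly on allele
frequency; extreme standardized scores in either direction indicate
unusually long haplotypes around one allele, the footprint of a recent
partial sweep.  Two-sided normal p-values are attached to the standardized
scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import HaplotypePanel

__all__ = [
    "EhhCurve",
    "ehh_curve",
    "integrate_ihh",
    "ihs_scan",
    "normalize_ihs",
    "ihs_pvalue",
]

try:  # JIT the inner walk when numba is present; identical semantics without it
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _ihh_walk(H, carriers, cm, core, step, cutoff):  # pragma: no cover - jit
    """One-sided iHH by walking outward, refining the identity partition of
    the carrier haplotypes and accumulating trapezoids; stops after the
    first marker with EHH < cutoff.  Returns (iHH, edge_truncated)."""
    n = carriers.size
    pairs = n * (n - 1) / 2.0
    labels = np.zeros(n, dtype=np.int64)
    n_lab = 1
    prev_d = 0.0
    prev_e = 1.0
    total = 0.0
    j = core + step
    truncated = True
    newlab = np.empty(n, dtype=np.int64)
    while 0 <= j < H.shape[1]:
        counts = np.zeros(2 * n_lab, dtype=np.int64)
        for t in range(n):
            l = 2 * labels[t] + H[carriers[t], j]
            newlab[t] = l
            counts[l] += 1
        s = 0.0
        for c in counts:
            s += c * (c - 1) / 2.0
        e = s / pairs
        d = abs(cm[j] - cm[core])
        total += (d - prev_d) * (e + prev_e) / 2.0
        prev_d = d
        prev_e = e
        if e < cutoff:
            truncated = False
            break
        remap = np.full(2 * n_lab, -1, dtype=np.int64)
        k = 0
        for t in range(n):
            l = newlab[t]
            if remap[l] < 0:
                remap[l] = k
                k += 1
            labels[t] = remap[l]
        n_lab = k
        j += step
    return total, truncated


@dataclass
class EhhCurve:
    """EHH values at marker positions on one side of (and including) a core.

    ``distance_cM`` is non-negative genetic distance from the core (the
    first point is the core itself, distance 0, EHH 1); ``edge_truncated``
    marks curves that hit the chromosome end before decaying below the
    integration cutoff.
    """

    core_variant: int
    allele: int  # 0 ancestral, 1 derived
    distance_cM: np.ndarray = field(default_factory=lambda: np.zeros(1))
    ehh: np.ndarray = field(default_factory=lambda: np.ones(1))
    edge_truncated: bool = False


def _ehh_one_side(
    H: np.ndarray, cm: np.ndarray, carriers: np.ndarray, core: int, step: int,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Walk outward from ``core`` refining the identity partition of the
    carrier haplotypes; stops after the first marker with EHH < cutoff.

    Returns (distances, ehh values) including the core point, plus an
    edge-truncation flag."""
    n = len(carriers)
    pairs = n * (n - 1) / 2.0
    labels = np.zeros(n, dtype=np.int64)
    dist = [0.0]
    ehh = [1.0]
    j = core + step
    truncated = True
    while 0 <= j < H.shape[1]:
        alleles = H[carriers, j].astype(np.int64)
        # refine partition: group identity = (old group, new allele)
        labels = labels * 2 + alleles
        _, labels, counts = np.unique(labels, return_inverse=True, return_counts=True)
        e = float((counts * (counts - 1)).sum() / 2.0 / pairs)
        dist.append(abs(cm[j] - cm[core]))
        ehh.append(e)
        if e < cutoff:
            truncated = False
            break
        j += step
    return np.asarray(dist), np.asarray(ehh), truncated


def ehh_curve(
    panel: HaplotypePanel, core_idx: int, allele: int, side: int = +1,
    cutoff: float = 0.0,
) -> EhhCurve:
    """EHH curve on one side of a core SNP for carriers of ``allele``.

    ``side`` is +1 (increasing position) or -1.  ``cutoff`` = 0 computes the
    full curve to the chromosome edge.  Fewer than 2 carriers is an error
    (EHH undefined).
    """
    H = panel.haplotypes
    carriers = np.flatnonzero(H[:, core_idx] == allele)
    if len(carriers) < 2:
        raise ValueError(f"< 2 carriers of allele {allele} at variant {core_idx}")
    cm = panel.variants["cM"].to_numpy(dtype=float)
    d, e, trunc = _ehh_one_side(H, cm, carriers, core_idx, +1 if side >= 0 else -1, cutoff)
    return EhhCurve(core_idx, allele, d, e, trunc)


def integrate_ihh(curve: EhhCurve, ehh_cutoff: float = 0.05) -> tuple[float, bool]:
    """Trapezoid-integrate one side's EHH curve over genetic distance.

    Integration proceeds outward and stops after the first marker whose EHH
    is below ``ehh_cutoff`` (that marker's trapezoid is included).  Returns
    (iHH contribution in cM, edge_truncated): the flag is set when the curve
    ends (chromosome edge) before crossing the cutoff.
    """
    d, e = curve.distance_cM, curve.ehh
    total = 0.0
    for i in range(1, len(d)):
        total += (d[i] - d[i - 1]) * (e[i] + e[i - 1]) / 2.0
        if e[i] < ehh_cutoff:
            return total, False
    return total, True


def _ihh_both_sides(
    panel: HaplotypePanel, core: int, allele: int, cutoff: float
) -> tuple[float, bool]:
    total = 0.0
    truncated = False
    H = panel.haplotypes
    cm = panel.variants["cM"].to_numpy(dtype=float)
    carriers = np.flatnonzero(H[:, core] == allele).astype(np.int64)
    if len(carriers) < 2:
        return 0.0, False  # undefined: too few carriers to form a pair
    for step in (+1, -1):
        side, trunc = _ihh_walk(H, carriers, cm, core, step, cutoff)
        total += side
        truncated |= trunc
    return total, truncated


def ihs_scan(
    panel: HaplotypePanel, maf_min: float = 0.01, ehh_cutoff: float = 0.05
) -> pd.DataFrame:
    """Raw (unstandardized) iHS for every passing variant of a polarized panel.

    Variants are skipped (not scored) when their MAF is below ``maf_min`` or
    their ancestral state is not established (``ancestral_ok`` False).
    Variants with zero iHH for either allele are kept but flagged
    ``undefined`` and excluded from normalization.
    """
    freqs = panel.derived_freq()
    maf = np.minimum(freqs, 1 - freqs)
    anc_ok = panel.variants["ancestral_ok"].to_numpy(dtype=bool)
    rows = []
    for j in np.flatnonzero((maf >= maf_min) & anc_ok):
        ihh_a, tr_a = _ihh_both_sides(panel, j, 0, ehh_cutoff)
        ihh_d, tr_d = _ihh_both_sides(panel, j, 1, ehh_cutoff)
        undefined = ihh_a <= 0.0 or ihh_d <= 0.0
        rows.append(
            {
                "variant": j,
                "chrom": panel.variants.at[j, "chrom"],
                "bp": panel.variants.at[j, "bp"],
                "cM": panel.variants.at[j, "cM"],
                "daf": freqs[j],
                "ihh_a": ihh_a,
                "ihh_d": ihh_d,
                "ihs_raw": np.nan if undefined else float(np.log(ihh_a / ihh_d)),
                "edge_truncated": bool(tr_a or tr_d),
                "undefined": undefined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "chrom", "bp", "cM", "daf", "ihh_a", "ihh_d",
            "ihs_raw", "edge_truncated", "undefined",
        ],
    )


def normalize_ihs(records: pd.DataFrame, n_bins: int = 100) -> pd.DataFrame:
    """Standardize raw iHS within equal-width derived-allele-frequency bins.

    Bins partition (0, 1) into ``n_bins`` intervals.  Bins holding fewer
    than 2 defined scores, or with zero spread, leave their members flagged
    (``norm_undefined``) with NaN ``ihs_norm``; the sample SD (ddof=1) is
    used otherwise.
    """
    out = records.copy()
    out["ihs_norm"] = np.nan
    out["norm_undefined"] = True
    defined = ~out["undefined"] & np.isfinite(out["ihs_raw"])
    bins = np.clip((out["daf"] * n_bins).astype(int), 0, n_bins - 1)
    out["daf_bin"] = bins
    for b, sub in out.loc[defined].groupby("daf_bin"):
        if len(sub) < 2:
            continue
        sd = sub["ihs_raw"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        mean = sub["ihs_raw"].mean()
        out.loc[sub.index, "ihs_norm"] = (sub["ihs_raw"] - mean) / sd
        out.loc[sub.index, "norm_undefined"] = False
    return out


def ihs_pvalue(records: pd.DataFrame) -> pd.DataFrame:
    """Two-sided standard-normal p-values for standardized iHS scores."""
    out = records.copy()
    z = out["ihs_norm"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out["p_ihs"] = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    return out
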