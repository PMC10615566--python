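"""Hudson F_ST per SNP, weighted genome-wide means with block-jackknife
standard errors, scaled-chi-square approximate p-values, and the small
association helpers used alongside the differentiation scan.

The per-SNP estimator is the Hudson/Bhatia ratio form

    N = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    F_ST = N / D

and multi-SNP summaries use the ratio-of-averages (sum N / sum D), which is
the recommended weighting for combining loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hudson_fst_snp",
    "hudson_fst_table",
    "weighted_mean_fst",
    "fst_pvalues",
    "chi2_2x2",
    "ld_r2",
]


@dataclass(frozen=True)
class FstRecord:
    p1: float
    p2: float
    n1: int
    n2: int
    N_term: float
    D_term: float
    fst: float
    monomorphic: bool


def hudson_fst_snp(p1: float, n1: int, p2: float, n2: int) -> FstRecord:
    """Hudson estimator at one biallelic site.

    n1, n2 are allele (haplotype) sample sizes.  Sites monomorphic in both
    populations (D = 0) are flagged rather than given a value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need allele sample sizes >= 2 in each population")
    N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    D = p1 * (1 - p2) + p2 * (1 - p1)
    if D == 0.0:
        return FstRecord(p1, p2, n1, n2, N, D, np.nan, True)
    return FstRecord(p1, p2, n1, n2, N, D, N / D, False)


def hudson_fst_table(
    p1: np.ndarray, n1: int, p2: np.ndarray, n2: int
) -> pd.DataFrame:
    """Vectorized per-SNP Hudson F_ST; monomorphic-in-both sites get
    ``monomorphic = True`` and NaN fst."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    N = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    D = p1 * (1 - p2) + p2 * (1 - p1)
    mono = D == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(mono, np.nan, N / np.where(mono, 1.0, D))
    return pd.DataFrame(
        {"p1": p1, "p2": p2, "N_term": N, "D_term": D, "fst": fst, "monomorphic": mono}
    )


def weighted_mean_fst(
    records: pd.DataFrame, n_blocks: int = 100
) -> tuple[float, float]:
    """Ratio-of-averages F_ST with a delete-one-block jackknife SE.

    Blocks are contiguous runs of (polymorphic) records in input order, as
    close to equal size as possible.  With fewer than ``n_blocks`` usable
    records the jackknife runs over what is available (warning semantics are
    the caller's concern); with < 2 blocks the SE is NaN.
    """
    use = records.loc[~records["monomorphic"]]
    N = use["N_term"].to_numpy(dtype=float)
    D = use["D_term"].to_numpy(dtype=float)
    if len(N) == 0:
        raise ValueError("no polymorphic records")
    theta = N.sum() / D.sum()
    B = min(n_blocks, len(N))
    if B < 2:
        return float(theta), float("nan")
    edges = np.linspace(0, len(N), B + 1).astype(int)
    cumN = np.concatenate([[0.0], np.cumsum(N)])
    cumD = np.concatenate([[0.0], np.cumsum(D)])
    blockN = cumN[edges[1:]] - cumN[edges[:-1]]
    blockD = cumD[edges[1:]] - cumD[edges[:-1]]
    loo = (N.sum() - blockN) / (D.sum() - blockD)
    se = np.sqrt((B - 1) / B * np.sum((loo - loo.mean()) ** 2))
    return float(theta), float(se)


def fst_pvalues(records: pd.DataFrame, df: float = 1.0) -> pd.DataFrame:
    """Approximate one-sided p-values from a scaled chi-square fit.

    Per-SNP F_ST values, clipped below at 0, are modelled as c * chi2(df);
    the scale is fitted by moments (c-hat = mean clipped statistic / df).
    Negative estimates keep their reported fst but map to p = 1.
    """
    vals = records["fst"].to_numpy(dtype=float)
    clipped = np.clip(np.nan_to_num(vals, nan=0.0), 0.0, None)
    if not (clipped > 0).any():
        raise ValueError("cannot fit null: no positive F_ST values")
    c_hat = clipped.mean() / df
    out = records.copy()
    out["p_fst"] = stats.chi2.sf(clipped / c_hat, df)
    out.loc[records["monomorphic"], "p_fst"] = np.nan
    return out


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) on 2x2 counts."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in 2x2 table")
    expected = np.outer(rows, cols) / t.sum()
    stat = ((t - expected) ** 2 / expected).sum()
    return float(stat), float(stats.chi2.sf(stat, 1))


def ld_r2(panel, idx_a: int, idx_b: int) -> float:
    """Haplotype-based LD r^2 between two variants of a phased panel."""
    ha = panel.haplotypes[:, idx_a].astype(float)
    hb = panel.haplotypes[:, idx_b].astype(float)
    if panel.missing is not None:
        ok = ~(panel.missing[:, idx_a] | panel.missing[:, idx_b])
        ha, hb = ha[ok], hb[ok]
    pa = ha.mean()
    pb = hb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (ha * hb).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def pairwise_fst_matrix(panel, labels: pd.Series, n_blocks: int = 100) -> pd.DataFrame:
    """Weighted F_ST with SE for every pair of labelled subpopulations."""
    groups = list(pd.unique(labels))
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = labels.index[labels == groups[i]]
            b = labels.index[labels == groups[j]]
            pa = panel.subset_samples(list(a))
            pb = panel.subset_samples(list(b))
            tab = hudson_fst_table(
                pa.derived_freq(), pa.n_haplotypes, pb.derived_freq(), pb.n_haplotypes
            )
            fst, se = weighted_mean_fst(tab, n_blocks)
            out.append(
                {"population1": groups[i], "population2": groups[j], "fst": fst, "se": se}
            )
    return pd.DataFrame(out)
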