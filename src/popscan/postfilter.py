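"""Multiple-testing thresholds, locus merging, and interval-based exclusion
of likely artifacts (structural variants, segmental duplications).

Genome scans report per-variant or per-bin p-values; significant records
are merged into candidate loci, and loci overlapping common large structural
variants are flagged: long SVs mimic extended haplotype sharing and inflate
both haplotype-homozygosity and IBD statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import SvInterval

__all__ = ["Locus", "bonferroni_threshold", "merge_to_loci", "sv_overlap_filter"]


@dataclass
class Locus:
    chrom: str
    start: int  # bp, inclusive
    end: int  # bp, inclusive
    lead_p: float
    lead_stat: float
    n_members: int
    member_index: list[int] = field(default_factory=list)
    sv_overlap: bool = False


def bonferroni_threshold(
    alpha: float = 0.05, n_tests: int = 1, n_groups: int = 1, n_timescales: int = 1
) -> tuple[float, float]:
    """Family-wise threshold alpha / (tests * groups * timescales).

    Returns (full-precision value, value rounded to 3 significant digits).
    """
    if min(n_tests, n_groups, n_timescales) <= 0 or alpha <= 0:
        raise ValueError("all counts and alpha must be positive")
    thr = alpha / (n_tests * n_groups * n_timescales)
    rounded = float(f"{thr:.2e}")
    return thr, rounded


def merge_to_loci(
    records: pd.DataFrame,
    threshold: float,
    merge_gap_cM: float = 0.1,
    p_col: str = "p",
    stat_col: str | None = None,
) -> list[Locus]:
    """Merge significant records into loci.

    Records with p <= ``threshold`` are sorted by (chrom, position);
    neighbors within ``merge_gap_cM`` genetic distance join one locus.
    Records need columns chrom, bp (or start/end bp for bins), cM (or
    start_cM/end_cM), and ``p_col``.
    """
    rec = records.copy()
    if "cM" not in rec.columns and "start_cM" in rec.columns:
        rec["cM"] = (rec["start_cM"] + rec["end_cM"]) / 2.0
    if "bp" not in rec.columns:
        if "start_bp" in rec.columns:
            rec["bp_lo"], rec["bp_hi"] = rec["start_bp"], rec["end_bp"]
        else:  # cM-only bins: place bp on a 1 cM/Mb scale
            rec["bp_lo"] = (rec["start_cM"] * 1e6).round().astype(int)
            rec["bp_hi"] = (rec["end_cM"] * 1e6).round().astype(int)
    else:
        rec["bp_lo"] = rec["bp"]
        rec["bp_hi"] = rec["bp"]
    sig = rec.loc[rec[p_col].notna() & (rec[p_col] <= threshold)]
    loci: list[Locus] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values("cM")
        current: list = []
        last_cm = None
        for row in sub.itertuples():
            if last_cm is not None and getattr(row, "cM") - last_cm > merge_gap_cM:
                loci.append(_locus_from(chrom, current, p_col, stat_col))
                current = []
            current.append(row)
            last_cm = getattr(row, "cM")
        if current:
            loci.append(_locus_from(chrom, current, p_col, stat_col))
    return loci


def _locus_from(chrom, rows, p_col: str, stat_col: str | None) -> Locus:
    ps = np.array([getattr(r, p_col) for r in rows])
    lead = int(np.argmin(ps))
    stat = float("nan")
    if stat_col is not None:
        stat = float(getattr(rows[lead], stat_col))
    return Locus(
        chrom=str(chrom),
        start=int(min(r.bp_lo for r in rows)),
        end=int(max(r.bp_hi for r in rows)),
        lead_p=float(ps[lead]),
        lead_stat=stat,
        n_members=len(rows),
        member_index=[r.Index for r in rows],
    )


def sv_overlap_filter(
    loci: list[Locus],
    svs: list[SvInterval],
    min_sv_length: int = 10_000,
    min_af: float = 0.01,
    min_overlap_frac: float = 0.10,
) -> list[Locus]:
    """Flag loci overlapping common large structural variants.

    Only SVs with length >= ``min_sv_length`` and allele frequency >=
    ``min_af`` are considered.  A locus is flagged iff, for some retained
    SV, the bp overlap is at least ``min_overlap_frac`` of the SV length
    (inclusive boundary).  Flagged loci are kept in the output with
    ``sv_overlap = True``; headline tables should drop them.
    """
    retained = [
        sv for sv in svs if sv.sv_length >= min_sv_length and sv.allele_frequency >= min_af
    ]
    out = []
    for loc in loci:
        flag = False
        for sv in retained:
            if sv.chrom != loc.chrom:
                continue
            # locus bp interval treated half-open [start, end + 1)
            ov = min(loc.end + 1, sv.end) - max(loc.start, sv.start)
            if ov >= min_overlap_frac * sv.sv_length:
                flag = True
                break
        out.append(
            Locus(
                loc.chrom, loc.start, loc.end, loc.lead_p, loc.lead_stat,
                loc.n_members, list(loc.member_index), flag,
            )
        )
    return out


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": l.chrom,
                "start_bp": l.start,
                "end_bp": l.end,
                "lead_p": l.lead_p,
                "lead_stat": l.lead_stat,
                "n_members": l.n_members,
                "sv_overlap": l.sv_overlap,
            }
            for l in loci
        ],
        columns=[
            "chrom", "start_bp", "end_bp", "lead_p", "lead_stat", "n_members", "sv_overlap",
        ],
    )
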