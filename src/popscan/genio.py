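"""Readers/writers for the formats the scan pipeline touches.

Conventions
-----------
* VCF and variant tables use 1-based positions; BED-style interval files are
  0-based half-open.
* Haplotypes are stored derived-allele coded: ``1`` means the derived
  (non-ancestral) allele.  Polarity is established from a user-supplied
  ancestral-allele table; sites whose ancestral state is missing, or matches
  neither REF nor ALT, are *flagged*, never guessed or silently dropped.
* All tabular formats are plain TSV with a header line; ``.gz`` paths are
  handled transparently.
"""

from __future__ import annotations

import gzip
import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "HaplotypePanel",
    "GeneticMap",
    "SvInterval",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_genetic_map",
    "write_genetic_map",
    "interpolate_cM",
    "read_ancestral_table",
    "write_ancestral_table",
    "read_labels",
    "write_labels",
    "read_sv_bed",
    "write_sv_bed",
    "read_scan_table",
    "write_scan_table",
]

VARIANT_COLUMNS = ["chrom", "bp", "cM", "ref", "alt", "ancestral_is_ref", "ancestral_ok"]


class GenioError(ValueError):
    """Malformed input file or inconsistent panel."""


@dataclass
class HaplotypePanel:
    """Phased haplotype matrix with variant and sample metadata.

    ``haplotypes`` is a (2 * n_samples, n_variants) uint8 matrix; rows
    ``2*i`` and ``2*i + 1`` are the two haplotypes of ``sample_ids[i]``.
    Entries are 0 (ancestral) / 1 (derived).  ``missing``, when present, is
    a boolean mask of the same shape marking no-call haplotype alleles
    (the matrix entry underneath a masked cell is meaningless).
    """

    haplotypes: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise GenioError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise GenioError(
                f"{self.haplotypes.shape[0]} haplotype rows for "
                f"{len(self.sample_ids)} samples (need 2 per sample)"
            )
        if self.haplotypes.shape[1] != len(self.variants):
            raise GenioError("variant table length does not match matrix width")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise GenioError("haplotype entries must be 0/1")
        self.variants = self.variants.reset_index(drop=True)
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            if not (np.diff(bp) > 0).all():
                raise GenioError(f"bp not strictly increasing on {chrom}")
            cm = sub["cM"].to_numpy(dtype=float)
            cm = cm[~np.isnan(cm)]  # cM may be unassigned until a map is applied
            if not (np.diff(cm) >= 0).all():
                raise GenioError(f"cM not non-decreasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per variant over called haplotypes."""
        if self.missing is None:
            return self.haplotypes.mean(axis=0)
        called = ~self.missing
        num = np.where(called, self.haplotypes, 0).sum(axis=0)
        den = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    def maf(self) -> np.ndarray:
        f = self.derived_freq()
        return np.minimum(f, 1.0 - f)

    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_samples, n_variants); NaN where either
        haplotype allele is missing."""
        h = self.haplotypes.astype(float)
        if self.missing is not None:
            h = np.where(self.missing, np.nan, h)
        return h[0::2] + h[1::2]

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of samples with both alleles called."""
        if self.missing is None:
            return np.ones(self.n_variants)
        ok = ~(self.missing[0::2] | self.missing[1::2])
        return ok.mean(axis=0)

    def subset_variants(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        return HaplotypePanel(
            self.haplotypes[:, index],
            list(self.sample_ids),
            self.variants.iloc[index].reset_index(drop=True),
            None if self.missing is None else self.missing[:, index],
        )

    def subset_samples(self, keep: list[str] | np.ndarray) -> "HaplotypePanel":
        if np.asarray(keep).dtype.kind == "b":
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        rows = np.empty(2 * len(idx), dtype=int)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypePanel(
            self.haplotypes[rows],
            [self.sample_ids[i] for i in idx],
            self.variants.copy(),
            None if self.missing is None else self.missing[rows],
        )


@dataclass
class GeneticMap:
    """Monotone bp -> cM lookup per chromosome, linearly interpolated."""

    knots: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, tab in self.knots.items():
            bp = tab["bp"].to_numpy()
            cm = tab["cM"].to_numpy(dtype=float)
            if not (np.diff(bp) > 0).all():
                raise GenioError(f"map bp not strictly increasing on {chrom}")
            if not (np.diff(cm) >= 0).all():
                raise GenioError(f"map cM not non-decreasing on {chrom}")


@dataclass(frozen=True)
class SvInterval:
    """Structural-variant interval (0-based half-open) with allele frequency."""

    chrom: str
    start: int
    end: int
    allele_frequency: float

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise GenioError(f"bad interval [{self.start}, {self.end})")
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise GenioError(f"AF {self.allele_frequency} outside [0, 1]")

    @property
    def sv_length(self) -> int:
        return self.end - self.start


def _opener(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(path, ancestral_table: pd.DataFrame) -> HaplotypePanel:
    """Read a phased biallelic-SNP VCF and polarize alleles by ancestral state.

    ``ancestral_table`` must have columns chrom, bp, ancestral_allele.  The
    returned panel codes 1 = derived.  Variants whose ancestral allele is
    missing from the table, is not A/C/G/T, or matches neither REF nor ALT
    are kept but flagged ``ancestral_ok = False`` (downstream haplotype
    statistics exclude them).  Multiallelic or indel records are dropped with
    a counted warning.  Any unphased genotype is an error naming the record.
    """
    anc = {
        (str(c), int(b)): str(a).upper()
        for c, b, a in zip(
            ancestral_table["chrom"], ancestral_table["bp"], ancestral_table["ancestral_allele"]
        )
    }
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    cols: list[np.ndarray] = []
    miss_cols: list[np.ndarray] = []
    rows = []
    n_skipped = 0
    any_missing = False
    for rec in vf:
        if (
            rec.alts is None
            or len(rec.alts) != 1
            or len(rec.ref) != 1
            or len(rec.alts[0]) != 1
            or rec.ref not in "ACGT"
            or rec.alts[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        col = np.zeros(2 * len(samples), dtype=np.uint8)
        mcol = np.zeros(2 * len(samples), dtype=bool)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            gt = call["GT"]
            if len(gt) != 2:
                raise GenioError(f"non-diploid GT at {rec.chrom}:{rec.pos} sample {s}")
            if gt[0] is None or gt[1] is None:
                mcol[2 * i : 2 * i + 2] = True
                any_missing = True
                continue
            if not call.phased:
                raise GenioError(
                    f"unphased genotype at {rec.chrom}:{rec.pos} sample {s}"
                )
            col[2 * i] = gt[0]
            col[2 * i + 1] = gt[1]
        a = anc.get((str(rec.chrom), int(rec.pos)))
        ancestral_ok = a in ("A", "C", "G", "T") and a in (rec.ref, rec.alts[0])
        ancestral_is_ref = bool(ancestral_ok and a == rec.ref)
        if ancestral_ok and not ancestral_is_ref:
            col ^= 1  # ALT is ancestral: flip so 1 = derived
        rows.append(
            {
                "chrom": str(rec.chrom),
                "bp": int(rec.pos),
                "cM": float(rec.info.get("CM", np.nan)) if "CM" in rec.info else np.nan,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "ancestral_is_ref": ancestral_is_ref,
                "ancestral_ok": ancestral_ok,
            }
        )
        cols.append(col)
        miss_cols.append(mcol)
    vf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP records", stacklevel=2)
    if not rows:
        raise GenioError(f"no usable biallelic SNP records in {path}")
    hap = np.column_stack(cols)
    missing = np.column_stack(miss_cols) if any_missing else None
    return HaplotypePanel(hap, samples, pd.DataFrame(rows), missing)


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as VCF 4.2 with phased GT (``|`` separator).

    Alleles are written back in REF/ALT coding (the derived-allele
    orientation is undone for sites where ALT is ancestral), so a write/read
    round trip through :func:`read_phased_vcf` is the identity.
    """
    with _opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = pd.unique(panel.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        H = panel.haplotypes
        for j, v in panel.variants.iterrows():
            col = H[:, j]
            if bool(v["ancestral_ok"]) and not bool(v["ancestral_is_ref"]):
                col = col ^ 1  # restore ALT-dosage coding
            gts = []
            for i in range(panel.n_samples):
                if panel.missing is not None and panel.missing[2 * i, j]:
                    gts.append(".|.")
                else:
                    gts.append(f"{col[2 * i]}|{col[2 * i + 1]}")
            fh.write(
                f"{v['chrom']}\t{int(v['bp'])}\t.\t{v['ref']}\t{v['alt']}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(path) -> GeneticMap:
    """Read a whitespace-separated (chrom, bp, cM) table with header."""
    tab = pd.read_csv(path, sep=r"\s+")
    tab.columns = ["chrom", "bp", "cM"]
    if (tab["bp"] < 0).any():
        raise GenioError("negative bp in genetic map")
    knots = {
        str(chrom): sub[["bp", "cM"]].reset_index(drop=True)
        for chrom, sub in tab.groupby("chrom", sort=False)
    }
    return GeneticMap(knots)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    parts = []
    for chrom, tab in gmap.knots.items():
        part = tab.copy()
        part.insert(0, "chrom", chrom)
        parts.append(part)
    pd.concat(parts).to_csv(path, sep="\t", index=False)


def interpolate_cM(gmap: GeneticMap, chrom: str, bp) -> np.ndarray | float:
    """Piecewise-linear bp -> cM; extrapolates terminal segment rates,
    floored at 0 cM."""
    chrom = str(chrom)
    if chrom not in gmap.knots:
        raise GenioError(f"chromosome {chrom!r} absent from genetic map")
    tab = gmap.knots[chrom]
    if len(tab) < 2:
        raise GenioError(f"need >= 2 map knots for {chrom}")
    kb = tab["bp"].to_numpy(dtype=float)
    kc = tab["cM"].to_numpy(dtype=float)
    bp_arr = np.atleast_1d(np.asarray(bp, dtype=float))
    out = np.interp(bp_arr, kb, kc)
    # np.interp clamps outside the knot range; extend with terminal rates
    lo = bp_arr < kb[0]
    if lo.any():
        rate = (kc[1] - kc[0]) / (kb[1] - kb[0])
        out[lo] = kc[0] + rate * (bp_arr[lo] - kb[0])
    hi = bp_arr > kb[-1]
    if hi.any():
        rate = (kc[-1] - kc[-2]) / (kb[-1] - kb[-2])
        out[hi] = kc[-1] + rate * (bp_arr[hi] - kb[-1])
    out = np.maximum(out, 0.0)
    return float(out[0]) if np.isscalar(bp) or np.ndim(bp) == 0 else out


# ---------------------------------------------------------------------------
# small TSV tables


def read_ancestral_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "bp", "ancestral_allele"}
    if not need.issubset(tab.columns):
        raise GenioError(f"ancestral table needs columns {sorted(need)}")
    return tab


def write_ancestral_table(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.Series:
    """Sample -> subpopulation labels from a two-column TSV."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"}.issubset(tab.columns):
        raise GenioError("labels table needs columns sample_id, group")
    return pd.Series(tab["group"].to_numpy(), index=tab["sample_id"], name="group")


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "group": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_sv_bed(path) -> list[SvInterval]:
    """Read BED intervals with allele frequency in column 4 (``AF=x`` or a
    bare number); empty files yield an empty list."""
    out: list[SvInterval] = []
    with _opener(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise GenioError(f"BED line needs 4 fields: {line!r}")
            chrom, start, end, af = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start < 0:
                raise GenioError(f"negative coordinate in BED: {line!r}")
            if af.startswith("AF="):
                af = af[3:]
            out.append(SvInterval(chrom, start, end, float(af)))
    return out


def write_sv_bed(svs: list[SvInterval], path) -> None:
    with _opener(path, "wt") as fh:
        for sv in svs:
            fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\tAF={sv.allele_frequency:g}\n")


def write_scan_table(table: pd.DataFrame, path) -> None:
    """Write a per-variant or per-bin scan table as TSV (1-based positions)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scan_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    if "bp" in tab.columns and (tab["bp"] < 0).any():
        raise GenioError("negative coordinates in scan table")
    return tab
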