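"""Reading, filtering and writing of VCF/BED/TSV artifacts.

Conventions
-----------
* VCF records and the classification table are 1-based (VCF standard).
* BED masks are 0-based, half-open (BED standard).
* Genotypes are encoded as integers: 0 = HOM_REF, 1 = HET, 2 = HOM_ALT,
  -1 = MISSING.  A genotype failing the per-genotype quality or depth
  threshold is set to MISSING before the site-level missingness test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from collapsemask.errors import FilterError, VcfFormatError

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GENOTYPE_NAMES = {HOM_REF: "HOM_REF", HET: "HET", HOM_ALT: "HOM_ALT", MISSING: "MISSING"}


@dataclass
class FilterConfig:
    """Site and genotype quality filters.

    Parameters
    ----------
    min_gq:
        Minimum genotype quality per individual and site; genotypes below
        are masked to MISSING.
    min_depth_per_genotype:
        Minimum total read depth per individual and site.
    max_missing_fraction:
        Maximum fraction of MISSING genotypes tolerated per site (after
        per-genotype masking); sites above are dropped.
    biallelic_snps_only:
        Keep only biallelic single-nucleotide records.
    """

    min_gq: int = 30
    min_depth_per_genotype: int = 5
    max_missing_fraction: float = 0.1
    biallelic_snps_only: bool = True

    def __post_init__(self) -> None:
        if self.min_gq < 0 or self.min_depth_per_genotype < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic site with per-individual observations."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # int8, codes above
    allelic_depths: np.ndarray  # (n_ind, 2) int32: (ref_reads, alt_reads)
    total_depth: np.ndarray  # int32
    genotype_quality: np.ndarray  # int32


class SiteTable:
    """Column-oriented collection of :class:`SiteRecord`.

    Per-site scalars are 1-D arrays of length ``n_sites``; per-genotype
    observations are ``(n_sites, n_ind)`` matrices.  Behaves as an ordered
    sequence of :class:`SiteRecord`.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        gt: np.ndarray,
        ad_ref: np.ndarray,
        ad_alt: np.ndarray,
        dp: np.ndarray,
        gq: np.ndarray,
        samples: Sequence[str],
    ):
        self.chrom = np.asarray(chrom)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref)
        self.alt = np.asarray(alt)
        self.gt = np.asarray(gt, dtype=np.int8)
        self.ad_ref = np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(ad_alt, dtype=np.int32)
        self.dp = np.asarray(dp, dtype=np.int32)
        self.gq = np.asarray(gq, dtype=np.int32)
        self.samples = list(samples)
        n = len(self.pos)
        for arr in (self.chrom, self.ref, self.alt):
            if len(arr) != n:
                raise ValueError("per-site arrays must share length")
        for mat in (self.gt, self.ad_ref, self.ad_alt, self.dp, self.gq):
            if mat.shape != (n, len(self.samples)):
                raise ValueError("per-genotype matrices must be (n_sites, n_ind)")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_ind(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return self.n_sites

    def __getitem__(self, i: int) -> SiteRecord:
        return SiteRecord(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref_allele=str(self.ref[i]),
            alt_allele=str(self.alt[i]),
            genotypes=self.gt[i],
            allelic_depths=np.stack([self.ad_ref[i], self.ad_alt[i]], axis=1),
            total_depth=self.dp[i],
            genotype_quality=self.gq[i],
        )

    def __iter__(self) -> Iterator[SiteRecord]:
        for i in range(self.n_sites):
            yield self[i]

    def subset(self, mask: np.ndarray) -> "SiteTable":
        """Return a new table restricted to sites where ``mask`` holds."""
        return SiteTable(
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.gt[mask],
            self.ad_ref[mask],
            self.ad_alt[mask],
            self.dp[mask],
            self.gq[mask],
            self.samples,
        )


def _site_is_snp(ref: str, alts: Sequence[str]) -> bool:
    if len(alts) != 1:
        return False
    alt = alts[0]
    return len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT"


def read_vcf(path: str, filters: FilterConfig | None = None) -> SiteTable:
    """Read a multi-sample VCF into a filtered :class:`SiteTable`.

    Genotypes failing the per-genotype GQ/depth thresholds are masked to
    MISSING *before* the site-level missingness test.  Sites that are
    monomorphic after masking, exceed the missingness threshold, or are not
    biallelic SNPs (when requested) are dropped.

    Raises
    ------
    VcfFormatError
        If the file is malformed, has fewer than two samples, or a retained
        site lacks the AD field.
    FilterError
        If no site survives filtering.
    """
    filters = filters or FilterConfig()
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfFormatError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise VcfFormatError(f"VCF {path!r} has {len(samples)} samples; need >= 2")

    chrom_l, pos_l, ref_l, alt_l = [], [], [], []
    gt_l, adr_l, ada_l, dp_l, gq_l = [], [], [], [], []
    last_pos: dict[str, int] = {}
    for line_no, var in enumerate(vcf, start=1):
        if filters.biallelic_snps_only and not _site_is_snp(var.REF, var.ALT):
            continue
        if len(var.ALT) != 1:
            continue
        site = f"{var.CHROM}:{var.POS}"
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise VcfFormatError(f"site {site} (record {line_no}): AD field is missing")
        ad = np.asarray(ad, dtype=np.int64)
        if ad.ndim != 2 or ad.shape[1] < 2:
            raise VcfFormatError(f"site {site}: AD field is not (ref, alt) shaped")
        ad_ref = np.clip(ad[:, 0], 0, None)
        ad_alt = np.clip(ad[:, 1], 0, None)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            dp = ad_ref + ad_alt  # DP defaults to AD sum when absent
        else:
            dp = np.clip(np.asarray(dp, dtype=np.int64).reshape(-1), 0, None)
        try:
            gq = var.format("GQ")
        except KeyError:
            gq = None
        if gq is None:
            gq = np.full(len(samples), 99, dtype=np.int64)
        else:
            gq = np.asarray(gq, dtype=np.int64).reshape(-1)
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt = np.where(gt == 3, MISSING, gt)

        prev = last_pos.get(var.CHROM)
        if prev is not None and var.POS <= prev:
            raise VcfFormatError(
                f"record {line_no}: positions not strictly increasing at {site}"
            )
        last_pos[var.CHROM] = var.POS

        chrom_l.append(var.CHROM)
        pos_l.append(var.POS)
        ref_l.append(var.REF)
        alt_l.append(var.ALT[0])
        gt_l.append(gt)
        adr_l.append(ad_ref)
        ada_l.append(ad_alt)
        dp_l.append(dp)
        gq_l.append(gq)

    if not pos_l:
        raise FilterError(f"no biallelic SNP records found in {path!r}")
    table = SiteTable(
        np.array(chrom_l),
        np.array(pos_l),
        np.array(ref_l),
        np.array(alt_l),
        np.array(gt_l),
        np.array(adr_l),
        np.array(ada_l),
        np.array(dp_l),
        np.array(gq_l),
        samples,
    )
    return apply_filters(table, filters)


def apply_filters(table: SiteTable, filters: FilterConfig | None = None) -> SiteTable:
    """Apply per-genotype masking and site-level filters to ``table``.

    Idempotent: applying the same configuration twice yields the same sites.
    """
    filters = filters or FilterConfig()
    gt = table.gt.copy()
    bad = (table.gq < filters.min_gq) | (table.dp < filters.min_depth_per_genotype)
    gt[bad] = MISSING

    called = gt != MISSING
    n_called = called.sum(axis=1)
    miss_frac = 1.0 - n_called / table.n_ind
    alt_count = np.where(called, gt, 0).sum(axis=1)
    polymorphic = (alt_count > 0) & (alt_count < 2 * n_called)
    keep = (miss_frac <= filters.max_missing_fraction) & (n_called >= 2) & polymorphic

    if not keep.any():
        raise FilterError("zero sites survive filtering; relax FilterConfig")
    out = SiteTable(
        table.chrom[keep],
        table.pos[keep],
        table.ref[keep],
        table.alt[keep],
        gt[keep],
        table.ad_ref[keep],
        table.ad_alt[keep],
        table.dp[keep],
        table.gq[keep],
        table.samples,
    )
    n_drop = table.n_sites - out.n_sites
    if n_drop:
        logger.info("filtering dropped %d of %d sites", n_drop, table.n_sites)
    return out


def write_vcf(table: SiteTable, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`SiteTable` as an uncompressed VCF 4.3 file.

    Output is deterministic (no timestamps), so identical tables produce
    byte-identical files.
    """
    contig_lengths = contig_lengths or {}
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write('##source=collapsemask\n')
        for chrom in dict.fromkeys(table.chrom.tolist()):
            length = contig_lengths.get(chrom)
            if length is None:
                length = int(table.pos[table.chrom == chrom].max()) + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            fields = [
                str(table.chrom[i]),
                str(int(table.pos[i])),
                ".",
                str(table.ref[i]),
                str(table.alt[i]),
                ".",
                "PASS",
                ".",
                "GT:AD:DP:GQ",
            ]
            row = [
                f"{gt_str[int(g)]}:{ar},{aa}:{d}:{q}"
                for g, ar, aa, d, q in zip(
                    table.gt[i], table.ad_ref[i], table.ad_alt[i], table.dp[i], table.gq[i]
                )
            ]
            fh.write("\t".join(fields + row) + "\n")


def write_mask_bed(regions, path: str) -> None:
    """Write multicopy regions as a BED3+ mask (0-based, half-open).

    Extra columns: n_snps, n_seeds.  Regions must be sorted and pairwise
    non-overlapping within each chromosome.
    """
    by_chrom: dict[str, list] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs_sorted = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs_sorted, rs_sorted[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping regions on {chrom}: [{a.start},{a.end}) and [{b.start},{b.end})"
                )
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{len(r.member_snps)}\t{r.n_seeds}\n")


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Read BED intervals as (chrom, start, end) tuples (0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_classification_table(classifications, path: str) -> None:
    """Write per-SNP classifications as a TSV (1-based positions)."""
    df = classifications.to_dataframe()
    df.to_csv(path, sep="\t", index=False)


def read_classification_table(path: str) -> pd.DataFrame:
    """Read a classification TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
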