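"""Population-scale genotype/read simulator with known multicopy structure.

The generator emulates, at the VCF level, the end product of sequencing a
mosaic diploid genome in which collapsed duplicated haplotypes are
interspersed among single-copy regions:

* the genome is tiled with duplicated haplotypes (exponential lengths,
  mean ~1 kb) totalling ``dup_fraction`` of the collapsed sequence length;
* single-copy SNPs arise at density ``theta * a_k`` per bp with population
  frequencies from the neutral 1/p law; genotypes are drawn under
  inbreeding: with probability ``fis`` an individual is autozygous
  (homozygous by descent), otherwise Hardy-Weinberg;
* duplications are fixed in the population or segregate at a uniform
  frequency; carriers of a duplicated haplotype have copy number 2 + d
  (d = carrier chromosomes) and ~2x depth when d = 2;
* within duplications, fixed inter-copy differences (rate
  ``dup_divergence``/bp) surface as spurious heterozygotes at read ratio
  d/(2+d) in every carrier; variants segregating on either copy produce
  read ratios centered at 0.25/0.75;
* per-site read counts are Poisson in the copy number; alternative reads
  follow the expected ratio with locus-level mapping bias, mild allelic
  overdispersion and a Q30 base-error rate; genotypes are called with a
  GATK-like likelihood caller (or a simple ratio-threshold caller) emitting
  GT:AD:DP:GQ.

Two runs with the same parameters (including ``seed``) produce identical
cohorts and byte-identical VCFs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from collapsemask.errors import DataError
from collapsemask.em_classifier import (
    Classifications,
    MULTI,
    SINGLE,
    STEP_CLUSTER,
    STEP_EM,
    STEP_RRD,
)
from collapsemask.vcf_io import HET, HOM_ALT, HOM_REF, MISSING, SiteTable, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Knobs of the synthetic cohort.

    Defaults correspond to the main simulation setting: 100 diploids at 10x
    genome-average depth on a ~1 Mbp mosaic with 10% collapsed duplications
    and random mating.
    """

    n_ind: int = 100
    mean_depth: float = 10.0  # genome-average depth of a diploid (2 copies)
    fis: float = 0.0
    dup_fraction: float = 0.1  # fraction of collapsed length that is duplicated
    genome_length: int = 1_000_000
    dup_divergence: float = 0.005  # fixed inter-copy differences per bp
    dup_fixed_fraction: float = 0.7  # duplications fixed in the population
    mean_hap_length: float = 1000.0  # mean duplicated-haplotype length (bp)
    min_hap_length: float = 100.0
    max_hap_length: float = 10000.0
    theta: float = 0.001  # per-bp scaled mutation rate (random-mating scale)
    error_rate: float = 0.001  # per-base miscall rate (Q30)
    read_overdispersion: float = 0.005  # beta-binomial rho of per-genotype read ratios
    site_bias_sd: float = 0.1  # per-site logit-scale read-ratio bias (mapping bias)
    caller_mode: str = "likelihood"  # "likelihood" (GATK-like) or "threshold"
    caller_threshold: float = 0.2  # alt-ratio bound for HET calls (threshold mode)
    caller_min_reads: int = 2  # min reads per allele for a HET call (threshold mode)
    seed: int = 0
    chrom_name: str = "sim1"

    def __post_init__(self) -> None:
        if not 0 <= self.fis <= 1:
            raise ValueError("fis must be in [0, 1]")
        if not 0 <= self.dup_fraction <= 0.667:
            raise ValueError("dup_fraction must be in [0, 0.667]")
        if self.n_ind < 2 or self.genome_length < 1000:
            raise ValueError("need >= 2 individuals and >= 1 kb of genome")


@dataclass
class TruthTrack:
    """Ground truth: genome tiling and per-SNP labels."""

    intervals: list[tuple[int, int, str]]  # (start, end, state), 0-based half-open
    snp_labels: np.ndarray  # per emitted SNP: SINGLE or MULTI

    def write_bed(self, path: str, chrom: str) -> None:
        with open(path, "w") as fh:
            for start, end, state in self.intervals:
                if state == MULTI:
                    fh.write(f"{chrom}\t{start}\t{end}\tMULTI\n")

    def write_snps(self, path: str, chrom: str, positions: np.ndarray) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\ttrue_label\n")
            for pos, lab in zip(positions, self.snp_labels):
                fh.write(f"{chrom}\t{int(pos)}\t{lab}\n")


@dataclass
class SimResult:
    """Simulated cohort: called data, truth, and generator internals."""

    table: SiteTable
    truth: TruthTrack
    params: SimParams
    true_genotypes: np.ndarray = field(repr=False, default=None)  # single-copy allele dose
    copy_number: np.ndarray = field(repr=False, default=None)  # per SNP x ind (2 + d)
    expected_ratio: np.ndarray = field(repr=False, default=None)

    def write_vcf(self, path: str) -> None:
        write_vcf(
            self.table,
            path,
            contig_lengths={self.params.chrom_name: self.params.genome_length},
        )

    def manifest(self) -> dict:
        return {"params": asdict(self.params), "n_snps": self.table.n_sites}

    def write_manifest(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k)))


def _draw_dup_layout(params: SimParams, rng: np.random.Generator):
    """Tile the genome with duplicated haplotypes totalling the target length."""
    L = params.genome_length
    target = params.dup_fraction * L
    if target <= 0:
        return []
    lengths = []
    total = 0.0
    while total < target:
        ln = float(
            np.clip(
                rng.exponential(params.mean_hap_length),
                params.min_hap_length,
                params.max_hap_length,
            )
        )
        ln = min(ln, target - total) if target - total > params.min_hap_length else ln
        lengths.append(max(ln, params.min_hap_length))
        total += lengths[-1]
    n = len(lengths)
    gap_total = max(L - total, n + 1.0)
    gaps = rng.exponential(1.0, size=n + 1)
    gaps = gaps / gaps.sum() * gap_total
    intervals = []
    cursor = 0.0
    for g, ln in zip(gaps, lengths):
        start = cursor + g
        intervals.append((int(start), int(start + ln)))
        cursor = start + ln
    return [(s, e) for s, e in intervals if e > s and e <= L]


def _draw_population_freq(rng: np.random.Generator, size: int, n_ind: int) -> np.ndarray:
    """Neutral-like frequencies with density proportional to 1/p."""
    a = 1.0 / (4.0 * n_ind)
    b = 1.0 - a
    u = rng.random(size)
    return a * (b / a) ** u


def _draw_genotypes(
    rng: np.random.Generator, p: np.ndarray, n_ind: int, fis: float
) -> np.ndarray:
    """Diploid allele doses (0/1/2) under inbreeding coefficient ``fis``."""
    n_snp = len(p)
    auto = rng.random((n_snp, n_ind)) < fis
    hw = rng.binomial(2, p[:, None], size=(n_snp, n_ind))
    ibd = 2 * rng.binomial(1, p[:, None], size=(n_snp, n_ind))
    return np.where(auto, ibd, hw).astype(np.int8)


def _call_genotypes(
    dp: np.ndarray,
    alt: np.ndarray,
    mode: str,
    t: float,
    min_reads: int,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype calls and phred-like GQ from per-individual read counts.

    ``likelihood`` mode emulates a GATK-style caller: the call maximizes the
    binomial likelihood among the three canonical genotypes (expected alt
    read fractions ``e``, 0.5, ``1 - e``).  ``threshold`` mode calls from
    the raw alt-read ratio with a minimum-reads rule for heterozygotes.
    GQ is the phred-scaled likelihood gap between the two best genotypes,
    capped at 99.
    """
    ref = dp - alt
    e = error_rate
    ll = np.stack(
        [
            alt * np.log(e) + ref * np.log(1 - e),
            (alt + ref) * np.log(0.5),
            alt * np.log(1 - e) + ref * np.log(e),
        ],
        axis=0,
    )
    covered = dp > 0
    if mode == "likelihood":
        # population allele-frequency prior (Hardy-Weinberg), as a
        # multi-sample caller would apply: suppresses spurious heterozygote
        # calls driven by isolated error reads
        with np.errstate(divide="ignore", invalid="ignore"):
            p_hat = alt.sum(axis=-1, keepdims=True) / np.maximum(
                dp.sum(axis=-1, keepdims=True), 1
            )
        p_hat = np.clip(p_hat, 1e-4, 1 - 1e-4)
        log_prior = np.stack(
            [
                2 * np.log1p(-p_hat),
                np.log(2 * p_hat * (1 - p_hat)),
                2 * np.log(p_hat),
            ],
            axis=0,
        )
        ll = ll + log_prior
        gt = np.argmax(ll, axis=0).astype(np.int8)
        gt[~covered] = MISSING
    elif mode == "threshold":
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(covered, alt / np.maximum(dp, 1), np.nan)
        gt = np.full(dp.shape, MISSING, dtype=np.int8)
        gt[covered & (ratio <= t)] = HOM_REF
        gt[covered & (ratio >= 1 - t)] = HOM_ALT
        mid = covered & (ratio > t) & (ratio < 1 - t)
        het_ok = mid & (alt >= min_reads) & (ref >= min_reads)
        gt[het_ok] = HET
        fallback = mid & ~het_ok
        gt[fallback & (alt > ref)] = HOM_ALT
        gt[fallback & (ref > alt)] = HOM_REF
        # fallback ties stay MISSING
    else:
        raise ValueError(f"unknown caller mode {mode!r}")

    ll_sorted = np.sort(ll, axis=0)
    gq = 10.0 / np.log(10.0) * (ll_sorted[-1] - ll_sorted[-2])
    gq = np.clip(np.nan_to_num(gq), 0, 99).astype(np.int32)
    gq[~covered] = 0
    return gt, gq


def simulate_cohort(params: SimParams) -> SimResult:
    """Generate a cohort with known single-copy and multicopy structure.

    Raises :class:`DataError` when the parameter combination yields fewer
    than 500 observed SNPs (too few for the mixture fit downstream).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_ind
    k = 2 * n
    a_k = _harmonic(k)
    # effective diversity shrinks with inbreeding (reduced effective size)
    theta_eff = params.theta / (1.0 + params.fis)

    dup_intervals = _draw_dup_layout(params, rng)

    pos_l: list[np.ndarray] = []
    ratio_l: list[np.ndarray] = []
    cn_l: list[np.ndarray] = []
    dose_l: list[np.ndarray] = []
    label_l: list[np.ndarray] = []

    def add_sites(positions, ratios, copy_number, dose, label):
        if len(positions) == 0:
            return
        pos_l.append(np.asarray(positions, dtype=np.int64))
        ratio_l.append(np.asarray(ratios, dtype=float))
        cn_l.append(np.asarray(copy_number, dtype=np.int8))
        dose_l.append(np.asarray(dose, dtype=np.int8))
        label_l.append(np.full(len(positions), label, dtype="U9"))

    # single-copy segments
    sc_segments = []
    cursor = 0
    for s, e in dup_intervals + [(params.genome_length, params.genome_length)]:
        if s > cursor:
            sc_segments.append((cursor, s))
        cursor = max(cursor, e)
    for s, e in sc_segments:
        seg_len = e - s
        m = rng.poisson(theta_eff * a_k * seg_len)
        if m == 0:
            continue
        positions = np.sort(rng.choice(np.arange(s + 1, e + 1), size=min(m, seg_len), replace=False))
        p = _draw_population_freq(rng, len(positions), n)
        dose = _draw_genotypes(rng, p, n, params.fis)
        cn = np.full((len(positions), n), 2, dtype=np.int8)
        add_sites(positions, dose / 2.0, cn, dose, SINGLE)

    # duplicated haplotypes
    for s, e in dup_intervals:
        seg_len = e - s
        fixed_dup = rng.random() < params.dup_fixed_fraction
        if fixed_dup:
            d = np.full(n, 2, dtype=np.int8)
        else:
            q = rng.random()
            auto = rng.random(n) < params.fis
            d = np.where(
                auto, 2 * rng.binomial(1, q, n), rng.binomial(2, q, n)
            ).astype(np.int8)
        cn_ind = 2 + d  # collapsed haplotype count per individual

        def dup_positions(m):
            if m == 0:
                return np.array([], dtype=np.int64)
            return np.sort(
                rng.choice(np.arange(s + 1, e + 1), size=min(m, seg_len), replace=False)
            )

        # (a) fixed inter-copy differences: alt on every duplicated copy
        m_div = rng.poisson(params.dup_divergence * seg_len)
        pos_a = dup_positions(m_div)
        if len(pos_a):
            ratio = np.broadcast_to(d / cn_ind.astype(float), (len(pos_a), n))
            add_sites(pos_a, ratio, np.broadcast_to(cn_ind, (len(pos_a), n)), np.zeros((len(pos_a), n), np.int8), MULTI)

        # (b) variants segregating on the original copy
        m_orig = rng.poisson(theta_eff * a_k * seg_len)
        pos_b = dup_positions(m_orig)
        if len(pos_b):
            p = _draw_population_freq(rng, len(pos_b), n)
            dose = _draw_genotypes(rng, p, n, params.fis)
            ratio = dose / (2.0 + d[None, :].astype(float))
            add_sites(pos_b, ratio, np.broadcast_to(cn_ind, (len(pos_b), n)), dose, MULTI)

        # (c) variants segregating on the duplicated copy (carriers only)
        m_dup = rng.poisson(theta_eff * a_k * seg_len)
        pos_c = dup_positions(m_dup)
        if len(pos_c):
            p = _draw_population_freq(rng, len(pos_c), n)
            dose = rng.binomial(d[None, :], p[:, None]).astype(np.int8)
            ratio = dose / (2.0 + d[None, :].astype(float))
            add_sites(pos_c, ratio, np.broadcast_to(cn_ind, (len(pos_c), n)), dose, MULTI)

    if not pos_l:
        raise DataError("no candidate sites generated; increase theta or genome_length")
    pos = np.concatenate(pos_l)
    ratio = np.concatenate([np.ascontiguousarray(r) for r in ratio_l])
    cn = np.concatenate([np.ascontiguousarray(c) for c in cn_l])
    dose = np.concatenate([np.ascontiguousarray(x) for x in dose_l])
    labels = np.concatenate(label_l)
    order = np.argsort(pos, kind="stable")
    # collisions between site classes at the same coordinate: keep the first
    pos, uniq_idx = np.unique(pos[order], return_index=True)
    order = order[uniq_idx]
    ratio, cn, dose, labels = ratio[order], cn[order], dose[order], labels[order]

    # read sampling: depth Poisson in copy number; alternative reads
    # beta-binomial around the expected ratio (read ratios in real mapped
    # data are overdispersed relative to binomial: mapping bias, local
    # alignment artifacts), with a small base-error rate
    e = params.error_rate
    dp = rng.poisson(params.mean_depth * cn / 2.0).astype(np.int32)
    p_alt = np.clip(ratio * (1 - 2 * e) + e, 1e-6, 1 - 1e-6)
    # allele-balance noise applies to genotypes with both alleles present
    # (mapping bias and sampling of real alleles); pure error reads at
    # homozygous genotypes stay simple binomial at the base-error rate
    interior = (ratio > 0.02) & (ratio < 0.98)
    p_draw = p_alt.copy() if isinstance(p_alt, np.ndarray) else np.asarray(p_alt)
    if params.site_bias_sd > 0:
        # locus-level mapping bias, shared by all individuals at a site:
        # the component of read-ratio overdispersion that grows with the
        # number of reads pooled across individuals
        gamma = rng.normal(0.0, params.site_bias_sd, size=(len(pos), 1))
        biased = 1.0 / (1.0 + (1.0 - p_alt) / p_alt * np.exp(-gamma))
        p_draw = np.where(interior, biased, p_draw)
    rho_r = params.read_overdispersion
    if rho_r > 0:
        scale = (1.0 - rho_r) / rho_r
        noisy = rng.beta(
            np.clip(p_draw, 1e-6, None) * scale,
            np.clip(1.0 - p_draw, 1e-6, None) * scale,
        )
        p_draw = np.where(interior, noisy, p_draw)
    alt = rng.binomial(dp, p_draw).astype(np.int32)

    gt, gq = _call_genotypes(
        dp, alt, params.caller_mode, params.caller_threshold, params.caller_min_reads, e
    )

    # emit sites a caller would report: at least one non-reference call
    called = gt != MISSING
    has_alt = ((gt == HET) | (gt == HOM_ALT)) & called
    emit = has_alt.any(axis=1)
    if emit.sum() < 500:
        raise DataError(
            f"only {int(emit.sum())} SNPs emitted; the mixture fit needs >= 500 "
            "(increase theta, genome_length or sample size)"
        )

    idx = np.flatnonzero(emit)
    n_sites = len(idx)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + 1 + rng.integers(0, 3, size=n_sites)) % 4
    ref_alleles = _BASES[ref_idx]
    alt_alleles = _BASES[alt_idx]
    samples = [f"ind{i + 1:04d}" for i in range(n)]
    table = SiteTable(
        chrom=np.full(n_sites, params.chrom_name),
        pos=pos[idx],
        ref=ref_alleles,
        alt=alt_alleles,
        gt=gt[idx],
        ad_ref=(dp - alt)[idx],
        ad_alt=alt[idx],
        dp=dp[idx],
        gq=gq[idx],
        samples=samples,
    )

    intervals = []
    cursor = 0
    for s, e_ in dup_intervals:
        if s > cursor:
            intervals.append((cursor, s, SINGLE))
        intervals.append((s, e_, MULTI))
        cursor = e_
    if cursor < params.genome_length:
        intervals.append((cursor, params.genome_length, SINGLE))
    truth = TruthTrack(intervals=intervals, snp_labels=labels[idx])

    return SimResult(
        table=table,
        truth=truth,
        params=params,
        true_genotypes=dose[idx],
        copy_number=cn[idx],
        expected_ratio=ratio[idx],
    )


@dataclass
class EvaluationReport:
    """Recall of the final classification against simulated truth."""

    recall_single: float
    recall_multi: float
    recall_total: float
    n_single: int
    n_multi: int
    step_fraction_single: dict[str, float]  # correct truth-single, by assigning step
    step_fraction_multi: dict[str, float]  # correct truth-multi, by assigning step
    region_tag_fraction: float | None = None  # true MULTI intervals tagged by >=1 MULTI SNP

    def to_dict(self) -> dict:
        return asdict(self)


def truth_compare(
    classifications: Classifications,
    truth_labels: np.ndarray,
    truth_intervals: list[tuple[int, int, str]] | None = None,
) -> EvaluationReport:
    """Recall per class, total recall, and per-step attribution.

    ``truth_labels`` must align one-to-one with ``classifications``.
    """
    truth_labels = np.asarray(truth_labels)
    if len(truth_labels) != len(classifications):
        raise DataError(
            f"classification ({len(classifications)}) and truth "
            f"({len(truth_labels)}) cover different SNP sets"
        )
    pred = classifications.label
    steps = classifications.step
    correct = pred == truth_labels
    is_single = truth_labels == SINGLE
    is_multi = truth_labels == MULTI
    n_single = int(is_single.sum())
    n_multi = int(is_multi.sum())

    def _recall(mask):
        return float(correct[mask].mean()) if mask.any() else float("nan")

    def _by_step(mask):
        total = max(mask.sum(), 1)
        return {
            step: float((correct & mask & (steps == step)).sum() / total)
            for step in (STEP_EM, STEP_RRD, STEP_CLUSTER)
        }

    region_frac = None
    if truth_intervals is not None:
        multi_iv = [(s, e) for s, e, state in truth_intervals if state == MULTI]
        if multi_iv:
            mpos = classifications.pos[pred == MULTI]
            tagged = sum(
                1 for s, e in multi_iv if np.any((mpos > s) & (mpos <= e))
            )
            region_frac = tagged / len(multi_iv)

    return EvaluationReport(
        recall_single=_recall(is_single),
        recall_multi=_recall(is_multi),
        recall_total=_recall(np.ones_like(correct, dtype=bool)),
        n_single=n_single,
        n_multi=n_multi,
        step_fraction_single=_by_step(is_single),
        step_fraction_multi=_by_step(is_multi),
        region_tag_fraction=region_frac,
    )
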