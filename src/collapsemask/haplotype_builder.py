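"""Step 3: haplotype elongation from seed SNPs and breakpoint placement.

Seeds are SNPs labeled MULTI by the first two steps.  Multicopy SNPs cluster
in haplotypes, so consecutive inter-seed distances are a mixture of short
within-haplotype and long between-haplotype distances; a two-component
geometric mixture fitted by EM yields a distance threshold (the point where
the component posteriors cross 0.5) that bounds elongation.

Starting from each seed, regions are elongated outward SNP by SNP:

a. an adjacent seed merges into the region;
b. a non-seed focal SNP is absorbed if the carrier set (individuals
   heterozygous at the nearest seed) shows depth excess there, at least
   ``depth_excess_factor`` times the genome-wide mean;
c. a focal SNP without depth excess labeled SINGLE places a breakpoint at
   the mid-distance between the previous SNP and the focal SNP;
d. a focal SNP without depth excess labeled UNCERTAIN is skipped, as long
   as the average distance from the last seed across the skipped SNPs stays
   below the threshold; otherwise a breakpoint is placed at the mid-distance
   between the last seed and its neighbor;
e. any breakpoint is capped at half the distance threshold from the last
   seed (also at contig ends).

After elongation every SNP inside a region is MULTI; SNPs left UNCERTAIN
outside all regions default to SINGLE (the mask complement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from collapsemask.errors import DataError
from collapsemask.em_classifier import (
    Classifications,
    MULTI,
    SINGLE,
    STEP_CLUSTER,
    UNCERTAIN,
)
from collapsemask.vcf_io import HET, SiteTable

logger = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    """Settings for the elongation step.

    ``genome_mean_depth`` is the mean per-individual per-site total depth
    over all retained sites; a focal SNP shows depth excess when the carrier
    set's mean depth reaches ``depth_excess_factor`` times that value.
    """

    depth_excess_factor: float = 1.5
    distance_threshold: float = 1000.0
    genome_mean_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_excess_factor <= 1:
            raise ValueError("depth_excess_factor must exceed 1")
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")


@dataclass
class MulticopyRegion:
    """A contiguous masked interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    n_seeds: int
    member_snps: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")


def _geometric_logpmf(d: np.ndarray, p: float) -> np.ndarray:
    return np.log(p) + (d - 1.0) * np.log1p(-p)


def fit_geometric_mixture(
    distances: np.ndarray, max_iter: int = 500, tol: float = 1e-10
) -> tuple[float, float, float, bool]:
    """EM fit of a two-component geometric mixture to inter-seed distances.

    Returns ``(pi_short, p_short, p_long, ok)`` with the short component
    first (larger success probability, shorter mean).  ``ok`` is False when
    the fit is degenerate (components collapse onto each other or one
    component vanishes).
    """
    d = np.asarray(distances, dtype=float)
    d = d[d >= 1]
    if len(d) < 4 or np.all(d == d[0]):
        return 0.5, np.nan, np.nan, False
    order = np.sort(d)
    half = len(order) // 2
    m1 = max(order[:half].mean(), 1.0)
    m2 = max(order[half:].mean(), m1 + 1.0)
    p1, p2 = 1.0 / m1, 1.0 / m2
    pi = 0.5
    prev_ll = -np.inf
    for _ in range(max_iter):
        l1 = np.log(pi) + _geometric_logpmf(d, p1)
        l2 = np.log1p(-pi) + _geometric_logpmf(d, p2)
        denom = np.logaddexp(l1, l2)
        r1 = np.exp(l1 - denom)
        ll = float(denom.sum())
        pi = float(np.clip(r1.mean(), 1e-9, 1 - 1e-9))
        p1 = float(np.clip(r1.sum() / np.sum(r1 * d), 1e-9, 1.0 - 1e-12))
        p2 = float(np.clip((1 - r1).sum() / np.sum((1 - r1) * d), 1e-9, 1.0 - 1e-12))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    if p1 < p2:  # ensure component 1 is the short-distance one
        p1, p2 = p2, p1
        pi = 1.0 - pi
    degenerate = (
        not np.isfinite(ll)
        or min(pi, 1 - pi) < 1e-3
        or p2 <= 0
        or p1 / p2 < 1.5  # components essentially identical
    )
    return pi, p1, p2, not degenerate


def mixture_crossing_point(pi: float, p1: float, p2: float) -> float:
    """Distance where the two geometric components' posteriors cross 0.5.

    Solves ``pi p1 (1-p1)^(d-1) = (1-pi) p2 (1-p2)^(d-1)`` for d.
    """
    num = np.log((1 - pi) * p2) - np.log(pi * p1)
    den = np.log1p(-p1) - np.log1p(-p2)
    return float(1.0 + num / den)


def estimate_distance_threshold(
    seed_positions: dict[str, np.ndarray],
    min_distances: int = 100,
    fallback: float = 1000.0,
) -> float:
    """Estimate the within-haplotype distance threshold from seed spacing.

    ``seed_positions`` maps chromosome names to sorted seed coordinates.
    Consecutive inter-seed distances are pooled genome-wide and a
    two-component geometric mixture is fitted; the threshold is the distance
    at which the posterior assignment crosses between components.  Falls
    back to ``fallback`` (with a warning) if the mixture degenerates.
    """
    dists = []
    for pos in seed_positions.values():
        pos = np.sort(np.asarray(pos))
        if len(pos) >= 2:
            dists.append(np.diff(pos))
    if not dists:
        raise DataError("no inter-seed distances available")
    d = np.concatenate(dists).astype(float)
    d = d[d >= 1]
    if len(d) < min_distances:
        raise DataError(
            f"only {len(d)} inter-seed distances (need >= {min_distances})"
        )
    pi, p1, p2, ok = fit_geometric_mixture(d)
    if not ok:
        logger.warning(
            "distance mixture degenerate; falling back to fixed threshold %.0f bp",
            fallback,
        )
        return float(fallback)
    thr = mixture_crossing_point(pi, p1, p2)
    if not np.isfinite(thr) or thr < 1:
        logger.warning("invalid crossing point; falling back to %.0f bp", fallback)
        return float(fallback)
    return thr


def _carrier_depth_ok(
    j: int,
    seed_order: np.ndarray,
    positions: np.ndarray,
    het: np.ndarray,
    dp: np.ndarray,
    factor: float,
    genome_mean: float,
) -> bool:
    """Depth-excess test at focal SNP ``j`` against the nearest seed's carriers."""
    pos_j = positions[j]
    k = np.searchsorted(positions[seed_order], pos_j)
    cands = []
    if k > 0:
        cands.append(seed_order[k - 1])
    if k < len(seed_order):
        cands.append(seed_order[k])
    # nearest seed; ties broken toward the upstream (lower-coordinate) seed
    nearest = min(cands, key=lambda s: (abs(int(positions[s]) - int(pos_j)), positions[s]))
    carriers = het[nearest]
    if not carriers.any():
        carriers = dp[nearest] > 0  # seed with no heterozygote left after filtering
        if not carriers.any():
            return False
    return float(dp[j, carriers].mean()) >= factor * genome_mean


def _scan_chromosome(
    positions: np.ndarray,
    labels: np.ndarray,
    seed_mask: np.ndarray,
    het: np.ndarray,
    dp: np.ndarray,
    config: ClusterConfig,
) -> list[tuple[float, float, set[int]]]:
    """One left-to-right elongation pass; returns (left_bp, right_bp, members).

    Breakpoints are continuous coordinates on the 1-based position axis.
    The left boundary produced by this pass is provisional (mirror pass
    refines it); members are indices into ``positions``.
    """
    thr = config.distance_threshold
    half = thr / 2.0
    m = len(positions)
    seeds = np.flatnonzero(seed_mask)
    out = []
    i = 0
    while i < m:
        if not seed_mask[i]:
            i += 1
            continue
        first_seed = i
        last_seed = i
        members = {i}
        skipped: list[int] = []
        right_bp = None
        j = i + 1
        while j < m:
            gap_cap = positions[last_seed] + half
            if seed_mask[j]:
                # rule (d) distance budget also limits seed-to-seed bridging
                chain = skipped + [j]
                avg = float(np.mean(positions[chain] - positions[last_seed]))
                if avg >= thr:
                    nb = positions[last_seed + 1] if last_seed + 1 < m else None
                    mid = (positions[last_seed] + nb) / 2.0 if nb is not None else gap_cap
                    right_bp = min(mid, gap_cap)
                    break
                members.update(chain)
                skipped = []
                last_seed = j
                j += 1
                continue
            within_reach = positions[j] - positions[last_seed] <= half
            if within_reach and _carrier_depth_ok(
                j, seeds, positions, het, dp,
                config.depth_excess_factor, config.genome_mean_depth,
            ):
                members.update(skipped)
                members.add(j)
                skipped = []
                j += 1
                continue
            if labels[j] == SINGLE:
                if skipped:
                    # closing after skipped SNPs: the boundary is anchored at
                    # the last seed so the skipped SNPs stay outside the mask
                    nb = positions[last_seed + 1] if last_seed + 1 < m else None
                    mid = (positions[last_seed] + nb) / 2.0 if nb is not None else gap_cap
                else:
                    mid = (positions[j - 1] + positions[j]) / 2.0
                right_bp = min(mid, gap_cap)
                break
            # UNCERTAIN (or SINGLE beyond reach is treated the same way):
            skipped.append(j)
            nxt = j + 1
            if nxt < m:
                chain = skipped + [nxt]
                avg = float(np.mean(positions[chain] - positions[last_seed]))
                if avg < thr:
                    j += 1
                    continue
            nb = positions[last_seed + 1] if last_seed + 1 < m else None
            mid = (positions[last_seed] + nb) / 2.0 if nb is not None else gap_cap
            right_bp = min(mid, gap_cap)
            break
        if right_bp is None:  # ran off the chromosome end
            right_bp = positions[last_seed] + half
        right_bp = max(right_bp, float(positions[max(members)]))
        left_bp = float(positions[first_seed]) - 1.0  # provisional
        out.append((left_bp, right_bp, members))
        i = j if j > i else i + 1
        # resume scanning after the last member to avoid re-opening inside
        i = max(i, max(members) + 1)
    return out


def elongate(
    classifications: Classifications,
    table: SiteTable,
    config: ClusterConfig,
) -> tuple[list[MulticopyRegion], Classifications]:
    """Elongate multicopy haplotypes from seeds and finalize SNP labels.

    Runs the elongation automaton in both directions (left and right
    elongation are independent and symmetric) and merges seed chains
    connected in either direction.  Returns the masked regions (0-based,
    half-open, disjoint per chromosome) and the final classifications, in
    which every SNP is SINGLE or MULTI.
    """
    out = classifications.copy()
    regions: list[MulticopyRegion] = []
    genome_mean = config.genome_mean_depth
    if genome_mean <= 0:
        raise ValueError("config.genome_mean_depth must be set and positive")

    for chrom in dict.fromkeys(out.chrom.tolist()):
        sel = np.flatnonzero(out.chrom == chrom)
        positions = out.pos[sel].astype(float)
        if np.any(np.diff(positions) <= 0):
            raise DataError(f"SNP positions not sorted on {chrom}")
        labels = out.label[sel]
        seed_mask = labels == MULTI
        if not seed_mask.any():
            continue
        site_rows = out.site_index[sel]
        het = (table.gt[site_rows] == HET)
        dp = table.dp[site_rows].astype(float)

        fwd = _scan_chromosome(positions, labels, seed_mask, het, dp, config)
        # mirror pass: reflect coordinates so the same automaton elongates left
        rev_pos = -positions[::-1]
        rev_labels = labels[::-1]
        rev_seed = seed_mask[::-1]
        bwd_raw = _scan_chromosome(
            rev_pos, rev_labels, rev_seed, het[::-1], dp[::-1], config
        )
        mlast = len(positions) - 1
        bwd = [
            (-rbp, -lbp, {mlast - k for k in mem})
            for (lbp, rbp, mem) in bwd_raw
        ]

        merged = _merge_passes(fwd, bwd, seed_mask)
        for left_bp, right_bp, members in merged:
            start = int(np.floor(left_bp))
            end = int(np.floor(right_bp))
            if end <= start:
                end = start + 1
            # the 0-based half-open [start, end) covers 1-based start+1..end;
            # every SNP inside the interval is part of the mask
            inside_local = np.flatnonzero(
                (positions > start) & (positions <= end)
            )
            n_seeds = int(seed_mask[inside_local].sum())
            member_rows = sorted(
                {int(site_rows[k]) for k in members}
                | {int(site_rows[k]) for k in inside_local}
            )
            newly = [k for k in inside_local if labels[k] != MULTI]
            out.label[sel[newly]] = MULTI
            out.step[sel[newly]] = STEP_CLUSTER
            regions.append(
                MulticopyRegion(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_seeds=max(n_seeds, 1),
                    member_snps=member_rows,
                )
            )

    # leftover UNCERTAIN SNPs lie outside every region: mask complement
    leftover = out.label == UNCERTAIN
    out.label[leftover] = SINGLE
    out.step[leftover] = STEP_CLUSTER
    regions.sort(key=lambda r: (str(r.chrom), r.start))
    return regions, out


def _merge_passes(fwd, bwd, seed_mask):
    """Union seed chains connected in either scan direction.

    Two pass-regions sharing a seed merge; the final interval spans the
    leftmost left-breakpoint (from the mirror pass) to the rightmost
    right-breakpoint (from the forward pass).
    """
    n = int(seed_mask.sum())
    seed_ids = {s: k for k, s in enumerate(np.flatnonzero(seed_mask))}
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    groups = []
    for lbp, rbp, mem in list(fwd) + list(bwd):
        seeds_in = [seed_ids[k] for k in mem if k in seed_ids]
        for a, b in zip(seeds_in, seeds_in[1:]):
            union(a, b)
        groups.append((lbp, rbp, mem, seeds_in))

    merged: dict[int, list] = {}
    for lbp, rbp, mem, seeds_in in groups:
        root = find(seeds_in[0])
        slot = merged.setdefault(root, [np.inf, -np.inf, set()])
        slot[0] = min(slot[0], lbp)
        slot[1] = max(slot[1], rbp)
        slot[2].update(mem)
    out = [(lbp, rbp, mem) for lbp, rbp, mem in merged.values()]
    out.sort(key=lambda t: t[0])
    # clip any residual overlap between consecutive merged intervals
    clipped = []
    prev_end = -np.inf
    for lbp, rbp, mem in out:
        lbp = max(lbp, prev_end)
        rbp = max(rbp, lbp + 1.0)
        clipped.append((lbp, rbp, mem))
        prev_end = rbp
    return clipped


def region_length_stats(
    regions: list[MulticopyRegion], n_bins: int = 20
) -> dict:
    """Mean region length and a binned histogram of the length distribution."""
    if not regions:
        raise DataError("no regions to summarize")
    lengths = np.array([r.length for r in regions], dtype=float)
    counts, edges = np.histogram(lengths, bins=n_bins)
    return {
        "n_regions": len(regions),
        "mean_length": float(lengths.mean()),
        "median_length": float(np.median(lengths)),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }
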