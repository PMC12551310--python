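"""Distance-threshold estimation and the haplotype elongation automaton."""

import numpy as np
import pytest

from collapsemask import (
    ClusterConfig,
    elongate,
    estimate_distance_threshold,
    region_length_stats,
)
from collapsemask.em_classifier import Classifications, MULTI, SINGLE, UNCERTAIN
from collapsemask.errors import DataError
from collapsemask.haplotype_builder import (
    MulticopyRegion,
    fit_geometric_mixture,
    mixture_crossing_point,
)
from collapsemask.vcf_io import HET, HOM_REF, SiteTable


class TestDistanceThreshold:
    def test_recovers_analytic_crossing_of_known_mixture(self):
        """50/50 geometric mixture (means 50 and 5000): threshold within 20%
        of the brute-force posterior crossing of the true mixture."""
        rng = np.random.default_rng(42)
        p1, p2 = 1 / 50, 1 / 5000
        d = np.where(rng.random(10_000) < 0.5,
                     rng.geometric(p1, 10_000), rng.geometric(p2, 10_000))
        positions = {"c1": np.cumsum(d)}
        thr = estimate_distance_threshold(positions)

        dd = np.arange(1, 50_000)
        log_r = (np.log(p1) + (dd - 1) * np.log1p(-p1)) - (
            np.log(p2) + (dd - 1) * np.log1p(-p2)
        )
        oracle = dd[np.argmin(np.abs(log_r))]
        assert thr == pytest.approx(oracle, rel=0.2)

    def test_identical_distances_trigger_fallback(self):
        positions = {"c1": np.arange(200) * 100}
        thr = estimate_distance_threshold(positions, fallback=777.0)
        assert thr == 777.0

    def test_invariant_under_chromosome_relabeling(self):
        rng = np.random.default_rng(1)
        d = np.where(rng.random(2000) < 0.5,
                     rng.geometric(0.02, 2000), rng.geometric(0.0002, 2000))
        pos = np.cumsum(d)
        t1 = estimate_distance_threshold({"a": pos})
        t2 = estimate_distance_threshold({"weird_name": pos})
        assert t1 == t2

    def test_too_few_distances_is_error(self):
        with pytest.raises(DataError):
            estimate_distance_threshold({"c": np.arange(10) * 7})

    def test_crossing_point_formula(self):
        """Posterior responsibilities really cross 0.5 at the returned point."""
        pi, p1, p2 = 0.4, 0.02, 0.0005
        d_star = mixture_crossing_point(pi, p1, p2)
        def post_short(d):
            f1 = pi * p1 * (1 - p1) ** (d - 1)
            f2 = (1 - pi) * p2 * (1 - p2) ** (d - 1)
            return f1 / (f1 + f2)
        assert post_short(np.floor(d_star)) > 0.5 > post_short(np.ceil(d_star) + 1)


def elongation_case(positions, labels, het_rows=None, dp=None, n_ind=6,
                    threshold=300.0, genome_mean=10.0):
    """Build a single-chromosome scenario for the elongation automaton."""
    n = len(positions)
    gt = np.full((n, n_ind), HOM_REF, dtype=np.int8)
    if het_rows:
        for i in het_rows:
            gt[i, :] = HET
    dparr = np.full((n, n_ind), 10, dtype=np.int32) if dp is None else np.asarray(dp)
    table = SiteTable(
        chrom=np.full(n, "c"), pos=np.asarray(positions, dtype=np.int64),
        ref=np.full(n, "A"), alt=np.full(n, "G"), gt=gt,
        ad_ref=dparr // 2, ad_alt=dparr - dparr // 2, dp=dparr,
        gq=np.full((n, n_ind), 99, dtype=np.int32),
        samples=[f"s{i}" for i in range(n_ind)],
    )
    cls = Classifications(
        chrom=table.chrom, pos=table.pos, maf=np.full(n, 0.2),
        het_fraction=np.full(n, 0.2), label=np.array(labels, dtype="U9"),
        llr=np.zeros(n), step=np.full(n, "EM", dtype="U7"),
        site_index=np.arange(n),
    )
    config = ClusterConfig(distance_threshold=threshold, genome_mean_depth=genome_mean)
    return elongate(cls, table, config)


class TestElongation:
    def test_adjacent_seeds_merge_into_one_region(self):
        """Two seeds 100 bp apart, threshold 254, nothing between: one region."""
        regions, final = elongation_case(
            [1000, 1100], [MULTI, MULTI], het_rows=[0, 1], threshold=254.0
        )
        assert len(regions) == 1
        assert regions[0].n_seeds == 2

    def test_breakpoints_at_mid_distance_to_flanking_singles(self):
        """Isolated seed at 10,000 with SINGLE flanks at 9,900/10,080 ->
        region [9950, 10040) (mid-distances)."""
        regions, _ = elongation_case(
            [9900, 10000, 10080], [SINGLE, MULTI, SINGLE], het_rows=[1],
            threshold=2000.0,
        )
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (9950, 10040)

    def test_breakpoints_capped_at_half_threshold(self):
        """Distant flanks: region spans threshold centered on the seed."""
        regions, _ = elongation_case(
            [5000, 10000, 15000], [SINGLE, MULTI, SINGLE], het_rows=[1],
            threshold=300.0,
        )
        assert len(regions) == 1
        assert regions[0].length == 300
        # seed (1-based 10000) inside [start, end)
        assert regions[0].start < 10000 <= regions[0].end

    def test_depth_excess_absorbs_focal_snp(self):
        """A non-seed SNP with 2x depth in the seed's carriers joins the region."""
        n, n_ind = 3, 6
        dp = np.full((n, n_ind), 10, dtype=np.int32)
        dp[1, :3] = 22  # focal SNP, carriers = the seed's heterozygotes 0..2
        regions, final = elongation_case_custom_hets(
            [1000, 1100, 1300], [MULTI, UNCERTAIN, SINGLE], {0: [0, 1, 2]},
            dp=dp, threshold=500.0,
        )
        assert final.label[1] == MULTI
        assert final.step[1] == "CLUSTER"
        assert len(regions) == 1
        assert 1100 <= regions[0].end  # absorbed SNP inside the mask

    def test_no_demotion_and_final_labels_are_binary(self, small_pipeline):
        _, _, _, result = small_pipeline
        rrd = result.rrd_classifications
        final = result.classifications
        assert ((rrd.label == MULTI) <= (final.label == MULTI)).all()
        assert set(np.unique(final.label)) <= {SINGLE, MULTI}

    def test_unsorted_positions_hard_error(self):
        with pytest.raises(DataError, match="sorted"):
            elongation_case([100, 90, 200], [MULTI, SINGLE, SINGLE], het_rows=[0])

    def test_region_invariants_on_pipeline_output(self, small_pipeline):
        """Regions are disjoint, each contains a seed, breakpoints capped."""
        _, table, _, result = small_pipeline
        thr = result.distance_threshold
        seeds = result.rrd_classifications.pos[
            result.rrd_classifications.label == MULTI
        ]
        by_chrom = {}
        for r in result.regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                assert a.end <= b.start
            for r in rs:
                inside = seeds[(seeds > r.start) & (seeds <= r.end)]
                assert len(inside) >= 1
                assert r.end - inside.max() <= thr / 2 + 1
                assert inside.min() - r.start <= thr / 2 + 1


def elongation_case_custom_hets(positions, labels, het_map, dp, n_ind=6,
                                threshold=300.0, genome_mean=10.0):
    n = len(positions)
    gt = np.full((n, n_ind), HOM_REF, dtype=np.int8)
    for i, inds in het_map.items():
        gt[i, inds] = HET
    table = SiteTable(
        chrom=np.full(n, "c"), pos=np.asarray(positions, dtype=np.int64),
        ref=np.full(n, "A"), alt=np.full(n, "G"), gt=gt,
        ad_ref=dp // 2, ad_alt=dp - dp // 2, dp=dp,
        gq=np.full((n, n_ind), 99, dtype=np.int32),
        samples=[f"s{i}" for i in range(n_ind)],
    )
    cls = Classifications(
        chrom=table.chrom, pos=table.pos, maf=np.full(n, 0.2),
        het_fraction=np.full(n, 0.2), label=np.array(labels, dtype="U9"),
        llr=np.zeros(n), step=np.full(n, "EM", dtype="U7"),
        site_index=np.arange(n),
    )
    config = ClusterConfig(distance_threshold=threshold, genome_mean_depth=genome_mean)
    return elongate(cls, table, config)


class TestRegionStats:
    def test_mean_length(self):
        regions = [
            MulticopyRegion("c", 0, 100, 1),
            MulticopyRegion("c", 200, 400, 1),
            MulticopyRegion("c", 500, 800, 1),
        ]
        stats = region_length_stats(regions)
        assert stats["mean_length"] == pytest.approx(200.0)
        assert sum(stats["hist_counts"]) == 3

    def test_empty_is_error(self):
        with pytest.raises(DataError):
            region_length_stats([])
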