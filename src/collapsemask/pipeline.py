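"""End-to-end orchestration of the three classification steps."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from collapsemask.em_classifier import (
    Classifications,
    MULTI,
    MixtureFit,
    SINGLE,
    classify_by_llr,
    fit_em,
    summarize_sites,
)
from collapsemask.errors import DataError
from collapsemask.haplotype_builder import (
    ClusterConfig,
    MulticopyRegion,
    elongate,
    estimate_distance_threshold,
)
from collapsemask.rrd import empirical_interval, refine_classification, site_rrd_z
from collapsemask.vcf_io import SiteTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All artifacts of one classification run."""

    classifications: Classifications
    regions: list[MulticopyRegion]
    fit: MixtureFit
    em_classifications: Classifications
    rrd_classifications: Classifications
    rrd_z: np.ndarray
    rrd_ci: tuple[float, float]
    distance_threshold: float
    genome_mean_depth: float

    def label_counts(self) -> dict[str, int]:
        return self.classifications.counts()


def run_pipeline(
    table: SiteTable,
    llr_thresholds: tuple[float, float] = (-2.0, 3.0),
    alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-4,
    min_snps: int = 500,
    depth_excess_factor: float = 1.5,
    distance_threshold: float | None = None,
    fallback_distance: float = 1000.0,
    min_rrd_reads: int = 4,
    seed: int | None = None,
) -> PipelineResult:
    """Run EM classification, read-ratio refinement and haplotype elongation.

    ``table`` must already be filtered (see
    :func:`collapsemask.vcf_io.apply_filters`).  ``distance_threshold``
    overrides the mixture-based estimate when given.
    """
    summaries = summarize_sites(table)
    fit = fit_em(summaries, max_iter=max_iter, tol=tol, seed=seed, min_snps=min_snps)
    em_cls = classify_by_llr(fit, thresholds=llr_thresholds)
    logger.info("EM step: %s", em_cls.counts())

    z_all, _ = site_rrd_z(table, min_total_reads=min_rrd_reads)
    z = z_all[summaries.site_index]
    single_z = z[em_cls.label == SINGLE]
    ci = empirical_interval(single_z, alpha=alpha)
    rrd_cls = refine_classification(em_cls, z, ci)
    logger.info("RRD step: %s (interval %.3f..%.3f)", rrd_cls.counts(), *ci)

    seed_positions: dict[str, np.ndarray] = {}
    for chrom in dict.fromkeys(rrd_cls.chrom.tolist()):
        m = (rrd_cls.chrom == chrom) & (rrd_cls.label == MULTI)
        seed_positions[chrom] = rrd_cls.pos[m]
    if distance_threshold is None:
        try:
            distance_threshold = estimate_distance_threshold(
                seed_positions, fallback=fallback_distance
            )
        except DataError as exc:
            logger.warning("distance threshold estimate failed (%s); using %.0f bp",
                           exc, fallback_distance)
            distance_threshold = fallback_distance
    genome_mean_depth = float(table.dp.mean())
    config = ClusterConfig(
        depth_excess_factor=depth_excess_factor,
        distance_threshold=float(distance_threshold),
        genome_mean_depth=genome_mean_depth,
    )
    regions, final_cls = elongate(rrd_cls, table, config)
    logger.info("cluster step: %s, %d regions", final_cls.counts(), len(regions))

    return PipelineResult(
        classifications=final_cls,
        regions=regions,
        fit=fit,
        em_classifications=em_cls,
        rrd_classifications=rrd_cls,
        rrd_z=z,
        rrd_ci=ci,
        distance_threshold=float(distance_threshold),
        genome_mean_depth=genome_mean_depth,
    )
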