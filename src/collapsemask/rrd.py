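"""Step 2: read-ratio-deviation z-scores with an empirical single-copy null.

At a true heterozygote the expected fraction of reads carrying the
alternative allele is 0.5.  At a collapsed multicopy SNP where one of two
copies is heterozygous, read ratios center at 0.25 or 0.75 instead.  For
each SNP we aggregate reads over heterozygous individuals and standardize
against Binomial(N, 0.5):

    z = (A - N/2) / sqrt(N/4)

with A the summed alternative-allele reads and N the summed total reads.
Rather than assuming a N(0, 1) null, the rejection interval is the empirical
two-sided 95% interval of z at SNPs the EM step classified as single-copy,
which absorbs residual overdispersion of real data relative to the binomial.
Only SNPs left UNCERTAIN by the EM step are eligible for promotion to MULTI.
"""

from __future__ import annotations

import numpy as np

from collapsemask.errors import DataError
from collapsemask.em_classifier import (
    Classifications,
    MULTI,
    SINGLE,
    STEP_RRD,
    UNCERTAIN,
)
from collapsemask.vcf_io import HET, SiteTable


def site_rrd_z(
    table: SiteTable, min_total_reads: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site read-ratio-deviation z-scores across heterozygous individuals.

    Returns ``(z, n_het_used)`` arrays over all sites in ``table``; ``z`` is
    NaN where no heterozygote contributes at least one read or the summed
    read count falls below ``min_total_reads``.
    """
    het = table.gt == HET
    alt = np.where(het, table.ad_alt, 0).sum(axis=1).astype(float)
    ref = np.where(het, table.ad_ref, 0).sum(axis=1).astype(float)
    reads = (np.where(het, table.ad_ref + table.ad_alt, 0) > 0) & het
    n_het_used = reads.sum(axis=1)
    total = alt + ref
    usable = (n_het_used >= 1) & (total >= max(min_total_reads, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (alt - total / 2.0) / np.sqrt(total / 4.0)
    z = np.where(usable, z, np.nan)
    return z, n_het_used


def empirical_interval(
    z_values: np.ndarray, alpha: float = 0.05, min_count: int = 200
) -> tuple[float, float]:
    """Two-sided empirical interval from single-copy z-scores.

    Returns the ``alpha/2`` and ``1 - alpha/2`` quantiles with linear
    interpolation between order statistics (type-7 convention).
    """
    z = np.asarray(z_values, dtype=float)
    z = z[np.isfinite(z)]
    if len(z) < min_count:
        raise DataError(
            f"only {len(z)} single-copy z-scores available (need >= {min_count}); "
            "relax the EM classification thresholds to obtain more single-copy SNPs"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    lo, hi = np.quantile(z, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def refine_classification(
    classifications: Classifications,
    z_values: np.ndarray,
    ci: tuple[float, float],
) -> Classifications:
    """Promote UNCERTAIN SNPs with z outside the interval to MULTI.

    EM-assigned SINGLE/MULTI labels are never overwritten; the SINGLE and
    MULTI sets can only grow and the UNCERTAIN set only shrink.
    """
    lo, hi = ci
    out = classifications.copy()
    z = np.asarray(z_values, dtype=float)
    promote = (
        (out.label == UNCERTAIN)
        & np.isfinite(z)
        & ((z < lo) | (z > hi))
    )
    out.label[promote] = MULTI
    out.step[promote] = STEP_RRD
    return out
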