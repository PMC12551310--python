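"""Summary statistics for the multicopy-bias experiments.

Implements the standard estimators on diploid genotype matrices
(codes 0/1/2 alt dose, -1 missing): Watterson's theta, mean pairwise
diversity, Tajima's D, the inbreeding coefficient F_IS, Weir-Cockerham
F_ST, and the (joint) allele frequency spectrum.  Diploid genotypes count
as two sequences; missing genotypes reduce the per-site sequence count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from collapsemask.errors import DataError

MISSING = -1


def _harmonic(k: int, power: int = 1) -> float:
    i = np.arange(1, k)
    return float(np.sum(1.0 / i**power))


def watterson_theta(S: int, k: int, L: float) -> float:
    """Watterson's estimator per bp: ``S / (a_k * L)`` with ``a_k = sum 1/i``."""
    if k < 2:
        raise ValueError("need at least 2 sequences")
    if L <= 0:
        raise ValueError("surveyed length must be positive")
    if S == 0:
        return 0.0
    return S / (_harmonic(k) * L)


def _site_freqs(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (alt frequency, sequence count, het count) ignoring missing."""
    called = gt != MISSING
    n_seq = 2 * called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_seq > 0, alt / np.maximum(n_seq, 1), np.nan)
    n_het = ((gt == 1) & called).sum(axis=1)
    return p, n_seq, n_het


def pairwise_pi(gt: np.ndarray, L: float) -> float:
    """Mean pairwise diversity per bp (unbiased per-site ``2 p q n/(n-1)``)."""
    if gt.shape[1] < 1:
        raise ValueError("need at least one individual")
    p, n_seq, _ = _site_freqs(gt)
    ok = n_seq >= 2
    p, n_seq = p[ok], n_seq[ok]
    per_site = 2.0 * p * (1.0 - p) * n_seq / (n_seq - 1.0)
    return float(per_site.sum() / L)


def tajimas_d(S: int, theta_pi_total: float, k: int) -> float:
    """Tajima's D from total pairwise diversity, S and sequence count k.

    ``theta_pi_total`` is summed over sites (not per bp).  Undefined (NaN)
    when ``S == 0``.
    """
    if k < 3:
        raise ValueError("need at least 3 sequences")
    if S == 0:
        return float("nan")
    n = k
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((theta_pi_total - S / a1) / np.sqrt(var))


def inbreeding_fis(gt: np.ndarray) -> float:
    """Inbreeding coefficient ``1 - H_obs / H_exp`` aggregated over sites.

    ``H_exp`` carries the small-sample correction ``2 p q * 2n/(2n-1)``.
    Undefined (NaN) when no polymorphic site is present.
    """
    p, n_seq, n_het = _site_freqs(gt)
    poly = (p > 0) & (p < 1) & (n_seq >= 2)
    if not poly.any():
        return float("nan")
    p, n_seq, n_het = p[poly], n_seq[poly], n_het[poly]
    h_obs = n_het / (n_seq / 2.0)
    h_exp = 2.0 * p * (1.0 - p) * n_seq / (n_seq - 1.0)
    return float(1.0 - h_obs.sum() / h_exp.sum())


def allele_frequency_spectrum(gt: np.ndarray, folded: bool = False) -> np.ndarray:
    """AFS as counts per alternative (or minor, if folded) allele count.

    Entry ``i`` counts sites with ``i`` alternative alleles among
    ``2 * n_ind`` sequences; entries 0 and 2n are monomorphic classes.
    """
    n_ind = gt.shape[1]
    k = 2 * n_ind
    called = gt != MISSING
    alt = np.where(called, gt, 0).sum(axis=1)
    # project sites with missing data onto the full sample size by rounding
    n_seq = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore"):
        scaled = np.where(n_seq > 0, np.rint(alt * k / np.maximum(n_seq, 1)), 0)
    counts = np.bincount(scaled.astype(int), minlength=k + 1)
    if folded:
        half = k // 2
        folded_counts = counts[: half + 1].copy()
        folded_counts[: k - half] += counts[k : half : -1]
        return folded_counts
    return counts


def fst_and_jafs(
    gt1: np.ndarray, gt2: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weir-Cockerham multi-site F_ST and the joint AFS of two populations.

    Genotype matrices must cover the same sites (rows aligned).  The jAFS is
    a ``(2 n1 + 1) x (2 n2 + 1)`` count matrix of alternative allele counts.
    """
    if gt1.shape[0] != gt2.shape[0]:
        raise DataError(
            f"site sets differ: {gt1.shape[0]} vs {gt2.shape[0]} rows"
        )
    p1, n1, h1 = _site_freqs(gt1)
    p2, n2, h2 = _site_freqs(gt2)
    ok = (n1 >= 2) & (n2 >= 2)
    p1, n1, h1 = p1[ok], n1[ok] / 2.0, h1[ok]
    p2, n2, h2 = p2[ok], n2[ok] / 2.0, h2[ok]
    hbar1 = h1 / n1
    hbar2 = h2 / n2

    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * hbar1 + n2 * hbar2) / (r * nbar)

    a = (nbar / nc) * (
        s2
        - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - (r - 1.0) / r * s2
        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = float(np.sum(a + b + c))
    fst = float(np.sum(a) / denom) if denom != 0 else float("nan")

    k1, k2 = 2 * gt1.shape[1], 2 * gt2.shape[1]
    alt1 = np.where(gt1 != MISSING, gt1, 0).sum(axis=1)
    alt2 = np.where(gt2 != MISSING, gt2, 0).sum(axis=1)
    jafs = np.zeros((k1 + 1, k2 + 1), dtype=np.int64)
    np.add.at(jafs, (alt1.astype(int), alt2.astype(int)), 1)
    return fst, jafs


@dataclass
class SummaryStats:
    """Bundle of genome-wide summaries for one SNP set."""

    S: int
    theta_w: float
    theta_pi: float
    tajimas_d: float
    fis: float
    afs: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "S": self.S,
            "theta_w": self.theta_w,
            "theta_pi": self.theta_pi,
            "tajimas_d": self.tajimas_d,
            "fis": self.fis,
            "afs": None if self.afs is None else self.afs.tolist(),
        }


def summary_stats(gt: np.ndarray, L: float) -> SummaryStats:
    """All within-population summaries on one genotype matrix over length L."""
    p, n_seq, _ = _site_freqs(gt)
    poly = (p > 0) & (p < 1) & (n_seq >= 2)
    S = int(poly.sum())
    k = 2 * gt.shape[1]
    pi = pairwise_pi(gt[poly], L) if S else 0.0
    return SummaryStats(
        S=S,
        theta_w=watterson_theta(S, k, L),
        theta_pi=pi,
        tajimas_d=tajimas_d(S, pi * L, k) if S else float("nan"),
        fis=inbreeding_fis(gt),
        afs=allele_frequency_spectrum(gt),
    )
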