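"""Step 1: beta-binomial mixture regression of heterozygosity on allele frequency.

Model
-----
At a single-copy SNP under inbreeding, the expected heterozygote frequency is
``E[f(het)] = 2 maf (1 - maf)(1 - F_IS)``.  At a collapsed multicopy SNP every
copy of the minor allele surfaces in a spurious heterozygote, so
``E[f(het)] = 2 maf``.  Dividing by ``2 maf`` (the maximum heterozygote
frequency at a given minor allele frequency) yields the *scaled* heterozygote
frequency, bounded in [0, 1]:

* single-copy component (K): ``s_K(maf) = b0 + b1 (1 - maf)``, which equals
  ``(1 - F_IS)(1 - maf)`` when b0 = 0 and b1 = 1 - F_IS — the inbreeding
  level is absorbed into the regression coefficients;
* multicopy component (D): a constant level ``s_D`` close to 1.

The observation at SNP *i* is the heterozygote count out of the site's
minor-allele copy count ``m = n_het + 2 n_hom_minor`` (each minor copy either
surfaces in a heterozygote or pairs into a minor homozygote), modeled as
beta-binomial ``n_het_i ~ BetaBin(m_i, s, rho)`` whose mean is the scaled
heterozygote frequency itself, with intra-class correlation ``rho`` per
component.  Overdispersion absorbs sequencing error, binomial sampling,
mapping bias and interlocus gene conversion without modeling them
explicitly.  Sites with ``m < 3`` are parity-degenerate (a lone minor copy
is always heterozygous) and are held out of the likelihood and classified
UNCERTAIN at this step.

The two components are fitted jointly by Expectation-Maximization: the E-step
recalibrates per-SNP weights (soft assignment to the multicopy component)
from the component densities and the current mixing proportion; the M-step
maximizes each component's weighted log-likelihood numerically (L-BFGS-B,
warm-started at the previous solution, so the total log-likelihood never
decreases).  SNPs are then classified from the per-SNP log-likelihood ratio
``llr = log f_D - log f_K``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import betabinom, binom
from scipy.special import expit, logit

from collapsemask.errors import DataError, FitError
from collapsemask.vcf_io import HET, HOM_ALT, HOM_REF, MISSING, SiteTable

logger = logging.getLogger(__name__)

SINGLE = "SINGLE"
MULTI = "MULTI"
UNCERTAIN = "UNCERTAIN"

STEP_EM = "EM"
STEP_RRD = "RRD"
STEP_CLUSTER = "CLUSTER"

_MU_EPS = 1e-6
_S_EPS = 1e-4
_RHO_MIN = 1e-6
_RHO_MAX = 0.95
_MIN_MINOR_COPIES = 3  # below this the scaled-het observation is degenerate


@dataclass
class SiteSummaries:
    """Per-SNP derived statistics, the EM's observation unit.

    All fields are arrays aligned over retained polymorphic SNPs.
    ``site_index`` is a stable back-reference into the source
    :class:`~collapsemask.vcf_io.SiteTable`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    n_called: np.ndarray
    n_het: np.ndarray
    n_hom_minor: np.ndarray
    het_fraction: np.ndarray
    scaled_het: np.ndarray
    mean_depth_het: np.ndarray  # NaN when no HET genotype
    mean_depth_hom: np.ndarray  # NaN when no HOM genotype
    site_index: np.ndarray

    @property
    def n_minor(self) -> np.ndarray:
        """Minor-allele copy count per site, ``n_het + 2 n_hom_minor``."""
        return self.n_het + 2 * self.n_hom_minor

    @property
    def n_snps(self) -> int:
        return len(self.maf)

    def __len__(self) -> int:
        return self.n_snps


def summarize_sites(table: SiteTable) -> SiteSummaries:
    """Compute per-SNP summaries from a filtered site table.

    Sites with ``maf == 0`` (monomorphic among called genotypes) are dropped;
    sites with no called genotype are dropped with a warning.
    """
    gt = table.gt
    called = gt != MISSING
    n_called = called.sum(axis=1)
    empty = n_called == 0
    if empty.any():
        logger.warning("dropping %d sites with no called genotype", int(empty.sum()))

    n_het = ((gt == HET) & called).sum(axis=1)
    n_hom_alt = (gt == HOM_ALT).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = (n_het + 2 * n_hom_alt) / (2 * np.maximum(n_called, 1))
    minor_is_alt = alt_freq <= 0.5
    n_hom_ref = ((gt == HOM_REF) & called).sum(axis=1)
    n_hom_minor = np.where(minor_is_alt, n_hom_alt, n_hom_ref)
    maf = np.where(minor_is_alt, alt_freq, 1.0 - alt_freq)

    keep = (~empty) & (maf > 0) & (n_called >= 2)
    idx = np.flatnonzero(keep)

    gtk = gt[idx]
    dpk = table.dp[idx].astype(float)
    het_mask = gtk == HET
    hom_mask = (gtk == HOM_REF) | (gtk == HOM_ALT)
    mean_depth_het = _row_mean_where(dpk, het_mask)
    mean_depth_hom = _row_mean_where(dpk, hom_mask)

    n_called_k = n_called[idx]
    n_het_k = n_het[idx]
    maf_k = maf[idx]
    het_fraction = n_het_k / n_called_k
    scaled_het = n_het_k / (2.0 * maf_k * n_called_k)

    return SiteSummaries(
        chrom=table.chrom[idx],
        pos=table.pos[idx],
        maf=maf_k,
        n_called=n_called_k,
        n_het=n_het_k,
        n_hom_minor=n_hom_minor[idx],
        het_fraction=het_fraction,
        scaled_het=scaled_het,
        mean_depth_het=mean_depth_het,
        mean_depth_hom=mean_depth_hom,
        site_index=idx,
    )


def _row_mean_where(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row means of ``values`` over ``mask``; NaN for empty rows."""
    counts = mask.sum(axis=1)
    sums = np.where(mask, values, 0.0).sum(axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _rho_to_ab(mu: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Convert (mean, intra-class correlation) to beta shape parameters."""
    scale = (1.0 - rho) / rho
    return mu * scale, (1.0 - mu) * scale


def beta_binomial_density(k, n, mu, rho) -> np.ndarray | float:
    """Beta-binomial probability mass with mean ``mu`` and overdispersion ``rho``.

    ``rho`` is the intra-class correlation in [0, 1); ``rho = 0`` degenerates
    to ``Binomial(n, mu)``.
    """
    return np.exp(beta_binomial_logpmf(k, n, mu, rho))


def beta_binomial_logpmf(k, n, mu, rho) -> np.ndarray | float:
    """Log probability mass of the beta-binomial; see :func:`beta_binomial_density`."""
    k = np.asarray(k)
    n = np.asarray(n)
    mu_arr = np.asarray(mu, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(mu_arr <= 0) or np.any(mu_arr >= 1):
        raise ValueError("mu must lie in (0, 1)")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if rho == 0:
        return binom.logpmf(k, n, mu_arr)
    a, b = _rho_to_ab(mu_arr, rho)
    return betabinom.logpmf(k, n, a, b)


def provisional_fis(summaries: SiteSummaries) -> float:
    """Crude genome-wide inbreeding estimate, ``1 - H_obs / H_exp``.

    Used only to seed the EM; multicopy SNPs inflate observed heterozygosity
    so this underestimates the true coefficient, which the EM then refines.
    Clipped to [0, 0.95].
    """
    h_obs = float(np.sum(summaries.n_het))
    h_exp = float(
        np.sum(2.0 * summaries.maf * (1.0 - summaries.maf) * summaries.n_called)
    )
    if h_exp <= 0:
        return 0.0
    return float(np.clip(1.0 - h_obs / h_exp, 0.0, 0.95))


def initialize_weights(summaries: SiteSummaries, min_snps: int = 500) -> np.ndarray:
    """Initial soft assignments from residuals to the two asymptotic lines.

    The single-copy line is ``s = (1 - F0)(1 - maf)`` with ``F0`` the
    provisional genome-wide inbreeding estimate (the random-mating line when
    ``F0 = 0``); the multicopy line is ``s = 1``.  The initial multicopy
    weight is ``d_K / (d_K + d_D)`` where ``d_K, d_D`` are the absolute
    residuals of the scaled heterozygote frequency from each line,
    floored/capped at [0.05, 0.95] to avoid degenerate starts.
    Deterministic given input order.
    """
    if summaries.n_snps < min_snps:
        raise DataError(
            f"{summaries.n_snps} SNPs available but at least {min_snps} are needed "
            "for a stable mixture fit; provide more data or lower min_snps"
        )
    f0 = provisional_fis(summaries)
    d_k = np.abs(summaries.scaled_het - (1.0 - f0) * (1.0 - summaries.maf))
    d_d = np.abs(summaries.scaled_het - 1.0)
    denom = d_k + d_d
    w = np.where(denom > 0, d_k / np.where(denom > 0, denom, 1.0), 0.5)
    return np.clip(w, 0.05, 0.95)


@dataclass
class MixtureFit:
    """State of the fitted two-component beta-binomial regression."""

    intercept_multi: float  # constant scaled-het level s_D of the multicopy component
    intercept_single: float  # b0 of the single-copy component (scaled-het scale)
    slope_single: float  # b1, coefficient on (1 - maf); absorbs (1 - F_IS)
    overdispersion: tuple[float, float]  # (rho_single, rho_multi)
    weights: np.ndarray  # per-SNP P(multicopy)
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    fis_hat: float
    mixing: float  # final mixture proportion of the multicopy component
    log_f_single: np.ndarray = field(repr=False, default=None)
    log_f_multi: np.ndarray = field(repr=False, default=None)
    summaries: SiteSummaries = field(repr=False, default=None)


def _component_loglik_single(theta, k, n, maf, w):
    # trials n are the minor-allele copy count, so the mean is the scaled
    # heterozygote frequency itself: s = b0 + b1 (1 - maf)
    b0, b1, lrho = theta
    rho = float(np.clip(expit(lrho), _RHO_MIN, _RHO_MAX))
    mu = np.clip(b0 + b1 * (1.0 - maf), _S_EPS, 1.0 - _S_EPS)
    a, b = _rho_to_ab(mu, rho)
    return float(np.sum(w * betabinom.logpmf(k, n, a, b)))


def _component_loglik_multi(theta, k, n, maf, w):
    ls, lrho = theta
    rho = float(np.clip(expit(lrho), _RHO_MIN, _RHO_MAX))
    mu = float(np.clip(expit(ls), _S_EPS, 1.0 - _S_EPS))
    a, b = _rho_to_ab(np.full_like(np.asarray(maf, dtype=float), mu), rho)
    return float(np.sum(w * betabinom.logpmf(k, n, a, b)))


def fit_weighted_single_component(
    k: np.ndarray,
    n: np.ndarray,
    maf: np.ndarray,
    weights: np.ndarray,
    init: tuple[float, float, float] = (0.0, 1.0, 0.01),
    extra_starts: tuple[float, ...] = (1.0, 0.5, 0.1),
) -> tuple[float, float, float]:
    """Weighted fit of the single-copy regression (b0, b1, rho) by quasi-Newton.

    The line passes through the origin in theory (``s = (1 - F_IS)(1 - maf)``)
    so the intercept is bounded near zero.  The identity-scale likelihood has
    flat clipped plateaus, so the optimization is restarted from several
    slope values (``extra_starts``, covering inbreeding levels from none to
    strong) and the best optimum is kept.  Exposed separately so the M-step
    can be cross-checked against an independent grid-search oracle.
    """
    obj = lambda t: -_component_loglik_single(t, k, n, maf, weights)
    bounds = [(-0.3, 0.3), (-0.1, 1.2), (logit(_RHO_MIN), logit(_RHO_MAX))]
    b0, b1, rho = init
    lrho = logit(np.clip(rho, _RHO_MIN, _RHO_MAX))
    starts = [np.array([b0, b1, lrho])]
    starts += [np.array([0.0, s, lrho]) for s in extra_starts if abs(s - b1) > 1e-3]
    best = None
    for x0 in starts:
        res = minimize(obj, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    b0, b1, lrho = best.x
    return float(b0), float(b1), float(np.clip(expit(lrho), _RHO_MIN, _RHO_MAX))


def _fit_multi_component(k, n, maf, weights, init=(0.97, 0.05)):
    # the collapsed component's scaled-het level is ~1 in theory (every minor
    # copy surfaces in a spurious heterozygote); bounding it away from the
    # inbred single-copy line prevents component collapse
    s, rho = init
    x0 = np.array(
        [logit(np.clip(s, 0.51, 1 - _S_EPS)), logit(np.clip(rho, _RHO_MIN, _RHO_MAX))]
    )
    res = minimize(
        lambda t: -_component_loglik_multi(t, k, n, maf, weights),
        x0,
        method="L-BFGS-B",
        bounds=[(logit(0.5), logit(1 - _S_EPS)), (logit(_RHO_MIN), logit(_RHO_MAX))],
    )
    ls, lrho = res.x
    return float(expit(ls)), float(np.clip(expit(lrho), _RHO_MIN, _RHO_MAX))


def _log_densities(summ, b0, b1, rho_k, s_d, rho_d):
    maf = summ.maf
    k, n = summ.n_het, summ.n_minor
    mu_k = np.clip(b0 + b1 * (1.0 - maf), _S_EPS, 1.0 - _S_EPS)
    mu_d = np.clip(np.full_like(mu_k, s_d), _S_EPS, 1.0 - _S_EPS)
    a_k, b_k = _rho_to_ab(mu_k, rho_k)
    a_d, b_d = _rho_to_ab(mu_d, rho_d)
    log_fk = betabinom.logpmf(k, n, a_k, b_k)
    log_fd = betabinom.logpmf(k, n, a_d, b_d)
    return log_fk, log_fd


def fit_em(
    summaries: SiteSummaries,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int | None = None,
    min_snps: int = 500,
) -> MixtureFit:
    """Fit the two-component mixture by Expectation-Maximization.

    Alternates weight recalibration (E) with weighted maximization of each
    component's beta-binomial regression (M) until the total log-likelihood
    changes by less than ``tol`` or ``max_iter`` is reached.  The implied
    inbreeding estimate is recovered from the single-copy mean relationship
    at ``maf -> 0``: ``fis_hat = 1 - (b0 + b1)``.

    ``seed`` is accepted for interface stability; the procedure is fully
    deterministic given the input order.
    """
    del seed
    w = initialize_weights(summaries, min_snps=min_snps)
    # observation: n_het spurious/true heterozygotes out of the site's
    # minor-allele copy count; the mean is the scaled heterozygote frequency
    k, n, maf = summaries.n_het, summaries.n_minor, summaries.maf
    # sites with < 3 minor copies are parity-degenerate (a single minor copy
    # is always heterozygous) and carry no usable signal: exclude from the
    # likelihood; they are classified UNCERTAIN at this step
    include = (n >= _MIN_MINOR_COPIES).astype(float)

    b0, b1, rho_k = 0.0, 1.0, 0.01
    s_d, rho_d = 0.97, 0.05
    pi = float(np.mean(w))
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # M-step: maximize each component's weighted log-likelihood
        b0, b1, rho_k = fit_weighted_single_component(
            k, n, maf, (1.0 - w) * include, init=(b0, b1, rho_k)
        )
        s_d, rho_d = _fit_multi_component(k, n, maf, w * include, init=(s_d, rho_d))
        pi = float(np.clip(np.average(w, weights=include), 1e-6, 1 - 1e-6))

        # E-step: recalibrate weights from component densities
        log_fk, log_fd = _log_densities(summaries, b0, b1, rho_k, s_d, rho_d)
        log_num = np.log(pi) + log_fd
        log_den = np.logaddexp(np.log(1 - pi) + log_fk, log_num)
        w = np.exp(log_num - log_den)
        ll = float(np.sum(log_den * include))
        if not np.isfinite(ll):
            raise FitError(f"non-finite mixture log-likelihood at iteration {it}")
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)

    log_fk, log_fd = _log_densities(summaries, b0, b1, rho_k, s_d, rho_d)
    fis_hat = float(np.clip(1.0 - (b0 + b1), -1.0, 1.0))
    return MixtureFit(
        intercept_multi=s_d,
        intercept_single=b0,
        slope_single=b1,
        overdispersion=(rho_k, rho_d),
        weights=w,
        loglik_trace=np.array(trace),
        converged=converged,
        n_iter=it,
        fis_hat=fis_hat,
        mixing=pi,
        log_f_single=log_fk,
        log_f_multi=log_fd,
        summaries=summaries,
    )


class Classifications:
    """Per-SNP labels with log-likelihood ratios and the assigning step."""

    def __init__(self, chrom, pos, maf, het_fraction, label, llr, step, site_index):
        self.chrom = np.asarray(chrom)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.maf = np.asarray(maf, dtype=float)
        self.het_fraction = np.asarray(het_fraction, dtype=float)
        self.label = np.asarray(label, dtype="U9")
        self.llr = np.asarray(llr, dtype=float)
        self.step = np.asarray(step, dtype="U7")
        self.site_index = np.asarray(site_index, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.label)

    def copy(self) -> "Classifications":
        return Classifications(
            self.chrom.copy(),
            self.pos.copy(),
            self.maf.copy(),
            self.het_fraction.copy(),
            self.label.copy(),
            self.llr.copy(),
            self.step.copy(),
            self.site_index.copy(),
        )

    def counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.label, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "maf": self.maf,
                "f_het": self.het_fraction,
                "label": self.label,
                "llr": self.llr,
                "assigning_step": self.step,
            }
        )


def classify_by_llr(
    fit: MixtureFit, thresholds: tuple[float, float] = (-2.0, 3.0)
) -> Classifications:
    """Classify SNPs from the mixture fit's per-SNP log-likelihood ratios.

    ``llr = log f_multi - log f_single``; values above the upper threshold
    are MULTI, below the lower threshold SINGLE, in between (and exactly at
    a threshold) UNCERTAIN.
    """
    lower, upper = thresholds
    if lower > upper:
        raise ValueError(f"lower threshold {lower} exceeds upper {upper}")
    llr = fit.log_f_multi - fit.log_f_single
    label = np.full(len(llr), UNCERTAIN, dtype="U9")
    s = fit.summaries
    # excess heterozygosity is one-sided: a SNP whose scaled heterozygote
    # frequency lies below the fitted single-copy line cannot be promoted to
    # MULTI, however the overdispersed multicopy density ranks it
    single_line = fit.intercept_single + fit.slope_single * (1.0 - s.maf)
    informative = s.n_minor >= _MIN_MINOR_COPIES
    label[(llr > upper) & (s.scaled_het >= single_line) & informative] = MULTI
    label[(llr < lower) & informative] = SINGLE
    s = fit.summaries
    return Classifications(
        chrom=s.chrom,
        pos=s.pos,
        maf=s.maf,
        het_fraction=s.het_fraction,
        label=label,
        llr=llr,
        step=np.full(len(llr), STEP_EM, dtype="U7"),
        site_index=s.site_index,
    )
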