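"""The beta-binomial EM mixture: summaries, densities, fitting, classification."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom

from collapsemask import (
    FilterConfig,
    SimParams,
    apply_filters,
    beta_binomial_density,
    classify_by_llr,
    fit_em,
    initialize_weights,
    simulate_cohort,
    summarize_sites,
)
from collapsemask.em_classifier import (
    MULTI,
    SINGLE,
    UNCERTAIN,
    SiteSummaries,
    fit_weighted_single_component,
)
from collapsemask.errors import DataError
from collapsemask.vcf_io import HET, HOM_ALT, HOM_REF, SiteTable
from tests.conftest import SIM_FILTER


def table_from_genotypes(gt):
    """Wrap a genotype matrix in a SiteTable with constant depth/quality."""
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_ind = gt.shape
    ones = np.full_like(gt, 10, dtype=np.int32)
    return SiteTable(
        chrom=np.full(n_sites, "c"),
        pos=np.arange(1, n_sites + 1) * 100,
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "G"),
        gt=gt,
        ad_ref=ones // 2,
        ad_alt=ones // 2,
        dp=ones,
        gq=np.full_like(gt, 99, dtype=np.int32),
        samples=[f"s{i}" for i in range(n_ind)],
    )


class TestSummaries:
    def test_worked_example(self):
        """5 HOM_REF + 4 HET + 1 HOM_ALT diploids: maf 0.3, scaled_het 2/3."""
        gt = [[HOM_REF] * 5 + [HET] * 4 + [HOM_ALT]]
        s = summarize_sites(table_from_genotypes(gt))
        assert s.maf[0] == pytest.approx(0.3)
        assert s.het_fraction[0] == pytest.approx(0.4)
        assert s.scaled_het[0] == pytest.approx(0.4 / 0.6)
        assert s.n_minor[0] == 6

    def test_all_het_site_is_upper_bound(self):
        gt = [[HET] * 8]
        s = summarize_sites(table_from_genotypes(gt))
        assert s.maf[0] == pytest.approx(0.5)
        assert s.scaled_het[0] == pytest.approx(1.0)

    def test_monomorphic_sites_dropped(self):
        gt = [[HOM_REF] * 6, [HET] * 3 + [HOM_REF] * 3]
        s = summarize_sites(table_from_genotypes(gt))
        assert s.n_snps == 1

    def test_scaled_het_bounded_on_random_tables(self):
        """scaled_het stays in [0, 1] over 10,000 random genotype draws."""
        rng = np.random.default_rng(7)
        gt = rng.integers(0, 3, size=(10_000, 20)).astype(np.int8)
        gt[rng.random(gt.shape) < 0.05] = -1
        s = summarize_sites(table_from_genotypes(gt))
        assert np.all(s.scaled_het >= 0)
        assert np.all(s.scaled_het <= 1 + 1e-12)
        # identity maf = (n_het + 2 n_hom_minor) / (2 n_called)
        assert np.allclose(s.maf, s.n_minor / (2 * s.n_called))


class TestBetaBinomialDensity:
    def test_binomial_limit(self):
        assert beta_binomial_density(1, 2, 0.5, 0.0) == pytest.approx(0.5)

    def test_normalization(self):
        total = sum(beta_binomial_density(k, 20, 0.3, 0.2) for k in range(21))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "k,n,mu,rho", [(3, 10, 0.4, 0.15), (0, 7, 0.2, 0.05), (12, 15, 0.8, 0.3)]
    )
    def test_matches_quadrature_oracle(self, k, n, mu, rho):
        """Density equals the integral of Binomial(n,p) over the implied Beta."""
        a = mu * (1 - rho) / rho
        b = (1 - mu) * (1 - rho) / rho
        from scipy.stats import beta as beta_dist

        oracle, _ = quad(
            lambda p: binom.pmf(k, n, p) * beta_dist.pdf(p, a, b), 0, 1,
            epsabs=1e-12, limit=200,
        )
        assert beta_binomial_density(k, n, mu, rho) == pytest.approx(oracle, abs=1e-8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            beta_binomial_density(3, 2, 0.5, 0.1)
        with pytest.raises(ValueError):
            beta_binomial_density(1, 2, 1.5, 0.1)
        with pytest.raises(ValueError):
            beta_binomial_density(1, 2, 0.5, 1.0)


def synthetic_summaries(rng, n=200, fis=0.0):
    """Summaries drawn from the single-copy model, for fitter tests."""
    maf = rng.uniform(0.02, 0.5, n)
    m = np.maximum((maf * 80).astype(int) * 2, 3)
    s = np.clip((1 - fis) * (1 - maf), 0.01, 0.99)
    k = rng.binomial(m, s)
    return SiteSummaries(
        chrom=np.full(n, "c"), pos=np.arange(n) * 10 + 1, maf=maf,
        n_called=np.full(n, 40), n_het=k, n_hom_minor=(m - k) // 2,
        het_fraction=k / 40, scaled_het=k / m,
        mean_depth_het=np.full(n, 10.0), mean_depth_hom=np.full(n, 10.0),
        site_index=np.arange(n),
    )


class TestWeightInitialization:
    def test_extremes_map_to_correct_side(self, small_cohort):
        _, table, _ = small_cohort
        s = summarize_sites(table)
        w = initialize_weights(s)
        assert np.all((w >= 0.05) & (w <= 0.95))
        at_line = s.scaled_het >= 0.999
        assert np.all(w[at_line] > 0.5)
        at_zero = s.scaled_het <= 1e-9
        if at_zero.any():
            assert np.all(w[at_zero] < 0.5)
        assert len(np.unique(w)) > 1

    def test_determinism(self, small_cohort):
        _, table, _ = small_cohort
        s = summarize_sites(table)
        assert np.array_equal(initialize_weights(s), initialize_weights(s))

    def test_too_few_snps_is_hard_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DataError, match="500"):
            initialize_weights(synthetic_summaries(rng, n=50))


class TestWeightedComponentFit:
    def test_matches_grid_search_oracle(self):
        """The quasi-Newton weighted fit agrees with grid-search ML to 1e-3.

        Binomially generated data (rho ~ 0), 200 SNPs, non-trivial weights.
        """
        rng = np.random.default_rng(3)
        s = synthetic_summaries(rng, n=200, fis=0.4)
        w = rng.uniform(0.3, 1.0, 200)
        b0, b1, rho = fit_weighted_single_component(
            s.n_het, s.n_minor, s.maf, w
        )
        assert rho < 0.01

        def ll(t0, t1):
            mu = np.clip(t0 + t1 * (1 - s.maf), 1e-4, 1 - 1e-4)
            return np.sum(w * binom.logpmf(s.n_het, s.n_minor, mu))

        g0, g1 = 0.0, 1.0
        span = 0.4
        for _ in range(6):  # coarse-to-fine grid refinement
            c0 = np.linspace(g0 - span, g0 + span, 21)
            c1 = np.linspace(g1 - span, g1 + span, 21)
            vals = np.array([[ll(a, b) for b in c1] for a in c0])
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            g0, g1 = c0[i], c1[j]
            span /= 8
        assert b0 == pytest.approx(g0, abs=1e-3)
        assert b1 == pytest.approx(g1, abs=1e-3)


class TestFitEM:
    def test_loglik_monotone_and_converged(self, small_pipeline):
        _, _, _, result = small_pipeline
        trace = result.fit.loglik_trace
        assert np.all(np.diff(trace) >= -1e-6)
        assert np.all(result.fit.weights >= 0) and np.all(result.fit.weights <= 1)
        assert -1 <= result.fit.fis_hat <= 1

    def test_random_mating_no_duplications(self):
        """F_IS = 0, no duplications: fis_hat ~ 0 and no confident multicopy calls."""
        sim = simulate_cohort(
            SimParams(n_ind=100, dup_fraction=0.0, genome_length=400_000, seed=21)
        )
        table = apply_filters(sim.table, SIM_FILTER)
        fit = fit_em(summarize_sites(table))
        assert abs(fit.fis_hat) <= 0.05
        cls = classify_by_llr(fit)
        assert (cls.label == MULTI).mean() < 0.02

    def test_label_order_invariance(self, small_cohort):
        """Classification is invariant under permutation of SNP input order."""
        _, table, _ = small_cohort
        s = summarize_sites(table)
        fit = fit_em(s)
        labels = classify_by_llr(fit).label

        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_sites)
        shuffled = table.subset(perm)
        order = np.argsort(shuffled.pos)  # summaries don't require sorting
        s2 = summarize_sites(shuffled)
        fit2 = fit_em(s2)
        labels2 = classify_by_llr(fit2).label
        # map back through positions
        back = {p: l for p, l in zip(s2.pos, labels2)}
        assert [back[p] for p in s.pos] == labels.tolist()


class TestClassifyByLLR:
    def test_llr_zero_with_symmetric_thresholds_is_uncertain(self, small_cohort):
        _, table, _ = small_cohort
        fit = fit_em(summarize_sites(table))
        cls = classify_by_llr(fit, thresholds=(-2.0, 2.0))
        mid = np.abs(cls.llr) < 1e-9
        if mid.any():
            assert np.all(cls.label[mid] == UNCERTAIN)
        # label/llr contract
        assert np.all(cls.llr[cls.label == MULTI] >= 2.0)
        assert np.all(cls.llr[cls.label == SINGLE] <= -2.0)

    def test_raising_upper_threshold_never_increases_multi(self, small_cohort):
        _, table, _ = small_cohort
        fit = fit_em(summarize_sites(table))
        counts = [
            (classify_by_llr(fit, thresholds=(-2.0, u)).label == MULTI).sum()
            for u in (1.0, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_thresholds(self, small_cohort):
        _, table, _ = small_cohort
        fit = fit_em(summarize_sites(table))
        with pytest.raises(ValueError):
            classify_by_llr(fit, thresholds=(2.0, -2.0))


def test_uncertainty_concentrates_at_low_maf(small_pipeline):
    """The fraction of EM-uncertain SNPs decreases with minor allele frequency."""
    _, table, _, result = small_pipeline
    cls = result.em_classifications
    bins = [0.0, 0.05, 0.15, 0.3, 0.5]
    fracs = []
    for lo, hi in zip(bins, bins[1:]):
        m = (cls.maf > lo) & (cls.maf <= hi)
        if m.sum() >= 20:
            fracs.append((cls.label[m] == UNCERTAIN).mean())
    assert all(a >= b - 0.02 for a, b in zip(fracs, fracs[1:]))
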