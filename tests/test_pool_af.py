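"""Pooled AF estimation: theta, grid posterior, fixation rules, AAF_ind."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import digamma

import swardpop as sp
from swardpop.pool_af import _prior_log


def oracle_posterior(ref, alt, theta, eps, n):
    """Independent brute-force grid posterior: explicit binomial pmf loop."""
    a_n = digamma(n) + np.euler_gamma  # harmonic number H_{n-1}
    f = np.arange(n + 1) / n
    raw = np.zeros(n + 1)
    raw[1:n] = 1.0 / f[1:n] + 1.0 / (1.0 - f[1:n])
    interior = max(min(1.0, theta * a_n), 1e-12)
    prior = np.zeros(n + 1)
    prior[1:n] = raw[1:n] / raw[1:n].sum() * interior
    prior[0] = prior[n] = (1.0 - interior) / 2.0
    q = f * (1 - eps) + (1 - f) * eps
    like = np.array(
        [stats.binom.pmf(alt, ref + alt, qi) for qi in q]
    )
    post = prior * like
    post /= post.sum()
    return float((f * post).sum()), float(post[0]), float(post[n])


class TestTheta:
    def test_monomorphic_sample_gives_zero(self, toy_counts):
        loci = [sp.Locus("chr1", i + 1, "A", "G") for i in range(5)]
        counts = sp.AlleleCountMatrix(
            loci=loci, samples=["s"],
            ref_count=np.full((5, 1), 100), alt_count=np.zeros((5, 1), int),
        )
        est = sp.estimate_theta(counts, "s")
        assert est.theta == 0.0
        assert est.n_segregating == 0

    def test_closed_form_matches_harmonic_oracle(self):
        """10 segregating of 1000 assessed sites, pool of 40 plants."""
        rng = np.random.default_rng(0)
        loci = [sp.Locus("chr1", i + 1, "A", "G") for i in range(1000)]
        ref = np.full((1000, 1), 100)
        alt = np.zeros((1000, 1), int)
        alt[:10] = 50  # 10 clearly segregating sites
        counts = sp.AlleleCountMatrix(
            loci=loci, samples=["s"], ref_count=ref, alt_count=alt
        )
        est = sp.estimate_theta(counts, "s", mac=3, min_depth=30, pool_size=40)
        a_80 = digamma(80) + np.euler_gamma  # independent harmonic sum
        assert a_80 == pytest.approx(4.952979, abs=1e-6)
        assert est.theta == pytest.approx(10 / (1000 * a_80), rel=1e-12)

    def test_theta_decreases_with_mac_on_noisy_data(self):
        """Raising the minor-allele-count threshold prunes error-driven sites."""
        rng = np.random.default_rng(1)
        L = 2000
        loci = [sp.Locus("chr1", i + 1, "A", "G") for i in range(L)]
        depth = rng.poisson(100, size=(L, 1))
        alt = rng.binomial(depth, 0.01)  # error-like low-frequency reads
        counts = sp.AlleleCountMatrix(
            loci=loci, samples=["s"], ref_count=depth - alt, alt_count=alt
        )
        thetas = [
            sp.estimate_theta(counts, "s", mac=m).theta for m in (2, 3, 4, 6)
        ]
        assert all(a >= b for a, b in zip(thetas, thetas[1:]))
        assert thetas[0] > thetas[-1]

    def test_no_assessable_sites_is_an_error(self):
        loci = [sp.Locus("chr1", 1, "A", "G")]
        counts = sp.AlleleCountMatrix(
            loci=loci, samples=["s"],
            ref_count=np.array([[5]]), alt_count=np.array([[5]]),
        )
        with pytest.raises(sp.ValidationError, match="assessable"):
            sp.estimate_theta(counts, "s", min_depth=30)


class TestPosterior:
    @pytest.mark.parametrize(
        "ref,alt,theta,eps",
        [(60, 0, 0.01, 0.001), (30, 30, 0.01, 0.001), (90, 10, 0.02, 0.005),
         (5, 45, 0.005, 0.001), (100, 1, 0.01, 0.01)],
    )
    def test_matches_bruteforce_oracle(self, ref, alt, theta, eps):
        got = sp.posterior_af(ref, alt, theta, eps, pool_chromosomes=80)
        exp_mean, exp_p0, exp_p1 = oracle_posterior(ref, alt, theta, eps, 80)
        assert got.aaf_estimate == pytest.approx(exp_mean, abs=1e-9)
        assert got.p0 == pytest.approx(exp_p0, abs=1e-9)
        assert got.p1 == pytest.approx(exp_p1, abs=1e-9)

    def test_balanced_counts_estimate_half(self):
        got = sp.posterior_af(30, 30, 0.01, 0.001, pool_chromosomes=80)
        assert abs(got.aaf_estimate - 0.5) < 0.01

    def test_all_reference_reads_fix_at_zero(self):
        got = sp.posterior_af(60, 0, 0.01, 0.001, pool_chromosomes=80)
        assert got.p0 > 0.9
        assert got.aaf_estimate < 0.01

    def test_posterior_mean_approaches_read_fraction_at_depth(self):
        got = sp.posterior_af(30_000, 10_000, 0.01, 1e-6,
                              pool_chromosomes=80)
        assert got.aaf_estimate == pytest.approx(0.25, abs=0.01)

    def test_prior_sums_to_one(self):
        for theta in (0.0, 0.005, 0.05, 1.0):
            prior = np.exp(_prior_log(theta, 80))
            assert prior.sum() == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        ref=st.integers(0, 200),
        alt=st.integers(0, 200),
        theta=st.floats(1e-4, 0.5),
    )
    def test_ref_alt_swap_symmetry(self, ref, alt, theta):
        """Folded prior: swapping counts mirrors the estimate and p0/p1."""
        if ref + alt == 0:
            return
        a = sp.posterior_af(ref, alt, theta, 0.001, pool_chromosomes=80)
        b = sp.posterior_af(alt, ref, theta, 0.001, pool_chromosomes=80)
        assert a.aaf_estimate == pytest.approx(1 - b.aaf_estimate, abs=1e-9)
        assert a.p0 == pytest.approx(b.p1, abs=1e-9)
        assert a.p1 == pytest.approx(b.p0, abs=1e-9)

    def test_error_rate_half_or_more_rejected(self):
        with pytest.raises(sp.ConfigError):
            sp.posterior_af(10, 10, 0.01, 0.5)

    def test_matrix_variant_agrees_with_scalar(self, toy_counts):
        aaf, p0, p1 = sp.posterior_af_matrix(
            toy_counts, 0.01, error_rate=0.001, pool_chromosomes=80
        )
        for i in range(toy_counts.n_loci):
            for j in range(toy_counts.n_samples):
                one = sp.posterior_af(
                    int(toy_counts.ref_count[i, j]),
                    int(toy_counts.alt_count[i, j]),
                    0.01, 0.001, pool_chromosomes=80,
                )
                assert aaf[i, j] == pytest.approx(one.aaf_estimate, abs=1e-12)
                assert p0[i, j] == pytest.approx(one.p0, abs=1e-12)


class TestFixationRules:
    def test_zero_rule_fires_on_high_p0(self):
        post = sp.PosteriorSummary(aaf_estimate=0.02, p0=0.95, p1=0.0, depth=60)
        assert sp.apply_fixation_rules(post) == 0.0

    def test_one_rule_fires_on_high_p1(self):
        post = sp.PosteriorSummary(aaf_estimate=0.98, p0=0.01, p1=0.95, depth=60)
        assert sp.apply_fixation_rules(post) == 1.0

    def test_interior_estimate_passes_through(self):
        post = sp.PosteriorSummary(aaf_estimate=0.42, p0=0.05, p1=0.05, depth=60)
        assert sp.apply_fixation_rules(post) == 0.42

    def test_zero_rule_literal_asymmetry(self):
        """The zero rule fires whenever p0 > 0.1, not only when p0 > 0.9."""
        post = sp.PosteriorSummary(aaf_estimate=0.1, p0=0.2, p1=0.0, depth=60)
        assert sp.apply_fixation_rules(post) == 0.0


class TestAAFInd:
    def test_dose_formula_as_printed(self):
        loci = [sp.Locus("chr1", 1, "A", "G")]
        calls = np.array([[0] * 25 + [1] * 10 + [2] * 5])
        gm = sp.GenotypeMatrix(
            loci=loci, individuals=[f"p{i}" for i in range(40)], calls=calls
        )
        assert sp.aaf_from_genotypes(gm, 0) == pytest.approx(0.25)

    def test_all_homalt_gives_one(self):
        loci = [sp.Locus("chr1", 1, "A", "G")]
        gm = sp.GenotypeMatrix(
            loci=loci, individuals=[f"p{i}" for i in range(40)],
            calls=np.full((1, 40), 2),
        )
        assert sp.aaf_from_genotypes(gm, 0) == 1.0

    def test_missing_calls_drop_from_both_sides(self):
        """Oracle: enumerate doses by hand for 39 called homref + 1 missing."""
        loci = [sp.Locus("chr1", 1, "A", "G")]
        calls = np.array([[0] * 39 + [sp.MISSING_CALL]])
        gm = sp.GenotypeMatrix(
            loci=loci, individuals=[f"p{i}" for i in range(40)], calls=calls
        )
        doses = [c for c in calls[0] if c != sp.MISSING_CALL]
        assert sp.aaf_from_genotypes(gm, 0) == sum(doses) / (2 * len(doses))
        assert sp.aaf_from_genotypes(gm, 0) == 0.0

    def test_all_missing_gives_nan(self):
        loci = [sp.Locus("chr1", 1, "A", "G")]
        gm = sp.GenotypeMatrix(
            loci=loci, individuals=["a", "b"],
            calls=np.full((1, 2), sp.MISSING_CALL),
        )
        assert np.isnan(sp.aaf_from_genotypes(gm, 0))
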