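"""The four-state mixture: densities, E/M steps, likelihood, EM fitting."""

import numpy as np
import pytest
from scipy.integrate import quad

from gpamds import (DegenerateDataError, GPAModel, GPAParams, ValidationError,
                    beta_density, fit_two_group, simulate_study)
from gpamds.simulate import (PhenotypeSpec, SharingSpec, SimulationDesign)


class TestBetaDensity:
    def test_uniform_limit(self):
        # alpha -> 1 recovers the Uniform(0,1) density
        p = np.array([0.05, 0.3, 0.7, 0.99])
        np.testing.assert_allclose(beta_density(p, 1 - 1e-6), 1.0, atol=1e-4)

    def test_known_value(self):
        # 0.4 * 0.01**(-0.6), evaluated with 50-digit arithmetic
        assert beta_density(0.01, 0.4) == pytest.approx(6.3395727698444536,
                                                        rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.9])
    def test_integrates_to_one(self, alpha):
        total, _ = quad(lambda p: beta_density(p, alpha), 0, 1)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_monotone_decreasing(self):
        p = np.linspace(0.01, 1, 50)
        d = beta_density(p, 0.4)
        assert np.all(np.diff(d) < 0)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, 1.2, -0.5])
    def test_shape_domain_error(self, alpha):
        with pytest.raises(ValueError):
            beta_density(0.5, alpha)


def _toy_model(pvals):
    return GPAModel(np.asarray(pvals, dtype=float))


class TestESteps:
    def test_symmetric_params_give_uniform_posteriors(self):
        model = _toy_model([[0.1, 0.9], [0.5, 0.5], [0.99, 0.01]])
        params = GPAParams(0.25, 0.25, 0.25, 0.25, 1 - 1e-6, 1 - 1e-6)
        post = model.e_step(params)
        np.testing.assert_allclose(post, 0.25, atol=1e-4)

    def test_concentrates_on_pheno1_states_for_tiny_p1(self):
        model = _toy_model([[1e-8, 0.5]])
        params = GPAParams(0.25, 0.25, 0.25, 0.25, 0.4, 0.4)
        post = model.e_step(params)[0]
        assert post[1] + post[3] > 0.99
        # direct Bayes computation on the single SNP
        f1 = beta_density(1e-8, 0.4)
        f2 = beta_density(0.5, 0.4)
        weights = np.array([1.0, f1, f2, f1 * f2]) * 0.25
        np.testing.assert_allclose(post, weights / weights.sum(), rtol=1e-9)

    def test_rows_sum_to_one_random_inputs(self):
        rng = np.random.default_rng(3)
        model = _toy_model(rng.uniform(size=(200, 2)))
        params = GPAParams(0.6, 0.15, 0.15, 0.1, 0.3, 0.7)
        post = model.e_step(params)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        assert post.min() >= 0


class TestMStep:
    def test_uniform_posteriors_give_equal_proportions(self):
        model = _toy_model([[0.2, 0.4], [0.6, 0.8], [0.1, 0.3], [0.5, 0.7]])
        post = np.full((4, 4), 0.25)
        params = model.m_step(post)
        np.testing.assert_allclose(params.pis, 0.25, atol=1e-12)

    def test_alpha_matches_analytic_beta_mle(self):
        # responsibility 1 on state 10 with P1 = e^-2 -> alpha1 = 1/2;
        # responsibility 1 on state 01 with P2 = e^-4 -> alpha2 = 1/4
        model = _toy_model([[np.exp(-2.0), 0.5], [0.5, np.exp(-4.0)]])
        post = np.array([[0.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
        params = model.m_step(post)
        assert params.alpha1 == pytest.approx(0.5, rel=1e-10)
        assert params.alpha2 == pytest.approx(0.25, rel=1e-10)

    def test_alpha_clipped_below_one(self):
        # all mass near p = 0.9 makes the unconstrained MLE exceed 1
        model = _toy_model([[0.9, 0.9], [0.9, 0.9]])
        post = np.array([[0.0, 0.5, 0.0, 0.5]] * 2)
        params = model.m_step(post)
        assert params.alpha1 == pytest.approx(1 - 1e-6)

    def test_weighted_alpha_update_general(self):
        # alpha_k = -sum w / sum w log p on hand-built responsibility vectors
        p1 = np.array([0.01, 0.2, 0.5, 0.9])
        p2 = np.array([0.05, 0.4, 0.6, 0.3])
        model = _toy_model(np.column_stack([p1, p2]))
        w1 = np.array([0.5, 0.3, 0.1, 0.05])   # states 10 (+ none on 11)
        w2 = np.array([0.2, 0.4, 0.3, 0.15])   # states 01
        post = np.zeros((4, 4))
        post[:, 1] = w1
        post[:, 2] = w2
        post[:, 0] = 1 - w1 - w2
        params = model.m_step(post)
        assert params.alpha1 == pytest.approx(-w1.sum() / (w1 @ np.log(p1)),
                                              rel=1e-10)
        assert params.alpha2 == pytest.approx(-w2.sum() / (w2 @ np.log(p2)),
                                              rel=1e-10)

    def test_degenerate_responsibilities_raise(self):
        model = _toy_model([[0.3, 0.3], [0.7, 0.7]])
        post = np.array([[1.0, 0.0, 0.0, 0.0]] * 2)  # no mass on pheno1 states
        with pytest.raises(DegenerateDataError):
            model.m_step(post)


class TestLogLikelihood:
    def test_pure_null_model_has_zero_loglik(self):
        rng = np.random.default_rng(0)
        model = _toy_model(rng.uniform(size=(50, 2)))
        params = GPAParams(1.0, 0.0, 0.0, 0.0, 0.5, 0.5)
        assert model.loglike(params) == pytest.approx(0.0, abs=1e-8)

    def test_matches_term_by_term_sum_on_toy_data(self):
        pv = np.array([[0.01, 0.5], [0.2, 0.03], [0.9, 0.8]])
        params = GPAParams(0.5, 0.2, 0.2, 0.1, 0.4, 0.6)
        model = _toy_model(pv)
        expected = 0.0
        for p1, p2 in pv:
            f1 = beta_density(p1, 0.4)
            f2 = beta_density(p2, 0.6)
            expected += np.log(0.5 + 0.2 * f1 + 0.2 * f2 + 0.1 * f1 * f2)
        assert model.loglike(params) == pytest.approx(expected, rel=1e-10)


class TestFitGPA:
    def test_pure_null_data_yields_no_signal(self):
        """On Uniform-only data the fit is likelihood-equivalent to the
        all-null model and declares no associations.

        pi00 itself is not identifiable here: a Beta component with shape
        near 1 mimics the Uniform, so EM stops on a likelihood ridge.  The
        identifiable facts are that the fitted density is essentially
        Uniform (no likelihood gain, vanishing non-null signal mass) and
        that FDR-controlled selection comes back empty."""
        rng = np.random.default_rng(77)
        model = _toy_model(rng.uniform(size=(10_000, 2)))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            res = model.fit(max_iter=20_000)
        p = res.params
        assert res.llf / model.nobs < 1e-3           # no real likelihood gain
        # non-null signal mass q(1-alpha) of each fitted margin is within the
        # O(1/sqrt(M)) density-fluctuation scale of Uniform data
        assert p.marg1 * (1 - p.alpha1) < 0.02
        assert p.marg2 * (1 - p.alpha2) < 0.02
        for target in ("pheno1", "pheno2", "both"):
            assert res.select_snps(tau=0.1, target=target).n_selected < 5

    def test_loglik_trace_monotone(self, pair12_fits):
        res, res0 = pair12_fits
        for r in (res, res0):
            assert np.all(np.diff(r.loglik_trace) >= -1e-8)
            assert r.llf == r.loglik_trace[-1]

    def test_constrained_satisfies_independence_exactly(self, pair12_fits):
        _, res0 = pair12_fits
        p = res0.params
        assert p.pi11 - p.marg1 * p.marg2 == pytest.approx(0.0, abs=1e-15)

    def test_constrained_loglik_below_unconstrained(self, pair12_fits):
        res, res0 = pair12_fits
        assert res0.llf <= res.llf + 1e-6

    def test_benchmark_recovery_of_beta_shape(self, pair12_fits):
        res, _ = pair12_fits
        assert res.params.alpha1 == pytest.approx(0.4, abs=0.05)
        assert res.params.alpha2 == pytest.approx(0.4, abs=0.05)

    @pytest.mark.parametrize("truth", [
        GPAParams(0.75, 0.05, 0.05, 0.15, 0.40, 0.40),
        GPAParams(0.64, 0.16, 0.16, 0.04, 0.25, 0.30),
        GPAParams(0.60, 0.15, 0.15, 0.10, 0.30, 0.45),
    ])
    def test_parameter_recovery_from_known_truth(self, truth):
        """EM recovers generating proportions within 0.03 and shapes within
        0.05 at M = 10,000 (block-design simulation matching the truth)."""
        r1, r2 = truth.marg1, truth.marg2
        design = SimulationDesign(
            n_snps=10_000,
            phenotypes=(PhenotypeSpec("p1", r1, truth.alpha1),
                        PhenotypeSpec("p2", r2, truth.alpha2)),
            sharing=(SharingSpec(("p1", "p2"),
                                 truth.pi11 / min(r1, r2)),),
            seed=42,
        )
        res = GPAModel.from_matrix(simulate_study(design).matrix).fit()
        np.testing.assert_allclose(res.params.pis, truth.pis, atol=0.03)
        assert res.params.alpha1 == pytest.approx(truth.alpha1, abs=0.05)
        assert res.params.alpha2 == pytest.approx(truth.alpha2, abs=0.05)

    def test_posterior_means_match_proportions_at_fixed_point(self):
        """At convergence the posterior column means equal the estimated
        mixing proportions (EM fixed point)."""
        study = simulate_study(five_phenotype_design_small())
        model = GPAModel.from_matrix(study.matrix, cols=(0, 1))
        res = model.fit(tol=0.0, atol=1e-13, max_iter=100_000)
        np.testing.assert_allclose(res.posteriors.mean(axis=0),
                                   res.params.pis, atol=1e-6)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValidationError):
            _toy_model([[0.5, 0.5]] * 5).fit()

    def test_non_convergence_warns_not_raises(self):
        rng = np.random.default_rng(1)
        model = _toy_model(rng.uniform(size=(500, 2)))
        with pytest.warns(UserWarning, match="did not converge"):
            res = model.fit(max_iter=3, atol=0.0, tol=0.0)
        assert not res.converged

    def test_multi_start_reaches_at_least_default_likelihood(self):
        study = simulate_study(five_phenotype_design_small())
        model = GPAModel.from_matrix(study.matrix, cols=(0, 1))
        single = model.fit()
        multi = model.fit(n_starts=3, seed=0)
        assert multi.llf >= single.llf - 1e-6


def five_phenotype_design_small():
    from gpamds import five_phenotype_design
    return five_phenotype_design(n_snps=2000, seed=5)


class TestTwoGroupModel:
    def test_recovers_marginal_mixture(self):
        rng = np.random.default_rng(9)
        m = 10_000
        p = rng.uniform(size=m)
        risk = rng.uniform(size=m) < 0.2
        p[risk] = rng.beta(0.4, 1.0, size=int(risk.sum()))
        fit = fit_two_group(p)
        assert fit.q == pytest.approx(0.2, abs=0.03)
        assert fit.alpha == pytest.approx(0.4, abs=0.05)
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_summary_mentions_key_quantities(self, pair12_fits):
        res, _ = pair12_fits
        text = res.summary()
        for token in ("pi11", "alpha1", "Log-likelihood", "converged"):
            assert token in text
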