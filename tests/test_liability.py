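"""Liability model: link functions, odds-ratio quadrature, line search,
importance sampling, and the joint liability predictor."""

import numpy as np
import pytest
from scipy.special import expit

from famprs.liability import (
    BracketError,
    DiseaseTrioObservation,
    estimate_beta_line_search,
    disease_probability,
    liability_predictor_weights,
    liability_scale_effect,
    parent_reference_covariates,
    predict_liability,
    predict_liability_frame,
    sample_parent_liability,
    theoretical_parent_child_or,
)
from famprs.params import BinaryParams, ParameterError


def posterior_mean_by_quadrature(z: int, params: BinaryParams, q=None) -> float:
    """Independent oracle: trapezoid quadrature of the unnormalized posterior
    f(H|Z) on [-8*sigma, 8*sigma] with 20001 nodes."""
    sigma = np.sqrt(params.h2)
    h = np.linspace(-8 * sigma, 8 * sigma, 20001)
    eta = params.linear_predictor(h, q)
    lik = expit(eta) if z == 1 else expit(-eta)
    post = lik * np.exp(-(h**2) / (2 * params.h2))
    return float(np.trapezoid(post * h, h) / np.trapezoid(post, h))


class TestDiseaseProbability:
    def test_logit_zero_is_half(self):
        params = BinaryParams(mu0=0.0, alpha=0.1, beta=0.1)
        assert disease_probability(0.0, None, params) == pytest.approx(0.5)

    def test_baseline_and_liability_cancel(self):
        params = BinaryParams(mu0=-3.0, alpha=0.1, beta=0.1)
        assert disease_probability(3.0, None, params) == pytest.approx(0.5)

    def test_covariate_contribution(self):
        params = BinaryParams(mu0=-2.0, alpha=0.1, beta=0.1, gamma=(0.1,), covariates=("age",))
        assert disease_probability(1.0, np.array([5.0]), params) == pytest.approx(expit(-0.5))

    def test_schema_mismatch_rejected(self):
        params = BinaryParams(mu0=-2.0, alpha=0.1, beta=0.1, gamma=(0.1,), covariates=("age",))
        with pytest.raises(ParameterError):
            disease_probability(1.0, np.array([5.0, 1.0]), params)
        with pytest.raises(ParameterError):
            disease_probability(1.0, None, params)


class TestLiabilityScaleEffect:
    def test_zero_effect(self):
        assert liability_scale_effect(0.0, -2.0) == 0.0

    def test_frozen_value(self):
        # oracle: high-precision probit/logistic evaluation of the conversion
        assert liability_scale_effect(0.5, -3.0) == pytest.approx(0.306, abs=1.5e-3)

    def test_strictly_increasing_in_effect(self):
        effects = np.linspace(0.0, 3.0, 31)
        taus = [liability_scale_effect(e, -2.0) for e in effects]
        assert np.all(np.diff(taus) > 0)

    def test_sign_matches_effect(self):
        assert liability_scale_effect(-0.5, -2.0) < 0


class TestTheoreticalOddsRatio:
    def test_degenerate_liability_gives_unit_or(self):
        params = BinaryParams(mu0=-1.0, alpha=0.0, beta=0.0)
        assert theoretical_parent_child_or(params) == pytest.approx(1.0)

    def test_positive_liability_correlation_inflates_or(self):
        params = BinaryParams(mu0=-2.0, alpha=0.4, beta=0.6)
        assert theoretical_parent_child_or(params) > 1.0

    def test_quadrature_converges_when_doubling_nodes(self, disease_params):
        or64 = theoretical_parent_child_or(disease_params, n_nodes=64)
        or128 = theoretical_parent_child_or(disease_params, n_nodes=128)
        assert or64 == pytest.approx(or128, rel=1e-8)

    def test_matches_monte_carlo_integration(self):
        """Brute-force 2-D Monte-Carlo integration oracle, 1e7 draws."""
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.7)
        h2 = params.h2
        cov = np.array([[h2, h2 / 2], [h2 / 2, h2]])
        rng = np.random.default_rng(99)
        n, batches = 10_000_000, 20
        log_ors = []
        for draws in np.array_split(rng.multivariate_normal([0, 0], cov, size=n), batches):
            pc = expit(params.mu0 + draws[:, 0])
            pp = expit(params.mu0 + draws[:, 1])
            f11, f01 = np.mean(pc * pp), np.mean((1 - pc) * pp)
            f10, f00 = np.mean(pc * (1 - pp)), np.mean((1 - pc) * (1 - pp))
            log_ors.append(np.log((f11 / f01) / (f10 / f00)))
        mc = np.mean(log_ors)
        se = np.std(log_ors, ddof=1) / np.sqrt(batches)
        quad = np.log(theoretical_parent_child_or(params))
        assert abs(quad - mc) < 3 * se

    def test_strictly_increasing_in_beta(self):
        betas = np.linspace(0.0, 2.0, 9)
        ors = [
            theoretical_parent_child_or(BinaryParams(mu0=-2.0, alpha=0.3, beta=b))
            for b in betas
        ]
        assert np.all(np.diff(ors) > 0)

    def test_parental_covariates_shift_the_or(self):
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.7, gamma=(0.5,), covariates=("sex",))
        q_child = np.array([0.0])
        or_m = theoretical_parent_child_or(params, "mother", q_child, q_parent=np.array([0.0]))
        or_f = theoretical_parent_child_or(params, "father", q_child, q_parent=np.array([1.0]))
        assert or_m != pytest.approx(or_f, rel=1e-4)


class TestLineSearch:
    def test_truth_at_zero_beta(self):
        params0 = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.0)
        orm = theoretical_parent_child_or(params0, "mother")
        orf = theoretical_parent_child_or(params0, "father")
        res = estimate_beta_line_search(orm, orf, mu0=-2.0, alpha=0.3)
        assert res.beta == pytest.approx(0.0, abs=1e-3)

    def test_round_trip_recovers_beta(self):
        truth = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.8)
        orm = theoretical_parent_child_or(truth, "mother")
        orf = theoretical_parent_child_or(truth, "father")
        res = estimate_beta_line_search(orm, orf, mu0=-2.0, alpha=0.3)
        assert res.beta == pytest.approx(0.8, abs=0.01)
        assert res.objective < 1e-3

    def test_inflated_ors_pull_beta_up(self):
        truth = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.8)
        orm = theoretical_parent_child_or(truth, "mother")
        orf = theoretical_parent_child_or(truth, "father")
        res = estimate_beta_line_search(1.5 * orm, 1.5 * orf, mu0=-2.0, alpha=0.3)
        assert res.beta > 0.8

    def test_bracket_exhaustion_raises(self):
        with pytest.raises(BracketError, match="beta_max"):
            estimate_beta_line_search(50.0, 50.0, mu0=-2.0, alpha=0.3, beta_max=0.5)


class TestImportanceSampling:
    def test_degenerate_prior_gives_zero_samples(self):
        params = BinaryParams(mu0=-1.0, alpha=0.0, beta=0.0)
        s = sample_parent_liability(1, None, params, n_samples=100, seed=0)
        assert np.all(s.values == 0.0)
        assert s.mean == 0.0

    def test_cases_have_elevated_liability(self):
        params = BinaryParams(mu0=-6.0, alpha=0.5, beta=0.5)
        s = sample_parent_liability(1, None, params, n_samples=50_000, seed=1)
        assert s.mean > 0.0

    @pytest.mark.parametrize("z", [0, 1])
    def test_weighted_mean_matches_quadrature_oracle(self, z):
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=np.sqrt(0.73 - 0.09))  # h2 = 0.73
        s = sample_parent_liability(z, None, params, n_samples=200_000, seed=2)
        oracle = posterior_mean_by_quadrature(z, params)
        assert abs(s.mean - oracle) < 3 * s.mean_se

    def test_reproducible_under_seed(self):
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.7)
        a = sample_parent_liability(1, None, params, 1000, seed=7)
        b = sample_parent_liability(1, None, params, 1000, seed=7)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.weights, b.weights)

    def test_low_ess_sets_warning_not_exception(self):
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.7)
        s = sample_parent_liability(1, None, params, n_samples=50, seed=3, ess_floor=100)
        assert s.ess <= 50
        assert s.ess_warning

    def test_weights_are_a_distribution(self):
        params = BinaryParams(mu0=-8.0, alpha=1.0, beta=1.0)  # rare disease
        s = sample_parent_liability(1, None, params, 10_000, seed=4)
        assert np.all(s.weights >= 0)
        assert np.sum(s.weights) == pytest.approx(1.0)
        assert 0 < s.ess <= 10_000


def liability_prediction_by_grid(obs, params, n_nodes=801):
    """Independent oracle: tensor-grid quadrature of the joint predictor,
    averaging the explicit-inverse conditional mean over the product of the
    two parental posteriors."""
    a, h2 = params.alpha, params.h2
    sigma = np.sqrt(h2)
    h = np.linspace(-8 * sigma, 8 * sigma, n_nodes)

    def posterior(z, q):
        eta = params.linear_predictor(h, q)
        lik = expit(eta) if z == 1 else expit(-eta)
        w = lik * np.exp(-(h**2) / (2 * h2))
        return w / w.sum()

    wm = posterior(obs.z_m, obs.q_m)
    wf = posterior(obs.z_f, obs.q_f)
    A = np.array([[h2, 0, a / 2], [0, h2, a / 2], [a / 2, a / 2, 1.0]])
    c = np.array([h2 / 2, h2 / 2, a])
    coef = c @ np.linalg.inv(A)
    HM, HF = np.meshgrid(h, h, indexing="ij")
    W = np.outer(wm, wf)
    inner = coef[0] * HM + coef[1] * HF + coef[2] * obs.p_c
    return float(np.sum(W * inner))


class TestPredictLiability:
    def test_degenerate_model_predicts_zero(self):
        params = BinaryParams(mu0=-1.0, alpha=0.0, beta=0.0)
        obs = DiseaseTrioObservation(p_c=2.0, z_m=1, z_f=1)
        assert predict_liability(obs, params, L=10, seed=0).value == 0.0

    def test_no_history_closed_form(self):
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=0.7)
        pred = predict_liability(DiseaseTrioObservation(p_c=1.2), params, L=10, seed=0)
        assert pred.value == pytest.approx(0.36)
        assert pred.mc_se is None

    def test_matches_grid_quadrature_oracle(self, disease_params):
        obs = DiseaseTrioObservation(p_c=0.0, z_m=1, z_f=1)
        pred = predict_liability(obs, disease_params, L=200_000, seed=5)
        oracle = liability_prediction_by_grid(obs, disease_params)
        assert abs(pred.value - oracle) < 3 * pred.mc_se

    def test_vanishing_beta_reduces_to_prs_only(self):
        params = BinaryParams(mu0=-2.0, alpha=0.3, beta=1e-6)
        obs = DiseaseTrioObservation(p_c=0.9, z_m=1, z_f=1)
        pred = predict_liability(obs, params, L=50_000, seed=6)
        assert pred.value == pytest.approx(0.3 * 0.9, abs=1e-3)

    def test_parent_exchange_symmetry_without_sex_covariate(self, disease_params):
        a = predict_liability(
            DiseaseTrioObservation(p_c=0.4, z_m=1, z_f=0), disease_params, L=100_000, seed=7
        )
        b = predict_liability(
            DiseaseTrioObservation(p_c=0.4, z_m=0, z_f=1), disease_params, L=100_000, seed=7
        )
        assert a.value == pytest.approx(b.value, abs=3 * (a.mc_se + b.mc_se))

    def test_monotone_in_prs_and_parental_history(self):
        grid = [
            BinaryParams(mu0=m, alpha=a, beta=b)
            for m in (-3.0, -1.0)
            for a in (0.2, 0.5)
            for b in (0.3, 0.8)
        ]
        for params in grid:
            lo = predict_liability(DiseaseTrioObservation(0.0, 0, 0), params, 20_000, seed=8)
            hi_p = predict_liability(DiseaseTrioObservation(1.0, 0, 0), params, 20_000, seed=8)
            hi_m = predict_liability(DiseaseTrioObservation(0.0, 1, 0), params, 20_000, seed=8)
            hi_f = predict_liability(DiseaseTrioObservation(0.0, 0, 1), params, 20_000, seed=8)
            assert hi_p.value > lo.value
            assert hi_m.value > lo.value
            assert hi_f.value > lo.value

    def test_frame_predictor_matches_per_observation_calls(self, disease_params):
        p_c = np.array([0.5, -0.2, 1.0, 0.0])
        z_m = np.array([1.0, np.nan, 0.0, np.nan])
        z_f = np.array([0.0, 1.0, np.nan, np.nan])
        values, ses = predict_liability_frame(p_c, z_m, z_f, disease_params, L=50_000, seed=9)
        w_both = liability_predictor_weights(disease_params, "both")
        w_single = liability_predictor_weights(disease_params, "single")
        # closed-form row has no sampling error
        assert values[3] == pytest.approx(disease_params.alpha * 0.0)
        assert np.isnan(ses[3])
        # sampled rows agree with per-observation predictions within MC error
        for i, (zm, zf) in enumerate([(1, 0), (None, 1), (0, None)]):
            obs = DiseaseTrioObservation(p_c=p_c[i], z_m=zm, z_f=zf)
            single = predict_liability(obs, disease_params, L=50_000, seed=10)
            assert values[i] == pytest.approx(single.value, abs=3 * (ses[i] + single.mc_se))
        assert w_both.shape == (3,) and w_single.shape == (2,)

    def test_parent_reference_covariates_fix_sex_by_role(self):
        params = BinaryParams(
            mu0=-2.0, alpha=0.3, beta=0.7, gamma=(0.02, 0.5), covariates=("age", "sex")
        )
        assert parent_reference_covariates(params, "mother")[1] == 0.0
        assert parent_reference_covariates(params, "father")[1] == 1.0
        assert parent_reference_covariates(BinaryParams(-2, 0.3, 0.7), "mother") is None
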