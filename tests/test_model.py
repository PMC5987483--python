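"""Prior assembly, likelihood, sampler correctness, prediction and transfer."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sf6dval.lattice import DEFAULT_LATTICE, LatticeSpec, enumerate_states, parse_state
from sf6dval.model import (
    MCMCConfig,
    ModelFit,
    ModelParams,
    PriorSpec,
    UtilityPosterior,
    build_prior,
    correlation,
    correlation_matrix,
    fit,
    load_prior_from_table,
    log_likelihood,
    posterior_as_prior,
    predict,
)
from sf6dval.lattice import levels_array
from sf6dval.synthetic import (
    Respondent,
    ValuationStudy,
    make_true_utility,
    simulate_respondents,
    simulate_study,
)


def quick_config(seed=0, **kw):
    base = dict(iterations=1200, burn_in=400, thinning=2, seed=seed)
    base.update(kw)
    return MCMCConfig(**base)


class TestCorrelation:
    def test_identical_states(self):
        s = parse_state("321445")
        assert correlation(s, s, [0.1] * 6) == 1.0

    def test_single_level_difference(self):
        a, b = parse_state("111111"), parse_state("211111")
        assert correlation(a, b, [math.log(2), 0, 0, 0, 0, 0]) == pytest.approx(0.5)

    def test_zero_roughness_degenerates_to_one(self):
        a, b = parse_state("111111"), parse_state("645655")
        assert correlation(a, b, [0.0] * 6) == 1.0

    def test_negative_roughness_rejected(self):
        with pytest.raises(ValueError):
            correlation(parse_state("111111"), parse_state("211111"), [-0.1] * 6)

    @settings(max_examples=40, deadline=None)
    @given(
        st.tuples(*(st.integers(1, c) for c in (6, 4, 5, 6, 5, 5))),
        st.tuples(*(st.integers(1, c) for c in (6, 4, 5, 6, 5, 5))),
        st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
    )
    def test_symmetric_bounded_and_decreasing(self, la, lb, b):
        from sf6dval.lattice import HealthState

        a, c = HealthState(la), HealthState(lb)
        r = correlation(a, c, b)
        assert 0 < r <= 1
        assert r == correlation(c, a, b)
        assert (r == 1.0) == (la == lb)

    def test_matrix_psd(self):
        states = enumerate_states(LatticeSpec((3, 2, 3, 2, 2, 2)))
        L = levels_array(states)
        C = correlation_matrix(L, L, np.full(6, 0.1))
        assert np.linalg.eigvalsh(C).min() > -1e-8


class TestBuildPrior:
    def test_standalone_anchor(self):
        states = [parse_state(c) for c in ("111111", "211111", "645655")]
        mean, cov = build_prior(states, PriorSpec())
        assert mean[0] == pytest.approx(1.0)
        assert cov[0, 0] == pytest.approx(0.0, abs=1e-10)
        assert cov[1, 1] > 0

    def test_transfer_limit_recovers_base(self):
        states = [parse_state(c) for c in ("211111", "121111", "645655")]
        base = UtilityPosterior(
            states, np.array([0.8, 0.75, 0.3]), np.diag([1e-4, 1e-4, 1e-4])
        )
        spec = PriorSpec(mode="transfer", base=base, sigma2=1e-10)
        mean, cov = build_prior(states, spec)
        # gamma0 = beta = 0 and sigma2 -> 0: prior collapses onto the base
        # (up to the anchoring correction, negligible for a tight base)
        np.testing.assert_allclose(mean, base.mean, atol=1e-3)

    def test_transfer_covariance_adds_components(self):
        states = [parse_state(c) for c in ("211111", "121111", "112111")]
        base_cov = 0.02 * np.eye(3)
        base = UtilityPosterior(states, np.array([0.8, 0.75, 0.7]), base_cov)
        sigma2 = 0.05
        spec = PriorSpec(mode="transfer", base=base, sigma2=sigma2, roughness=np.full(6, 50.0))
        # enormous roughness: kernel ~ identity, anchoring correction ~ 0
        mean, cov = build_prior(states, spec)
        for i in range(3):
            assert cov[i, i] == pytest.approx(base_cov[i, i] + sigma2, rel=1e-3)

    def test_beta_enters_through_centered_levels(self):
        states = [parse_state(c) for c in ("111111", "211111")]
        spec = PriorSpec(beta=np.array([-0.1, 0, 0, 0, 0, 0]), sigma2=1e-8)
        mean, _ = build_prior(states, spec)
        assert mean[0] == pytest.approx(1.0)
        assert mean[1] == pytest.approx(0.9, abs=1e-3)


class TestLogLikelihood:
    def test_hand_computed_three_record_toy(self):
        design = [parse_state("211111"), parse_state("121111")]
        records = pd.DataFrame(
            {
                "respondent_id": [0, 0, 1],
                "state": ["211111", "121111", "211111"],
                "y": [0.82, 0.74, 0.69],
                "missing": [False] * 3,
            }
        )
        resp = [Respondent(0, (1.0,), 1.1), Respondent(1, (1.0,), 0.9)]
        study = ValuationStudy(records, resp, design)
        u = np.array([0.8, 0.7])
        params = ModelParams(gamma_alpha=[0.0], tau2=0.04, upsilon2=0.01)
        # independent oracle: direct density evaluation, record by record
        expected = 0.0
        alphas = {0: 1.1, 1: 0.9}
        for _, r in records.iterrows():
            uj = u[design.index(parse_state(r["state"]))]
            mu = 1 - alphas[r["respondent_id"]] * (1 - uj)
            expected += stats.norm.logpdf(r["y"], mu, 0.1)
        for a in (1.1, 0.9):
            expected += stats.lognorm.logpdf(a, s=0.2, scale=1.0)
        assert log_likelihood(study, u, params) == pytest.approx(expected, abs=1e-10)

    def test_perfect_fit_record_is_at_density_mode(self):
        design = [parse_state("211111"), parse_state("121111")]
        records = pd.DataFrame(
            {
                "respondent_id": [0],
                "state": ["211111"],
                "y": [0.8],
                "missing": [False],
            }
        )
        study = ValuationStudy(records, [Respondent(0, (1.0,), 1.0)], design)
        params = ModelParams(gamma_alpha=[0.0], tau2=0.04, upsilon2=0.01)
        best = log_likelihood(study, np.array([0.8, 0.5]), params)
        for off in (0.75, 0.85):
            assert log_likelihood(study, np.array([off, 0.5]), params) < best
        # doubling the error variance lowers the density at its mode
        wider = ModelParams(gamma_alpha=[0.0], tau2=0.04, upsilon2=0.02)
        assert log_likelihood(study, np.array([0.8, 0.5]), wider) < best

    def test_missing_u_rejected(self):
        design = [parse_state("211111")]
        records = pd.DataFrame(
            {"respondent_id": [0], "state": ["211111"], "y": [0.8], "missing": [False]}
        )
        study = ValuationStudy(records, [Respondent(0, (1.0,), 1.0)], design)
        params = ModelParams(gamma_alpha=[0.0], tau2=0.04, upsilon2=0.01)
        with pytest.raises(ValueError):
            log_likelihood(study, np.array([0.8, 0.1]), params)


def _toy_study(design_codes, y_rows, alphas):
    """y_rows: list of (respondent, state_code, y)."""
    design = [parse_state(c) for c in design_codes]
    records = pd.DataFrame(
        {
            "respondent_id": [r[0] for r in y_rows],
            "state": [r[1] for r in y_rows],
            "y": [r[2] for r in y_rows],
            "missing": [False] * len(y_rows),
        }
    )
    resp = [Respondent(j, (1.0,), a) for j, a in enumerate(alphas)]
    return ValuationStudy(records, resp, design)


class TestSamplerOracles:
    def test_noiseless_data_dominate(self):
        # alpha fixed at 1, tiny fixed error variance: posterior mean of u at
        # observed states reproduces the observations
        rows = [(0, "211111", 0.82), (0, "121111", 0.74), (0, "112111", 0.67)]
        study = _toy_study(["211111", "121111", "112111"], rows, [1.0])
        cfg = quick_config(
            seed=1, sample_alpha=False, fixed_upsilon2=1e-8, sample_theta=False,
            sample_sigma2=False,
        )
        f = fit(study, PriorSpec(sigma2=0.05), cfg)
        pm = f.posterior_mean_u()
        for (_, code, y) in rows:
            i = [s.code for s in f.states].index(code)
            assert pm[i] == pytest.approx(y, abs=1e-3)

    def test_u_step_matches_closed_form_gaussian_posterior(self):
        # 3 design states, everything but u held fixed: the sampler's u draws
        # are iid from the exact conjugate posterior; compare against the
        # closed form computed independently here.
        codes = ["211111", "121111", "645655"]
        rows = [
            (0, "211111", 0.85), (0, "121111", 0.70), (0, "645655", 0.25),
            (1, "211111", 0.78), (1, "645655", 0.38),
        ]
        alphas = [1.0, 1.0]
        study = _toy_study(codes, rows, alphas)
        ups2 = 0.02
        prior = PriorSpec(sigma2=0.05)
        cfg = quick_config(
            seed=2, iterations=4000, burn_in=500, thinning=1,
            sample_alpha=False, fixed_upsilon2=ups2, sample_theta=False,
            sample_sigma2=False,
        )
        f = fit(study, prior, cfg)
        # independent closed form: N(m, V) prior (anchored), Gaussian obs
        states = [parse_state(c) for c in codes]
        m, V = build_prior(states, prior)
        A = np.zeros(3)
        b = np.zeros(3)
        pos = {c: i for i, c in enumerate(codes)}
        for j, code, y in rows:
            i = pos[code]
            A[i] += 1.0 / ups2
            b[i] += (y - 1.0 + 1.0) / ups2
        P = np.linalg.inv(V + 1e-10 * np.eye(3)) + np.diag(A)
        Sigma = np.linalg.inv(P)
        mu = Sigma @ (np.linalg.solve(V + 1e-10 * np.eye(3), m) + b)
        mc_se = f.u.std(axis=0, ddof=1) / np.sqrt(f.n_draws)
        np.testing.assert_array_less(np.abs(f.posterior_mean_u() - mu), 3 * mc_se + 1e-12)
        np.testing.assert_allclose(f.u.std(axis=0, ddof=1), np.sqrt(np.diag(Sigma)), rtol=0.15)

    def test_parameter_recovery_rank_correlation(self):
        spec = DEFAULT_LATTICE
        truth = make_true_utility(spec, seed=10)
        from sf6dval.lattice import sample_states_without_replacement

        design = sample_states_without_replacement(
            spec, 30, seed=11, exclude=[spec.full_health]
        )
        resp = simulate_respondents(100, tau2=0.04, seed=12)
        study = simulate_study(truth, resp, design, 8, upsilon2=0.02, seed=13)
        f = fit(study, PriorSpec(), quick_config(seed=14))
        rho = stats.spearmanr(f.posterior_mean_u(), truth.at(design)).statistic
        assert rho > 0.9

    def test_anchoring_holds_in_predictions(self):
        rows = [(0, "211111", 0.8), (0, "121111", 0.7)]
        study = _toy_study(["211111", "121111"], rows, [1.0])
        f = fit(study, PriorSpec(), quick_config(seed=3))
        pred = predict(f, [DEFAULT_LATTICE.full_health, parse_state("211111")])
        assert pred.loc[0, "predicted_mean"] == 1.0
        assert pred.loc[0, "predicted_sd"] == 0.0

    def test_design_state_prediction_is_draw_moments(self):
        rows = [(0, "211111", 0.8), (0, "121111", 0.7), (1, "211111", 0.75)]
        study = _toy_study(["211111", "121111"], rows, [1.0, 1.0])
        f = fit(study, PriorSpec(), quick_config(seed=4))
        pred = predict(f, f.states)
        np.testing.assert_allclose(
            pred["predicted_mean"].to_numpy(), f.posterior_mean_u(), atol=1e-12
        )
        np.testing.assert_allclose(
            pred["predicted_sd"].to_numpy(), f.posterior_sd_u(), atol=1e-12
        )

    def test_off_design_prediction_reverts_to_trend_under_rough_kernel(self):
        # with an enormous roughness the kernel correlation to any other
        # state vanishes, so an off-design state reverts to the prior mean
        # at that state (the fitted linear trend), with full prior spread
        rows = [(0, "211111", 0.8), (0, "121111", 0.7), (1, "112111", 0.75)]
        study = _toy_study(["211111", "121111", "112111"], rows, [1.0, 1.0])
        prior = PriorSpec(roughness=np.full(6, 60.0))
        f = fit(study, prior, quick_config(seed=5, sample_sigma2=False))
        target = parse_state("645655")
        pred = predict(f, [target])
        # prior mean at the target per draw: 1 + gamma0 + beta' z
        z = (np.array(target.levels) - 1).astype(float)
        trend = 1.0 + f.gamma0 + f.beta @ z
        assert pred.loc[0, "predicted_mean"] == pytest.approx(trend.mean(), abs=0.02)


class TestPosteriorAsPrior:
    def test_carrying_forward_design_states_reproduces_fit_moments(self):
        rows = [(0, "211111", 0.8), (0, "121111", 0.7), (1, "211111", 0.72)]
        study = _toy_study(["211111", "121111"], rows, [1.0, 1.0])
        f = fit(study, PriorSpec(), quick_config(seed=6))
        post = posterior_as_prior(f, f.states)
        np.testing.assert_allclose(post.mean, f.posterior_mean_u(), atol=1e-12)
        np.testing.assert_allclose(
            np.sqrt(np.diag(post.cov)), f.posterior_sd_u(), atol=1e-10
        )

    def test_no_data_transfer_returns_base(self):
        # empty-ish B study (two barely-informative records), tiny sigma2:
        # the posterior stays at the carried base
        rows = [(0, "211111", 0.8), (0, "121111", 0.7), (1, "211111", 0.72),
                (1, "112111", 0.66)]
        study = _toy_study(["211111", "121111", "112111"], rows, [1.0, 1.0])
        f = fit(study, PriorSpec(), quick_config(seed=7))
        base = posterior_as_prior(f, f.states)
        rows_b = [(0, "211111", base.mean[0])]
        study_b = _toy_study(["211111", "121111", "112111"], rows_b, [1.0])
        prior_b = PriorSpec(mode="transfer", base=base, sigma2=1e-8)
        cfg = quick_config(
            seed=8, sample_sigma2=False, sample_theta=False, fixed_upsilon2=0.5,
            sample_alpha=False,
        )
        fb = fit(study_b, prior_b, cfg)
        np.testing.assert_allclose(fb.posterior_mean_u(), base.mean, atol=0.02)

    def test_too_few_draws_rejected(self):
        rows = [(0, "211111", 0.8), (0, "121111", 0.7)]
        study = _toy_study(["211111", "121111"], rows, [1.0])
        f = fit(study, PriorSpec(), quick_config(seed=9))
        f2 = ModelFit(**{**f.__dict__})
        f2.u = f.u[:1]
        with pytest.raises(ValueError):
            posterior_as_prior(f2, f.states)


class TestTablePrior:
    def test_published_uk_values(self):
        post = load_prior_from_table(which="UK")
        idx = post.index()["645655"]
        assert post.mean[idx] == pytest.approx(0.3575)
        assert np.sqrt(post.cov[idx, idx]) == pytest.approx(0.0186)

    def test_huge_roughness_gives_diagonal_covariance(self):
        post = load_prior_from_table(which="HK", roughness=100.0)
        off = post.cov - np.diag(np.diag(post.cov))
        assert np.abs(off).max() < 1e-8

    def test_default_roughness_matrix_is_psd(self):
        post = load_prior_from_table(which="UK", roughness=0.1)
        assert np.linalg.eigvalsh(post.cov).min() > -1e-8

    def test_unknown_column_rejected(self):
        with pytest.raises(ValueError):
            load_prior_from_table(which="US")


class TestSerialization:
    def test_fit_roundtrip_bit_exact(self, tmp_path):
        rows = [(0, "211111", 0.8), (0, "121111", 0.7), (1, "211111", 0.72)]
        study = _toy_study(["211111", "121111"], rows, [1.0, 1.0])
        f = fit(study, PriorSpec(), quick_config(seed=10))
        f.save(tmp_path / "fit")
        back = ModelFit.load(tmp_path / "fit")
        np.testing.assert_array_equal(back.u, f.u)
        np.testing.assert_array_equal(back.sigma2, f.sigma2)
        assert [s.code for s in back.states] == [s.code for s in f.states]

    def test_posterior_roundtrip_bit_exact(self, tmp_path):
        post = load_prior_from_table(which="UK")
        post.save(tmp_path / "post")
        back = UtilityPosterior.load(tmp_path / "post")
        np.testing.assert_array_equal(back.mean, post.mean)
        np.testing.assert_array_equal(back.cov, post.cov)
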