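"""LCMM likelihood oracles, EM properties, selection, trajectories, G=1 LMM."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pacctraj.lcmm import (
    LcmmFit,
    LcmmParams,
    LcmmSpec,
    build_model_data,
    class_trajectories,
    component_logliks,
    fit_biomarker_lmm,
    fit_lcmm,
    information_criteria,
    loglik,
    posterior_matrix,
    select_model,
)
from pacctraj.mnl import mnl_probs
from pacctraj.simulate import (
    preset_a4learn_like,
    preset_single_class,
    simulate_cohort,
)
from tests.conftest import make_tiny_cohort


def random_params(md, G, seed=0, sigma_b=0.8, sigma_e=1.2):
    rng = np.random.default_rng(seed)
    return LcmmParams(
        alpha=rng.normal(size=(G, md.S.shape[1])),
        gamma=rng.normal(size=md.W.shape[1]) * 0.1,
        zeta=rng.normal(size=(G - 1, 1 + md.Xm.shape[1])) * 0.3,
        sigma_e=sigma_e,
        sigma_b=sigma_b,
    )


def brute_force_loglik(md, params):
    """Dense multivariate-normal mixture oracle (explicit V_i)."""
    G = params.alpha.shape[0]
    pi = (
        np.ones((md.n_subjects, 1))
        if G == 1
        else mnl_probs(params.zeta, md.Xm)
    )
    total = 0.0
    for i, (a, b) in enumerate(md.subject_slices()):
        n = b - a
        V = params.sigma_b**2 * np.ones((n, n)) + params.sigma_e**2 * np.eye(n)
        li = 0.0
        for g in range(G):
            mu = md.S[a:b] @ params.alpha[g]
            if md.W.shape[1]:
                mu = mu + md.W[a:b] @ params.gamma
            li += pi[i, g] * multivariate_normal.pdf(md.y[a:b], mean=mu, cov=V)
        total += np.log(li)
    return total


class TestLoglikOracle:
    @pytest.mark.parametrize("G", [1, 2, 3])
    @pytest.mark.parametrize("n_subjects,n_visits", [(3, 2), (5, 4)])
    def test_matches_brute_force(self, G, n_subjects, n_visits):
        cohort = make_tiny_cohort(n_subjects, n_visits, seed=G)
        spec = LcmmSpec(n_classes=G)
        md = build_model_data(cohort, spec, boxcox=None)
        for seed in range(3):
            params = random_params(md, G, seed=seed)
            assert loglik(md, params) == pytest.approx(
                brute_force_loglik(md, params), abs=1e-8
            )

    def test_mixture_of_identical_components_collapses(self):
        cohort = make_tiny_cohort(4, 3, seed=1)
        md2 = build_model_data(cohort, LcmmSpec(n_classes=2), boxcox=None)
        md1 = build_model_data(cohort, LcmmSpec(n_classes=1), boxcox=None)
        p1 = random_params(md1, 1, seed=2)
        p2 = LcmmParams(
            alpha=np.vstack([p1.alpha, p1.alpha]),
            gamma=p1.gamma,
            zeta=np.zeros((1, 1 + md2.Xm.shape[1])),
            sigma_e=p1.sigma_e,
            sigma_b=p1.sigma_b,
        )
        assert loglik(md2, p2) == pytest.approx(loglik(md1, p1), abs=1e-10)

    def test_label_permutation_invariance(self):
        cohort = make_tiny_cohort(5, 3, seed=3)
        md = build_model_data(cohort, LcmmSpec(n_classes=3), boxcox=None)
        params = random_params(md, 3, seed=4)
        base = loglik(md, params)
        from itertools import permutations

        zeta_full = np.vstack([np.zeros(params.zeta.shape[1]), params.zeta])
        for perm in permutations(range(3)):
            perm = list(perm)
            zf = zeta_full[perm]
            q = LcmmParams(
                alpha=params.alpha[perm],
                gamma=params.gamma,
                zeta=(zf - zf[0])[1:],
                sigma_e=params.sigma_e,
                sigma_b=params.sigma_b,
            )
            assert loglik(md, q) == pytest.approx(base, abs=1e-9)


class TestPosteriors:
    def test_rows_sum_to_one(self, fitted_model):
        fit, md = fitted_model
        tau = posterior_matrix(md, fit.params)
        np.testing.assert_allclose(tau.sum(axis=1), 1.0, atol=1e-10)

    def test_identical_components_give_prior(self):
        cohort = make_tiny_cohort(5, 3, seed=5)
        md = build_model_data(cohort, LcmmSpec(n_classes=2), boxcox=None)
        p1 = random_params(md, 1, seed=6)
        params = LcmmParams(
            alpha=np.vstack([p1.alpha, p1.alpha]),
            gamma=p1.gamma,
            zeta=np.random.default_rng(7).normal(size=(1, 1 + md.Xm.shape[1])),
            sigma_e=1.0,
            sigma_b=0.5,
        )
        tau = posterior_matrix(md, params)
        np.testing.assert_allclose(tau, mnl_probs(params.zeta, md.Xm), atol=1e-12)

    def test_vanishing_noise_gives_hard_assignment(self):
        """Classes separated by ~10 sigma: posteriors approach indicators."""
        truth = preset_a4learn_like(n_subjects=80, seed=8)
        truth = dataclasses.replace(truth, sigma_b=0.1, sigma_e=0.1)
        cohort, tc = simulate_cohort(truth)
        spec = LcmmSpec()
        md = build_model_data(cohort, spec, boxcox=truth.boxcox)
        fit = fit_lcmm(md, spec, n_starts=2, seed=1)
        assert fit.posterior.max(axis=1).min() > 0.999


class TestInformationCriteria:
    def test_closed_form_bic(self):
        tau = np.eye(3)[np.repeat([0, 1, 2], 10)]
        bic, icl = information_criteria(-100.0, 10, 100, tau)
        assert bic == pytest.approx(200 + 10 * np.log(100), abs=1e-9)
        assert icl == pytest.approx(bic)  # hard posteriors: zero entropy

    def test_icl_at_least_bic(self, fitted_model):
        fit, _ = fitted_model
        assert fit.icl >= fit.bic


class TestEmFitting:
    def test_loglik_trace_monotone(self, fitted_model):
        fit, _ = fitted_model
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-9)

    def test_g1_matches_statsmodels_mixedlm(self):
        """Independent route: G=1 random-intercept ML fit via statsmodels."""
        import statsmodels.api as sm

        truth = preset_single_class(n_subjects=150, seed=9)
        cohort, _ = simulate_cohort(truth)
        spec = LcmmSpec(n_classes=1)
        md = build_model_data(cohort, spec, boxcox=truth.boxcox)
        fit = fit_lcmm(md, spec, n_starts=1, seed=0)

        X = np.column_stack([md.S, md.W])
        groups = np.repeat(np.arange(md.n_subjects), md.n_i)
        sm_fit = sm.MixedLM(md.y, X, groups=groups).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        np.testing.assert_allclose(
            np.concatenate([fit.alpha[0], fit.gamma]),
            sm_fit.fe_params,
            atol=2e-3,
        )

    def test_parameter_recovery_single_seed(self, fitted_model, preset_truth,
                                            small_cohort):
        """Class proportions within 4 points, variance components within 10%."""
        fit, _ = fitted_model
        _, tc = small_cohort
        true_props = np.bincount(list(tc.values()), minlength=3) / len(tc)
        np.testing.assert_allclose(fit.class_proportions, true_props, atol=0.04)
        assert abs(fit.sigma_e - preset_truth.sigma_e) / preset_truth.sigma_e < 0.10
        assert abs(fit.sigma_b - preset_truth.sigma_b) / preset_truth.sigma_b < 0.15

    def test_canonical_ordering_stable_first(self, fitted_model):
        fit, md = fitted_model
        s_end = np.concatenate([[1.0], fit.spline.evaluate([md.t_max])[0]])
        means = fit.alpha @ s_end
        assert np.all(np.diff(means) < 0)  # descending: stable -> fast decliner

    def test_standardization_invariance(self, small_cohort, preset_truth):
        """Raw- and standardized-covariate fits give the same loglik."""
        cohort, _ = small_cohort
        sub = cohort.subset(cohort.subject_ids[:150])
        kw = dict(n_starts=1, seed=3)
        f_std = fit_lcmm(
            build_model_data(sub, LcmmSpec(standardize=True), boxcox=preset_truth.boxcox),
            LcmmSpec(standardize=True), **kw,
        )
        f_raw = fit_lcmm(
            build_model_data(sub, LcmmSpec(standardize=False), boxcox=preset_truth.boxcox),
            LcmmSpec(standardize=False), **kw,
        )
        assert f_std.loglik == pytest.approx(f_raw.loglik, abs=0.05)

    def test_fit_serialization_roundtrip(self, fitted_model, tmp_path):
        fit, _ = fitted_model
        fit.to_json(tmp_path / "fit.json")
        again = LcmmFit.from_json(tmp_path / "fit.json")
        np.testing.assert_allclose(again.alpha, fit.alpha)
        np.testing.assert_allclose(again.zeta, fit.zeta)
        assert again.loglik == pytest.approx(fit.loglik)
        assert again.spec == fit.spec


class TestModelSelection:
    def test_selection_table_well_formed(self, small_cohort, preset_truth):
        cohort, _ = small_cohort
        sub = cohort.subset(cohort.subject_ids[:200])
        best, table = select_model(
            sub, df_grid=(1, 2), G_grid=(1, 2), n_starts=1, seed=0,
            boxcox=preset_truth.boxcox,
        )
        assert len(table) == 4
        assert table.loc[table["selected"], "dBIC"].iloc[0] == pytest.approx(0.0)
        assert (table["ICL"] >= table["BIC"] - 1e-6).all()

    def test_recovers_generating_model(self, small_cohort, preset_truth):
        cohort, _ = small_cohort
        best, _ = select_model(
            cohort, n_starts=2, seed=1, boxcox=preset_truth.boxcox
        )
        assert best.spec.n_classes == 3
        assert best.spec.spline_df == 2


class TestClassTrajectories:
    def test_noise_free_recovery(self):
        truth = preset_single_class(n_subjects=40, seed=11)
        truth = dataclasses.replace(
            truth,
            sigma_b=0.0,
            sigma_e=1e-5,  # tiny but positive: V_i must stay PD
            shared_effects=np.zeros_like(truth.shared_effects),
        )
        cohort, _ = simulate_cohort(truth)
        spec = LcmmSpec(n_classes=1)
        # evaluate in the generating spline space so the comparison is exact
        md = build_model_data(cohort, spec, boxcox=truth.boxcox, spline=truth.spline)
        fit = fit_lcmm(md, spec, n_starts=1, seed=0)
        t = np.array([0.0, 2.0, 4.0, 6.0])
        traj = class_trajectories(fit, t, ci=False)[0]
        np.testing.assert_allclose(
            traj.mean, truth.class_mean_pacc(0, t), atol=1e-5
        )

    def test_ci_width_scales_inverse_sqrt_n(self):
        widths = {}
        for n in (250, 1000):
            truth = preset_a4learn_like(n_subjects=n, seed=12)
            cohort, _ = simulate_cohort(truth)
            spec = LcmmSpec()
            md = build_model_data(cohort, spec, boxcox=truth.boxcox)
            fit = fit_lcmm(md, spec, n_starts=2, seed=2)
            traj = class_trajectories(fit, [2.0, 4.0], md=md)[0]
            widths[n] = np.mean(traj.ci_high - traj.ci_low)
        ratio = widths[250] / widths[1000]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_delta_ci_vs_parametric_sampling(self, fitted_model):
        """Two uncertainty routes agree: delta method vs sampling from the
        estimated covariance of (alpha, gamma)."""
        fit, md = fitted_model
        from pacctraj.lcmm import _observed_information

        t = np.array([2.0, 5.0])
        trajs = class_trajectories(fit, t, md=md)
        info = _observed_information(md, fit.params)
        cov = np.linalg.inv(info)
        rng = np.random.default_rng(13)
        G, k = fit.spec.n_classes, fit.alpha.shape[1]
        theta0 = np.concatenate([fit.alpha.ravel(), fit.gamma])
        draws = rng.multivariate_normal(theta0, cov, size=500)
        B = np.column_stack([np.ones(len(t)), fit.spline.evaluate(t)])
        for g, traj in enumerate(trajs):
            curves = np.array(
                [
                    fit.boxcox.inverse(
                        B @ d[g * k : (g + 1) * k] + fit.w_reference @ d[G * k :]
                    )
                    for d in draws
                ]
            )
            lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
            width = traj.ci_high - traj.ci_low
            assert np.all(np.abs(lo - traj.ci_low) < 0.15 * width)
            assert np.all(np.abs(hi - traj.ci_high) < 0.15 * width)


@pytest.fixture(scope="module")
def ptau_series():
    truth = preset_a4learn_like(n_subjects=250, seed=14)
    cohort, _ = simulate_cohort(truth)
    return cohort.visits[["subject_id", "time_years", "ptau217"]].rename(
        columns={"ptau217": "value"}
    ), truth


class TestBiomarkerLmm:

    def test_recovers_linear_growth(self, ptau_series):
        series, truth = ptau_series
        fit, traj = fit_biomarker_lmm(series)
        assert fit.converged
        # population mean slope under the mixture of class slopes
        slope_target = sum(
            p * s
            for p, s in zip(
                truth.class_proportions, truth.biomarker_slopes["ptau217"]
            )
        )
        slope_hat = (traj.mean[-1] - traj.mean[0]) / (traj.times[-1] - traj.times[0])
        assert slope_hat == pytest.approx(slope_target, abs=0.003)
        # measurement noise recovered
        assert fit.sigma_e == pytest.approx(
            truth.biomarker_noise["ptau217"][1], rel=0.15
        )

    def test_cholesky_reconstructs_pd_covariance(self, ptau_series):
        series, _ = ptau_series
        fit, _ = fit_biomarker_lmm(series)
        L = fit.params.chol
        D = L @ L.T
        np.testing.assert_allclose(D, D.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(D) >= 0)

    def test_zero_slope_variance_boundary(self):
        """Simulate without random slopes: estimated slope SD is tiny."""
        rng = np.random.default_rng(15)
        rows = []
        for i in range(250):
            b = rng.normal(0, 1.0)
            for t in np.arange(0, 11):
                rows.append(
                    {
                        "subject_id": f"Z{i}",
                        "time_years": float(t),
                        "value": 1.0 + 0.3 * t + b + rng.normal(0, 1.0),
                    }
                )
        fit, _ = fit_biomarker_lmm(pd.DataFrame(rows))
        D = fit.params.chol @ fit.params.chol.T
        assert np.sqrt(D[1, 1]) < 0.05 * fit.sigma_e
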