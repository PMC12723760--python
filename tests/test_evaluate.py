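"""Folds, baseline-only prediction, CV leakage, PR curves, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pacctraj.errors import SpecificationError, ValidationError
from pacctraj.evaluate import (
    classification_agreement,
    classification_metrics,
    cross_validate,
    make_folds,
    pr_curve,
    predict_class_baseline,
    stratified_folds,
    wilson_interval,
)
from pacctraj.lcmm import LcmmSpec, build_model_data
from pacctraj.mnl import mnl_probs


class TestFolds:
    def test_single_stratum_balanced(self):
        labels = {f"s{i}": 0 for i in range(100)}
        fa = stratified_folds(labels, K=10, seed=1)
        sizes = np.bincount(list(fa.fold.values()), minlength=10)
        assert (sizes == 10).all()

    def test_partition_property(self):
        labels = {f"s{i}": i % 3 for i in range(83)}
        ptau = {f"s{i}": float(i) for i in range(83)}
        fa = make_folds(labels, ptau, K=10, seed=2)
        assert sorted(fa.fold) == sorted(labels)
        assert set(fa.fold.values()) <= set(range(10))

    def test_small_stratum_spreads_over_distinct_folds(self):
        labels = {f"s{i}": 0 for i in range(7)}
        fa = stratified_folds(labels, K=10, seed=3)
        assert len(set(fa.fold.values())) == 7

    def test_within_stratum_fold_sizes_differ_by_at_most_one(self):
        labels = {f"s{i}": i % 2 for i in range(47)}
        ptau = {f"s{i}": float(i % 13) for i in range(47)}
        fa = make_folds(labels, ptau, K=10, seed=4)
        for stratum in set(fa.strata.values()):
            members = [s for s, st_ in fa.strata.items() if st_ == stratum]
            sizes = np.bincount([fa.fold[s] for s in members], minlength=10)
            assert sizes.max() - sizes.min() <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(SpecificationError):
            stratified_folds({"a": 0, "b": 0}, K=1, seed=0)


class TestPredictBaseline:
    def test_one_visit_closed_form(self, fitted_model, small_cohort):
        """Hand computation: pi_g * N(y0; mu_g0, sigma_b^2+sigma_e^2)."""
        fit, md = fitted_model
        cohort, _ = small_cohort
        sub = cohort.subset(cohort.subject_ids[:6])
        preds = predict_class_baseline(fit, sub)
        md_new = build_model_data(
            sub,
            fit.spec,
            boxcox=fit.boxcox,
            spline=fit.spline,
            scalers=(fit.w_scaler, fit.xm_scaler),
            atrophy_fit=fit.atrophy_fit,
        )
        pi = mnl_probs(fit.zeta, md_new.Xm)
        var = fit.sigma_b**2 + fit.sigma_e**2
        for i in range(md_new.n_subjects):
            a = md_new.starts[i]
            y0 = md_new.y[a]
            mu = md_new.S[a] @ fit.alpha.T + md_new.W[a] @ fit.gamma
            dens = np.exp(-0.5 * (y0 - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
            expected = pi[i] * dens
            expected /= expected.sum()
            got = preds.iloc[i][["p_class1", "p_class2", "p_class3"]].to_numpy(float)
            np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_rows_sum_to_one(self, fitted_model, small_cohort):
        fit, _ = fitted_model
        cohort, _ = small_cohort
        preds = predict_class_baseline(fit, cohort)
        probs = preds[["p_class1", "p_class2", "p_class3"]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_identical_trajectories_give_prior(self, fitted_model, small_cohort):
        fit, _ = fitted_model
        cohort, _ = small_cohort
        sub = cohort.subset(cohort.subject_ids[:10])
        clone = fit.params.copy()
        clone.alpha = np.tile(clone.alpha[:1], (3, 1))
        import dataclasses as dc

        degenerate = dc.replace(fit, params=clone)
        preds = predict_class_baseline(degenerate, sub)
        md_new = build_model_data(
            sub, fit.spec, boxcox=fit.boxcox, spline=fit.spline,
            scalers=(fit.w_scaler, fit.xm_scaler), atrophy_fit=fit.atrophy_fit,
        )
        pi = mnl_probs(fit.zeta, md_new.Xm)
        got = preds[["p_class1", "p_class2", "p_class3"]].to_numpy()
        np.testing.assert_allclose(got, pi, atol=1e-12)

    def test_prior_only_mode(self, fitted_model, small_cohort):
        fit, _ = fitted_model
        cohort, _ = small_cohort
        sub = cohort.subset(cohort.subject_ids[:10])
        preds = predict_class_baseline(fit, sub, use_baseline_outcome=False)
        md_new = build_model_data(
            sub, fit.spec, boxcox=fit.boxcox, spline=fit.spline,
            scalers=(fit.w_scaler, fit.xm_scaler), atrophy_fit=fit.atrophy_fit,
        )
        np.testing.assert_allclose(
            preds[["p_class1", "p_class2", "p_class3"]].to_numpy(),
            mnl_probs(fit.zeta, md_new.Xm),
            atol=1e-12,
        )


@pytest.fixture(scope="module")
def cv_setup(fitted_model, small_cohort, preset_truth):
    fit, _ = fitted_model
    cohort, _ = small_cohort
    labels = fit.class_labels
    ptau = dict(zip(cohort.baseline.subject_id, cohort.baseline.ptau217))
    folds = make_folds(labels, ptau, K=5, seed=11)
    preds, meta = cross_validate(
        cohort, fit.spec, folds, fit, n_starts=1, seed=5,
        boxcox=preset_truth.boxcox,
    )
    return cohort, fit, folds, preds, meta


class TestCrossValidate:

    def test_each_subject_predicted_exactly_once(self, cv_setup):
        cohort, fit, folds, preds, meta = cv_setup
        if meta["converged"].all():
            assert sorted(preds["subject_id"]) == sorted(folds.fold)
        assert preds["subject_id"].is_unique

    def test_no_leakage_from_post_baseline_outcomes(
        self, cv_setup, preset_truth
    ):
        """Permuting held-out subjects' outcomes after t=0 leaves their
        predictions unchanged (baseline-only contract)."""
        cohort, fit, folds, preds, _ = cv_setup
        test_ids = folds.subjects_in_fold(0)[:8]
        sub = cohort.subset(test_ids)
        scrambled = sub.visits.copy()
        later = scrambled["time_years"] > 0
        rng = np.random.default_rng(6)
        scrambled.loc[later, "pacc"] = rng.permutation(
            scrambled.loc[later, "pacc"].to_numpy()
        )
        from pacctraj.cohort import CohortData

        sub2 = CohortData(visits=scrambled, baseline=sub.baseline)
        p1 = predict_class_baseline(fit, sub)
        p2 = predict_class_baseline(fit, sub2)
        np.testing.assert_allclose(
            p1[["p_class1", "p_class2", "p_class3"]].to_numpy(),
            p2[["p_class1", "p_class2", "p_class3"]].to_numpy(),
            atol=1e-12,
        )

    def test_near_oracle_regime_auprc(self):
        """Strongly separated classes: one-vs-rest AUPRC > 0.95 for all."""
        import dataclasses as dc

        from pacctraj.lcmm import fit_lcmm
        from pacctraj.simulate import preset_a4learn_like, simulate_cohort

        truth = preset_a4learn_like(n_subjects=300, seed=16)
        truth = dc.replace(truth, sigma_b=0.15, sigma_e=0.15)
        cohort, tc = simulate_cohort(truth)
        spec = LcmmSpec()
        md = build_model_data(cohort, spec, boxcox=truth.boxcox)
        fit = fit_lcmm(md, spec, n_starts=2, seed=1)
        labels = fit.class_labels
        ptau = dict(zip(cohort.baseline.subject_id, cohort.baseline.ptau217))
        folds = make_folds(labels, ptau, K=5, seed=2)
        preds, meta = cross_validate(
            cohort, spec, folds, fit, n_starts=1, seed=3, boxcox=truth.boxcox
        )
        pred_map = dict(zip(preds.subject_id, preds.predicted))
        m = classification_metrics(
            pred_map, {s: labels[s] for s in pred_map}, probabilities=preds
        )
        # baseline-only prediction of a 10-sigma-separated longitudinal
        # process: baseline means already differ by several sigma
        assert all(v > 0.95 for v in m["auprc_per_class"].values())


class TestPrCurve:
    def test_hand_enumerated_four_items(self):
        c = pr_curve([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert c.auprc == pytest.approx((1.0 * 1 + (2 / 3) * 1) / 2)

    def test_hand_enumerated_ten_items_with_ties(self):
        # scores tie in pairs; curve is evaluated at distinct thresholds
        scores = [0.9, 0.9, 0.7, 0.7, 0.5, 0.5, 0.3, 0.3, 0.1, 0.1]
        pos = [1, 1, 0, 1, 0, 0, 0, 1, 0, 0]
        c = pr_curve(scores, pos)
        # hand enumeration: thresholds 0.9,0.7,0.5,0.3,0.1
        # tp: 2,3,3,4,4  n_pred: 2,4,6,8,10  recall: .5,.75,.75,1,1
        expected = 0.5 * (2 / 2) + 0.25 * (3 / 4) + 0.25 * (4 / 8)
        assert c.auprc == pytest.approx(expected)

    def test_perfect_ranking(self):
        c = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert c.auprc == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        c = pr_curve(np.full(10, 0.5), [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert c.auprc == pytest.approx(0.3)

    def test_recall_monotone_nondecreasing(self):
        rng = np.random.default_rng(17)
        c = pr_curve(rng.random(50), rng.integers(0, 2, 50))
        assert np.all(np.diff(c.recall) >= 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_sklearn_average_precision(self, seed):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        pos = rng.integers(0, 2, n)
        if pos.sum() in (0, n):
            return
        assert pr_curve(scores, pos).auprc == pytest.approx(
            average_precision_score(pos, scores)
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            pr_curve([0.5, 0.6], [0, 0])
        with pytest.raises(ValidationError):
            pr_curve([0.5, 0.6], [1, 1])

    def test_any_predictor_beats_nothing(self):
        """Sanity bound: AUPRC >= prevalence - MC slack for random scores."""
        rng = np.random.default_rng(18)
        pos = rng.integers(0, 2, 500)
        prev = pos.mean()
        c = pr_curve(rng.random(500), pos)
        assert c.auprc > prev - 0.1


class TestClassificationMetrics:
    def test_identity_prediction(self):
        truth = {f"s{i}": i % 3 for i in range(30)}
        m = classification_metrics(truth, truth)
        assert m["accuracy"] == 1.0
        assert m["balanced_accuracy"] == 1.0

    def test_hand_computed_two_class_confusion(self):
        truth, pred = {}, {}
        i = 0
        for t, p, n in [(0, 0, 8), (0, 1, 2), (1, 0, 1), (1, 1, 9)]:
            for _ in range(n):
                truth[f"s{i}"], pred[f"s{i}"] = t, p
                i += 1
        m = classification_metrics(pred, truth)
        assert m["accuracy"] == pytest.approx(17 / 20)
        assert m["balanced_accuracy"] == pytest.approx((0.8 + 0.9) / 2)
        assert m["confusion"].loc[0, 0] == 8
        assert m["confusion"].loc[1, 0] == 1

    def test_majority_vote_closed_form(self):
        rng = np.random.default_rng(19)
        classes = rng.choice([0, 1, 2], size=1000, p=[0.77, 0.16, 0.07])
        truth = {f"s{i}": int(c) for i, c in enumerate(classes)}
        pred = {s: 0 for s in truth}
        m = classification_metrics(pred, truth)
        assert m["accuracy"] == pytest.approx((classes == 0).mean())
        assert m["balanced_accuracy"] == pytest.approx(1 / 3)

    def test_subject_order_invariance(self):
        truth = {f"s{i}": i % 3 for i in range(30)}
        pred = {f"s{i}": (i + 1) % 3 for i in range(30)}
        m1 = classification_metrics(pred, truth)
        shuffled = dict(reversed(list(pred.items())))
        m2 = classification_metrics(shuffled, truth)
        assert m1["accuracy"] == m2["accuracy"]

    def test_wilson_interval_contains_point_estimate(self):
        lo, hi = wilson_interval(80, 100)
        assert lo < 0.8 < hi
        assert (hi - lo) < 0.17  # about +-4 points at n=100


class TestAgreement:
    def test_identical_and_one_off(self):
        a = {f"s{i}": i % 3 for i in range(10)}
        assert classification_agreement(a, a) == (0, 0.0)
        b = dict(a)
        b["s0"] = (a["s0"] + 1) % 3
        assert classification_agreement(a, b) == (1, 0.1)

    def test_invariant_to_consistent_relabelling(self):
        a = {f"s{i}": i % 3 for i in range(12)}
        b = {f"s{i}": (i + 1) % 3 for i in range(12)}
        relab = {0: 2, 1: 0, 2: 1}
        a2 = {s: relab[v] for s, v in a.items()}
        b2 = {s: relab[v] for s, v in b.items()}
        assert classification_agreement(a, b) == classification_agreement(a2, b2)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError):
            classification_agreement({"a": 0}, {"b": 0})
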