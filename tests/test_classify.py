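"""Logistic fit, leave-pair-out CV, and classification metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticscreen import (
    CVPrediction,
    SeparationWarning,
    balanced_accuracy,
    fit_logistic,
    leave_pair_out_cv,
    log_likelihood,
    predict_p_gts,
    roc_auroc,
    score_rating_correlation,
    scores_table,
)


def _preds(p_gts, truths):
    return [
        CVPrediction(video_id=f"v{i}", true_group=t, p_gts=float(p), fold_id="f")
        for i, (p, t) in enumerate(zip(p_gts, truths))
    ]


class TestFitLogistic:
    def test_saturated_2x2_closed_form(self):
        """8/10 GTS at x=1 and 2/10 at x=0: slope 2*ln4, intercept logit(0.2)."""
        df = pd.DataFrame({"x": [1] * 10 + [0] * 10})
        labels = ["GTS"] * 8 + ["HC"] * 2 + ["GTS"] * 2 + ["HC"] * 8
        m = fit_logistic(df, labels, ["x"], ridge=0.0)
        assert m.converged
        assert m.coefficients["x"] == pytest.approx(2 * np.log(4), abs=1e-6)
        assert m.intercept == pytest.approx(np.log(0.2 / 0.8), abs=1e-6)
        # prediction consistency with the fitted cell probability
        assert predict_p_gts(m, pd.DataFrame({"x": [1]}))[0] == pytest.approx(0.8, abs=1e-6)

    def test_symmetric_data_zero_intercept(self):
        df = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0]})
        m = fit_logistic(df, ["HC", "HC", "GTS", "GTS"], ["x"], ridge=1e-6)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_statsmodels_mle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 3))
        eta = 0.4 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        ours = fit_logistic(df, ["GTS" if v else "HC" for v in y], ["a", "b", "c"], ridge=0.0)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(
            [ours.intercept, *(ours.coefficients[c] for c in "abc")], ref.params, atol=1e-6
        )

    def test_separable_data_warns_but_stays_finite(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]})
        labels = ["HC"] * 3 + ["GTS"] * 3
        with pytest.warns(SeparationWarning):
            m = fit_logistic(df, labels, ["x"], ridge=1e-6)
        assert m.separation
        assert np.isfinite(m.coefficients["x"])

    def test_standardization_returns_original_units(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.normal(50, 10, 60)})
        labels = ["GTS" if v > 50 else "HC" for v in df["x"] + rng.normal(0, 15, 60)]
        raw = fit_logistic(df, labels, ["x"], ridge=0.0)
        std = fit_logistic(df, labels, ["x"], ridge=0.0, standardize=True)
        assert std.coefficients["x"] == pytest.approx(raw.coefficients["x"], rel=1e-5)
        assert std.intercept == pytest.approx(raw.intercept, rel=1e-5)

    def test_rejects_degenerate_inputs(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError, match="both groups"):
            fit_logistic(df, ["GTS", "GTS"], ["x"])
        with pytest.raises(ValueError, match="finite"):
            fit_logistic(pd.DataFrame({"x": [np.nan, 1.0]}), ["GTS", "HC"], ["x"])


class TestPredict:
    def test_null_model_gives_half(self):
        df = pd.DataFrame({"x": [0] * 4})
        m = fit_logistic(df, ["GTS", "HC", "GTS", "HC"], [], ridge=0.0)
        np.testing.assert_allclose(predict_p_gts(m, df), 0.5)

    def test_intercept_only_closed_form(self):
        df = pd.DataFrame({"x": [0.0] * 4})
        # 3 GTS of 4 -> intercept ln(3) -> p = 0.75
        m = fit_logistic(df, ["GTS", "GTS", "GTS", "HC"], [], ridge=0.0)
        assert m.intercept == pytest.approx(np.log(3), abs=1e-6)
        assert predict_p_gts(m, df)[0] == pytest.approx(0.75, abs=1e-6)

    def test_name_mismatch_raises(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        m = fit_logistic(df, ["HC", "GTS", "GTS", "HC"], ["x"])
        with pytest.raises(KeyError, match="x"):
            predict_p_gts(m, pd.DataFrame({"y": [1.0]}))


class TestLeavePairOutCV:
    def test_one_fold_per_pair_one_prediction_per_video(self, small_cohort):
        tab = scores_table(small_cohort.videos)
        preds = leave_pair_out_cv(small_cohort.manifest(), tab, ["proportion_tic_intervals"])
        assert len(preds) == len(small_cohort.videos)
        assert len({p.fold_id for p in preds}) == small_cohort.n_pairs
        assert len({p.video_id for p in preds}) == len(preds)
        assert all(0.0 <= p.p_gts <= 1.0 for p in preds)

    def test_fold_refit_oracle(self, small_cohort):
        """Each video's p_gts is reproduced by an explicit refit on its complement."""
        manifest = small_cohort.manifest()
        tab = scores_table(small_cohort.videos)
        predictors = ["proportion_tic_intervals", "clusters_per_minute"]
        preds = leave_pair_out_cv(manifest, tab, predictors, ridge=1e-6)
        merged = manifest.merge(tab[["video_id", *predictors]], on="video_id")
        by_video = {p.video_id: p for p in preds}
        part = manifest.drop_duplicates("participant_id").set_index("participant_id")
        for vid, pred in by_video.items():
            row = merged.loc[merged["video_id"] == vid].iloc[0]
            members = {row["participant_id"], part.loc[row["participant_id"], "matched_partner_id"]}
            train = merged[~merged["participant_id"].isin(members)]
            model = fit_logistic(train, train["group"], predictors, ridge=1e-6)
            expected = predict_p_gts(model, merged.loc[merged["video_id"] == vid])[0]
            assert pred.p_gts == pytest.approx(expected, abs=1e-12)

    def test_held_out_videos_cannot_influence_their_fold_model(self, small_cohort):
        """Making one pair's videos extreme outliers leaves that pair's fold
        model untouched: its training complement never sees the perturbation."""
        manifest = small_cohort.manifest()
        tab = scores_table(small_cohort.videos)
        predictors = ["proportion_tic_intervals"]
        base = leave_pair_out_cv(manifest, tab, predictors)
        target_pair = base[0].fold_id
        members = set(target_pair.split("|"))
        perturbed = tab.copy()
        mask = perturbed["participant_id"].isin(members)
        perturbed.loc[mask, "proportion_tic_intervals"] += 1e6  # extreme outliers
        after = leave_pair_out_cv(manifest, perturbed, predictors)
        # fold model unchanged => predictions for the pair equal the original
        # fold model applied to the perturbed scores
        merged = manifest.merge(tab[["video_id", *predictors]], on="video_id")
        train = merged[~merged["participant_id"].isin(members)]
        fold_model = fit_logistic(train, train["group"], predictors)
        pert_rows = manifest.merge(perturbed[["video_id", *predictors]], on="video_id")
        for a in after:
            if a.fold_id == target_pair:
                expected = predict_p_gts(
                    fold_model, pert_rows[pert_rows["video_id"] == a.video_id]
                )[0]
                assert a.p_gts == pytest.approx(expected, abs=1e-12)

    def test_unmatched_participant_raises(self, small_cohort):
        manifest = small_cohort.manifest()
        tab = scores_table(small_cohort.videos)
        bad = manifest.copy()
        bad.loc[bad.index[0], "matched_partner_id"] = "nobody"
        with pytest.raises(ValueError, match="partner"):
            leave_pair_out_cv(bad, tab, ["proportion_tic_intervals"])

    def test_single_pair_cohort_has_one_class_folds(self):
        manifest = pd.DataFrame(
            {
                "video_id": ["a", "b"],
                "participant_id": ["g1", "h1"],
                "group": ["GTS", "HC"],
                "matched_partner_id": ["h1", "g1"],
            }
        )
        tab = pd.DataFrame({"video_id": ["a", "b"], "proportion_tic_intervals": [5.0, 1.0]})
        with pytest.raises(ValueError, match="fold"):
            leave_pair_out_cv(manifest, tab, ["proportion_tic_intervals"])


class TestMetrics:
    def test_balanced_accuracy_definition(self):
        # sensitivity 1.0 (2/2 GTS), specificity 0.8 (4/5 HC) -> 90%
        preds = _preds([0.9, 0.8, 0.1, 0.2, 0.3, 0.4, 0.6], ["GTS"] * 2 + ["HC"] * 5)
        assert balanced_accuracy(preds) == pytest.approx(90.0)
        assert balanced_accuracy(_preds([0.9, 0.1], ["GTS", "HC"])) == 100.0

    def test_balanced_accuracy_matches_confusion_matrix_oracle(self):
        rng = np.random.default_rng(11)
        p = rng.random(200)
        truth = rng.choice(["GTS", "HC"], 200)
        preds = _preds(p, truth)
        tp = sum(1 for pi, t in zip(p, truth) if t == "GTS" and pi >= 0.5)
        fn = sum(1 for pi, t in zip(p, truth) if t == "GTS" and pi < 0.5)
        tn = sum(1 for pi, t in zip(p, truth) if t == "HC" and pi < 0.5)
        fp = sum(1 for pi, t in zip(p, truth) if t == "HC" and pi >= 0.5)
        expected = 100 * (tp / (tp + fn) + tn / (tn + fp)) / 2
        assert balanced_accuracy(preds) == pytest.approx(expected)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            balanced_accuracy(_preds([0.9, 0.8], ["GTS", "GTS"]))
        with pytest.raises(ValueError):
            roc_auroc(_preds([0.9, 0.8], ["HC", "HC"]))

    def test_auroc_extremes(self):
        assert roc_auroc(_preds([0.9, 0.8, 0.1, 0.2], ["GTS", "GTS", "HC", "HC"])).auroc == 1.0
        assert roc_auroc(_preds([0.5] * 6, ["GTS"] * 3 + ["HC"] * 3)).auroc == 0.5

    def test_auroc_matches_pairwise_mann_whitney_count(self):
        rng = np.random.default_rng(3)
        p = np.round(rng.random(20), 1)  # rounding forces ties
        truth = ["GTS"] * 8 + ["HC"] * 12
        preds = _preds(p, truth)
        gts = p[:8]
        hc = p[8:]
        wins = sum((g > h) + 0.5 * (g == h) for g in gts for h in hc)
        assert roc_auroc(preds).auroc == pytest.approx(wins / (8 * 12))

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(8)
        roc = roc_auroc(_preds(rng.random(50), rng.choice(["GTS", "HC"], 50)))
        assert np.all(np.diff(roc.thresholds) >= 0)
        assert np.all(np.diff(roc.sensitivity) <= 0)  # non-increasing in threshold

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_auroc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(30)
        truth = ["GTS"] * 10 + ["HC"] * 20
        base = roc_auroc(_preds(p, truth)).auroc
        transformed = roc_auroc(_preds(p**3 / 2 + 0.1, truth)).auroc
        assert transformed == pytest.approx(base)

    def test_multivariate_likelihood_dominates_nested_univariate(self, small_cohort):
        tab = scores_table(small_cohort.videos)
        labels = tab["group"]
        full = fit_logistic(
            tab, labels, ["proportion_tic_intervals", "clusters_per_minute"], ridge=0.0
        )
        for sub in (["proportion_tic_intervals"], ["clusters_per_minute"]):
            nested = fit_logistic(tab, labels, sub, ridge=0.0)
            assert log_likelihood(full, tab, labels) >= log_likelihood(nested, tab, labels) - 1e-9


class TestCorrelation:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert score_rating_correlation(x, 2 * x) == pytest.approx(1.0)
        assert score_rating_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(21)
        x = rng.random(50)
        y = 0.5 * x + rng.random(50)
        num = np.mean((x - x.mean()) * (y - y.mean()))
        expected = num / (x.std() * y.std())
        assert score_rating_correlation(x, y) == pytest.approx(expected)

    def test_spearman_is_rank_based(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert score_rating_correlation(x, np.exp(x), method="spearman") == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            score_rating_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
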