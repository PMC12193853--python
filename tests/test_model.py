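"""Split plan, undersampling, standardization, Youden search, model results."""

import numpy as np
import pandas as pd
import pytest

from hypowatch.config import ModelingConfig
from hypowatch.model import (
    NotModelableError,
    PersonalizedHypoglycemiaModel,
    fit_tree_ensemble,
    make_split_plan,
    standardize,
    summarize_cohort,
    undersample_majority,
    youden_threshold,
)
from hypowatch.segmentation import Segment

T0 = pd.Timestamp("2024-03-01 00:00")


def _segments(n, event_idx, kind="night"):
    segs = []
    for i in range(n):
        s = Segment(f"P01_s{i}_{kind}", "P01", kind, T0 + pd.Timedelta(days=i), T0 + pd.Timedelta(days=i, hours=8))
        s.contains_event = i in event_idx
        segs.append(s)
    return segs


class TestSplitPlan:
    def test_one_iteration_per_event_segment(self):
        plan = make_split_plan(_segments(10, {1, 4, 7}))
        assert len(plan) == 3
        for test_id, train_ids in plan.iterations:
            assert len(train_ids) == 9 and test_id not in train_ids

    def test_single_event_among_five(self):
        plan = make_split_plan(_segments(5, {2}))
        assert len(plan) == 1 and len(plan.iterations[0][1]) == 4

    def test_all_segments_event_bearing(self):
        plan = make_split_plan(_segments(5, set(range(5))))
        assert len(plan) == 5
        assert all(len(t) == 4 for _, t in plan.iterations)

    def test_no_event_segment_is_not_modelable(self):
        with pytest.raises(NotModelableError):
            make_split_plan(_segments(5, set()))

    def test_single_segment_errors(self):
        with pytest.raises(NotModelableError):
            make_split_plan(_segments(1, {0}))


def _rows(n_neg, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range(T0, periods=n_neg + n_pos, freq="min")
    df = pd.DataFrame({"x": rng.normal(size=n_neg + n_pos)}, index=idx)
    df["label"] = [0] * n_neg + [1] * n_pos
    return df.sample(frac=1, random_state=seed).sort_index()


class TestUndersampling:
    def test_one_to_one_balance(self):
        out = undersample_majority(_rows(5000, 60), seed=0)
        assert (out["label"] == 1).sum() == 60 and (out["label"] == 0).sum() == 60

    def test_reproducible_per_seed_and_varies_across_seeds(self):
        rows = _rows(500, 20)
        a = undersample_majority(rows, seed=3)
        b = undersample_majority(rows, seed=3)
        c = undersample_majority(rows, seed=4)
        assert a.equals(b) and not a.equals(c)

    def test_minority_negatives_all_kept(self):
        out = undersample_majority(_rows(10, 40), seed=0)
        assert (out["label"] == 0).sum() == 10 and (out["label"] == 1).sum() == 40

    def test_temporal_order_preserved(self):
        out = undersample_majority(_rows(300, 30), seed=1)
        assert out.index.is_monotonic_increasing

    def test_zero_positives_invalid(self):
        with pytest.raises(ValueError, match="positive"):
            undersample_majority(_rows(100, 0), seed=0)


class TestStandardize:
    def test_zscore_uses_training_statistics(self):
        train = pd.DataFrame({"f": [60.0, 70.0, 80.0], "label": [0, 0, 1]})
        test = pd.DataFrame({"f": [80.0], "label": [1]})
        tr, te, params = standardize(train, test, ["f"])
        sd = np.std([60, 70, 80])
        assert te["f"].iloc[0] == pytest.approx((80 - 70) / sd)
        assert params.loc["f", "mean"] == 70.0

    def test_constant_column_centered_not_divided(self):
        train = pd.DataFrame({"f": [5.0, 5.0], "label": [0, 1]})
        tr, te, _ = standardize(train, train.copy(), ["f"])
        assert (tr["f"] == 0.0).all()

    def test_missing_cells_stay_missing(self):
        train = pd.DataFrame({"f": [1.0, np.nan, 3.0], "label": [0, 1, 1]})
        tr, _, _ = standardize(train, train.copy(), ["f"])
        assert np.isnan(tr["f"].iloc[1])


class TestYouden:
    def test_perfect_classifier(self):
        thr, sens, spec = youden_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert sens == 1.0 and spec == 1.0 and 0.2 < thr <= 0.8

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 60))
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            thr, sens, spec = youden_threshold(scores, labels)
            best_j, best_thr = -np.inf, None
            for t in np.unique(scores)[::-1]:
                pred = scores >= t
                s = (pred & (labels == 1)).sum() / (labels == 1).sum()
                p = (~pred & (labels == 0)).sum() / (labels == 0).sum()
                if s + p - 1 > best_j:
                    best_j, best_thr = s + p - 1, t
            assert sens + spec - 1 == pytest.approx(best_j)
            assert thr == pytest.approx(best_thr)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            youden_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestTreeEnsemble:
    def test_separable_toy_data_reaches_auroc_one(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=200)})
        y = (X["f"] > 0).astype(int).to_numpy()
        clf = fit_tree_ensemble(X, y, seed=0)
        from sklearn.metrics import roc_auc_score

        # held-out points keep a margin wider than the trees' split resolution
        f = rng.normal(size=300)
        f = f[np.abs(f) > 0.25][:80]
        Xt = pd.DataFrame({"f": f})
        yt = (Xt["f"] > 0).astype(int).to_numpy()
        assert roc_auc_score(yt, clf.predict_proba(Xt)[:, 1]) == 1.0

    def test_regularization_terms_set(self):
        clf = fit_tree_ensemble(pd.DataFrame({"f": [0.0, 1.0] * 10}), np.array([0, 1] * 10))
        assert clf.get_params()["reg_alpha"] == 10 and clf.get_params()["reg_lambda"] == 10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            fit_tree_ensemble(pd.DataFrame({"f": [1.0, 2.0]}), np.array([1, 1]))

    def test_refit_same_seed_identical_scores(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        y = rng.integers(0, 2, size=100)
        s1 = fit_tree_ensemble(X, y, seed=5).predict_proba(X)[:, 1]
        s2 = fit_tree_ensemble(X, y, seed=5).predict_proba(X)[:, 1]
        np.testing.assert_array_equal(s1, s2)


def _toy_model(signal=3.0, n_seg=5, seed=0, seeds_cfg=2):
    """Tiny synthetic (features, segments) pair with a controllable signal."""
    rng = np.random.default_rng(seed)
    segs = _segments(n_seg, set(range(n_seg)))
    frames = []
    for s in segs:
        idx = pd.date_range(s.start, s.end - pd.Timedelta(minutes=1), freq="min")
        n = len(idx)
        y = np.zeros(n, dtype=int)
        a = rng.integers(60, n - 120)
        y[a : a + 30] = 1
        from hypowatch.labeling import HypoEvent

        s.events = [HypoEvent(idx[a], idx[a + 29] + pd.Timedelta(minutes=1), s.segment_id)]
        df = pd.DataFrame(
            {
                "f1": rng.normal(size=n) + signal * y,
                "f2": rng.normal(size=n),
                "label": y,
                "segment_id": s.segment_id,
            },
            index=idx,
        )
        frames.append(df)
    feats = pd.concat(frames)
    cfg = ModelingConfig(n_undersample_seeds=seeds_cfg)
    return PersonalizedHypoglycemiaModel(feats, segs, "P01", "night", cfg), segs


class TestModelResults:
    def test_train_test_segments_disjoint_every_iteration(self):
        model, _ = _toy_model()
        for test_id, train_ids in model.split_plan.iterations:
            assert test_id not in train_ids
            test_idx = set(model.features[model.features.segment_id == test_id].index)
            train_idx = set(model.features[model.features.segment_id.isin(train_ids)].index)
            assert not (test_idx & train_idx)

    def test_strong_signal_gives_high_auroc_and_detections(self):
        model, _ = _toy_model(signal=4.0)
        res = model.fit(compute_attributions=False)
        assert res.auroc_mean > 0.9
        assert res.detection_any_rate > 0.9
        assert res.n_events == 5

    def test_auroc_invariant_under_monotone_score_transform(self, rng):
        """AUROC is rank-based: squashing scores through a monotone map keeps it."""
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=300)
        labels = rng.integers(0, 2, size=300)
        a = roc_auc_score(labels, scores)
        b = roc_auc_score(labels, 1 / (1 + np.exp(-5 * scores)))
        assert a == pytest.approx(b)

    def test_shuffled_labels_interval_covers_chance(self):
        """Segment-preserving label shuffles: no real association, AUROC ~ 0.5."""
        rng = np.random.default_rng(0)
        aurocs = []
        for trial in range(4):
            model, segs = _toy_model(signal=4.0, seed=trial)
            feats = model.features.copy()
            for sid, grp in feats.groupby("segment_id"):
                perm = rng.permutation(len(grp))
                feats.loc[grp.index, "label"] = grp["label"].to_numpy()[perm]
            for s in segs:  # re-anchor events onto shuffled labels: skip detection
                s.events = []
            cfg = ModelingConfig(n_undersample_seeds=2)
            shuffled = PersonalizedHypoglycemiaModel(feats, segs, "P01", "night", cfg)
            res = shuffled.fit(compute_attributions=False)
            aurocs.append(res.auroc_mean)
        mean, sd = np.mean(aurocs), np.std(aurocs, ddof=1)
        half = 1.96 * sd / np.sqrt(len(aurocs))
        assert mean - half <= 0.5 <= mean + half

    def test_test_sets_keep_natural_imbalance(self):
        model, _ = _toy_model()
        test_id = model.split_plan.iterations[0][0]
        test = model.features[model.features.segment_id == test_id]
        assert (test["label"] == 1).sum() == 30  # untouched by resampling

    def test_aggregation_identity_and_mean(self):
        model, _ = _toy_model(seeds_cfg=1)
        res = model.fit(seeds=[0], compute_attributions=False)
        per_iter = res.frame[res.frame.valid]
        assert res.auroc_mean == pytest.approx(per_iter["auroc"].mean())
        mn, mx = per_iter["auroc"].min(), per_iter["auroc"].max()
        assert mn <= res.auroc_mean <= mx

    def test_summary_contains_key_metrics(self):
        model, _ = _toy_model()
        res = model.fit(compute_attributions=False)
        text = res.summary()
        assert "AUROC" in text and "P01" in text and "night" in text

    def test_cohort_summary_means(self):
        model, _ = _toy_model(seed=1)
        model2, _ = _toy_model(seed=2)
        r1 = model.fit(compute_attributions=False)
        r2 = model2.fit(compute_attributions=False)
        rep = summarize_cohort([r1, r2])
        assert rep.auroc_mean == pytest.approx((r1.auroc_mean + r2.auroc_mean) / 2)
        assert len(rep.per_model) == 2
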