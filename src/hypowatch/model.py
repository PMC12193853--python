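"""Personalized hypoglycemia detection models.

One model per (participant, day|night) pair, trained and evaluated only on
that participant's own data through an iterative leave-hypo-segment-out
split: each event-bearing segment is singled out once as the test set while
every other segment of the same kind forms the training set. Minutes of one
segment never appear on both sides of a split, which is what makes the
evaluation honest for non-i.i.d. time series.

Each iteration trains a gradient-boosted tree ensemble (XGBoost, L1 = L2 = 10,
remaining hyperparameters at library defaults) on a class-balanced training
set obtained by random undersampling of the majority (non-hypo) minutes; the
test segment keeps its natural imbalance. Undersampling is repeated over
``n_undersample_seeds`` random states and results averaged. Discrimination is
summarized by AUROC; an operating point is chosen by maximizing Youden's
J = sensitivity + specificity - 1, and event-level detection (any minute of
the event / any of its first 15 minutes flagged) is reported at that point.

Usage follows the statsmodels pattern::

    model = PersonalizedHypoglycemiaModel(features, segments, "P01", "day")
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .config import ModelingConfig
from .segmentation import Segment


class NotModelableError(ValueError):
    """Raised when a (participant, kind) dataset cannot support the split."""


@dataclass
class SplitPlan:
    """Ordered leave-hypo-segment-out iterations."""

    iterations: list[tuple[str, list[str]]]  # (test_segment_id, train_segment_ids)

    def __len__(self) -> int:
        return len(self.iterations)


def make_split_plan(segments: Sequence[Segment]) -> SplitPlan:
    """One iteration per event-bearing segment; the rest of the same kind train.

    Raises :class:`NotModelableError` when no segment carries an event or only
    a single segment exists (no training data would remain).
    """
    seg_ids = [s.segment_id for s in segments]
    if len(seg_ids) < 2:
        raise NotModelableError("need at least 2 segments to form a train/test split")
    event_ids = [s.segment_id for s in segments if s.contains_event]
    if not event_ids:
        raise NotModelableError("no event-bearing segment; nothing to hold out")
    iterations = [(t, [s for s in seg_ids if s != t]) for t in event_ids]
    return SplitPlan(iterations)


def undersample_majority(rows: pd.DataFrame, seed: int, ratio: float = 1.0) -> pd.DataFrame:
    """Randomly drop majority-class (label 0) rows down to ``ratio`` x positives.

    Positives are untouched; retained rows keep their temporal order. When
    negatives are already at or below the target count, all are kept (no
    upsampling). Reproducible for a given seed.
    """
    pos = rows[rows["label"] == 1]
    neg = rows[rows["label"] == 0]
    if len(pos) == 0:
        raise ValueError("training rows contain no positive minutes; split plan invalid")
    n_keep = int(round(ratio * len(pos)))
    if len(neg) > n_keep:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(neg), size=n_keep, replace=False)
        neg = neg.iloc[np.sort(keep)]
    out = pd.concat([pos, neg]).sort_index(kind="stable")
    return out


def standardize(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_cols: Sequence[str],
    scope: str = "train",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-feature z-scoring; statistics from the training rows only by default.

    ``scope="global"`` reproduces a pooled-statistics variant (train + test
    together). Missing cells stay missing; zero-variance features are centered
    but not divided.
    """
    if scope == "train":
        ref = train[feature_cols]
    elif scope == "global":
        ref = pd.concat([train[feature_cols], test[feature_cols]])
    else:
        raise ValueError(f"unknown standardization scope {scope!r}")
    mean = ref.mean(skipna=True)
    sd = ref.std(skipna=True, ddof=0)
    sd = sd.replace(0.0, 1.0).fillna(1.0)
    train_s, test_s = train.copy(), test.copy()
    train_s[list(feature_cols)] = (train[feature_cols] - mean) / sd
    test_s[list(feature_cols)] = (test[feature_cols] - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return train_s, test_s, params


def fit_tree_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    reg_alpha: float = 10.0,
    reg_lambda: float = 10.0,
) -> XGBClassifier:
    """Gradient-boosted tree binary classifier with L1 = L2 regularization.

    Everything else stays at the library defaults; missing feature values are
    handled natively by the trees (learned default split directions).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training data; cannot fit a classifier")
    clf = XGBClassifier(
        reg_alpha=reg_alpha,
        reg_lambda=reg_lambda,
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        tree_method="hist",
    )
    clf.fit(X, y)
    return clf


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Operating point maximizing J = sensitivity + specificity - 1.

    The search runs over all distinct score cut-points (predict positive when
    score >= threshold); ties in J are broken toward the higher threshold.
    Returns (threshold, sensitivity, specificity).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; Youden's J undefined")
    thr = np.unique(scores)[::-1]  # candidate cut-points, descending
    pos, neg = scores[labels == 1], scores[labels == 0]
    # integer counts keep J exact, so ties break cleanly toward high thresholds
    tp = len(pos) - np.searchsorted(np.sort(pos), thr, side="left")
    fp = len(neg) - np.searchsorted(np.sort(neg), thr, side="left")
    sens = tp / len(pos)
    spec = 1.0 - fp / len(neg)
    j = sens + spec - 1.0
    jmax = j.max()
    best = int(np.flatnonzero(j >= jmax - 1e-12)[0])  # first = highest threshold
    return float(thr[best]), float(sens[best]), float(spec[best])


@dataclass
class EventDetection:
    segment_id: str
    start: pd.Timestamp
    detected_any: bool
    detected_first15: bool


@dataclass
class IterationResult:
    """Metrics of one (held-out segment, undersampling seed) evaluation."""

    test_segment_id: str
    undersample_seed: int
    valid: bool
    auroc: float = np.nan
    youden_threshold: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    events: list[EventDetection] = field(default_factory=list)
    mean_abs_attribution: Optional[pd.Series] = None
    reason: str = ""


class PersonalizedHypoglycemiaModel:
    """Leave-hypo-segment-out model for one participant and diurnal kind.

    Parameters
    ----------
    features : feature matrix as built by
        :func:`hypowatch.features.build_feature_matrix` — schema feature
        columns plus ``label`` and ``segment_id``, minute-indexed.
    segments : the participant's segments of this kind, with
        ``contains_event`` flags and attached qualifying events.
    participant_id, kind : identification carried into the results.
    config : modeling settings (seeds, regularization, thresholds).
    """

    def __init__(
        self,
        features: pd.DataFrame,
        segments: Sequence[Segment],
        participant_id: str,
        kind: str,
        config: ModelingConfig | None = None,
    ) -> None:
        self.config = config or ModelingConfig()
        self.participant_id = participant_id
        self.kind = kind
        self.feature_cols = [c for c in features.columns if c not in ("label", "segment_id")]
        self.features = features
        self.segments = [s for s in segments if s.kind == kind]
        self.split_plan = make_split_plan(self.segments)
        self._seg_by_id = {s.segment_id: s for s in self.segments}

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        segments: Sequence[Segment],
        participant_id: str,
        kind: str,
        config: ModelingConfig | None = None,
    ) -> "PersonalizedHypoglycemiaModel":
        """Construct from a flat exported feature table (label + segment_id columns)."""
        return cls(df, segments, participant_id, kind, config)

    # ------------------------------------------------------------------
    def _rows_for(self, segment_ids: Sequence[str]) -> pd.DataFrame:
        return self.features[self.features["segment_id"].isin(segment_ids)]

    def fit(
        self,
        seeds: Sequence[int] | None = None,
        compute_attributions: bool = True,
    ) -> "PersonalizedResults":
        """Run every split iteration under every undersampling seed."""
        cfg = self.config
        if seeds is None:
            seeds = list(range(cfg.n_undersample_seeds))
        results: list[IterationResult] = []
        for test_id, train_ids in self.split_plan.iterations:
            train_all = self._rows_for(train_ids)
            test = self._rows_for([test_id])
            for seed in seeds:
                results.append(
                    self._run_one(train_all, test, test_id, int(seed), compute_attributions)
                )
        return PersonalizedResults(self, results)

    def _run_one(
        self,
        train_all: pd.DataFrame,
        test: pd.DataFrame,
        test_id: str,
        seed: int,
        compute_attributions: bool,
    ) -> IterationResult:
        cfg = self.config
        if test["label"].nunique() < 2:
            return IterationResult(test_id, seed, valid=False, reason="one-class test segment")
        try:
            train = undersample_majority(train_all, seed, cfg.undersample_ratio)
        except ValueError as exc:
            return IterationResult(test_id, seed, valid=False, reason=str(exc))
        if train["label"].nunique() < 2:
            return IterationResult(test_id, seed, valid=False, reason="one-class training data")

        train_s, test_s, _ = standardize(train, test, self.feature_cols, cfg.standardize_scope)
        clf = fit_tree_ensemble(
            train_s[self.feature_cols],
            train_s["label"].to_numpy(),
            seed=seed,
            reg_alpha=cfg.reg_alpha,
            reg_lambda=cfg.reg_lambda,
        )
        scores = clf.predict_proba(test_s[self.feature_cols])[:, 1]
        y_test = test_s["label"].to_numpy()
        auroc = float(roc_auc_score(y_test, scores))

        if cfg.threshold_source == "train":
            tr_scores = clf.predict_proba(train_s[self.feature_cols])[:, 1]
            thr, _, _ = youden_threshold(tr_scores, train_s["label"].to_numpy())
            pred = scores >= thr
            tp = int(((pred == 1) & (y_test == 1)).sum())
            fn = int(((pred == 0) & (y_test == 1)).sum())
            tn = int(((pred == 0) & (y_test == 0)).sum())
            fp = int(((pred == 1) & (y_test == 0)).sum())
            sens = tp / (tp + fn) if tp + fn else np.nan
            spec = tn / (tn + fp) if tn + fp else np.nan
        else:
            thr, sens, spec = youden_threshold(scores, y_test)

        detections = []
        score_s = pd.Series(scores, index=test_s.index)
        seg = self._seg_by_id[test_id]
        for ev in seg.events:
            ev_scores = score_s.loc[ev.start : ev.end - pd.Timedelta(minutes=1)]
            first15 = score_s.loc[ev.start : ev.start + pd.Timedelta(minutes=14)]
            detections.append(
                EventDetection(
                    segment_id=test_id,
                    start=ev.start,
                    detected_any=bool((ev_scores >= thr).any()),
                    detected_first15=bool((first15 >= thr).any()),
                )
            )

        mean_abs = None
        if compute_attributions:
            from .interpret import feature_attributions

            contrib = feature_attributions(clf, test_s[self.feature_cols])
            mean_abs = contrib.abs().mean(axis=0)

        return IterationResult(
            test_id,
            seed,
            valid=True,
            auroc=auroc,
            youden_threshold=float(thr),
            sensitivity=float(sens),
            specificity=float(spec),
            events=detections,
            mean_abs_attribution=mean_abs,
        )


class PersonalizedResults:
    """Fit results of one personalized model.

    Per-iteration metrics are first averaged over undersampling seeds within
    each held-out segment, then over held-out segments, so every hypoglycemic
    day/night contributes equally regardless of how many seeds were run.
    """

    def __init__(self, model: PersonalizedHypoglycemiaModel, iterations: list[IterationResult]):
        self.model = model
        self.iterations = iterations

    # ------------------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "test_segment_id": r.test_segment_id,
                "seed": r.undersample_seed,
                "valid": r.valid,
                "auroc": r.auroc,
                "threshold": r.youden_threshold,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for r in self.iterations
        ]
        return pd.DataFrame(rows)

    @property
    def n_valid(self) -> int:
        return int(self.frame["valid"].sum())

    def _per_iteration(self) -> pd.DataFrame:
        df = self.frame
        df = df[df["valid"]]
        return df.groupby("test_segment_id")[["auroc", "sensitivity", "specificity"]].mean()

    @property
    def auroc_mean(self) -> float:
        per_it = self._per_iteration()
        return float(per_it["auroc"].mean()) if len(per_it) else np.nan

    @property
    def auroc_sd(self) -> float:
        df = self.frame
        vals = df.loc[df["valid"], "auroc"]
        return float(vals.std(ddof=1)) if len(vals) > 1 else np.nan

    @property
    def sensitivity_mean(self) -> float:
        per_it = self._per_iteration()
        return float(per_it["sensitivity"].mean()) if len(per_it) else np.nan

    @property
    def specificity_mean(self) -> float:
        per_it = self._per_iteration()
        return float(per_it["specificity"].mean()) if len(per_it) else np.nan

    @property
    def event_detections(self) -> pd.DataFrame:
        rows = []
        for r in self.iterations:
            if not r.valid:
                continue
            for d in r.events:
                rows.append(
                    {
                        "segment_id": d.segment_id,
                        "event_start": d.start,
                        "seed": r.undersample_seed,
                        "detected_any": d.detected_any,
                        "detected_first15": d.detected_first15,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def detection_any_rate(self) -> float:
        det = self.event_detections
        return float(det["detected_any"].mean()) if len(det) else np.nan

    @property
    def detection_first15_rate(self) -> float:
        det = self.event_detections
        return float(det["detected_first15"].mean()) if len(det) else np.nan

    @property
    def n_events(self) -> int:
        det = self.event_detections
        return int(det.groupby(["segment_id", "event_start"]).ngroups) if len(det) else 0

    # ------------------------------------------------------------------
    def feature_importance(self) -> pd.Series:
        """Per-feature relative importance (%) from mean |Shapley attribution|.

        Attribution magnitudes are averaged over all valid (iteration, seed)
        evaluations on held-out rows, then normalized to percentages within
        this model.
        """
        mats = [r.mean_abs_attribution for r in self.iterations if r.valid and r.mean_abs_attribution is not None]
        if not mats:
            raise ValueError("no attributions available (fit with compute_attributions=True)")
        mean_abs = pd.concat(mats, axis=1).mean(axis=1)
        total = mean_abs.sum()
        if total == 0:
            return mean_abs * 0.0
        return 100.0 * mean_abs / total

    def category_importance(self) -> pd.Series:
        from .interpret import aggregate_importance

        return aggregate_importance([self.feature_importance()]).category_percent

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Personalized Hypoglycemia Detection Results",
            "=" * 56,
            f"Participant:            {self.model.participant_id}",
            f"Diurnal kind:           {self.model.kind}",
            f"Split iterations:       {len(self.model.split_plan)}",
            f"Undersampling seeds:    {self.frame['seed'].nunique()}",
            f"Valid evaluations:      {self.n_valid}/{len(self.iterations)}",
            "-" * 56,
            f"AUROC (mean +/- SD):    {self.auroc_mean:.3f} +/- {self.auroc_sd:.3f}",
            f"Sensitivity (Youden):   {self.sensitivity_mean:.3f}",
            f"Specificity (Youden):   {self.specificity_mean:.3f}",
            f"Events detected (any):  {100 * self.detection_any_rate:.1f}% of {self.n_events}",
            f"Events detected (<=15min): {100 * self.detection_first15_rate:.1f}%",
            "=" * 56,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PersonalizedResults {self.model.participant_id}/{self.model.kind} "
            f"AUROC={self.auroc_mean:.3f}>"
        )


# ---------------------------------------------------------------------------
# cohort-level aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortReport:
    """Mean +/- SD over personalized models plus pooled event detection."""

    per_model: pd.DataFrame
    auroc_mean: float
    auroc_sd: float
    sensitivity_mean: float
    specificity_mean: float
    detection_any_rate: float
    detection_first15_rate: float
    n_events: int
    category_importance: dict[str, pd.Series]

    def summary(self) -> str:
        lines = [
            "Cohort Summary (personalized models)",
            "=" * 56,
            f"Models:                 {len(self.per_model)}",
            f"AUROC:                  {self.auroc_mean:.3f} +/- {self.auroc_sd:.3f}",
            f"Sensitivity:            {self.sensitivity_mean:.3f}",
            f"Specificity:            {self.specificity_mean:.3f}",
            f"Events detected (any):  {100 * self.detection_any_rate:.1f}% of {self.n_events}",
            f"Events detected (<=15min): {100 * self.detection_first15_rate:.1f}%",
        ]
        for kind, cat in self.category_importance.items():
            lines.append("-" * 56)
            lines.append(f"{kind.capitalize()} feature-category importance (%):")
            for name, pct in cat.sort_values(ascending=False).items():
                lines.append(f"  {name:<14} {pct:5.1f}")
        lines.append("=" * 56)
        return "\n".join(lines)


def summarize_cohort(results: Sequence[PersonalizedResults]) -> CohortReport:
    """Aggregate personalized results: model-level means, pooled detections."""
    from .interpret import aggregate_importance

    results = [r for r in results if r.n_valid > 0]
    if not results:
        raise ValueError("no valid personalized models to summarize")
    rows = [
        {
            "participant_id": r.model.participant_id,
            "kind": r.model.kind,
            "n_iterations": len(r.model.split_plan),
            "auroc": r.auroc_mean,
            "sensitivity": r.sensitivity_mean,
            "specificity": r.specificity_mean,
        }
        for r in results
    ]
    per_model = pd.DataFrame(rows)
    det = pd.concat([r.event_detections for r in results], ignore_index=True)
    cat: dict[str, pd.Series] = {}
    for kind in ("day", "night"):
        kind_res = [r for r in results if r.model.kind == kind]
        if not kind_res:
            continue
        try:
            cat[kind] = aggregate_importance(
                [r.feature_importance() for r in kind_res]
            ).category_percent
        except ValueError:
            # attributions not computed, or features outside the standard schema
            pass
    return CohortReport(
        per_model=per_model,
        auroc_mean=float(per_model["auroc"].mean()),
        auroc_sd=float(per_model["auroc"].std(ddof=1)) if len(per_model) > 1 else np.nan,
        sensitivity_mean=float(per_model["sensitivity"].mean()),
        specificity_mean=float(per_model["specificity"].mean()),
        detection_any_rate=float(det["detected_any"].mean()) if len(det) else np.nan,
        detection_first15_rate=float(det["detected_first15"].mean()) if len(det) else np.nan,
        n_events=int(det.groupby(["segment_id", "event_start"]).ngroups) if len(det) else 0,
        category_importance=cat,
    )
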