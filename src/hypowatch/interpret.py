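"""Shapley feature attributions and category-level importance.

Per-prediction attributions come from the exact TreeSHAP algorithm built into
XGBoost (``pred_contribs=True``), which computes, for every row, an additive
decomposition of the model's margin output over features: base value plus the
per-feature contributions equals the raw margin exactly (local accuracy).

Importance is summarized as the mean absolute attribution per feature over
held-out rows, normalized to percentages within a model, and rolled up into
five physiological categories: cardiac (heart-rate and HRV features),
activity (steps, active energy), respiratory (blood oxygen, respiratory
rate), manual (diary-derived meal and insulin features) and time (the cyclic
hour-of-day encoding). Cohort-level importance is the mean of the per-model
percentages, so each personalized model weighs equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost

CATEGORY_MAP: dict[str, str] = {
    "hr_ra10": "cardiac",
    "hr_ra30": "cardiac",
    "hr_ra60": "cardiac",
    "hrv_last": "cardiac",
    "hrv_delta": "cardiac",
    "steps_rs30": "activity",
    "steps_rs60": "activity",
    "energy_rs30": "activity",
    "energy_rs60": "activity",
    "bos_last": "respiratory",
    "rr_last": "respiratory",
    "time_since_meal": "manual",
    "insulin_on_board": "manual",
    "tod_sin": "time",
    "tod_cos": "time",
}

CATEGORIES = ("cardiac", "activity", "respiratory", "manual", "time")


def feature_attributions(clf, rows: pd.DataFrame) -> pd.DataFrame:
    """Exact per-row, per-feature Shapley attributions for a tree ensemble.

    Returns a DataFrame aligned with ``rows`` (one attribution column per
    feature); the expected-value (bias) column is dropped. Raises when the
    row columns do not match the features the model was trained on.
    """
    booster = clf.get_booster()
    trained = list(booster.feature_names or [])
    if trained and trained != list(rows.columns):
        raise ValueError(
            f"feature-name mismatch: model trained on {trained}, got {list(rows.columns)}"
        )
    dmat = xgboost.DMatrix(rows, feature_names=trained or list(rows.columns))
    contrib = booster.predict(dmat, pred_contribs=True)
    return pd.DataFrame(contrib[:, :-1], index=rows.index, columns=rows.columns)


def local_accuracy_residuals(clf, rows: pd.DataFrame) -> np.ndarray:
    """Per-row |base + sum(attributions) - margin|; ~0 by construction."""
    booster = clf.get_booster()
    dmat = xgboost.DMatrix(rows, feature_names=list(rows.columns))
    contrib = booster.predict(dmat, pred_contribs=True)
    margin = booster.predict(dmat, output_margin=True)
    return np.abs(contrib.sum(axis=1) - margin)


@dataclass
class ImportanceReport:
    """Relative importance, per feature and per category, in percent."""

    feature_percent: pd.Series
    category_percent: pd.Series
    level: str  # "per-model" | "cohort-average"


def aggregate_importance(
    per_model_percent: Sequence[pd.Series],
    category_map: dict[str, str] | None = None,
) -> ImportanceReport:
    """Average per-model percentage shares and roll them up into categories.

    Each input Series is one model's per-feature importance in percent
    (summing to 100); the cohort value of a feature is the mean of its share
    across models, so a category's percentage always equals the sum of its
    member features' percentages.
    """
    category_map = category_map or CATEGORY_MAP
    per_model_percent = list(per_model_percent)
    if not per_model_percent:
        raise ValueError("no importance vectors to aggregate")
    for s in per_model_percent:
        unmapped = [f for f in s.index if f not in category_map]
        if unmapped:
            raise ValueError(f"features without a category: {unmapped}")
    avg = pd.concat(per_model_percent, axis=1).mean(axis=1)
    cats = avg.groupby(avg.index.map(category_map)).sum()
    level = "per-model" if len(per_model_percent) == 1 else "cohort-average"
    return ImportanceReport(feature_percent=avg, category_percent=cats, level=level)


def importance_table(report: ImportanceReport, category_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Long-format (category, feature, percent) table, categories ordered by weight."""
    category_map = category_map or CATEGORY_MAP
    rows = []
    order = report.category_percent.sort_values(ascending=False)
    for cat, cat_pct in order.items():
        members = [f for f in report.feature_percent.index if category_map[f] == cat]
        for f in members:
            rows.append(
                {
                    "category": cat,
                    "category_percent": round(float(cat_pct), 1),
                    "feature": f,
                    "feature_percent": round(float(report.feature_percent[f]), 1),
                }
            )
    return pd.DataFrame(rows)


def plot_category_importance(reports: dict[str, ImportanceReport], path=None):
    """Grouped bar chart of category importance for day/night models."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.8 / max(1, len(reports))
    x = np.arange(len(CATEGORIES))
    for i, (kind, rep) in enumerate(reports.items()):
        vals = [float(rep.category_percent.get(c, 0.0)) for c in CATEGORIES]
        ax.bar(x + i * width, vals, width=width, label=kind)
    ax.set_xticks(x + width * (len(reports) - 1) / 2)
    ax.set_xticklabels(CATEGORIES, rotation=20)
    ax.set_ylabel("relative importance (%)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
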