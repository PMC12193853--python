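"""Feature engineering on the imputed minute grid.

Fifteen input variables are derived in total; the waking models use 13 of
them and the sleeping models 10, reflecting which channels are informative
(step counts are irrelevant in bed) and which are measured at all (the watch
records respiratory rate and blood oxygen only during sleep):

* cardiac — trailing 10/30/60-min rolling means of heart rate; last measured
  HRV; HRV change from the previous measurement (when one exists);
* activity (waking only) — trailing 30/60-min rolling sums of step count and
  active energy;
* respiratory (sleeping only) — last blood oxygen saturation, last
  respiratory rate;
* time — sine and cosine of the (fractional) hour of day;
* manual — whole hours since the last diary meal (waking only) and a
  stepwise insulin-on-board fraction.

Every feature at minute t is a function of data at minutes <= t only; the
rolling windows are trailing and the diary features look strictly backward.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import DAY, NIGHT, Segment
from .timeline import FLAG_OBSERVED, ParticipantTimeline

ROLLING_MEAN_WINDOWS = (10, 30, 60)
ROLLING_SUM_WINDOWS = (30, 60)

#: waking-model schema (13 features)
DAY_FEATURES = [
    "hr_ra10",
    "hr_ra30",
    "hr_ra60",
    "hrv_last",
    "hrv_delta",
    "steps_rs30",
    "steps_rs60",
    "energy_rs30",
    "energy_rs60",
    "tod_sin",
    "tod_cos",
    "time_since_meal",
    "insulin_on_board",
]

#: sleeping-model schema (10 features). time_since_meal is omitted at night:
#: hours-since-dinner saturates at its cap for most of the night and carries
#: essentially no within-night information.
NIGHT_FEATURES = [
    "hr_ra10",
    "hr_ra30",
    "hr_ra60",
    "hrv_last",
    "hrv_delta",
    "bos_last",
    "rr_last",
    "tod_sin",
    "tod_cos",
    "insulin_on_board",
]

ALL_FEATURES = sorted(set(DAY_FEATURES) | set(NIGHT_FEATURES) | {"steps_rs30"})

MEAL_FEATURES = ["time_since_meal"]

SCHEMA_VERSION = "hypowatch-features/1"


def rolling_mean(values: pd.Series, window_minutes: int) -> pd.Series:
    """Trailing mean over the window ending at the current minute.

    Computed over the non-missing values in the window; missing only when the
    whole window is missing. Window sizes are restricted to the configured
    set so exported schemas stay stable.
    """
    if window_minutes not in ROLLING_MEAN_WINDOWS:
        raise ValueError(f"window {window_minutes} not in {ROLLING_MEAN_WINDOWS}")
    return values.rolling(window=window_minutes, min_periods=1).mean()


def rolling_sum(values: pd.Series, window_minutes: int) -> pd.Series:
    """Trailing sum over the window; missing counts contribute 0."""
    if window_minutes not in ROLLING_SUM_WINDOWS:
        raise ValueError(f"window {window_minutes} not in {ROLLING_SUM_WINDOWS}")
    return values.fillna(0.0).rolling(window=window_minutes, min_periods=1).sum()


def hrv_features(timeline: ParticipantTimeline) -> tuple[pd.Series, pd.Series]:
    """(hrv_last, hrv_delta) from the imputed column and the raw observations.

    ``hrv_last`` is the bounded forward-filled column. ``hrv_delta`` is the
    difference between the two most recent raw observations, held constant
    until the next observation arrives, and missing while fewer than two
    observations exist.
    """
    hrv_last = timeline.data["hrv"]
    observed = timeline.flags["hrv"] == FLAG_OBSERVED
    obs = timeline.data["hrv"][observed]
    delta_at_obs = obs.diff()
    hrv_delta = pd.Series(np.nan, index=timeline.index)
    hrv_delta.loc[delta_at_obs.index] = delta_at_obs.to_numpy()
    hrv_delta = hrv_delta.ffill()
    return hrv_last, hrv_delta


def encode_time_of_day(index: pd.DatetimeIndex) -> tuple[pd.Series, pd.Series]:
    """Cyclic encoding of the fractional hour of day onto the unit circle."""
    h = index.hour + index.minute / 60.0
    ang = 2.0 * np.pi * h / 24.0
    return (
        pd.Series(np.sin(ang), index=index, name="tod_sin"),
        pd.Series(np.cos(ang), index=index, name="tod_cos"),
    )


def time_since_last_meal(
    meal_times: pd.Series | list, index: pd.DatetimeIndex, cap_hours: int = 12
) -> pd.Series:
    """Whole hours elapsed since the most recent meal (floor), capped.

    Missing before the first recorded meal. The cap bounds the ordinal range
    overnight; without it the feature would grow without limit during sleep.
    """
    meals = pd.DatetimeIndex(pd.Series(meal_times)).sort_values()
    out = pd.Series(np.nan, index=index)
    if len(meals) == 0:
        return out
    pos = meals.searchsorted(index, side="right") - 1
    valid = pos >= 0
    last = meals.to_numpy()[np.clip(pos, 0, None)]
    hours = (index.to_numpy() - last) / np.timedelta64(1, "h")
    out[valid] = np.minimum(np.floor(hours[valid]), cap_hours)
    return out


def insulin_on_board(
    dose_times: pd.Series | list, index: pd.DatetimeIndex
) -> pd.Series:
    """Stepwise insulin-on-board fraction from the most recent short-acting dose.

    The dose decays 100% -> 75% -> 50% -> 25% over the four hours after
    administration (hour k after the dose, half-open (k-1, k], maps to the
    k-th step) and 0 afterwards or when no dose was logged. Doses are binary
    diary ticks without units, so overlapping doses do not stack: the most
    recent dose resets the clock.
    """
    doses = pd.DatetimeIndex(pd.Series(dose_times)).sort_values()
    out = pd.Series(0.0, index=index)
    if len(doses) == 0:
        return out
    pos = doses.searchsorted(index, side="right") - 1
    valid = pos >= 0
    last = doses.to_numpy()[np.clip(pos, 0, None)]
    hours = (index.to_numpy() - last) / np.timedelta64(1, "h")
    k = np.maximum(np.ceil(hours), 1.0)  # dose minute itself belongs to hour 1
    frac = np.select([k == 1, k == 2, k == 3, k == 4], [1.0, 0.75, 0.5, 0.25], default=0.0)
    out[valid] = frac[valid]
    return out


def compute_features(
    timeline: ParticipantTimeline,
    diary: pd.DataFrame,
    include_meal: bool = True,
    meal_cap_hours: int = 12,
) -> pd.DataFrame:
    """All 15 engineered variables on the full minute grid."""
    idx = timeline.index
    feats = pd.DataFrame(index=idx)
    for w in ROLLING_MEAN_WINDOWS:
        feats[f"hr_ra{w}"] = rolling_mean(timeline.data["hr"], w)
    feats["hrv_last"], feats["hrv_delta"] = hrv_features(timeline)
    feats["bos_last"] = timeline.data["bos"]
    feats["rr_last"] = timeline.data["rr"]
    for w in ROLLING_SUM_WINDOWS:
        feats[f"steps_rs{w}"] = rolling_sum(timeline.data["steps"], w)
        feats[f"energy_rs{w}"] = rolling_sum(timeline.data["energy"], w)
    feats["tod_sin"], feats["tod_cos"] = encode_time_of_day(idx)
    if include_meal:
        meals = diary.loc[diary["entry_type"] == "meal", "timestamp"]
        feats["time_since_meal"] = time_since_last_meal(meals, idx, meal_cap_hours)
    doses = diary.loc[diary["entry_type"] == "insulin", "timestamp"]
    feats["insulin_on_board"] = insulin_on_board(doses, idx)
    return feats


def schema_for(kind: str, include_meal: bool = True) -> list[str]:
    if kind == DAY:
        cols = list(DAY_FEATURES)
    elif kind == NIGHT:
        cols = list(NIGHT_FEATURES)
    else:
        raise ValueError(f"unknown diurnal kind {kind!r}")
    if not include_meal:
        cols = [c for c in cols if c not in MEAL_FEATURES]
    return cols


def build_feature_matrix(
    timeline: ParticipantTimeline,
    diary: pd.DataFrame,
    segments: list[Segment],
    labels: pd.Series,
    kind: str,
    include_meal: bool = True,
) -> pd.DataFrame:
    """Feature rows for every minute in segments of one diurnal kind.

    Returns the schema's feature columns plus ``label`` and ``segment_id``
    bookkeeping columns; rows keep their minute timestamps as the index.
    """
    cols = schema_for(kind, include_meal)
    feats = compute_features(timeline, diary, include_meal=include_meal)
    parts = []
    for seg in segments:
        if seg.kind != kind:
            continue
        rows = feats.loc[seg.start : seg.end - pd.Timedelta(minutes=1), cols].copy()
        rows["label"] = labels.loc[rows.index].to_numpy()
        rows["segment_id"] = seg.segment_id
        parts.append(rows)
    if not parts:
        return pd.DataFrame(columns=cols + ["label", "segment_id"])
    return pd.concat(parts)


def write_features(matrix: pd.DataFrame, path) -> None:
    """Export a feature matrix as CSV with a schema-version header line."""
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        matrix.to_csv(fh, index_label="timestamp")
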