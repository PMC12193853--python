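"""Minute-grid assembly of multi-rate sensor streams with bounded, leakage-safe imputation.

Raw smartwatch and CGM channels arrive at different cadences (glucose every
5 min, heart rate every minute, HRV every 15-30 min, ...). All downstream
stages operate on a single per-participant table with one row per minute.
Missing cells are filled only by the bounded rules the analysis allows:

* glucose: backfilled from the next observation, at most 5 minutes ahead
  (a CGM sample describes the recent past, so this is not future leakage
  in the physiological sense, and it is the only backward-in-time fill);
* HRV and respiratory rate: forward-filled up to 15 minutes;
* blood oxygen saturation: forward-filled up to 30 minutes;
* heart rate, steps, active energy: never imputed — the downstream tree
  ensemble handles missing values natively.

Every cell carries a provenance flag (observed / backfilled / forward_filled
/ missing) so the anti-leakage contracts can be audited after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

CHANNELS = ("glucose", "hr", "hrv", "bos", "rr", "steps", "energy")

#: channels Table-style imputation never touches
NEVER_IMPUTED = ("hr", "steps", "energy")

FLAG_OBSERVED = "observed"
FLAG_BACKFILLED = "backfilled"
FLAG_FFILLED = "forward_filled"
FLAG_MISSING = "missing"


@dataclass
class SensorStream:
    """One raw channel: timestamped values at a nominal cadence, with gaps."""

    channel: str
    samples: pd.Series  # DatetimeIndex -> float
    nominal_cadence_min: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        idx = self.samples.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise TypeError(f"{self.channel}: samples must be indexed by timestamps")
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError(f"{self.channel}: timestamps must be strictly increasing")
        if len(idx) > 1 and idx.has_duplicates:
            # duplicates are allowed only within distinct sub-minute readings;
            # exact duplicate timestamps indicate a corrupt export
            raise ValueError(f"{self.channel}: duplicate timestamps")
        values = self.samples.to_numpy(dtype=float)
        if len(values) and not np.isfinite(values).all():
            raise ValueError(f"{self.channel}: non-finite values")
        if self.channel == "glucose" and len(values) and (values <= 0).any():
            raise ValueError("glucose: values must be positive")


@dataclass
class ParticipantTimeline:
    """1-minute-grid table merging all channels, with imputation provenance.

    ``data`` holds one column per channel; ``flags`` a parallel table of
    provenance strings. Both share a minute-resolution DatetimeIndex.
    """

    participant_id: str
    data: pd.DataFrame
    flags: pd.DataFrame = field(repr=False)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    def copy(self) -> "ParticipantTimeline":
        return ParticipantTimeline(self.participant_id, self.data.copy(), self.flags.copy())


def align_to_minute_grid(
    streams: Iterable[SensorStream], participant_id: str = ""
) -> ParticipantTimeline:
    """Merge raw streams onto one row per minute.

    The grid spans from the earliest to the latest observation over all
    streams. Each observation is assigned to its containing minute (floor);
    multiple observations inside one minute are reduced by their mean.
    """
    streams = list(streams)
    if not streams:
        raise ValueError("empty stream set")
    seen = [s.channel for s in streams]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate channels in stream set: {seen}")

    start = min(s.samples.index[0] for s in streams if len(s.samples)).floor("min")
    end = max(s.samples.index[-1] for s in streams if len(s.samples)).floor("min")
    grid = pd.date_range(start, end, freq="min")

    data = pd.DataFrame(index=grid, columns=list(CHANNELS), dtype=float)
    flags = pd.DataFrame(FLAG_MISSING, index=grid, columns=list(CHANNELS))
    for s in streams:
        if not len(s.samples):
            continue
        per_minute = s.samples.groupby(s.samples.index.floor("min")).mean()
        data.loc[per_minute.index, s.channel] = per_minute.to_numpy()
        flags.loc[per_minute.index, s.channel] = FLAG_OBSERVED
    return ParticipantTimeline(participant_id, data, flags)


def backfill_glucose(timeline: ParticipantTimeline, limit_minutes: int = 5) -> ParticipantTimeline:
    """Fill missing glucose cells from the nearest later observation <= ``limit_minutes`` ahead.

    The limit is inclusive: a cell exactly ``limit_minutes`` before its source
    observation is filled. Observed cells are never altered; cells farther
    than the limit from any future observation stay missing.
    """
    out = timeline.copy()
    col = out.data["glucose"]
    # fill only from truly observed cells so repeated application cannot
    # chain imputed values past the limit
    observed = col.where(out.flags["glucose"] == FLAG_OBSERVED)
    filled = observed.bfill(limit=limit_minutes)
    newly = col.isna() & filled.notna()
    out.data.loc[newly, "glucose"] = filled[newly]
    out.flags.loc[newly, "glucose"] = FLAG_BACKFILLED
    return out


FFILL_CHANNELS = {"hrv", "rr", "bos"}


def forward_fill_limited(
    timeline: ParticipantTimeline, channel: str, limit_minutes: int
) -> ParticipantTimeline:
    """Fill missing cells of ``channel`` from the most recent prior observation.

    Only HRV, respiratory rate and blood oxygen saturation may be forward
    filled; their fill limits mirror each channel's measurement cadence so
    a value is never carried further than one sampling interval. The source
    observation always precedes the filled cell, so no information flows
    backward in time.
    """
    if channel not in FFILL_CHANNELS:
        raise ValueError(
            f"channel {channel!r} is never imputed; forward filling applies only to "
            f"{sorted(FFILL_CHANNELS)}"
        )
    out = timeline.copy()
    col = out.data[channel]
    observed = col.where(out.flags[channel] == FLAG_OBSERVED)
    filled = observed.ffill(limit=limit_minutes)
    newly = col.isna() & filled.notna()
    out.data.loc[newly, channel] = filled[newly]
    out.flags.loc[newly, channel] = FLAG_FFILLED
    return out


def assemble_timeline(
    streams: Iterable[SensorStream],
    participant_id: str = "",
    glucose_backfill: int = 5,
    hrv_ffill: int = 15,
    rr_ffill: int = 15,
    bos_ffill: int = 30,
) -> ParticipantTimeline:
    """Align to the minute grid and apply all bounded imputations in order."""
    tl = align_to_minute_grid(streams, participant_id)
    tl = backfill_glucose(tl, glucose_backfill)
    tl = forward_fill_limited(tl, "hrv", hrv_ffill)
    tl = forward_fill_limited(tl, "rr", rr_ffill)
    tl = forward_fill_limited(tl, "bos", bos_ffill)
    return tl


def timeline_to_frame(timeline: ParticipantTimeline) -> pd.DataFrame:
    """Flatten a timeline into one exportable table (value + flag columns)."""
    df = timeline.data.copy()
    for ch in CHANNELS:
        df[f"{ch}_flag"] = timeline.flags[ch]
    df.index.name = "timestamp"
    return df
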