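"""Diurnal segmentation: cut each participant's record into day and night blocks.

The diary's sleep times are authoritative (no sensor-based sleep detection).
A "day" spans wake -> sleep onset, a "night" spans sleep onset -> next wake;
each gets a unique identifier and is the unit of the leave-hypo-segment-out
train/test split. The partial stretch before the first wake and after the
last wake is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAY = "day"
NIGHT = "night"


def make_segment_id(participant_id: str, start: pd.Timestamp, kind: str) -> str:
    return f"{participant_id}_{start.date().isoformat()}_{kind}"


@dataclass
class Segment:
    """One day (wake->sleep) or night (sleep->wake) block.

    ``end`` is exclusive: the segment owns minutes start <= t < end.
    """

    segment_id: str
    participant_id: str
    kind: str  # "day" | "night"
    start: pd.Timestamp
    end: pd.Timestamp
    contains_event: bool = False
    events: list = field(default_factory=list)

    @property
    def duration_min(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(minutes=1))


def assign_segments(diary: pd.DataFrame, participant_id: str) -> list[Segment]:
    """Build day/night segments from alternating wake / sleep_onset diary entries.

    Parameters
    ----------
    diary : DataFrame with columns ``timestamp`` and ``entry_type``; the sleep
        schedule is the subset with entry_type in {"wake", "sleep_onset"}.

    Raises on non-alternating sleep entries, naming the offending date.
    """
    sched = diary[diary["entry_type"].isin(["wake", "sleep_onset"])].copy()
    if sched.empty:
        raise ValueError(f"{participant_id}: diary contains no sleep schedule entries")
    sched = sched.sort_values("timestamp").reset_index(drop=True)

    # drop a leading sleep_onset (a night already in progress before the first
    # recorded wake would be a partial segment)
    while len(sched) and sched.iloc[0]["entry_type"] == "sleep_onset":
        sched = sched.iloc[1:].reset_index(drop=True)

    prev = None
    for _, row in sched.iterrows():
        if prev is not None and row["entry_type"] == prev:
            raise ValueError(
                f"{participant_id}: non-alternating sleep diary entries around "
                f"{pd.Timestamp(row['timestamp']).date()}"
            )
        prev = row["entry_type"]

    segments: list[Segment] = []
    times = list(sched["timestamp"])
    kinds = list(sched["entry_type"])
    for i in range(len(times) - 1):
        start, end = pd.Timestamp(times[i]), pd.Timestamp(times[i + 1])
        kind = DAY if kinds[i] == "wake" else NIGHT
        if end <= start:
            logger.warning("%s: dropping empty segment at %s", participant_id, start)
            continue
        segments.append(
            Segment(
                segment_id=make_segment_id(participant_id, start, kind),
                participant_id=participant_id,
                kind=kind,
                start=start,
                end=end,
            )
        )
    return segments


def segment_of(segments: Iterable[Segment], ts: pd.Timestamp) -> Optional[Segment]:
    """The segment containing minute ``ts``, or None if it falls in trimmed time."""
    for seg in segments:
        if seg.start <= ts < seg.end:
            return seg
    return None


def mark_event_segments(segments: list[Segment], events) -> list[Segment]:
    """Set ``contains_event`` on each segment from qualifying event onsets.

    An event belongs to the segment containing its onset; a segment counts as
    event-bearing when one or more qualifying events start inside it.
    """
    for seg in segments:
        seg.events = []
        seg.contains_event = False
    for ev in events:
        seg = segment_of(segments, ev.start)
        if seg is None:
            logger.warning("event at %s falls outside all segments; ignored", ev.start)
            continue
        ev.segment_id = seg.segment_id
        seg.events.append(ev)
        seg.contains_event = True
    return segments


def sleep_schedule_consistent(
    segments: Iterable[Segment],
    sd_max_hours: float = 3.0,
    min_night_hours: float = 3.0,
) -> bool:
    """Heuristic gate on night modeling for irregular sleepers.

    Night models assume a recurring sleep window (the time-of-day encoding is
    a strong input). Participants whose sleep-onset hour varies widely, or who
    log very short nights (shift work, interrupted sleep), violate that
    assumption; night modeling is skipped for them.
    """
    nights = [s for s in segments if s.kind == NIGHT]
    if not nights:
        return False
    onset_hours = np.array(
        [s.start.hour + s.start.minute / 60.0 for s in nights], dtype=float
    )
    # circular SD via the resultant vector, so 23:30 and 00:30 are 1 h apart
    ang = 2 * np.pi * onset_hours / 24.0
    r = np.hypot(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    circ_sd_hours = np.sqrt(max(0.0, -2.0 * np.log(max(r, 1e-12)))) * 24.0 / (2 * np.pi)
    if circ_sd_hours > sd_max_hours:
        return False
    if any(s.duration_min < min_night_hours * 60 for s in nights):
        return False
    return True


def segments_to_frame(segments: Iterable[Segment]) -> pd.DataFrame:
    rows = [
        {
            "segment_id": s.segment_id,
            "participant_id": s.participant_id,
            "kind": s.kind,
            "start": s.start,
            "end": s.end,
            "contains_event": s.contains_event,
        }
        for s in segments
    ]
    return pd.DataFrame(rows)
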