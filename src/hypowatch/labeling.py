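"""Per-minute hypoglycemia outcome labeling and event qualification.

The outcome is binary: a minute is positive when it belongs to a maximal run
of consecutive minutes with interstitial glucose strictly below 4.0 mmol/L
lasting at least 15 minutes. Shorter dips are physiologically ambiguous
(sensor noise, compression artifacts) and stay negative. Minutes with missing
glucose break a run — events are never fabricated across CGM gaps.

Prolonged nocturnal events are truncated at 180 minutes: the sustained
counter-regulatory response flattens out, and label mass hours into an event
teaches the classifier little about onset detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .segmentation import NIGHT, Segment, segment_of


@dataclass
class HypoEvent:
    """One qualifying hypoglycemic event (end exclusive)."""

    start: pd.Timestamp
    end: pd.Timestamp
    segment_id: Optional[str] = None
    truncated: bool = False

    @property
    def duration_min(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(minutes=1))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end-exclusive) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def label_hypoglycemia(
    timeline,
    threshold: float = 4.0,
    min_duration_min: int = 15,
) -> tuple[pd.Series, list[HypoEvent]]:
    """Label each minute and extract qualifying events from the glucose column.

    Parameters
    ----------
    timeline : ParticipantTimeline with glucose imputation already applied.
    threshold : strict cutoff; a minute counts only when glucose < threshold.
    min_duration_min : minimum run length for a run to qualify as an event.

    Returns
    -------
    labels : int8 Series on the timeline's minute index (1 inside events).
    events : list of HypoEvent, ordered by onset.
    """
    if "glucose" not in timeline.data.columns:
        raise ValueError("timeline has no glucose column")
    glucose = timeline.data["glucose"]
    below = (glucose < threshold).to_numpy() & glucose.notna().to_numpy()
    labels = np.zeros(len(below), dtype=np.int8)
    events: list[HypoEvent] = []
    idx = timeline.index
    one_min = pd.Timedelta(minutes=1)
    for a, b in _runs(below):
        if b - a >= min_duration_min:
            labels[a:b] = 1
            events.append(HypoEvent(start=idx[a], end=idx[b - 1] + one_min))
    return pd.Series(labels, index=idx, name="label"), events


def truncate_prolonged_nocturnal(
    events: list[HypoEvent],
    labels: pd.Series,
    segments: Iterable[Segment],
    cutoff_min: int = 180,
) -> tuple[list[HypoEvent], pd.Series]:
    """Truncate nocturnal events longer than ``cutoff_min`` (labels reset past it).

    Events are assigned to the segment containing their onset before the rule
    is applied; daytime events are untouched regardless of length. The event
    itself is kept (its first ``cutoff_min`` minutes), marked ``truncated``.
    """
    segments = list(segments)
    labels = labels.copy()
    out: list[HypoEvent] = []
    for ev in events:
        if ev.segment_id is None:
            seg = segment_of(segments, ev.start)
            ev.segment_id = seg.segment_id if seg is not None else None
        kind = None
        for seg in segments:
            if seg.segment_id == ev.segment_id:
                kind = seg.kind
                break
        if kind == NIGHT and ev.duration_min > cutoff_min:
            new_end = ev.start + pd.Timedelta(minutes=cutoff_min)
            labels.loc[new_end : ev.end - pd.Timedelta(minutes=1)] = 0
            ev = HypoEvent(start=ev.start, end=new_end, segment_id=ev.segment_id, truncated=True)
        out.append(ev)
    return out, labels


def qualify_participant_segments(
    events_by_participant: dict[str, list[HypoEvent]],
    segments_by_participant: dict[str, list[Segment]],
) -> dict[tuple[str, str], bool]:
    """Decide which (participant, day|night) pairs are modelable.

    A pair is modelable iff at least one qualifying event starts in a segment
    of that kind; participants with no qualifying events anywhere contribute
    no models at all.
    """
    eligibility: dict[tuple[str, str], bool] = {}
    for pid, segments in segments_by_participant.items():
        events = events_by_participant.get(pid, [])
        seg_kind = {s.segment_id: s.kind for s in segments}
        kinds_with_events = {seg_kind[e.segment_id] for e in events if e.segment_id in seg_kind}
        for kind in ("day", "night"):
            eligibility[(pid, kind)] = kind in kinds_with_events
    return eligibility


def events_to_frame(events: Iterable[HypoEvent], participant_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "participant_id": participant_id,
            "start": e.start,
            "end": e.end,
            "duration_min": e.duration_min,
            "segment_id": e.segment_id,
            "truncated": e.truncated,
        }
        for e in events
    ]
    return pd.DataFrame(rows)
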