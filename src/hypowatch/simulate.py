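"""Synthetic smartwatch + CGM + diary cohort generator.

Emulates the data environment of a free-living wearable study: a blinded CGM
sampling interstitial glucose every 5 minutes, a consumer smartwatch emitting
heart rate / steps / active energy every minute, HRV on a sparse irregular
schedule (regular 15-min at night, thinned during the day because the watch
measures only in restful states), respiratory rate (15 min) and blood oxygen
saturation (30 min) during sleep only, and a hand-kept diary of mealtimes,
short-acting insulin doses, and sleep/wake times.

Hypoglycemic episodes are injected as ground-truth intervals per diurnal
segment; during event minutes the glucose trace is forced below 4.0 mmol/L
and each physiological channel is shifted by its configured effect size
(tachycardia, reduced HRV, mild hyperventilation, small desaturation).
Everything is driven by a single seed through `numpy.random.SeedSequence`
spawning, so a (config, seed) pair reproduces the cohort byte-for-byte.

The generator makes no claim of pharmacokinetic realism: glucose is a
mean-reverting Gaussian walk with events pasted in, not an insulin-glucose
simulator, and effects are level shifts without individual response shapes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig
from .segmentation import DAY, NIGHT, make_segment_id
from .timeline import SensorStream

ORIGIN = pd.Timestamp("2024-03-01 00:00")

# mean-reversion rate of the latent glucose walk, per minute
_GLUCOSE_THETA = 0.03
# glucose floor outside events (keeps the non-event trace clear of threshold)
_EUGLYCEMIC_FLOOR = 4.6
# margin kept between events / segment edges so labeling recovers events exactly
_EVENT_MARGIN_MIN = 15


@dataclass
class GroundTruthEvent:
    start: pd.Timestamp
    end: pd.Timestamp  # exclusive
    segment_id: str

    @property
    def duration_min(self) -> int:
        return int((self.end - self.start) / pd.Timedelta(minutes=1))


@dataclass
class GroundTruth:
    participant_id: str
    events: list[GroundTruthEvent] = field(default_factory=list)
    diary: pd.DataFrame | None = None


@dataclass
class ParticipantData:
    participant_id: str
    streams: dict[str, SensorStream]
    diary: pd.DataFrame
    truth: GroundTruth


def _child_rngs(participant_seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(participant_seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _minutes(ts: pd.Timestamp) -> int:
    return int((ts - ORIGIN) / pd.Timedelta(minutes=1))


def generate_diary(config: CohortConfig, participant_seed: int, participant_id: str = "P00") -> pd.DataFrame:
    """Meal / insulin / sleep diary for one participant.

    Nightly sleep onset and morning wake are jittered around the configured
    hours; meals fall at habitual times (breakfast/lunch/dinner anchors for
    up to three meals, extra meals spread over the waking window) and each is
    followed by an insulin dose with the configured probability.
    """
    rng = _child_rngs(participant_seed, 4)[0]
    entries: list[dict] = []
    d = config.days_per_participant
    jitter = lambda: rng.normal(0.0, config.sleep_jitter_sd_min)  # noqa: E731

    wake_times: list[pd.Timestamp] = []
    onset_times: list[pd.Timestamp] = []
    for day in range(d + 1):
        w = ORIGIN + pd.Timedelta(days=day, hours=config.wake_hour, minutes=jitter())
        wake_times.append(w.floor("min"))
    for day in range(d):
        onset = ORIGIN + pd.Timedelta(days=day, hours=config.sleep_onset_hour, minutes=jitter())
        onset = onset.floor("min")
        # keep the schedule alternating even under extreme jitter
        onset = max(onset, wake_times[day] + pd.Timedelta(hours=1))
        onset = min(onset, wake_times[day + 1] - pd.Timedelta(hours=1))
        onset_times.append(onset)

    for w in wake_times:
        entries.append({"timestamp": w, "entry_type": "wake"})
    for s in onset_times:
        entries.append({"timestamp": s, "entry_type": "sleep_onset"})

    anchors = [8.5, 12.5, 19.0]
    for day in range(d):
        wake, onset = wake_times[day], onset_times[day]
        for m in range(config.meal_count_per_day):
            if m < 3:
                t = ORIGIN + pd.Timedelta(days=day, hours=anchors[m], minutes=rng.normal(0, 30))
            else:
                frac = rng.uniform(0.1, 0.9)
                t = wake + frac * (onset - wake)
            t = min(max(t.floor("min"), wake + pd.Timedelta(minutes=15)), onset - pd.Timedelta(minutes=15))
            entries.append({"timestamp": t, "entry_type": "meal"})
            if rng.uniform() < config.insulin_prob_per_meal:
                entries.append(
                    {"timestamp": t + pd.Timedelta(minutes=int(rng.integers(0, 6))), "entry_type": "insulin"}
                )

    diary = pd.DataFrame(entries).sort_values("timestamp", kind="stable").reset_index(drop=True)
    diary["participant_id"] = participant_id
    return diary


def _diary_segments(diary: pd.DataFrame, participant_id: str) -> list[tuple[str, str, pd.Timestamp, pd.Timestamp]]:
    """(segment_id, kind, start, end) tuples from the diary sleep schedule."""
    sched = diary[diary["entry_type"].isin(["wake", "sleep_onset"])].sort_values("timestamp")
    times = list(sched["timestamp"])
    kinds = list(sched["entry_type"])
    out = []
    for i in range(len(times) - 1):
        kind = DAY if kinds[i] == "wake" else NIGHT
        start, end = pd.Timestamp(times[i]), pd.Timestamp(times[i + 1])
        out.append((make_segment_id(participant_id, start, kind), kind, start, end))
    return out


def _place_events(
    config: CohortConfig,
    rng: np.random.Generator,
    segments: list[tuple[str, str, pd.Timestamp, pd.Timestamp]],
    participant_id: str,
) -> list[GroundTruthEvent]:
    """Draw per-segment Poisson event counts and place non-overlapping intervals.

    Events keep a margin from segment edges and from each other so that the
    5-min CGM sampling plus bounded backfill recovers each one as a distinct
    labeled run (start/end within one CGM sample of the truth).
    """
    lo, hi = config.event_duration_range
    events: list[GroundTruthEvent] = []
    for seg_id, kind, start, end in segments:
        seg_len = int((end - start) / pd.Timedelta(minutes=1))
        rate = config.day_event_rate if kind == DAY else config.night_event_rate
        if rate <= 0:
            continue
        if lo + 2 * _EVENT_MARGIN_MIN > seg_len:
            raise ValueError(
                f"event duration range {config.event_duration_range} incompatible with "
                f"segment length {seg_len} min ({seg_id})"
            )
        n = int(rng.poisson(rate))
        placed: list[tuple[int, int]] = []
        for _ in range(n):
            dur = int(rng.integers(lo, min(hi, seg_len - 2 * _EVENT_MARGIN_MIN) + 1))
            for _attempt in range(50):
                s = int(rng.integers(_EVENT_MARGIN_MIN, seg_len - dur - _EVENT_MARGIN_MIN + 1))
                e = s + dur
                if all(
                    e + _EVENT_MARGIN_MIN <= ps or s >= pe + _EVENT_MARGIN_MIN
                    for ps, pe in placed
                ):
                    placed.append((s, e))
                    break
        for s, e in sorted(placed):
            events.append(
                GroundTruthEvent(
                    start=start + pd.Timedelta(minutes=s),
                    end=start + pd.Timedelta(minutes=e),
                    segment_id=seg_id,
                )
            )
    events.sort(key=lambda ev: ev.start)
    return events


def _event_mask(events: list[GroundTruthEvent], n_minutes: int, lag: int = 0) -> np.ndarray:
    mask = np.zeros(n_minutes, dtype=bool)
    for ev in events:
        a = max(0, _minutes(ev.start) + lag)
        b = min(n_minutes, _minutes(ev.end) + lag)
        mask[a:b] = True
    return mask


def generate_glucose_trace(
    config: CohortConfig,
    participant_seed: int,
    participant_id: str = "P00",
    diary: pd.DataFrame | None = None,
) -> tuple[SensorStream, GroundTruth]:
    """CGM trace (5-min cadence) plus the ground-truth event set.

    The latent minute-level process is a mean-reverting Gaussian walk around
    the euglycemic baseline, floored well above the 4.0 mmol/L threshold
    outside events. Ground-truth intervals force the trace into the 3.0-3.9
    range; occasional short (<=10 min) sub-threshold dips are injected at a
    low rate to exercise the 15-minute duration filter downstream.
    """
    rngs = _child_rngs(participant_seed, 4)
    rng = rngs[1]
    if diary is None:
        diary = generate_diary(config, participant_seed, participant_id)
    segments = _diary_segments(diary, participant_id)
    events = _place_events(config, rng, segments, participant_id)

    end_ts = max(end for *_ignored, end in [(s[0], s[1], s[2], s[3]) for s in segments]) + pd.Timedelta(minutes=30)
    n_min = _minutes(end_ts) + 1

    mu = config.baselines.glucose
    steps = rng.normal(0.0, config.noise_sd.glucose, size=n_min)
    g = np.empty(n_min)
    g[0] = mu
    for t in range(1, n_min):
        g[t] = g[t - 1] + _GLUCOSE_THETA * (mu - g[t - 1]) + steps[t]
    g = np.maximum(g, _EUGLYCEMIC_FLOOR)

    mask = _event_mask(events, n_min)
    g[mask] = np.clip(3.5 + rng.normal(0.0, 0.15, size=int(mask.sum())), 3.0, 3.9)

    # transient dips: short enough (<=10 min) that the duration rule always rejects them
    for seg_id, kind, start, end in segments:
        if rng.uniform() < config.transient_dip_prob:
            seg_a, seg_b = _minutes(start), _minutes(end)
            dur = int(rng.choice([5, 10]))
            for _attempt in range(20):
                s = int(rng.integers(seg_a + _EVENT_MARGIN_MIN, seg_b - dur - _EVENT_MARGIN_MIN))
                window = slice(max(0, s - _EVENT_MARGIN_MIN), min(n_min, s + dur + _EVENT_MARGIN_MIN))
                if not mask[window].any():
                    g[s : s + dur] = 3.7 + rng.normal(0.0, 0.1, size=dur).clip(-0.5, 0.2)
                    break

    sample_idx = np.arange(0, n_min, 5)
    ts = ORIGIN + pd.to_timedelta(sample_idx, unit="min")
    stream = SensorStream("glucose", pd.Series(g[sample_idx], index=ts), nominal_cadence_min=5)
    truth = GroundTruth(participant_id=participant_id, events=events, diary=diary)
    return stream, truth


def _sleep_mask(segments, n_min: int) -> np.ndarray:
    mask = np.zeros(n_min, dtype=bool)
    for _seg_id, kind, start, end in segments:
        if kind == NIGHT:
            mask[max(0, _minutes(start)) : min(n_min, _minutes(end))] = True
    return mask


def generate_wearable_streams(
    config: CohortConfig,
    truth: GroundTruth,
    participant_seed: int,
    participant_id: str = "P00",
) -> dict[str, SensorStream]:
    """All smartwatch channels, conditioned on the ground truth and diary.

    Heart rate carries a circadian waking/sleeping baseline, coupling to step
    activity, and the configured bpm shift during event minutes. HRV is
    sampled every 15 min in sleep and on a Bernoulli-thinned 15-min grid while
    awake. Respiratory rate and blood oxygen are emitted during sleep only.
    Steps / active energy follow a two-state rest/active Markov chain during
    waking minutes and are zero during sleep.
    """
    rng = _child_rngs(participant_seed, 4)[2]
    diary = truth.diary
    segments = _diary_segments(diary, participant_id)
    end_ts = max(end for *_x, end in segments) + pd.Timedelta(minutes=30)
    n_min = _minutes(end_ts) + 1
    minutes = ORIGIN + pd.to_timedelta(np.arange(n_min), unit="min")

    asleep = _sleep_mask(segments, n_min)
    in_event = _event_mask(truth.events, n_min, lag=config.effect_lag_min)

    # --- activity: two-state Markov chain over waking minutes ---
    steps = np.zeros(n_min)
    active = False
    p_up, p_down = 0.08, 0.25
    for t in range(n_min):
        if asleep[t]:
            active = False
            continue
        active = (rng.uniform() < p_up) if not active else (rng.uniform() >= p_down)
        if active:
            steps[t] = max(0.0, rng.normal(90.0, 18.0))
        elif rng.uniform() < 0.15:
            steps[t] = rng.poisson(8.0)
    steps = np.round(steps)
    energy = np.where(
        asleep, 0.0, np.maximum(0.0, 0.06 * steps + rng.normal(0.8, 0.3, size=n_min))
    )

    # --- heart rate: circadian baseline + activity coupling + event effect ---
    awake_level = np.where(asleep, 0.0, 1.0)
    # smooth the sleep/wake transition over ~20 min
    kernel = np.ones(21) / 21.0
    awake_smooth = np.convolve(awake_level, kernel, mode="same")
    hr_base = config.baselines.hr_night + (config.baselines.hr_day - config.baselines.hr_night) * awake_smooth
    hr = hr_base + 0.08 * steps + config.hr_effect * in_event + rng.normal(0, config.noise_sd.hr, n_min)
    hr = np.maximum(hr, 35.0)

    # --- HRV latent: higher during sleep, reduced during events ---
    hrv_latent = (
        config.baselines.hrv
        + 8.0 * (1.0 - awake_smooth)
        + config.hrv_effect * in_event
        + rng.normal(0, config.noise_sd.hrv, n_min)
    )
    hrv_latent = np.maximum(hrv_latent, 3.0)

    rr_latent = config.baselines.rr + config.rr_effect * in_event + rng.normal(0, config.noise_sd.rr, n_min)
    rr_latent = np.maximum(rr_latent, 6.0)
    bos_latent = config.baselines.bos + config.bos_effect * in_event + rng.normal(0, config.noise_sd.bos, n_min)
    bos_latent = np.minimum(np.maximum(bos_latent, 80.0), 100.0)

    # --- sampling schedules ---
    hrv_idx: list[int] = []
    rr_idx: list[int] = []
    bos_idx: list[int] = []
    for _seg_id, kind, start, end in segments:
        a, b = _minutes(start), min(_minutes(end), n_min)
        if kind == NIGHT:
            hrv_idx.extend(range(a, b, 15))
            rr_idx.extend(range(a, b, 15))
            bos_idx.extend(range(a, b, 30))
        else:
            for t in range(a, b, 15):
                if rng.uniform() < config.daytime_hrv_keep_prob:
                    hrv_idx.append(t)

    def _stream(name: str, values: np.ndarray, idx, cadence: float) -> SensorStream:
        idx = np.asarray(sorted(idx), dtype=int)
        return SensorStream(name, pd.Series(values[idx], index=minutes[idx]), nominal_cadence_min=cadence)

    all_min = np.arange(n_min)
    return {
        "hr": _stream("hr", hr, all_min, 1),
        "hrv": _stream("hrv", hrv_latent, hrv_idx, 15),
        "rr": _stream("rr", rr_latent, rr_idx, 15),
        "bos": _stream("bos", bos_latent, bos_idx, 30),
        "steps": _stream("steps", steps, all_min, 1),
        "energy": _stream("energy", energy, all_min, 1),
    }


def simulate_participant(config: CohortConfig, participant_seed: int, participant_id: str) -> ParticipantData:
    diary = generate_diary(config, participant_seed, participant_id)
    glucose, truth = generate_glucose_trace(config, participant_seed, participant_id, diary=diary)
    streams = generate_wearable_streams(config, truth, participant_seed, participant_id)
    streams["glucose"] = glucose
    return ParticipantData(participant_id=participant_id, streams=streams, diary=diary, truth=truth)


def simulate_cohort(config: CohortConfig) -> list[ParticipantData]:
    """Simulate all participants; per-participant seeds are spawned from ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_participants) % (2**31)
    cohort = []
    for i, s in enumerate(seeds):
        pid = f"P{i + 1:02d}"
        cohort.append(simulate_participant(config, int(s), pid))
    return cohort


# ---------------------------------------------------------------------------
# disk round-trip (one CSV per channel, diary CSV, ground-truth JSON)
# ---------------------------------------------------------------------------

def write_participant(data: ParticipantData, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pid = data.participant_id
    for name, stream in data.streams.items():
        df = pd.DataFrame({"timestamp": stream.samples.index, "value": stream.samples.to_numpy()})
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        df.to_csv(outdir / f"{pid}_{name}.csv", index=False)
    diary = data.diary[["timestamp", "entry_type"]].copy()
    diary["timestamp"] = pd.to_datetime(diary["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    diary.to_csv(outdir / f"{pid}_diary.csv", index=False)
    truth = {
        "participant_id": pid,
        "events": [
            {
                "start": e.start.isoformat(),
                "end": e.end.isoformat(),
                "segment_id": e.segment_id,
            }
            for e in data.truth.events
        ],
    }
    (outdir / f"{pid}_truth.json").write_text(json.dumps(truth, indent=1))


def write_cohort(cohort: list[ParticipantData], outdir: str | Path) -> None:
    for data in cohort:
        write_participant(data, outdir)


_CADENCES = {"glucose": 5, "hr": 1, "hrv": 15, "bos": 30, "rr": 15, "steps": 1, "energy": 1}


def read_participant(indir: str | Path, participant_id: str) -> ParticipantData:
    """Load one participant's channel CSVs, diary and (if present) ground truth."""
    indir = Path(indir)
    streams: dict[str, SensorStream] = {}
    for name, cadence in _CADENCES.items():
        path = indir / f"{participant_id}_{name}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path, parse_dates=["timestamp"])
        streams[name] = SensorStream(name, pd.Series(df["value"].to_numpy(), index=pd.DatetimeIndex(df["timestamp"])), cadence)
    diary = pd.read_csv(indir / f"{participant_id}_diary.csv", parse_dates=["timestamp"])
    diary["participant_id"] = participant_id
    truth = GroundTruth(participant_id=participant_id, diary=diary)
    truth_path = indir / f"{participant_id}_truth.json"
    if truth_path.exists():
        raw = json.loads(truth_path.read_text())
        truth.events = [
            GroundTruthEvent(pd.Timestamp(e["start"]), pd.Timestamp(e["end"]), e["segment_id"])
            for e in raw["events"]
        ]
    return ParticipantData(participant_id=participant_id, streams=streams, diary=diary, truth=truth)


def cohort_participant_ids(indir: str | Path) -> list[str]:
    return sorted({p.name.split("_")[0] for p in Path(indir).glob("P*_diary.csv")})
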