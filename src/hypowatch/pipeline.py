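"""End-to-end orchestration: simulate/ingest -> assemble -> label -> segment
-> features -> model -> interpret, with a manifest for reproducibility.

A single global seed fans out deterministically: the cohort simulator derives
per-participant seeds from it via `numpy.random.SeedSequence`, and the
undersampling random states are the integers 0..n_seeds-1 offset by the
global seed, so a rerun with the same config and seed reproduces every
metric file byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import interpret, labeling, segmentation, simulate, timeline
from .config import RunConfig
from .model import (
    CohortReport,
    NotModelableError,
    PersonalizedHypoglycemiaModel,
    PersonalizedResults,
    summarize_cohort,
)

logger = logging.getLogger(__name__)


@dataclass
class ParticipantArtifacts:
    """Intermediate products of one participant's pass through the pipeline."""

    participant_id: str
    timeline: timeline.ParticipantTimeline
    segments: list[segmentation.Segment]
    labels: pd.Series
    events: list[labeling.HypoEvent]
    eligibility: dict[str, bool]
    has_meals: bool
    diary: pd.DataFrame


@dataclass
class PipelineResult:
    config: RunConfig
    participants: list[ParticipantArtifacts]
    results: list[PersonalizedResults] = field(default_factory=list)
    cohort: CohortReport | None = None


def process_participant(
    data: simulate.ParticipantData, config: RunConfig
) -> ParticipantArtifacts:
    """Assemble, impute, label, truncate and segment one participant."""
    imp = config.imputation
    tl = timeline.assemble_timeline(
        data.streams.values(),
        participant_id=data.participant_id,
        glucose_backfill=imp.glucose_backfill,
        hrv_ffill=imp.hrv_ffill,
        rr_ffill=imp.rr_ffill,
        bos_ffill=imp.bos_ffill,
    )
    segments = segmentation.assign_segments(data.diary, data.participant_id)
    labels, events = labeling.label_hypoglycemia(
        tl, threshold=config.label.threshold_mmol_l, min_duration_min=config.label.min_duration_min
    )
    segmentation.mark_event_segments(segments, events)
    events, labels = labeling.truncate_prolonged_nocturnal(
        events, labels, segments, cutoff_min=config.label.nocturnal_cutoff_min
    )
    segmentation.mark_event_segments(segments, events)

    kinds_with_events = {
        s.kind for s in segments if s.contains_event
    }
    eligibility = {k: (k in kinds_with_events) for k in ("day", "night")}
    if eligibility["night"] and not segmentation.sleep_schedule_consistent(
        segments,
        sd_max_hours=config.modeling.sleep_onset_sd_max_hours,
        min_night_hours=config.modeling.min_night_hours,
    ):
        logger.warning(
            "%s: inconsistent sleep schedule; night modeling skipped", data.participant_id
        )
        eligibility["night"] = False

    has_meals = bool((data.diary["entry_type"] == "meal").any())
    return ParticipantArtifacts(
        participant_id=data.participant_id,
        timeline=tl,
        segments=segments,
        labels=labels,
        events=events,
        eligibility=eligibility,
        has_meals=has_meals,
        diary=data.diary,
    )


def build_models(
    art: ParticipantArtifacts, config: RunConfig
) -> list[PersonalizedHypoglycemiaModel]:
    models = []
    for kind in ("day", "night"):
        if not art.eligibility.get(kind):
            continue
        matrix = feat.build_feature_matrix(
            art.timeline, art.diary, art.segments, art.labels, kind, include_meal=art.has_meals
        )
        try:
            models.append(
                PersonalizedHypoglycemiaModel(
                    matrix, art.segments, art.participant_id, kind, config.modeling
                )
            )
        except NotModelableError as exc:
            logger.warning("%s/%s not modelable: %s", art.participant_id, kind, exc)
    return models


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis and (optionally) write reports + manifest."""
    if config.input_dir:
        pids = simulate.cohort_participant_ids(config.input_dir)
        cohort = [simulate.read_participant(config.input_dir, p) for p in pids]
    else:
        sim_cfg = config.simulate.model_copy(update={"seed": config.seed})
        cohort = simulate.simulate_cohort(sim_cfg)

    result = PipelineResult(config=config, participants=[])
    seeds = [config.seed + i for i in range(config.modeling.n_undersample_seeds)]

    for data in cohort:
        art = process_participant(data, config)
        result.participants.append(art)
        for model in build_models(art, config):
            res = model.fit(seeds=seeds)
            if res.n_valid > 0:
                result.results.append(res)
            else:
                logger.warning(
                    "%s/%s: no valid iterations; model dropped",
                    model.participant_id,
                    model.kind,
                )

    if result.results:
        result.cohort = summarize_cohort(result.results)
    else:
        logger.warning("no modelable participants in this cohort")

    if out_dir is not None:
        write_run(result, out_dir)
    return result


def write_run(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # per-participant events and segments
    ev_frames, seg_frames = [], []
    for art in result.participants:
        ev_frames.append(labeling.events_to_frame(art.events, art.participant_id))
        seg_frames.append(segmentation.segments_to_frame(art.segments))
    pd.concat([f for f in ev_frames if len(f)] or [pd.DataFrame()]).to_csv(
        out / "events.csv", index=False
    )
    pd.concat(seg_frames).to_csv(out / "segments.csv", index=False)

    # per-model reports
    for res in result.results:
        name = f"model_{res.model.participant_id}_{res.model.kind}"
        res.frame.to_csv(out / f"{name}_iterations.csv", index=False)
        report = {
            "participant_id": res.model.participant_id,
            "kind": res.model.kind,
            "auroc_mean": res.auroc_mean,
            "auroc_sd": res.auroc_sd,
            "sensitivity_mean": res.sensitivity_mean,
            "specificity_mean": res.specificity_mean,
            "detection_any_rate": res.detection_any_rate,
            "detection_first15_rate": res.detection_first15_rate,
            "n_events": res.n_events,
        }
        (out / f"{name}.json").write_text(json.dumps(report, indent=1))

    if result.cohort is not None:
        result.cohort.per_model.to_csv(out / "cohort_summary.csv", index=False)
        (out / "cohort_summary.txt").write_text(result.cohort.summary() + "\n")
        for kind, cat in result.cohort.category_importance.items():
            kind_res = [r for r in result.results if r.model.kind == kind]
            rep = interpret.aggregate_importance([r.feature_importance() for r in kind_res])
            interpret.importance_table(rep).to_csv(out / f"importance_{kind}.csv", index=False)

    manifest = {
        "config": result.config.model_dump(),
        "undersample_seeds": [
            result.config.seed + i for i in range(result.config.modeling.n_undersample_seeds)
        ],
        "versions": _versions(),
        "n_models": len(result.results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _versions() -> dict[str, str]:
    import sklearn
    import xgboost

    return {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "xgboost": xgboost.__version__,
    }
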