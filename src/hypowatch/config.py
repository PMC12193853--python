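"""Configuration objects for cohort simulation and the end-to-end analysis.

All fixed constants of the analysis (imputation limits, label rule, nocturnal
cutoff, regularization, number of undersampling states) live here as defaults,
so a run manifest that echoes the config records every constant actually used.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator


class ChannelNoise(BaseModel):
    """Per-channel Gaussian noise SD, in each channel's native units."""

    glucose: float = 0.25  # mmol/L
    hr: float = 4.0  # bpm
    hrv: float = 8.0  # ms
    bos: float = 0.7  # percentage points
    rr: float = 1.0  # breaths/min


class ChannelBaselines(BaseModel):
    """Euglycemic / resting baselines, in native units."""

    glucose: float = 7.0  # mmol/L
    hr_day: float = 74.0  # bpm, awake resting
    hr_night: float = 60.0  # bpm, asleep
    hrv: float = 45.0  # ms (SDNN-like)
    bos: float = 97.0  # %
    rr: float = 14.0  # breaths/min


class CohortConfig(BaseModel):
    """Parameters of the synthetic smartwatch + CGM + diary cohort.

    Effect sizes are the shifts applied to each physiological channel during
    hypoglycemic minutes. They are illustrative magnitudes in the range the
    physiology literature reports for sympathoadrenal activation (tachycardia,
    reduced beat-to-beat variability, mild hyperventilation), not estimates
    from any particular dataset.
    """

    n_participants: int = Field(4, gt=0)
    days_per_participant: int = Field(10, gt=0)

    sleep_onset_hour: float = Field(23.0, ge=0, lt=24)
    wake_hour: float = Field(7.0, ge=0, lt=24)
    sleep_jitter_sd_min: float = Field(20.0, ge=0)

    day_event_rate: float = Field(0.5, ge=0)  # expected events per day segment
    night_event_rate: float = Field(0.3, ge=0)  # expected events per night segment
    event_duration_range: tuple[int, int] = (20, 90)  # minutes

    hr_effect: float = 10.0  # bpm added during event minutes
    hrv_effect: float = -15.0  # ms added during event minutes
    rr_effect: float = 2.0  # breaths/min added during night event minutes
    bos_effect: float = -2.0  # percentage points added during night event minutes
    effect_lag_min: int = Field(0, ge=0)  # onset lag of physiological response

    transient_dip_prob: float = Field(0.05, ge=0, le=1)  # short (<15 min) sub-4 dips per segment
    daytime_hrv_keep_prob: float = Field(0.5, ge=0, le=1)  # Bernoulli thinning of day HRV grid

    noise_sd: ChannelNoise = ChannelNoise()
    baselines: ChannelBaselines = ChannelBaselines()

    meal_count_per_day: int = Field(3, ge=0)
    insulin_prob_per_meal: float = Field(0.8, ge=0, le=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_durations(self) -> "CohortConfig":
        lo, hi = self.event_duration_range
        if lo < 15:
            raise ValueError(
                "event_duration_range minimum must be >= 15 min so injected "
                "events satisfy the >=15-min labeling rule"
            )
        if hi < lo:
            raise ValueError("event_duration_range must be (min, max) with max >= min")
        return self


class ImputationLimits(BaseModel):
    """Bounded fill limits, minutes. Glucose is backfilled; the rest forward-filled."""

    glucose_backfill: int = 5
    hrv_ffill: int = 15
    rr_ffill: int = 15
    bos_ffill: int = 30


class LabelRule(BaseModel):
    """Hypoglycemia outcome definition."""

    threshold_mmol_l: float = 4.0  # strict: glucose < threshold
    min_duration_min: int = 15
    nocturnal_cutoff_min: int = 180  # prolonged night events truncated here


class ModelingConfig(BaseModel):
    """Classifier and evaluation settings for the personalized models."""

    n_undersample_seeds: int = 10
    reg_alpha: float = 10.0  # L1
    reg_lambda: float = 10.0  # L2
    undersample_ratio: float = Field(1.0, gt=0)  # negatives per positive after undersampling
    threshold_source: Literal["test", "train"] = "test"
    standardize_scope: Literal["train", "global"] = "train"
    sleep_onset_sd_max_hours: float = 3.0  # night modeling skipped above this
    min_night_hours: float = 3.0  # ... or when any night is shorter than this


class RunConfig(BaseModel):
    """End-to-end pipeline configuration."""

    input_dir: Optional[str] = None  # read an existing cohort; otherwise simulate
    simulate: CohortConfig = CohortConfig()
    imputation: ImputationLimits = ImputationLimits()
    label: LabelRule = LabelRule()
    modeling: ModelingConfig = ModelingConfig()
    output_dir: str = "hypowatch_run"
    seed: int = 0
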