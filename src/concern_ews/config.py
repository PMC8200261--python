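"""Configuration objects for the simulation and pipeline stages.

Every stage validates its configuration before any work starts; errors
name the offending field so a bad YAML file fails loudly and early.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import yaml


class ConfigurationError(ValueError):
    """A configuration value is missing, unknown, or out of range."""


#: Event channels the simulator can emit, keyed the way ``base_rates`` and
#: ``concern_multipliers`` are keyed.  The five vital-measurement channels
#: are *extra* (discretionary) measurements on top of the forced routine
#: schedule; comments, PRN administrations, withheld scheduled medications
#: and nursing notes are purely rate-driven.
EVENT_CHANNELS = (
    "hr_measurement",
    "rr_measurement",
    "bp_measurement",
    "temp_measurement",
    "spo2_measurement",
    "hr_comment",
    "rr_comment",
    "bp_comment",
    "temp_comment",
    "spo2_comment",
    "prn_administered",
    "scheduled_withheld",
    "note_written",
)

# Documentation rates (events/hour) under the standard-of-care schedule.
# The source cohorts' empirical rate distributions are not public; these
# defaults are stated as assumptions chosen to resemble an acute-care
# med-surg unit: discretionary vital rechecks are a few per day on top of
# the q4h routine, flowsheet comments are rarer, and roughly three nursing
# notes are written per shift-day.
DEFAULT_BASE_RATES: dict[str, float] = {
    "hr_measurement": 0.06,
    "rr_measurement": 0.06,
    "bp_measurement": 0.06,
    "temp_measurement": 0.06,
    "spo2_measurement": 0.06,
    "hr_comment": 0.02,
    "rr_comment": 0.02,
    "bp_comment": 0.02,
    "temp_comment": 0.02,
    "spo2_comment": 0.02,
    "prn_administered": 0.04,
    "scheduled_withheld": 0.01,
    "note_written": 0.12,
}

#: At full concern the event rate is base × (1 + multiplier), i.e. 4× with
#: the default multiplier of 3.
DEFAULT_CONCERN_MULTIPLIERS: dict[str, float] = {ch: 3.0 for ch in EVENT_CHANNELS}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic clinician-interaction cohort.

    The generator encodes the temporal structure the analysis is designed
    to exploit: for encounters that end in a deterioration event, a latent
    *concern* ramp inflates documentation rates starting
    ``behavioral_onset_hours`` before the event, while physiological drift
    toward abnormal vital values begins only ``physiological_onset_hours``
    before it.
    """

    n_encounters: int = 500
    event_fraction: float = 0.10
    behavioral_onset_hours: float = 48.0
    physiological_onset_hours: float = 6.0
    base_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    concern_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONCERN_MULTIPLIERS)
    )
    #: Wall-clock hours at which routine vitals are forced (q4h schedule).
    #: Empty tuple disables forced vitals and flattens the schedule weight.
    vitals_schedule: Sequence[int] = (0, 4, 8, 12, 16, 20)
    #: Fraction of baseline discretionary-event mass concentrated in the
    #: scheduled hours (the remainder is spread over off-schedule hours).
    schedule_mass: float = 0.9
    los_distribution: Mapping[str, float] = field(
        default_factory=lambda: {
            "median_hours": 96.0,
            "sigma": 0.6,
            "min_hours": 30.0,
            "max_hours": 1500.0,
        }
    )
    age_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"mean": 64.0, "sd": 16.0, "min": 16.0, "max": 100.0}
    )
    concern_ramp: str = "linear"  # or "sigmoid"
    #: Scales the physiological drift d(t); 0 disables vital-value drift
    #: entirely (null simulations).
    drift_scale: float = 1.0
    #: Range of the per-encounter concern gain: event encounters scale the
    #: concern ramp by a uniform draw from this range, modelling variation
    #: in how strongly clinicians escalate documentation.
    concern_gain_range: tuple[float, float] = (0.3, 1.0)
    #: Fraction of event encounters whose deterioration is unanticipated:
    #: no concern ramp at all (gain 0).
    unanticipated_fraction: float = 0.15
    #: Fraction of event encounters with a physiologically sudden event
    #: (arrhythmia, embolism): no vital-sign drift before it.  Drawn
    #: independently of the unanticipated fraction.
    sudden_fraction: float = 0.15
    #: Per-measurement probability of a mildly abnormal vital value
    #: unrelated to deterioration (transient noise, measurement artifact).
    #: Keeps comparator scores realistically nonzero in stable patients.
    vital_outlier_rate: float = 0.02
    #: Fraction of encounters with chronically shifted vital baselines
    #: (sick-but-stable patients: COPD with low SpO2, AF with high HR, ...).
    #: They hold sustained moderate/high comparator-score exposure without
    #: deteriorating, as real ward populations do.
    chronic_abnormal_fraction: float = 0.10
    #: Range of the chronic severity draw (fraction of the calm-to-abnormal
    #: distance applied persistently to a random subset of vitals).
    chronic_severity_range: tuple[float, float] = (0.2, 0.7)
    #: Per-note probability that a given concept is tagged, at zero concern.
    note_concept_rate: float = 0.08
    hospice_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encounters <= 0:
            raise ConfigurationError("n_encounters must be positive")
        if not 0.0 <= self.event_fraction <= 1.0:
            raise ConfigurationError("event_fraction must lie in [0, 1]")
        if self.behavioral_onset_hours < self.physiological_onset_hours:
            raise ConfigurationError(
                "behavioral_onset_hours must be >= physiological_onset_hours"
            )
        if self.physiological_onset_hours <= 0:
            raise ConfigurationError("physiological_onset_hours must be positive")
        for name, mapping in (
            ("base_rates", self.base_rates),
            ("concern_multipliers", self.concern_multipliers),
        ):
            unknown = set(mapping) - set(EVENT_CHANNELS)
            if unknown:
                raise ConfigurationError(f"{name}: unknown channels {sorted(unknown)}")
            for ch, v in mapping.items():
                if v < 0:
                    raise ConfigurationError(f"{name}[{ch}] must be >= 0, got {v}")
        if any(h not in range(24) for h in self.vitals_schedule):
            raise ConfigurationError("vitals_schedule hours must be in 0..23")
        if not 0.0 < self.schedule_mass < 1.0:
            raise ConfigurationError("schedule_mass must lie in (0, 1)")
        if self.concern_ramp not in ("linear", "sigmoid"):
            raise ConfigurationError("concern_ramp must be 'linear' or 'sigmoid'")
        if self.drift_scale < 0:
            raise ConfigurationError("drift_scale must be >= 0")
        if not 0.0 <= self.note_concept_rate <= 1.0:
            raise ConfigurationError("note_concept_rate must lie in [0, 1]")
        if not 0.0 <= self.vital_outlier_rate <= 1.0:
            raise ConfigurationError("vital_outlier_rate must lie in [0, 1]")
        if not 0.0 <= self.chronic_abnormal_fraction <= 1.0:
            raise ConfigurationError("chronic_abnormal_fraction must lie in [0, 1]")
        c_lo, c_hi = self.chronic_severity_range
        if not 0.0 <= c_lo <= c_hi <= 1.0:
            raise ConfigurationError(
                "chronic_severity_range must satisfy 0 <= lo <= hi <= 1"
            )
        g_lo, g_hi = self.concern_gain_range
        if not 0.0 <= g_lo <= g_hi <= 1.0:
            raise ConfigurationError("concern_gain_range must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 <= self.unanticipated_fraction <= 1.0:
            raise ConfigurationError("unanticipated_fraction must lie in [0, 1]")
        if not 0.0 <= self.sudden_fraction <= 1.0:
            raise ConfigurationError("sudden_fraction must lie in [0, 1]")
        los = self.los_distribution
        if los.get("median_hours", 1.0) <= 0 or los.get("sigma", 1.0) <= 0:
            raise ConfigurationError("los_distribution median_hours/sigma must be > 0")

    def rate(self, channel: str) -> float:
        return float(self.base_rates.get(channel, 0.0))

    def multiplier(self, channel: str) -> float:
        return float(self.concern_multipliers.get(channel, 0.0))

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class FeatureConfig:
    window_hours: int = 12
    common_threshold: float = 1.0 / 24.0
    min_events_for_profile: int = 100

    def __post_init__(self) -> None:
        if self.window_hours <= 0:
            raise ConfigurationError("window_hours must be positive")
        if not 0.0 < self.common_threshold <= 1.0:
            raise ConfigurationError("common_threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ScoringConfig:
    horizon_hours: int = 12
    cutpoint_quantiles: tuple[float, float] = (0.80, 0.95)
    train_fraction: float = 0.5
    l2_strength: float = 1.0
    staleness_hours: int = 12
    #: Minimum event encounters required in the training split.  The
    #: L2-regularized fit stays stable well below the conservative
    #: library default of 50, so desk-scale pipelines use a lower floor.
    min_event_encounters: int = 10

    def __post_init__(self) -> None:
        if self.min_event_encounters < 2:
            raise ConfigurationError("min_event_encounters must be >= 2")
        if self.horizon_hours <= 0:
            raise ConfigurationError("horizon_hours must be positive")
        q1, q2 = self.cutpoint_quantiles
        if not 0.0 < q1 < q2 < 1.0:
            raise ConfigurationError(
                "cutpoint_quantiles must be strictly increasing in (0, 1)"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.l2_strength <= 0:
            raise ConfigurationError("l2_strength must be positive")


@dataclass(frozen=True)
class EvaluationConfig:
    horizons: tuple[int, ...] = tuple(range(1, 61))
    smoothing: float = 0.5
    #: "exact" — the first event falls exactly in hour bin t+h;
    #: "cumulative" — the first event falls within (t, t+h].
    horizon_convention: str = "exact"

    def __post_init__(self) -> None:
        if not self.horizons or any(h < 1 or h > 72 for h in self.horizons):
            raise ConfigurationError("horizons must be a nonempty subset of 1..72")
        if self.smoothing < 0:
            raise ConfigurationError("smoothing must be >= 0")
        if self.horizon_convention not in ("exact", "cumulative"):
            raise ConfigurationError(
                "horizon_convention must be 'exact' or 'cumulative'"
            )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration: one block per stage plus a
    single global seed that fans out to per-stage substreams."""

    sim: SimConfig = field(default_factory=SimConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        def as_plain(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: as_plain(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, Mapping):
                return {k: as_plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [as_plain(v) for v in obj]
            return obj

        return as_plain(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


_BLOCK_TYPES = {
    "sim": SimConfig,
    "features": FeatureConfig,
    "scoring": ScoringConfig,
    "evaluation": EvaluationConfig,
}


def _build_block(cls: type, raw: Mapping[str, Any], block: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{block}: unknown keys {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) and k in (
            "cutpoint_quantiles", "horizons", "vitals_schedule") else v
        for k, v in raw.items()
    }
    return cls(**coerced)


def load_pipeline_config(path: str | None = None, text: str | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file (or raw YAML text).

    Unknown top-level or block-level keys are rejected rather than ignored.
    """
    if text is None:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config file must contain a mapping")
    unknown = set(raw) - (set(_BLOCK_TYPES) | {"seed"})
    if unknown:
        raise ConfigurationError(f"unknown top-level keys {sorted(unknown)}")
    blocks = {
        name: _build_block(cls, raw.get(name, {}) or {}, name)
        for name, cls in _BLOCK_TYPES.items()
    }
    seed = int(raw.get("seed", 0))
    return PipelineConfig(seed=seed, **blocks)
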