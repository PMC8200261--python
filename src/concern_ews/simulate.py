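"""Synthetic clinician–CIS interaction cohorts.

The generator produces encounter, event-stream, and outcome tables whose
statistical structure mirrors what the behavioral early-warning analysis
assumes about real ward data:

* documentation events (vital rechecks, flowsheet comments, PRN
  administrations, withheld scheduled medications, nursing notes) arrive
  as inhomogeneous Poisson streams whose baseline intensity follows the
  standard-of-care charting schedule;
* for encounters that end in a deterioration event, a latent *concern*
  ramp ``c(t)`` inflates those intensities beginning tens of hours before
  the event, modelling nurses acting on clinical concern well before
  physiology changes;
* vital *values* drift toward MEWS/NEWS-abnormal ranges only in the last
  few hours before the event, driven by a separate ramp ``d(t)``.

Time is discretised to 1-hour, left-closed bins; admissions fall on whole
hours so bin boundaries align with wall-clock hours.  All randomness flows
through a single :class:`numpy.random.Generator`, so identical
(config, seed) pairs yield byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EVENT_CHANNELS, ConfigurationError, SimConfig

VITAL_KINDS = ("HR", "RR", "BP", "Temp", "SpO2")

OUTCOME_COMPONENTS = (
    "mortality",
    "cardiac_arrest",
    "icu_transfer",
    "rapid_response",
    "sepsis",
)
# Plausible composite mix on acute-care units: rapid responses and ICU
# transfers dominate; arrests are rare.
_COMPONENT_PROBS = (0.10, 0.05, 0.30, 0.35, 0.20)

UNIT_TYPES = ("medsurg", "stepdown", "icu")
_UNIT_PROBS = (0.60, 0.25, 0.15)

# Calm vital bands sit inside the zero-point bands of both comparator
# score tables, so an undrifted patient scores MEWS = NEWS = 0.  Abnormal
# targets are where the mean heads as d(t) -> 1.
_VITAL_PARAMS = {
    #  kind: (calm_lo, calm_hi, calm_center, sd, abnormal_target, hard_lo, hard_hi, decimals)
    "HR": (55.0, 90.0, 72.0, 5.0, 135.0, 20.0, 220.0, 0),
    "RR": (12.0, 14.0, 13.0, 0.7, 32.0, 4.0, 60.0, 0),
    "BP": (112.0, 160.0, 126.0, 7.0, 78.0, 40.0, 260.0, 0),
    "Temp": (36.2, 37.9, 37.0, 0.25, 39.5, 33.0, 42.0, 1),
    "SpO2": (96.0, 100.0, 98.0, 0.8, 88.0, 60.0, 100.0, 0),
}

_BASE_DATE = np.datetime64("2024-01-01T00:00:00", "s")

_MEASUREMENT_CHANNELS = {f"{k.lower()}_measurement": k for k in VITAL_KINDS}
_COMMENT_CHANNELS = {f"{k.lower()}_comment": k for k in VITAL_KINDS}


@dataclass(frozen=True)
class LatentTrajectory:
    """Hourly latent state of one encounter.

    ``concern[k]`` and ``physiological_drift[k]`` are the ramp values for
    hour bin ``[k, k+1)``, evaluated at the bin midpoint.  Both are
    identically zero for non-event encounters.
    """

    encounter_id: str
    concern: np.ndarray
    physiological_drift: np.ndarray
    event_time: float | None


def _ramp(t_mid: np.ndarray, event_time: float, onset: float, shape: str) -> np.ndarray:
    start = event_time - onset
    if shape == "linear":
        out = np.clip((t_mid - start) / onset, 0.0, 1.0)
    else:  # sigmoid, zeroed before onset start to honour the onset contract
        center = event_time - onset / 2.0
        out = 1.0 / (1.0 + np.exp(-(t_mid - center) * 10.0 / onset))
        out = np.where(t_mid < start, 0.0, out)
    return out


def simulate_latent_trajectory(
    event_time: float | None,
    los: float,
    config: SimConfig,
    encounter_id: str = "E00000",
    concern_gain: float = 1.0,
) -> LatentTrajectory:
    """Build the hourly concern and drift ramps for one encounter.

    ``event_time`` is hours since admission (or None for a censored
    encounter); both ramps rise linearly (or sigmoidally) from 0 at their
    onset, the concern ramp to ``concern_gain`` and the drift ramp to
    ``drift_scale``, at the event.
    """
    if los <= 0:
        raise ValueError("los must be positive")
    if event_time is not None and not (0.0 < event_time <= los):
        raise ValueError(
            f"event_time must lie in (0, los]; got event_time={event_time}, los={los}"
        )
    n_hours = int(math.ceil(los))
    t_mid = np.arange(n_hours) + 0.5
    if event_time is None:
        zero = np.zeros(n_hours)
        return LatentTrajectory(encounter_id, zero, zero.copy(), None)
    c = concern_gain * _ramp(
        t_mid, event_time, config.behavioral_onset_hours, config.concern_ramp
    )
    d = config.drift_scale * _ramp(
        t_mid, event_time, config.physiological_onset_hours, config.concern_ramp
    )
    return LatentTrajectory(encounter_id, c, d, float(event_time))


def schedule_weights(config: SimConfig) -> np.ndarray:
    """Hour-of-day weights for baseline documentation intensity (mean 1).

    A ``schedule_mass`` fraction of baseline event mass falls in the
    scheduled charting hours.  With an empty schedule the weights are flat.
    """
    w = np.ones(24)
    sched = sorted(set(config.vitals_schedule))
    if sched:
        n_s = len(sched)
        w[:] = (1.0 - config.schedule_mass) * 24.0 / (24 - n_s)
        w[list(sched)] = config.schedule_mass * 24.0 / n_s
    return w


# Mild-abnormality ranges for outlier draws (typically 0-2 comparator
# points per component, occasionally more)
_OUTLIER_RANGES = {
    "HR": (40.0, 140.0),
    "RR": (8.0, 28.0),
    "BP": (85.0, 200.0),
    "Temp": (35.0, 39.2),
    "SpO2": (88.0, 100.0),
}


def _draw_vital_values(
    kinds: np.ndarray,
    drift: np.ndarray,
    rng: np.random.Generator,
    outlier_rate: float = 0.0,
) -> np.ndarray:
    """Vital values whose mean interpolates from a calm center toward an
    abnormal target as drift rises; calm (d=0) draws are clipped into the
    zero-point band of both comparator tables.  A small fraction of
    measurements are mildly abnormal outliers regardless of drift."""
    n = len(kinds)
    values = np.empty(n, dtype=float)
    noise = rng.standard_normal(n)
    is_outlier = rng.random(n) < outlier_rate
    outlier_u = rng.random(n)
    for kind in VITAL_KINDS:
        sel = kinds == kind
        if not sel.any():
            continue
        lo, hi, center, sd, target, hard_lo, hard_hi, dec = _VITAL_PARAMS[kind]
        mean = center + drift[sel] * (target - center)
        v = np.round(mean + sd * noise[sel], dec)
        calm = drift[sel] == 0.0
        v = np.where(calm, np.clip(v, lo, hi), np.clip(v, hard_lo, hard_hi))
        o_lo, o_hi = _OUTLIER_RANGES[kind]
        v_out = np.round(o_lo + (o_hi - o_lo) * outlier_u[sel], dec)
        values[sel] = np.where(is_outlier[sel], v_out, v)
    return values


def _stream_from_grid(
    encounter_ids: np.ndarray,
    admit_ts: np.ndarray,
    admit_hod: np.ndarray,
    enc_row: np.ndarray,
    t: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    exposure: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    chronic: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw the event stream over a stacked encounter-hour grid.

    ``enc_row`` maps grid rows to encounters; ``t`` is the integer hour
    since admission; ``exposure`` in (0, 1] is the at-risk fraction of the
    bin (partial final hours).  ``chronic`` is an optional per-encounter ×
    vital-kind matrix of persistent baseline shifts; the effective drift of
    a measurement is the larger of the acute ramp and the chronic shift.
    """
    if chronic is None:
        chronic = np.zeros((len(encounter_ids), len(VITAL_KINDS)))
    n_rows = len(t)
    hod = (admit_hod[enc_row] + t) % 24
    w = schedule_weights(config)[hod]

    base = np.array([config.rate(ch) for ch in EVENT_CHANNELS])
    mult = np.array([config.multiplier(ch) for ch in EVENT_CHANNELS])
    rates = base[None, :] * w[:, None] * (1.0 + mult[None, :] * c[:, None])
    counts = rng.poisson(rates * exposure[:, None])

    flat = counts.ravel()
    nz = np.nonzero(flat)[0]
    reps = flat[nz]
    row = np.repeat(nz // len(EVENT_CHANNELS), reps)
    ch = np.repeat(nz % len(EVENT_CHANNELS), reps)
    offs = rng.random(len(row)) * exposure[row]

    parts: list[pd.DataFrame] = []

    def make_part(rows, frac, event_type, kind, value, o2, tags):
        ts = admit_ts[enc_row[rows]] + np.round((t[rows] + frac) * 3600.0).astype(
            "timedelta64[s]"
        )
        return pd.DataFrame(
            {
                "encounter_id": encounter_ids[enc_row[rows]],
                "timestamp": ts,
                "event_type": event_type,
                "vital_kind": kind,
                "value": value,
                "oxygen_supplemental": o2,
                "note_concepts": tags,
            }
        )

    channel_names = np.array(EVENT_CHANNELS)
    ch_name = channel_names[ch]

    # --- Poisson-driven discretionary measurements -----------------------
    meas_sel = np.isin(ch_name, list(_MEASUREMENT_CHANNELS))
    forced_rows = np.nonzero(
        np.isin(hod, list(config.vitals_schedule)) if config.vitals_schedule else
        np.zeros(n_rows, dtype=bool)
    )[0]

    meas_rows = row[meas_sel]
    meas_kinds = np.array(
        [_MEASUREMENT_CHANNELS[n] for n in ch_name[meas_sel]], dtype=object
    )
    # Forced routine vitals: all five kinds at the same timestamp (minute 0)
    forced_rep = np.repeat(forced_rows, len(VITAL_KINDS))
    forced_kinds = np.tile(np.array(VITAL_KINDS, dtype=object), len(forced_rows))

    all_meas_rows = np.concatenate([forced_rep, meas_rows])
    all_meas_frac = np.concatenate([np.zeros(len(forced_rep)), offs[meas_sel]])
    all_meas_kinds = np.asarray(
        np.concatenate([forced_kinds, meas_kinds]), dtype=object
    )
    kind_order = {k: i for i, k in enumerate(VITAL_KINDS)}
    kind_idx = np.array([kind_order[k] for k in all_meas_kinds])
    meas_drift = np.maximum(
        d[all_meas_rows], chronic[enc_row[all_meas_rows], kind_idx]
    )
    values = _draw_vital_values(
        all_meas_kinds,
        meas_drift,
        rng,
        config.vital_outlier_rate,
    )
    o2_flag = np.where(all_meas_kinds == "SpO2", meas_drift > 0.5, None)
    parts.append(
        make_part(
            all_meas_rows,
            all_meas_frac,
            "vital_measurement",
            all_meas_kinds,
            values,
            o2_flag,
            "",
        )
    )

    # --- Flowsheet comments ---------------------------------------------
    com_sel = np.isin(ch_name, list(_COMMENT_CHANNELS))
    if com_sel.any():
        parts.append(
            make_part(
                row[com_sel],
                offs[com_sel],
                "vital_comment",
                np.array([_COMMENT_CHANNELS[n] for n in ch_name[com_sel]], dtype=object),
                np.nan,
                None,
                "",
            )
        )

    # --- PRN / withheld ---------------------------------------------------
    for channel, etype in (
        ("prn_administered", "prn_administered"),
        ("scheduled_withheld", "scheduled_withheld"),
    ):
        sel = ch_name == channel
        if sel.any():
            parts.append(
                make_part(row[sel], offs[sel], etype, None, np.nan, None, "")
            )

    # --- Nursing notes with concept tags ----------------------------------
    note_sel = ch_name == "note_written"
    if note_sel.any():
        from .features import NOTE_CONCEPTS  # vocabulary lives with extraction

        note_rows = row[note_sel]
        # concept-tag enrichment scales with the same concern multiplier
        # as note volume, so zeroed multipliers null the tag signal too
        tag_mult = (2.0 / 3.0) * config.multiplier("note_written")
        p = np.clip(
            config.note_concept_rate * (1.0 + tag_mult * c[note_rows]), 0.0, 0.9
        )
        tags = rng.random((len(note_rows), len(NOTE_CONCEPTS))) < p[:, None]
        vocab = np.array(NOTE_CONCEPTS, dtype=object)
        joined = np.array(
            [";".join(vocab[t_row]) for t_row in tags], dtype=object
        )
        parts.append(
            make_part(note_rows, offs[note_sel], "note_written", None, np.nan, None, joined)
        )

    events = pd.concat(parts, ignore_index=True)
    events = events.sort_values(
        ["encounter_id", "timestamp", "event_type", "vital_kind"],
        kind="mergesort",
        na_position="last",
    ).reset_index(drop=True)
    return events


def simulate_events(
    trajectory: LatentTrajectory,
    encounter: pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Event stream for a single encounter given its latent trajectory."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if str(encounter["encounter_id"]) != trajectory.encounter_id:
        raise ValueError("trajectory does not belong to this encounter")
    admit = np.datetime64(encounter["admit_time"], "s")
    los = (np.datetime64(encounter["discharge_time"], "s") - admit) / np.timedelta64(
        1, "h"
    )
    at_risk = float(min(los, trajectory.event_time or np.inf))
    n_hours = int(math.ceil(at_risk))
    t = np.arange(n_hours)
    exposure = np.clip(at_risk - t, 0.0, 1.0)
    admit_hod = np.array([pd.Timestamp(admit).hour])
    return _stream_from_grid(
        np.array([trajectory.encounter_id], dtype=object),
        np.array([admit], dtype="datetime64[s]"),
        admit_hod,
        np.zeros(n_hours, dtype=int),
        t,
        trajectory.concern[:n_hours],
        trajectory.physiological_drift[:n_hours],
        exposure,
        config,
        rng,
    )


def simulate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: (encounters, events, outcomes).

    Event encounters carry exactly one outcome; their event streams stop
    at the event, censored encounters' at discharge.  Deterministic under
    a fixed (config, seed) pair.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters

    encounter_ids = np.array([f"E{i:05d}" for i in range(n)], dtype=object)
    patient_ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    unit_type = rng.choice(UNIT_TYPES, size=n, p=_UNIT_PROBS)
    ad = config.age_distribution
    age = np.clip(
        np.round(rng.normal(ad["mean"], ad["sd"], size=n), 1), ad["min"], ad["max"]
    )
    hospice = rng.random(n) < config.hospice_fraction
    admit_day = rng.integers(0, 365, size=n)
    admit_hour = rng.integers(0, 24, size=n)
    admit_ts = (
        _BASE_DATE
        + admit_day.astype("timedelta64[D]").astype("timedelta64[s]")
        + admit_hour.astype("timedelta64[h]").astype("timedelta64[s]")
    )
    los_cfg = config.los_distribution
    los = np.clip(
        los_cfg["median_hours"] * np.exp(los_cfg["sigma"] * rng.standard_normal(n)),
        los_cfg["min_hours"],
        los_cfg["max_hours"],
    )
    # Memoryless event generation: every encounter carries a constant
    # deterioration hazard; an event occurs iff the exponential candidate
    # time lands within the stay.  The hazard is calibrated so the
    # expected event share equals event_fraction.  Conditional on being at
    # risk at hour t, the event probability over any future window is then
    # constant in t — time since admission carries no artificial signal.
    if config.event_fraction > 0:
        m = _calibrate_event_scale(los, config.event_fraction)
        e_cand = np.maximum(rng.exponential(m, size=n), 2.0)
        is_event = e_cand <= 0.98 * los
        event_time = np.where(is_event, e_cand, np.nan)
    else:
        is_event = np.zeros(n, dtype=bool)
        event_time = np.full(n, np.nan)
    component = rng.choice(OUTCOME_COMPONENTS, size=n, p=_COMPONENT_PROBS)

    encounters = pd.DataFrame(
        {
            "encounter_id": encounter_ids,
            "patient_id": patient_ids,
            "age": age,
            "unit_type": unit_type,
            "admit_time": admit_ts,
            "discharge_time": admit_ts
            + np.round(los * 3600.0).astype("timedelta64[s]"),
            "hospice_flag": hospice,
        }
    )
    outcomes = pd.DataFrame(
        {
            "encounter_id": encounter_ids[is_event],
            "event_time": np.round(event_time[is_event], 3),
            "component": component[is_event],
        }
    ).reset_index(drop=True)

    # Stacked encounter-hour grid over the at-risk period
    at_risk = np.where(is_event, event_time, los)
    n_hours = np.ceil(at_risk).astype(int)
    enc_row = np.repeat(np.arange(n), n_hours)
    offsets = np.concatenate([[0], np.cumsum(n_hours)])[:-1]
    t = np.arange(n_hours.sum()) - offsets[enc_row]
    t_mid = t + 0.5

    # Per-encounter concern gain: heterogeneous anticipation, including a
    # fraction of wholly unanticipated deteriorations.
    g_lo, g_hi = config.concern_gain_range
    gain = rng.uniform(g_lo, g_hi, size=n)
    gain[rng.random(n) < config.unanticipated_fraction] = 0.0
    # Sudden deteriorations: no physiological warning before the event
    drift_gain = np.ones(n)
    drift_gain[rng.random(n) < config.sudden_fraction] = 0.0

    # Chronically shifted vital baselines for a sick-but-stable subgroup
    c_lo, c_hi = config.chronic_severity_range
    chronic = np.zeros((n, len(VITAL_KINDS)))
    is_chronic = rng.random(n) < config.chronic_abnormal_fraction
    severity = rng.uniform(c_lo, c_hi, size=n)
    affected = rng.random((n, len(VITAL_KINDS))) < 0.5
    chronic[is_chronic] = (severity[:, None] * affected)[is_chronic]

    ev_rows = is_event[enc_row]
    c = np.zeros(len(t))
    d = np.zeros(len(t))
    if ev_rows.any():
        et = event_time[enc_row[ev_rows]]
        c[ev_rows] = gain[enc_row[ev_rows]] * _ramp_vec(
            t_mid[ev_rows], et, config.behavioral_onset_hours, config.concern_ramp
        )
        d[ev_rows] = (
            config.drift_scale
            * drift_gain[enc_row[ev_rows]]
            * _ramp_vec(
                t_mid[ev_rows], et, config.physiological_onset_hours,
                config.concern_ramp,
            )
        )
    exposure = np.clip(at_risk[enc_row] - t, 0.0, 1.0)

    events = _stream_from_grid(
        encounter_ids,
        admit_ts,
        admit_hour,
        enc_row,
        t,
        c,
        d,
        exposure,
        config,
        rng,
        chronic=chronic,
    )
    return encounters, events, outcomes


def _calibrate_event_scale(los: np.ndarray, fraction: float) -> float:
    """Exponential scale m such that P(Exp(m) <= 0.98 los) averages to the
    requested event fraction over the realized stays."""
    from scipy.optimize import brentq

    frac = min(fraction, 0.995)

    def excess(log_m: float) -> float:
        return float(np.mean(1.0 - np.exp(-0.98 * los / np.exp(log_m)))) - frac

    return float(np.exp(brentq(excess, np.log(1e-2), np.log(1e7), xtol=1e-10)))


def _ramp_vec(
    t_mid: np.ndarray, event_time: np.ndarray, onset: float, shape: str
) -> np.ndarray:
    start = event_time - onset
    if shape == "linear":
        return np.clip((t_mid - start) / onset, 0.0, 1.0)
    center = event_time - onset / 2.0
    out = 1.0 / (1.0 + np.exp(-(t_mid - center) * 10.0 / onset))
    return np.where(t_mid < start, 0.0, out)


def simulate_planted_hazard_cohort(
    n_encounters: int,
    hazard_ratio_high: float,
    seed: int,
    baseline_hazard: float = 0.002,
    p_enter_high: float = 0.02,
    p_exit_high: float = 0.10,
    max_hours: int = 240,
) -> pd.DataFrame:
    """Cohort with a *known* planted hazard ratio, in counting-process form.

    Each encounter carries a two-state (low/high) hourly covariate process
    evolving as a Markov chain; the event hazard is ``baseline_hazard`` in
    the low state and ``baseline_hazard × hazard_ratio_high`` in the high
    state.  Used as a generative oracle for parameter-recovery checks of
    the time-varying Cox fit.

    Returns a DataFrame with columns ``encounter_id, start, stop, high,
    event`` (half-open (start, stop] hour intervals).
    """
    if hazard_ratio_high <= 0:
        raise ConfigurationError("hazard_ratio_high must be positive")
    rng = np.random.default_rng(seed)
    n, T = n_encounters, max_hours

    # Hourly covariate states (n, T), stationary start
    pi_high = p_enter_high / (p_enter_high + p_exit_high)
    z = np.zeros((n, T), dtype=np.int8)
    z[:, 0] = rng.random(n) < pi_high
    flips = rng.random((n, T))
    for k in range(1, T):
        enter = (z[:, k - 1] == 0) & (flips[:, k] < p_enter_high)
        stay = (z[:, k - 1] == 1) & (flips[:, k] >= p_exit_high)
        z[:, k] = (enter | stay).astype(np.int8)

    lam = baseline_hazard * np.where(z == 1, hazard_ratio_high, 1.0)
    p_event = 1.0 - np.exp(-lam)
    hit = rng.random((n, T)) < p_event
    first = np.where(hit.any(axis=1), hit.argmax(axis=1), T)  # event hour bin or censor
    has_event = first < T
    end_hour = np.where(has_event, first + 1, T)

    # Run-length encode states up to the end hour
    frames = []
    hour_idx = np.arange(T)
    enc_ids = np.array([f"H{i:05d}" for i in range(n)], dtype=object)
    keep = hour_idx[None, :] < end_hour[:, None]
    enc_of = np.repeat(np.arange(n), end_hour)
    t_of = hour_idx[None, :].repeat(n, axis=0)[keep]
    z_of = z[keep]
    new_run = np.ones(len(t_of), dtype=bool)
    new_run[1:] = (enc_of[1:] != enc_of[:-1]) | (z_of[1:] != z_of[:-1])
    run_id = np.cumsum(new_run) - 1
    df = pd.DataFrame({"enc": enc_of, "t": t_of, "z": z_of, "run": run_id})
    runs = df.groupby("run", sort=True).agg(
        enc=("enc", "first"), start=("t", "min"), stop=("t", "max"), z=("z", "first")
    )
    runs["stop"] = runs["stop"] + 1
    runs["event"] = False
    last_run = df.groupby("enc")["run"].max()
    runs.loc[last_run[has_event].to_numpy(), "event"] = True
    out = pd.DataFrame(
        {
            "encounter_id": enc_ids[runs["enc"].to_numpy()],
            "start": runs["start"].to_numpy(float),
            "stop": runs["stop"].to_numpy(float),
            "high": runs["z"].to_numpy(int),
            "event": runs["event"].to_numpy(bool),
        }
    ).reset_index(drop=True)
    return out
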