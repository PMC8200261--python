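"""Cohort inclusion filters and the hourly behavioral feature matrix.

The feature matrix has one row per (encounter, patient-hour) and 55
columns: 15 base documentation-frequency features, each split into a
*common-time* and an *uncommon-time* count (30 columns), 21 nursing-note
concept counts, and 4 temporal features.  All count features are trailing
window sums (default 12 hours), so every row is computable in simulated
real time from the stream observed up to that hour.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class VocabularyError(ValueError):
    """A note carries a concept label outside the fixed vocabulary."""


class ReferentialIntegrityError(ValueError):
    """Events reference encounters absent from the encounter table."""


#: The 21-term nursing-note concept vocabulary.  Synthetic notes carry
#: these tags directly; no free-text processing happens here.
NOTE_CONCEPTS = (
    "abdominal_pain",
    "abnormal_heart_rhythm",
    "abnormal_mental_state",
    "abnormal_respirations",
    "abnormal_temperature",
    "back_pain",
    "chest_pain",
    "communication_problem",
    "infection_diagnosis",
    "circulation_deficit",
    "fall_risk",
    "fluid_volume_alteration",
    "general_concern",
    "headache",
    "improper_renal_function",
    "infection_medication",
    "monitoring",
    "mood_disorder",
    "musculoskeletal_pain",
    "pain_level",
    "violence_gesture",
)

#: The 15 base measurement features, in column order.  Each expands to a
#: ``*_common`` / ``*_uncommon`` pair by whether the underlying event fell
#: in an hour of day the feature is commonly charted.
BASE_FEATURES = (
    "hr_measurement",
    "rr_measurement",
    "bp_measurement",
    "temp_measurement",
    "spo2_measurement",
    "all_vitals_same_time",
    "only_one_vital",
    "hr_comment",
    "rr_comment",
    "bp_comment",
    "temp_comment",
    "spo2_comment",
    "prn_administered",
    "scheduled_withheld",
    "note_written",
)

TEMPORAL_FEATURES = ("month", "day_of_week", "hour", "patient_hour")

#: Two charting actions count as simultaneous when they share a 5-minute
#: timestamp bin; a vitals-taking episode is a maximal run of vital
#: measurements with gaps under 15 minutes.
SIMULTANEITY_BIN_MINUTES = 5
EPISODE_GAP_MINUTES = 15


def measurement_columns() -> list[str]:
    return [f"{f}_{side}" for f in BASE_FEATURES for side in ("common", "uncommon")]


def note_columns() -> list[str]:
    return list(NOTE_CONCEPTS)


def feature_columns() -> list[str]:
    """The 55 feature columns in their stable documented order."""
    return measurement_columns() + note_columns() + list(TEMPORAL_FEATURES)


@dataclass(frozen=True)
class CommonTimeProfile:
    """Hours of day at which a feature is commonly charted."""

    feature_name: str
    common_hours: frozenset[int]
    source: str  # "empirical" or "configured"

    def __post_init__(self) -> None:
        if not self.common_hours:
            raise ValueError(f"{self.feature_name}: common_hours must be nonempty")
        if any(h not in range(24) for h in self.common_hours):
            raise ValueError(f"{self.feature_name}: hours must be in 0..23")


# ---------------------------------------------------------------------------
# Inclusion filters
# ---------------------------------------------------------------------------

_FILTER_COLUMNS = ("encounter_id", "age", "admit_time", "discharge_time", "hospice_flag")

INCLUSION_RULES = (
    "unit_stay_24h_or_less",
    "age_under_18",
    "hospice",
    "stay_over_60_days",
)


def apply_inclusion_filters(
    encounters: pd.DataFrame, outcomes: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Retain encounters eligible for the analysis cohort.

    Eligibility: more than 24 hours on a study unit (strict), age >= 18,
    not receiving hospice care, and a total stay of at most 60 days
    (a stay of exactly 60 days is retained).  Returns the filtered table
    and a per-rule exclusion tally; an encounter violating several rules
    is tallied under each.
    """
    missing = [c for c in _FILTER_COLUMNS if c not in encounters.columns]
    if missing:
        raise SchemaError(f"encounter table missing columns: {missing}")
    stay_h = (
        pd.to_datetime(encounters["discharge_time"])
        - pd.to_datetime(encounters["admit_time"])
    ) / pd.Timedelta(hours=1)
    violations = {
        "unit_stay_24h_or_less": stay_h <= 24.0,
        "age_under_18": encounters["age"] < 18.0,
        "hospice": encounters["hospice_flag"].astype(bool),
        "stay_over_60_days": stay_h > 60.0 * 24.0,
    }
    tally = {rule: int(mask.sum()) for rule, mask in violations.items()}
    keep = ~np.logical_or.reduce(list(violations.values()))
    filtered = encounters.loc[keep].reset_index(drop=True)
    logger.info(
        "inclusion filters: %d/%d retained; exclusions %s",
        len(filtered),
        len(encounters),
        tally,
    )
    return filtered, tally


# ---------------------------------------------------------------------------
# Common/uncommon hour profiles
# ---------------------------------------------------------------------------


def _event_feature_names(events: pd.DataFrame) -> pd.Series:
    """Map event rows to base feature names (excluding the two derived
    vitals-pattern features)."""
    etype = events["event_type"].astype(str)
    kind = events["vital_kind"].astype(str).str.lower()
    name = etype.copy()
    is_meas = etype == "vital_measurement"
    is_com = etype == "vital_comment"
    name[is_meas] = kind[is_meas] + "_measurement"
    name[is_com] = kind[is_com] + "_comment"
    return name


def learn_common_hours(
    events: pd.DataFrame,
    feature_name: str,
    threshold: float = 1.0 / 24.0,
    min_events: int = 100,
    fallback_hours: tuple[int, ...] = (0, 4, 8, 12, 16, 20),
) -> CommonTimeProfile:
    """Learn the hours of day at which ``feature_name`` events commonly occur.

    An hour is *common* when its empirical share of events is at least
    ``threshold`` (default 1/24: above-uniform density).  With fewer than
    ``min_events`` observations the routine-vitals schedule is used as a
    configured fallback, with a logged warning.
    """
    names = _event_feature_names(events)
    ts = pd.to_datetime(events.loc[names == feature_name, "timestamp"])
    if len(ts) < min_events:
        logger.warning(
            "%s: only %d events (< %d); falling back to configured schedule",
            feature_name,
            len(ts),
            min_events,
        )
        return CommonTimeProfile(feature_name, frozenset(fallback_hours), "configured")
    share = ts.dt.hour.value_counts(normalize=True)
    common = frozenset(int(h) for h, s in share.items() if s >= threshold - 1e-12)
    return CommonTimeProfile(feature_name, common, "empirical")


def learn_all_profiles(
    events: pd.DataFrame,
    threshold: float = 1.0 / 24.0,
    min_events: int = 100,
    fallback_hours: tuple[int, ...] = (0, 4, 8, 12, 16, 20),
) -> dict[str, CommonTimeProfile]:
    """Profiles for all 15 base features.

    The two derived vitals-pattern features share the pooled profile of
    all vital measurements (their occurrences are vitals-taking actions).
    """
    profiles: dict[str, CommonTimeProfile] = {}
    for f in BASE_FEATURES:
        if f in ("all_vitals_same_time", "only_one_vital"):
            continue
        profiles[f] = learn_common_hours(events, f, threshold, min_events, fallback_hours)
    pooled_events = events[events["event_type"] == "vital_measurement"]
    pooled_ts = pd.to_datetime(pooled_events["timestamp"])
    if len(pooled_ts) >= min_events:
        share = pooled_ts.dt.hour.value_counts(normalize=True)
        pooled = frozenset(int(h) for h, s in share.items() if s >= threshold - 1e-12)
        source = "empirical"
    else:
        pooled, source = frozenset(fallback_hours), "configured"
    for f in ("all_vitals_same_time", "only_one_vital"):
        profiles[f] = CommonTimeProfile(f, pooled, source)
    return profiles


# ---------------------------------------------------------------------------
# Hourly feature matrix
# ---------------------------------------------------------------------------


def _hour_grid(
    encounters: pd.DataFrame, outcomes: pd.DataFrame | None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-encounter hourly grid up to censoring (event or discharge).

    Only fully observed hours form rows: the partial bin truncated by the
    event or discharge is dropped, as in discrete-time survival person-
    periods — a row's window otherwise systematically undercounts exactly
    where the outcome happens.
    """
    enc = encounters.copy()
    enc["admit_time"] = pd.to_datetime(enc["admit_time"])
    enc["discharge_time"] = pd.to_datetime(enc["discharge_time"])
    at_risk = (enc["discharge_time"] - enc["admit_time"]) / pd.Timedelta(hours=1)
    if outcomes is not None and len(outcomes):
        first = outcomes.groupby("encounter_id")["event_time"].min()
        mapped = enc["encounter_id"].map(first)
        at_risk = np.fmin(at_risk, mapped.astype(float))
    n_hours = np.floor(at_risk).astype(int).clip(lower=1)
    enc["n_hours"] = n_hours
    offsets = np.concatenate([[0], np.cumsum(n_hours)])[:-1]
    enc["row_offset"] = offsets
    return enc, {e: i for i, e in enumerate(enc["encounter_id"])}


def _occurrences(events: pd.DataFrame) -> pd.DataFrame:
    """One row per base-feature occurrence: (encounter_id, timestamp, feature).

    Includes the two derived vitals-pattern occurrences: a simultaneity
    bin containing all five vital kinds, and a vitals-taking episode
    containing exactly one measurement.
    """
    base = pd.DataFrame(
        {
            "encounter_id": events["encounter_id"],
            "timestamp": pd.to_datetime(events["timestamp"]),
            "feature": _event_feature_names(events),
        }
    )
    meas = base[events["event_type"].to_numpy() == "vital_measurement"]
    extras = []
    if len(meas):
        m = meas.sort_values(["encounter_id", "timestamp"], kind="mergesort")
        # all five kinds within one simultaneity bin
        bins = m["timestamp"].dt.floor(f"{SIMULTANEITY_BIN_MINUTES}min")
        kinds = events.loc[m.index, "vital_kind"]
        g = pd.DataFrame(
            {"encounter_id": m["encounter_id"], "bin": bins, "kind": kinds,
             "timestamp": m["timestamp"]}
        ).groupby(["encounter_id", "bin"], sort=False)
        agg = g.agg(nk=("kind", "nunique"), ts=("timestamp", "min"))
        all5 = agg[agg["nk"] == 5].reset_index()
        if len(all5):
            extras.append(
                pd.DataFrame(
                    {
                        "encounter_id": all5["encounter_id"],
                        "timestamp": all5["ts"],
                        "feature": "all_vitals_same_time",
                    }
                )
            )
        # episodes: maximal runs with gaps < EPISODE_GAP_MINUTES
        gap = m.groupby("encounter_id", sort=False)["timestamp"].diff()
        new_ep = gap.isna() | (gap >= pd.Timedelta(minutes=EPISODE_GAP_MINUTES))
        ep_id = new_ep.cumsum()
        sizes = ep_id.map(ep_id.value_counts())
        singles = m[sizes == 1]
        if len(singles):
            extras.append(
                pd.DataFrame(
                    {
                        "encounter_id": singles["encounter_id"],
                        "timestamp": singles["timestamp"],
                        "feature": "only_one_vital",
                    }
                )
            )
    return pd.concat([base] + extras, ignore_index=True)


def _windowed_sums(
    counts: np.ndarray, row_start: np.ndarray, window: int
) -> np.ndarray:
    """Trailing-window sums along rows, resetting at encounter boundaries.

    ``row_start[i]`` is the first grid row of row i's encounter; the
    window for row i covers rows max(i-window+1, start) .. i.
    """
    cs = np.vstack([np.zeros((1, counts.shape[1])), np.cumsum(counts, axis=0)])
    i = np.arange(len(counts))
    lower = np.maximum(i - window + 1, row_start)
    return cs[i + 1] - cs[lower]


def count_note_concepts(
    events: pd.DataFrame,
    encounters: pd.DataFrame,
    window_hours: int = 12,
    outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Trailing-window counts of notes tagged with each of the 21 concepts.

    Returns one row per (encounter, patient_hour) with the 21 concept
    columns; unknown concept labels raise :class:`VocabularyError`.
    """
    matrix = build_hourly_features(
        events, encounters, profiles=None, window_hours=window_hours, outcomes=outcomes
    )
    return matrix[["encounter_id", "patient_hour"] + note_columns()]


def build_hourly_features(
    events: pd.DataFrame,
    encounters: pd.DataFrame,
    profiles: dict[str, CommonTimeProfile] | None = None,
    window_hours: int = 12,
    outcomes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Construct the per patient-hour feature matrix.

    Parameters
    ----------
    events, encounters, outcomes
        Tables as produced by the simulator (or equivalent real exports).
        When ``outcomes`` is given, each event encounter's grid stops at
        the hour containing its first event.
    profiles
        Common-hour profile per base feature; when None, profiles are
        learned from ``events`` with defaults.
    window_hours
        Trailing aggregation window, closed on the right at the row's
        hour end.
    """
    unknown_enc = set(events["encounter_id"]) - set(encounters["encounter_id"])
    if unknown_enc:
        raise ReferentialIntegrityError(
            f"events reference unknown encounters: {sorted(unknown_enc)[:10]}"
        )
    if profiles is None:
        profiles = learn_all_profiles(events)
    for f in BASE_FEATURES:
        if f not in profiles:
            raise ValueError(f"missing common-time profile for feature {f!r}")

    enc, enc_index = _hour_grid(encounters, outcomes)
    n_rows = int(enc["n_hours"].sum())
    n_meas, n_note = 2 * len(BASE_FEATURES), len(NOTE_CONCEPTS)
    counts = np.zeros((n_rows, n_meas + n_note), dtype=np.int64)

    admit_by_enc = enc.set_index("encounter_id")["admit_time"]
    offset_arr = enc["row_offset"].to_numpy()
    nh_arr = enc["n_hours"].to_numpy()

    occ = _occurrences(events)
    eidx = occ["encounter_id"].map(enc_index)
    if eidx.isna().any():
        # encounters excluded by filters: their events are simply dropped
        keep = eidx.notna()
        occ, eidx = occ[keep], eidx[keep]
    eidx = eidx.astype(int).to_numpy()
    ts = occ["timestamp"].to_numpy()
    admits = admit_by_enc.to_numpy()[eidx]
    ph = ((ts - admits) / np.timedelta64(1, "h")).astype(float)
    hour_bin = np.floor(ph).astype(int)
    in_grid = (hour_bin >= 0) & (hour_bin < nh_arr[eidx])
    occ, eidx, hour_bin = occ[in_grid], eidx[in_grid], hour_bin[in_grid]
    hod = pd.DatetimeIndex(occ["timestamp"]).hour.to_numpy()

    feat_idx = occ["feature"].map({f: i for i, f in enumerate(BASE_FEATURES)})
    common_sets = {i: profiles[f].common_hours for i, f in enumerate(BASE_FEATURES)}
    is_common = np.zeros(len(occ), dtype=bool)
    fi = feat_idx.to_numpy()
    for i, hours in common_sets.items():
        sel = fi == i
        if sel.any():
            is_common[sel] = np.isin(hod[sel], list(hours))
    col = 2 * fi + np.where(is_common, 0, 1)
    rows = offset_arr[eidx] + hour_bin
    np.add.at(counts, (rows, col), 1)

    # note concepts
    notes = events[events["event_type"] == "note_written"]
    tags = notes["note_concepts"].fillna("")
    tagged = notes[tags.str.len() > 0]
    if len(tagged):
        exploded = (
            tagged["note_concepts"].str.split(";").explode().to_frame("concept")
        )
        exploded["encounter_id"] = tagged.loc[exploded.index, "encounter_id"]
        exploded["timestamp"] = pd.to_datetime(tagged.loc[exploded.index, "timestamp"])
        bad = set(exploded["concept"]) - set(NOTE_CONCEPTS)
        if bad:
            raise VocabularyError(f"unknown note concepts: {sorted(bad)}")
        ne = exploded["encounter_id"].map(enc_index)
        keep = ne.notna()
        exploded, ne = exploded[keep], ne[keep].astype(int).to_numpy()
        nts = exploded["timestamp"].to_numpy()
        nph = np.floor(
            (nts - admit_by_enc.to_numpy()[ne]) / np.timedelta64(1, "h")
        ).astype(int)
        ok = (nph >= 0) & (nph < nh_arr[ne])
        cidx = exploded["concept"].map({c: i for i, c in enumerate(NOTE_CONCEPTS)})
        np.add.at(
            counts,
            (offset_arr[ne[ok]] + nph[ok], n_meas + cidx.to_numpy()[ok]),
            1,
        )

    row_start = np.repeat(offset_arr, nh_arr)
    windowed = _windowed_sums(counts, row_start, window_hours).astype(np.int64)

    enc_of_row = np.repeat(np.arange(len(enc)), nh_arr)
    t = np.arange(n_rows) - row_start
    wallclock = admit_by_enc.to_numpy()[enc_of_row] + t.astype("timedelta64[h]")
    wc = pd.DatetimeIndex(wallclock)

    out = pd.DataFrame(
        windowed, columns=measurement_columns() + note_columns()
    )
    out.insert(0, "encounter_id", enc["encounter_id"].to_numpy()[enc_of_row])
    out["month"] = wc.month
    out["day_of_week"] = wc.dayofweek
    out["hour"] = wc.hour
    out["patient_hour"] = t
    return out
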