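"""Feature extraction: inclusion filters, common-hour learning, and the
hourly window counts checked against a naive full-rescan oracle."""

import numpy as np
import pandas as pd
import pytest

from concern_ews.features import (
    BASE_FEATURES,
    NOTE_CONCEPTS,
    CommonTimeProfile,
    ReferentialIntegrityError,
    SchemaError,
    VocabularyError,
    apply_inclusion_filters,
    build_hourly_features,
    count_note_concepts,
    feature_columns,
    learn_all_profiles,
    learn_common_hours,
    measurement_columns,
    note_columns,
)
from concern_ews.simulate import simulate_cohort
from concern_ews.config import SimConfig

from conftest import make_events


def toy_encounter_table():
    """Six encounters violating one inclusion rule each plus one clean."""
    admit = pd.Timestamp("2024-05-01 08:00:00")

    def enc(i, age, los_h, hospice):
        return {
            "encounter_id": f"F{i}",
            "patient_id": f"P{i}",
            "age": age,
            "unit_type": "medsurg",
            "admit_time": admit,
            "discharge_time": admit + pd.Timedelta(hours=los_h),
            "hospice_flag": hospice,
        }

    return pd.DataFrame(
        [
            enc(0, 55.0, 48.0, False),        # clean
            enc(1, 55.0, 20.0, False),        # stay too short
            enc(2, 55.0, 24.0, False),        # boundary: exactly 24 h excluded
            enc(3, 17.0, 48.0, False),        # minor
            enc(4, 17.9, 48.0, False),        # boundary: still under 18
            enc(5, 55.0, 48.0, True),         # hospice
            enc(6, 55.0, 61 * 24.0, False),   # stay over 60 days
        ]
    )


class TestInclusionFilters:
    def test_one_survivor_and_per_rule_tally(self):
        filtered, tally = apply_inclusion_filters(toy_encounter_table())
        assert list(filtered["encounter_id"]) == ["F0"]
        assert tally == {
            "unit_stay_24h_or_less": 2,
            "age_under_18": 2,
            "hospice": 1,
            "stay_over_60_days": 1,
        }

    def test_sixty_day_stay_retained(self):
        df = toy_encounter_table()
        df.loc[6, "discharge_time"] = df.loc[6, "admit_time"] + pd.Timedelta(days=60)
        filtered, _ = apply_inclusion_filters(df)
        assert set(filtered["encounter_id"]) == {"F0", "F6"}

    def test_idempotent(self):
        once, _ = apply_inclusion_filters(toy_encounter_table())
        twice, tally = apply_inclusion_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(v == 0 for v in tally.values())

    def test_missing_column_raises_schema_error(self):
        with pytest.raises(SchemaError, match="age"):
            apply_inclusion_filters(toy_encounter_table().drop(columns=["age"]))


class TestCommonHours:
    def _events_at_hours(self, hours):
        day = pd.Timestamp("2024-01-01")
        return make_events(
            [
                ("E0", day + pd.Timedelta(days=i, hours=int(h)),
                 "prn_administered", None, np.nan, None, "")
                for i, h in enumerate(np.resize(hours, 120))
            ]
        )

    def test_point_mass_single_common_hour(self):
        prof = learn_common_hours(self._events_at_hours([8]), "prn_administered")
        assert prof.common_hours == frozenset({8})
        assert prof.source == "empirical"

    def test_uniform_distribution_all_common(self):
        prof = learn_common_hours(self._events_at_hours(range(24)), "prn_administered")
        assert prof.common_hours == frozenset(range(24))

    def test_schedule_recovered_from_concentrated_mass(self, rng):
        # 90% of events on the q4h schedule, 10% spread elsewhere
        sched = [0, 4, 8, 12, 16, 20]
        off = [h for h in range(24) if h not in sched]
        hours = np.concatenate(
            [rng.choice(sched, 900), rng.choice(off, 100)]
        )
        prof = learn_common_hours(self._events_at_hours(hours), "prn_administered")
        assert prof.common_hours == frozenset(sched)

    def test_too_few_events_falls_back_to_schedule(self, caplog):
        events = self._events_at_hours([8])[:10]
        with caplog.at_level("WARNING"):
            prof = learn_common_hours(events, "prn_administered")
        assert prof.source == "configured"
        assert prof.common_hours == frozenset({0, 4, 8, 12, 16, 20})
        assert any("falling back" in r.message for r in caplog.records)

    def test_profile_requires_nonempty_hours(self):
        with pytest.raises(ValueError, match="nonempty"):
            CommonTimeProfile("x", frozenset(), "configured")


def brute_force_cell(events, enc_id, admit, hour, feature, profiles, window, side):
    """Independent O(n^2) rescan: count feature occurrences in the trailing
    window, split by common/uncommon hour of day."""
    lo = admit + pd.Timedelta(hours=hour + 1 - window)
    hi = admit + pd.Timedelta(hours=hour + 1)
    n = 0
    for _, ev in events[events["encounter_id"] == enc_id].iterrows():
        ts = ev["timestamp"]
        if not (lo <= ts < hi) or ts < admit:
            continue
        etype, kind = ev["event_type"], ev["vital_kind"]
        name = {
            "vital_measurement": f"{str(kind).lower()}_measurement",
            "vital_comment": f"{str(kind).lower()}_comment",
        }.get(etype, etype)
        if name != feature:
            continue
        is_common = ts.hour in profiles[feature].common_hours
        if (side == "common") == is_common:
            n += 1
    return n


class TestHourlyFeatures:
    def test_column_group_counts(self, default_cohort):
        _, (encounters, events, outcomes) = default_cohort
        filtered, _ = apply_inclusion_filters(encounters)
        kept = events[events["encounter_id"].isin(set(filtered["encounter_id"]))]
        matrix = build_hourly_features(kept, filtered, outcomes=outcomes)
        assert len(measurement_columns()) == 30
        assert len(note_columns()) == 21
        cols = [c for c in matrix.columns if c != "encounter_id"]
        assert len(cols) == 55
        assert cols == feature_columns()

    def test_partition_identity_common_plus_uncommon(self, default_cohort):
        _, (encounters, events, outcomes) = default_cohort
        matrix = build_hourly_features(events, encounters, outcomes=outcomes)
        # totals recomputed with a single all-hours "common" profile
        profiles = {
            f: CommonTimeProfile(f, frozenset(range(24)), "configured")
            for f in BASE_FEATURES
        }
        totals = build_hourly_features(events, encounters, profiles, outcomes=outcomes)
        for f in BASE_FEATURES:
            lhs = matrix[f"{f}_common"] + matrix[f"{f}_uncommon"]
            np.testing.assert_array_equal(lhs.to_numpy(), totals[f"{f}_common"].to_numpy())
            assert (totals[f"{f}_uncommon"] == 0).all()

    def test_cells_match_brute_force_oracle(self, toy_encounters, rng):
        admits = toy_encounters.set_index("encounter_id")["admit_time"]
        rows = []
        kinds = ["HR", "RR", "BP", "Temp", "SpO2"]
        for enc_id, admit in admits.items():
            for _ in range(40):
                offs = rng.uniform(0, 30 * 3600)
                etype = rng.choice(
                    ["vital_measurement", "vital_comment", "prn_administered",
                     "scheduled_withheld", "note_written"]
                )
                kind = rng.choice(kinds) if "vital" in etype else None
                rows.append(
                    (enc_id, admit + pd.Timedelta(seconds=float(offs)), etype,
                     kind, 100.0 if etype == "vital_measurement" else np.nan,
                     None, "")
                )
        events = make_events(rows)
        profiles = learn_all_profiles(events, min_events=1)
        matrix = build_hourly_features(events, toy_encounters, profiles)
        checks = 0
        simple = [f for f in BASE_FEATURES
                  if f not in ("all_vitals_same_time", "only_one_vital")]
        for _ in range(60):
            row = matrix.iloc[rng.integers(len(matrix))]
            feature = simple[rng.integers(len(simple))]
            side = ("common", "uncommon")[rng.integers(2)]
            expected = brute_force_cell(
                events, row["encounter_id"], admits[row["encounter_id"]],
                int(row["patient_hour"]), feature, profiles, 12, side,
            )
            assert row[f"{feature}_{side}"] == expected
            checks += 1
        assert checks == 60

    def test_monotonicity_adding_event_never_decreases_counts(self, toy_encounters):
        base_rows = [
            ("T0", "2024-03-04 10:15", "prn_administered", None, np.nan, None, ""),
            ("T0", "2024-03-04 19:40", "note_written", None, np.nan, None, "pain_level"),
        ]
        events = make_events(base_rows)
        profiles = learn_all_profiles(events, min_events=10**9)  # configured fallback
        before = build_hourly_features(events, toy_encounters, profiles)
        extra = make_events(
            base_rows + [("T0", "2024-03-04 14:05", "vital_comment", "RR",
                          np.nan, None, "")]
        )
        after = build_hourly_features(extra, toy_encounters, profiles)
        num_cols = measurement_columns() + note_columns()
        assert (after[num_cols].to_numpy() >= before[num_cols].to_numpy()).all()

    def test_all_five_vitals_same_bin_indicator(self, toy_encounters):
        ts = pd.Timestamp("2024-03-04 10:02")
        rows = [
            ("T0", ts + pd.Timedelta(minutes=i % 3), "vital_measurement", k,
             100.0, None, "")
            for i, k in enumerate(["HR", "RR", "BP", "Temp", "SpO2"])
        ]
        # an isolated single measurement 2 h later -> one-vital episode
        rows.append(("T0", ts + pd.Timedelta(hours=2), "vital_measurement", "HR",
                     90.0, None, ""))
        events = make_events(rows)
        profiles = learn_all_profiles(events, min_events=10**9)
        matrix = build_hourly_features(events, toy_encounters, profiles)
        t0 = matrix[matrix["encounter_id"] == "T0"].set_index("patient_hour")
        all5 = t0["all_vitals_same_time_common"] + t0["all_vitals_same_time_uncommon"]
        only1 = t0["only_one_vital_common"] + t0["only_one_vital_uncommon"]
        assert all5.loc[4] == 1   # window (hour 4) covers the 10:02 cluster
        assert only1.loc[6] == 1  # covers the isolated 12:02 measurement
        assert all5.loc[20] == 0  # window has slid past

    def test_unknown_encounter_raises(self, toy_encounters):
        events = make_events(
            [("GHOST", "2024-03-04 10:00", "note_written", None, np.nan, None, "")]
        )
        with pytest.raises(ReferentialIntegrityError, match="GHOST"):
            build_hourly_features(events, toy_encounters)


class TestNoteConcepts:
    def test_empty_window_all_zero(self, toy_encounters):
        events = make_events(
            [("T0", "2024-03-04 07:00", "note_written", None, np.nan, None, "")]
        )
        counts = count_note_concepts(events, toy_encounters)
        row = counts[(counts["encounter_id"] == "T1")].iloc[0]
        assert row[list(NOTE_CONCEPTS)].sum() == 0

    def test_tagged_concepts_counted(self, toy_encounters):
        events = make_events(
            [("T0", "2024-03-04 07:00", "note_written", None, np.nan, None,
              "pain_level;monitoring")]
        )
        counts = count_note_concepts(events, toy_encounters)
        row = counts[(counts["encounter_id"] == "T0")
                     & (counts["patient_hour"] == 1)].iloc[0]
        assert row["pain_level"] == 1 and row["monitoring"] == 1
        assert row[list(NOTE_CONCEPTS)].sum() == 2

    def test_random_tags_match_rescan_oracle(self, toy_encounters, rng):
        rows = []
        for _ in range(80):
            tags = ";".join(
                sorted(rng.choice(NOTE_CONCEPTS, size=rng.integers(0, 4),
                                  replace=False))
            )
            rows.append(
                ("T0", pd.Timestamp("2024-03-04 06:00")
                 + pd.Timedelta(seconds=float(rng.uniform(0, 30 * 3600))),
                 "note_written", None, np.nan, None, tags)
            )
        events = make_events(rows)
        counts = count_note_concepts(events, toy_encounters)
        t0 = counts[counts["encounter_id"] == "T0"].set_index("patient_hour")
        admit = toy_encounters.set_index("encounter_id").loc["T0", "admit_time"]
        for hour in (0, 5, 11, 17, 29):
            lo = admit + pd.Timedelta(hours=hour - 11)
            hi = admit + pd.Timedelta(hours=hour + 1)
            for concept in ("pain_level", "fall_risk", "monitoring"):
                expected = sum(
                    1
                    for _, ev in events.iterrows()
                    if lo <= ev["timestamp"] < hi
                    and concept in str(ev["note_concepts"]).split(";")
                )
                assert t0.loc[hour, concept] == expected

    def test_unknown_concept_rejected(self, toy_encounters):
        events = make_events(
            [("T0", "2024-03-04 07:00", "note_written", None, np.nan, None,
              "not_a_concept")]
        )
        with pytest.raises(VocabularyError, match="not_a_concept"):
            count_note_concepts(events, toy_encounters)


def test_windowed_counts_match_oracle_on_simulated_streams():
    """Window equivalence on a simulated stream: rolling implementation
    equals per-row rescan for total counts."""
    cfg = SimConfig(n_encounters=6, seed=99)
    encounters, events, outcomes = simulate_cohort(cfg)
    profiles = {
        f: CommonTimeProfile(f, frozenset(range(24)), "configured")
        for f in BASE_FEATURES
    }
    matrix = build_hourly_features(events, encounters, profiles, outcomes=outcomes)
    admits = encounters.set_index("encounter_id")["admit_time"]
    rng = np.random.default_rng(1)
    simple = [f for f in BASE_FEATURES
              if f not in ("all_vitals_same_time", "only_one_vital")]
    for _ in range(40):
        row = matrix.iloc[rng.integers(len(matrix))]
        feature = simple[rng.integers(len(simple))]
        expected = brute_force_cell(
            events, row["encounter_id"], admits[row["encounter_id"]],
            int(row["patient_hour"]), feature, profiles, 12, "common",
        )
        assert row[f"{feature}_common"] == expected
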