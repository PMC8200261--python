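import numpy as np
import pandas as pd
import pytest

from concern_ews.config import PipelineConfig, SimConfig
from concern_ews.simulate import simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A moderately sized cohort under default study conditions."""
    cfg = SimConfig(n_encounters=150, seed=421)
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def toy_encounters():
    """Three short encounters with whole-hour admissions."""
    admit = pd.Timestamp("2024-03-04 06:00:00")
    rows = []
    for i, los_h in enumerate((30, 40, 36)):
        rows.append(
            {
                "encounter_id": f"T{i}",
                "patient_id": f"P{i}",
                "age": 50.0 + i,
                "unit_type": "medsurg",
                "admit_time": admit + pd.Timedelta(hours=3 * i),
                "discharge_time": admit + pd.Timedelta(hours=3 * i + los_h),
                "hospice_flag": False,
            }
        )
    return pd.DataFrame(rows)


def make_events(rows):
    """Build an event table from (encounter_id, timestamp, event_type,
    vital_kind, value, o2, concepts) tuples."""
    df = pd.DataFrame(
        rows,
        columns=[
            "encounter_id",
            "timestamp",
            "event_type",
            "vital_kind",
            "value",
            "oxygen_supplemental",
            "note_concepts",
        ],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
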