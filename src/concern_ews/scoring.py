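"""Hourly risk scores: a behavioral reference scorer and MEWS/NEWS comparators.

The behavioral (CONCERN-style) scorer is a discrete-time pooled logistic
model of "composite event within the next H hours" fitted on the 55-column
hourly feature matrix; its continuous score (linear predictor) is mapped to
low/moderate/high categories at quantile cutpoints of the training-score
distribution (aliased green/yellow/red).  MEWS and NEWS are computed from
vital values using the standard published component tables bundled as
versioned data files, with last-observation-carried-forward vitals subject
to a staleness limit.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.linear_model import LogisticRegression

from .features import _hour_grid, feature_columns

CATEGORY_LEVELS = ("low", "moderate", "high")
#: Presentation aliases for the behavioral score's categories.
CONCERN_COLORS = {"low": "green", "moderate": "yellow", "high": "red"}


class DomainError(ValueError):
    """A score or input value is outside its valid domain."""


class FitError(RuntimeError):
    """The reference scorer could not be fitted."""


class AlignmentError(ValueError):
    """Inputs are not aligned on the same hourly grid."""


@dataclass(frozen=True)
class ScoreBands:
    """Partition of a score range into low/moderate/high.

    ``moderate_at`` and ``high_at`` are the lowest scores of the moderate
    and high bands.
    """

    system: str
    moderate_at: float
    high_at: float

    def __post_init__(self) -> None:
        if not self.moderate_at < self.high_at:
            raise ValueError("band edges must be strictly increasing")


MEWS_BANDS = ScoreBands("MEWS", moderate_at=3, high_at=5)
NEWS_BANDS = ScoreBands("NEWS", moderate_at=4, high_at=7)


def categorize(score, bands: ScoreBands):
    """Map scores to categories; vectorized over array input."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise DomainError(f"{bands.system}: negative score")
    out = np.where(
        arr >= bands.high_at,
        "high",
        np.where(arr >= bands.moderate_at, "moderate", "low"),
    ).astype(object)
    out[np.isnan(arr)] = None
    if np.isscalar(score) or np.ndim(score) == 0:
        return out.item()
    return out


# ---------------------------------------------------------------------------
# Comparator point tables
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _load_table(name: str) -> dict:
    path = importlib.resources.files("concern_ews.data") / name
    return yaml.safe_load(path.read_text())


def _band_points(values: np.ndarray, spec: Mapping) -> np.ndarray:
    edges = np.asarray(spec["edges"], dtype=float)
    points = np.asarray(spec["points"], dtype=float)
    idx = np.searchsorted(edges, values, side="right")
    out = points[idx]
    out[np.isnan(values)] = np.nan
    return out


def _avpu_points(avpu: np.ndarray, mapping: Mapping[str, int]) -> np.ndarray:
    out = np.full(avpu.shape, np.nan)
    for level, pts in mapping.items():
        out[avpu == level] = pts
    return out


def _finalize(total: np.ndarray, scalar: bool):
    if scalar:
        v = total[0]
        return float(v) if np.isnan(v) else int(v)
    return total


def mews_total(sbp, hr, rr, temp, avpu="A"):
    """MEWS integer total from systolic BP, heart rate, respiratory rate,
    temperature (deg C), and AVPU consciousness level.

    Accepts scalars or arrays; NaN in any component yields NaN (the hourly
    score is undefined until every component has been observed).
    """
    table = _load_table("mews_subbe2001.yaml")["components"]
    scalar = np.ndim(sbp) == 0
    sbp, hr, rr, temp = (
        np.atleast_1d(np.asarray(v, dtype=float)) for v in (sbp, hr, rr, temp)
    )
    avpu_arr = np.broadcast_to(np.atleast_1d(np.asarray(avpu, dtype=object)), sbp.shape)
    total = (
        _band_points(sbp, table["sbp"])
        + _band_points(hr, table["hr"])
        + _band_points(rr, table["rr"])
        + _band_points(temp, table["temp"])
        + _avpu_points(avpu_arr, table["avpu"])
    )
    return _finalize(total, scalar)


def news_total(rr, spo2, supplemental_o2, temp, sbp, hr, consciousness="A"):
    """NEWS integer total from respiratory rate, SpO2 (%), supplemental-O2
    flag, temperature (deg C), systolic BP, heart rate, and consciousness
    (AVPU; any of V/P/U scores 3)."""
    table = _load_table("news_rcp2012.yaml")["components"]
    scalar = np.ndim(rr) == 0
    rr, spo2, temp, sbp, hr = (
        np.atleast_1d(np.asarray(v, dtype=float)) for v in (rr, spo2, temp, sbp, hr)
    )
    o2 = np.broadcast_to(np.atleast_1d(np.asarray(supplemental_o2, dtype=bool)), rr.shape)
    o2_pts = np.where(
        o2, table["supplemental_o2"]["yes_points"], table["supplemental_o2"]["no_points"]
    )
    cons = np.broadcast_to(np.atleast_1d(np.asarray(consciousness, dtype=object)), rr.shape)
    total = (
        _band_points(rr, table["rr"])
        + _band_points(spo2, table["spo2"])
        + o2_pts
        + _band_points(temp, table["temp"])
        + _band_points(sbp, table["sbp"])
        + _band_points(hr, table["hr"])
        + _avpu_points(cons, table["consciousness"])
    )
    return _finalize(total, scalar)


# ---------------------------------------------------------------------------
# Behavioral reference scorer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceScorer:
    """Fitted behavioral scorer: standardized logistic coefficients over
    the 55 feature columns plus quantile category cutpoints.

    Scoring is a pure function of a feature row; the continuous score is
    the linear predictor of the event-within-H-hours model.
    """

    feature_names: tuple[str, ...]
    coef: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    cutpoints: tuple[float, float]
    horizon_hours: int
    l2_strength: float

    def __post_init__(self) -> None:
        if not self.cutpoints[0] < self.cutpoints[1]:
            raise FitError("category cutpoints must be strictly increasing")

    def score(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise AlignmentError(f"feature table missing columns: {missing}")
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        return z @ self.coef + self.intercept

    def categorize(self, scores: np.ndarray) -> np.ndarray:
        c1, c2 = self.cutpoints
        return np.where(
            scores >= c2, "high", np.where(scores >= c1, "moderate", "low")
        ).astype(object)


def split_encounters(
    encounter_ids: Sequence[str], train_fraction: float, rng: np.random.Generator
) -> tuple[set[str], set[str]]:
    """Random train/test split by encounter (never by row)."""
    ids = np.asarray(sorted(set(encounter_ids)))
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    return set(ids[perm[:n_train]]), set(ids[perm[n_train:]])


def make_outcome_labels(
    features: pd.DataFrame, outcomes: pd.DataFrame, horizon_hours: int
) -> np.ndarray:
    """Row labels: 1 if the encounter's first event falls within
    (t, t + horizon] of the row's hour t."""
    first = outcomes.groupby("encounter_id")["event_time"].min()
    e = features["encounter_id"].map(first).to_numpy(dtype=float)
    t = features["patient_hour"].to_numpy(dtype=float)
    return ((e - t > 0) & (e - t <= horizon_hours)).astype(int)


def fit_reference_scorer(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    horizon_hours: int = 12,
    cutpoint_quantiles: tuple[float, float] = (0.80, 0.95),
    l2_strength: float = 1.0,
    min_event_encounters: int = 50,
) -> ReferenceScorer:
    """Fit the pooled per patient-hour logistic model and its cutpoints.

    The model is L2-regularized by default (strength ``l2_strength`` on
    the standardized scale), which also guards against complete
    separation in small cohorts.
    """
    cols = feature_columns()
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise AlignmentError(f"feature table missing columns: {missing}")
    n_event_enc = features["encounter_id"].isin(set(outcomes["encounter_id"])).pipe(
        lambda s: features.loc[s, "encounter_id"].nunique()
    )
    if n_event_enc < min_event_encounters:
        raise FitError(
            f"need >= {min_event_encounters} event encounters in the training "
            f"split, got {n_event_enc}"
        )
    y = make_outcome_labels(features, outcomes, horizon_hours)
    x = features[cols].to_numpy(dtype=float)
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - center) / scale
    if y.min() == y.max():
        raise FitError("outcome labels are constant; cannot fit")
    model = LogisticRegression(
        penalty="l2", C=1.0 / l2_strength, solver="lbfgs", max_iter=500
    )
    model.fit(z, y)
    coef = model.coef_.ravel()
    intercept = float(model.intercept_[0])
    scores = z @ coef + intercept
    q1, q2 = np.quantile(scores, cutpoint_quantiles)
    if not q1 < q2:
        raise FitError(
            "degenerate training-score distribution: cutpoint quantiles "
            "coincide; consider stronger regularization or more data"
        )
    return ReferenceScorer(
        feature_names=tuple(cols),
        coef=coef,
        intercept=intercept,
        center=center,
        scale=scale,
        cutpoints=(float(q1), float(q2)),
        horizon_hours=horizon_hours,
        l2_strength=l2_strength,
    )


# ---------------------------------------------------------------------------
# Hourly score series
# ---------------------------------------------------------------------------


def concern_series(scorer: ReferenceScorer, features: pd.DataFrame) -> pd.DataFrame:
    """Hourly behavioral score series: one row per (encounter, hour)."""
    scores = scorer.score(features)
    return pd.DataFrame(
        {
            "encounter_id": features["encounter_id"].to_numpy(),
            "patient_hour": features["patient_hour"].to_numpy(),
            "system": "CONCERN",
            "score": scores,
            "category": scorer.categorize(scores),
        }
    )


def _locf_grid(
    events: pd.DataFrame,
    encounters: pd.DataFrame,
    outcomes: pd.DataFrame | None,
    staleness_hours: int,
) -> pd.DataFrame:
    """Per (encounter, hour) last-observed vital values with staleness cap."""
    enc, enc_index = _hour_grid(encounters, outcomes)
    nh = enc["n_hours"].to_numpy()
    n_rows = int(nh.sum())
    enc_of_row = np.repeat(np.arange(len(enc)), nh)
    t = np.arange(n_rows) - np.repeat(enc["row_offset"].to_numpy(), nh)

    grid = pd.DataFrame(
        {
            "enc_idx": enc_of_row,
            "encounter_id": enc["encounter_id"].to_numpy()[enc_of_row],
            "patient_hour": t,
        }
    )

    meas = events[events["event_type"] == "vital_measurement"].copy()
    meas["timestamp"] = pd.to_datetime(meas["timestamp"])
    meas["enc_idx"] = meas["encounter_id"].map(enc_index)
    meas = meas[meas["enc_idx"].notna()]
    meas["enc_idx"] = meas["enc_idx"].astype(int)
    admits = enc["admit_time"].to_numpy()[meas["enc_idx"].to_numpy()]
    meas["patient_hour"] = np.floor(
        (meas["timestamp"].to_numpy() - admits) / np.timedelta64(1, "h")
    ).astype(int)
    meas = meas[
        (meas["patient_hour"] >= 0)
        & (meas["patient_hour"] < nh[meas["enc_idx"].to_numpy()])
    ]
    meas = meas.sort_values(["enc_idx", "patient_hour", "timestamp"], kind="mergesort")
    last = meas.groupby(["enc_idx", "patient_hour", "vital_kind"], sort=False).tail(1)

    for kind in ("HR", "RR", "BP", "Temp", "SpO2"):
        sub = last[last["vital_kind"] == kind]
        col = pd.Series(np.nan, index=grid.index)
        obs = pd.Series(np.nan, index=grid.index)
        # position in the stacked grid
        pos = (
            enc["row_offset"].to_numpy()[sub["enc_idx"].to_numpy()]
            + sub["patient_hour"].to_numpy()
        )
        col.iloc[pos] = sub["value"].to_numpy(dtype=float)
        obs.iloc[pos] = sub["patient_hour"].to_numpy(dtype=float)
        grid[f"val_{kind}"] = col
        grid[f"obs_{kind}"] = obs
        if kind == "SpO2":
            o2 = pd.Series(np.nan, index=grid.index)
            flags = sub["oxygen_supplemental"].map(
                lambda v: float(bool(v)) if pd.notna(v) else 0.0
            )
            o2.iloc[pos] = flags.to_numpy(dtype=float)
            grid["o2_obs"] = o2

    g = grid.groupby("enc_idx", sort=False)
    for kind in ("HR", "RR", "BP", "Temp", "SpO2"):
        filled = g[f"val_{kind}"].ffill()
        last_obs = g[f"obs_{kind}"].ffill()
        stale = grid["patient_hour"] - last_obs > staleness_hours
        grid[kind] = filled.where(~stale)
    grid["supplemental_o2"] = g["o2_obs"].ffill().fillna(0.0).astype(bool)
    return grid


def comparator_series(
    events: pd.DataFrame,
    encounters: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    staleness_hours: int = 12,
) -> pd.DataFrame:
    """Hourly MEWS and NEWS series from the vital-measurement stream.

    Vitals are carried forward from the last observation for up to
    ``staleness_hours``; hours where any required component is missing
    (e.g. before the first vitals set) carry an undefined score, emitted
    as missing and excluded from downstream models.  Consciousness is
    treated as Alert throughout (the event stream carries no AVPU
    channel).
    """
    grid = _locf_grid(events, encounters, outcomes, staleness_hours)
    mews = mews_total(grid["BP"], grid["HR"], grid["RR"], grid["Temp"], "A")
    news = news_total(
        grid["RR"],
        grid["SpO2"],
        grid["supplemental_o2"].to_numpy(),
        grid["Temp"],
        grid["BP"],
        grid["HR"],
        "A",
    )
    frames = []
    for system, scores, bands in (
        ("MEWS", np.asarray(mews, dtype=float), MEWS_BANDS),
        ("NEWS", np.asarray(news, dtype=float), NEWS_BANDS),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": grid["encounter_id"],
                    "patient_hour": grid["patient_hour"],
                    "system": system,
                    "score": scores,
                    "category": categorize(scores, bands),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def score_series(
    scorer: ReferenceScorer,
    features: pd.DataFrame,
    events: pd.DataFrame,
    encounters: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    staleness_hours: int = 12,
) -> pd.DataFrame:
    """All three hourly score series stacked long:
    (encounter_id, patient_hour, system, score, category)."""
    concern = concern_series(scorer, features)
    comparators = comparator_series(events, encounters, outcomes, staleness_hours)
    return pd.concat([concern, comparators], ignore_index=True)
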