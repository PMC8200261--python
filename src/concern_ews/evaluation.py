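"""Score–outcome evaluation: time-varying Cox model and lead-time statistic.

Two complementary analyses quantify how well an hourly categorical risk
score anticipates the composite deterioration outcome (first of in-hospital
mortality, cardiac arrest, unanticipated ICU transfer, rapid response, or
sepsis):

* a Cox proportional-hazards model with the hourly categories as
  time-varying covariates in counting-process form, low risk as the
  reference level (Efron ties);
* the lead-time likelihood ratio
  ``L(x, h) = P(x | event h hours ahead) / P(x | no event h hours ahead)``,
  estimated from smoothed conditional category frequencies over a horizon
  grid.  Separation of ``log L`` from 0 at large ``h`` indicates early
  warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError

from .scoring import CATEGORY_LEVELS

logger = logging.getLogger(__name__)


class ConsistencyError(ValueError):
    """Outcome and encounter tables disagree."""


class EmptyStratumError(ValueError):
    """No patient-hours support a requested horizon."""


class CoxFitError(RuntimeError):
    """The partial-likelihood fit failed to converge."""


# ---------------------------------------------------------------------------
# Composite endpoint
# ---------------------------------------------------------------------------


def composite_first_event(
    outcomes: pd.DataFrame, encounters: pd.DataFrame | None = None
) -> pd.Series:
    """Per-encounter time (hours since admission) of the first component
    event; encounters with no component are absent (censored at discharge).
    """
    if len(outcomes) == 0:
        return pd.Series(dtype=float, name="event_time")
    first = outcomes.groupby("encounter_id")["event_time"].min()
    first.name = "event_time"
    if encounters is not None:
        enc = encounters.set_index("encounter_id")
        stay_h = (
            pd.to_datetime(enc["discharge_time"]) - pd.to_datetime(enc["admit_time"])
        ) / pd.Timedelta(hours=1)
        joined = stay_h.reindex(first.index)
        bad = first.index[first > joined + 1e-9]
        if len(bad):
            raise ConsistencyError(
                f"events after discharge for encounters: {sorted(bad)[:10]}"
            )
    return first


# ---------------------------------------------------------------------------
# Counting-process construction
# ---------------------------------------------------------------------------


def _category_panel(scores: pd.DataFrame, system: str) -> pd.DataFrame:
    sub = scores[scores["system"] == system]
    if len(sub) == 0:
        raise ValueError(f"no score rows for system {system!r}")
    return sub[["encounter_id", "patient_hour", "category"]].rename(
        columns={"category": system}
    )


def to_counting_process(
    scores: pd.DataFrame,
    first_events: pd.Series,
    systems: Sequence[str] = ("CONCERN", "MEWS", "NEWS"),
) -> pd.DataFrame:
    """Collapse hourly categories into (start, stop] covariate intervals.

    One interval per maximal run of a constant covariate vector; hours
    where any requested system's category is missing are excluded
    (complete-case across the requested systems).  The event is attached
    to the interval containing the first event time, and the at-risk
    period ends there (or at censoring).
    """
    panel: pd.DataFrame | None = None
    for system in systems:
        p = _category_panel(scores, system)
        panel = p if panel is None else panel.merge(
            p, on=["encounter_id", "patient_hour"], how="outer"
        )
    panel = panel.dropna(subset=list(systems))
    panel = panel.sort_values(["encounter_id", "patient_hour"], kind="mergesort")

    cov_cols = []
    for system in systems:
        for level in ("moderate", "high"):
            col = f"{system.lower()}_{level}"
            panel[col] = (panel[system] == level).astype(int)
            cov_cols.append(col)

    e = panel["encounter_id"].map(first_events).to_numpy(dtype=float)
    t = panel["patient_hour"].to_numpy(dtype=int)
    enc = panel["encounter_id"].to_numpy()
    cov = panel[cov_cols].to_numpy()

    # hours at or beyond the event bin contribute no at-risk time
    with np.errstate(invalid="ignore"):
        keep = np.isnan(e) | (t < np.ceil(e))
    enc, t, cov, e = enc[keep], t[keep], cov[keep], e[keep]

    new_run = np.ones(len(t), dtype=bool)
    if len(t) > 1:
        new_run[1:] = (
            (enc[1:] != enc[:-1])
            | (t[1:] != t[:-1] + 1)
            | (cov[1:] != cov[:-1]).any(axis=1)
        )
    run_id = np.cumsum(new_run) - 1
    df = pd.DataFrame({"encounter_id": enc, "t": t, "run": run_id})
    agg = df.groupby("run", sort=True).agg(
        encounter_id=("encounter_id", "first"), start=("t", "min"), stop=("t", "max")
    )
    agg["stop"] = agg["stop"] + 1.0
    agg["start"] = agg["start"].astype(float)
    for j, col in enumerate(cov_cols):
        agg[col] = cov[new_run][:, j]
    agg["event"] = False

    # Final interval of each event encounter ends at the event time.  When
    # the category grid stops at the last fully observed hour, the event
    # falls within the following hour; the last covariate value is carried
    # forward to it.
    e_by_enc = first_events
    last_run = df.groupby("encounter_id")["run"].max()
    for enc_id, run in last_run.items():
        ev = e_by_enc.get(enc_id, np.nan)
        if np.isnan(ev):
            continue
        stop = agg.loc[run, "stop"]
        if agg.loc[run, "start"] < ev <= stop:
            agg.loc[run, "stop"] = float(ev)
            agg.loc[run, "event"] = True
        elif stop < ev <= stop + 1.0:
            agg.loc[run, "stop"] = float(ev)
            agg.loc[run, "event"] = True

    records = agg.reset_index(drop=True)
    if (records["stop"] <= records["start"]).any():
        raise ValueError("constructed an empty or inverted interval")
    return records


# ---------------------------------------------------------------------------
# Time-varying Cox fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HazardModelResult:
    """Forest-plot-ready summary of a counting-process Cox fit."""

    summary: pd.DataFrame  # covariate, hr, ci_low, ci_high, p
    ties_method: str
    n_intervals: int
    n_events: int

    def __post_init__(self) -> None:
        s = self.summary
        if ((s["ci_low"] > s["hr"]) | (s["hr"] > s["ci_high"])).any():
            raise ValueError("confidence intervals must bracket the hazard ratio")
        if (s["hr"] <= 0).any():
            raise ValueError("hazard ratios must be positive")

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.set_index("covariate").loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.set_index("covariate").loc[covariate]
        return float(row["ci_low"]), float(row["ci_high"])


def fit_time_varying_cox(
    records: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    min_events: int = 10,
    penalizer: float = 0.0,
) -> HazardModelResult:
    """Partial-likelihood fit of the counting-process records.

    Covariates constant across all records are dropped with a warning;
    95% confidence intervals are Wald on the log-hazard scale.  A small
    ``penalizer`` (L2 on the coefficients) can stabilize near-separated
    fits.
    """
    if covariates is None:
        covariates = [
            c
            for c in records.columns
            if c not in ("encounter_id", "start", "stop", "event")
        ]
    n_events = int(records["event"].sum())
    if n_events < min_events:
        raise ValueError(f"need >= {min_events} events, got {n_events}")
    usable = []
    for c in covariates:
        if records[c].nunique() > 1:
            usable.append(c)
        else:
            logger.warning("covariate %s is constant; dropped from the fit", c)
    if not usable:
        raise ValueError("no non-constant covariates to fit")

    ctv = CoxTimeVaryingFitter(penalizer=penalizer)
    df = records[["encounter_id", "start", "stop", "event"] + usable]
    # Full Newton steps can overshoot when hazard ratios are large; retry
    # with damped steps before giving up.  The optimum is unchanged.
    last_err: Exception | None = None
    for step_size in (0.95, 0.3, 0.1):
        try:
            ctv.fit(
                df,
                id_col="encounter_id",
                start_col="start",
                stop_col="stop",
                event_col="event",
                fit_options={"step_size": step_size},
            )
            last_err = None
            break
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as err:
            last_err = err
    if last_err is not None:
        raise CoxFitError(
            f"partial-likelihood fit did not converge: {last_err}"
        ) from last_err
    s = ctv.summary
    summary = pd.DataFrame(
        {
            "covariate": s.index,
            "hr": np.exp(s["coef"]).to_numpy(),
            "ci_low": np.exp(s["coef lower 95%"]).to_numpy(),
            "ci_high": np.exp(s["coef upper 95%"]).to_numpy(),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return HazardModelResult(
        summary=summary,
        ties_method="efron",
        n_intervals=len(records),
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Lead-time likelihood ratio
# ---------------------------------------------------------------------------


def smoothed_level_probs(counts: np.ndarray, k: float) -> np.ndarray:
    """Add-k smoothed category frequencies (one entry per level)."""
    total = counts.sum()
    return (counts + k) / (total + k * len(counts))


def compute_lead_time_lr(
    scores: pd.DataFrame,
    first_events: pd.Series,
    horizons: Sequence[int],
    smoothing: float = 0.5,
    convention: str = "exact",
    systems: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Estimate ``L(x, h)`` per system, score level, and horizon.

    Under the default exact-horizon convention the numerator pools
    patient-hours ``t`` whose encounter has its first event in hour bin
    ``t + h``; the ``cumulative`` convention instead pools hours with an
    event within ``(t, t+h]``.  The denominator pools hours known to have
    no event at ``t + h``; hours within ``h`` of censoring are excluded
    (their status at ``t + h`` is unobserved).  Add-``smoothing`` counts
    are applied to both conditional frequency tables before the ratio.
    """
    if convention not in ("exact", "cumulative"):
        raise ValueError("convention must be 'exact' or 'cumulative'")
    if systems is None:
        systems = list(pd.unique(scores["system"]))
    level_code = {lev: i for i, lev in enumerate(CATEGORY_LEVELS)}

    out_rows = []
    empty: list[int] = []
    for system in systems:
        panel = _category_panel(scores, system).dropna(subset=[system])
        enc = panel["encounter_id"].to_numpy()
        t = panel["patient_hour"].to_numpy(dtype=float)
        cat = panel[system].map(level_code).to_numpy(dtype=int)
        e = panel["encounter_id"].map(first_events).to_numpy(dtype=float)
        e_bin = np.floor(e)
        n_hours = panel.groupby("encounter_id")["patient_hour"].transform("max").to_numpy() + 1
        is_event_enc = ~np.isnan(e)

        for h in horizons:
            if convention == "exact":
                num_mask = is_event_enc & (e_bin == t + h)
                den_mask = (is_event_enc & (t + h < e_bin)) | (
                    ~is_event_enc & (t + h < n_hours)
                )
            else:
                dt = e_bin - t
                num_mask = is_event_enc & (dt > 0) & (dt <= h)
                den_mask = (is_event_enc & (dt > h)) | (
                    ~is_event_enc & (t + h < n_hours)
                )
            n_num, n_den = int(num_mask.sum()), int(den_mask.sum())
            if n_num == 0 or n_den == 0:
                empty.append(h)
                continue
            num_counts = np.bincount(cat[num_mask], minlength=3).astype(float)
            den_counts = np.bincount(cat[den_mask], minlength=3).astype(float)
            p_num = smoothed_level_probs(num_counts, smoothing)
            p_den = smoothed_level_probs(den_counts, smoothing)
            lr = p_num / p_den
            for lev, code in level_code.items():
                out_rows.append(
                    {
                        "system": system,
                        "level": lev,
                        "h": h,
                        "lr": lr[code],
                        "log_lr": math.log(lr[code]),
                        "n_num": n_num,
                        "n_den": n_den,
                        "n_num_level": int(num_counts[code]),
                        "n_den_level": int(den_counts[code]),
                        "smoothing": smoothing,
                    }
                )
    if empty:
        raise EmptyStratumError(
            f"horizons with no supporting patient-hours: {sorted(set(empty))}"
        )
    return pd.DataFrame(out_rows)


def warning_horizon(
    curve: pd.DataFrame,
    system: str,
    level: str = "high",
    tau: float = math.log(1.5),
    min_support: int = 3,
) -> int:
    """Hours before an event for which ``level`` continuously separates.

    Scanning the horizon grid outward from the event, this is the last
    horizon before ``log L(level, h)`` first falls below ``tau`` — i.e.
    the length of the contiguous near-event window over which observing
    the level shifts the odds of an upcoming event by at least ``e^tau``.
    Isolated exceedances at distant horizons do not extend it, and a
    horizon where the level is seen in fewer than ``min_support``
    pre-event patient-hours ends the run: a smoothed frequency ratio with
    singleton support is dominated by the add-k prior and can float above
    ``tau`` indefinitely against a rarely-elevated comparator, the same
    way chi-square practice distrusts cells with tiny expected counts.
    Returns 0 when even the nearest horizon fails, and the largest
    horizon when none fails.
    """
    sub = curve[(curve["system"] == system) & (curve["level"] == level)]
    sub = sub.sort_values("h")
    if not len(sub):
        raise ValueError(f"no curve for {system}/{level}")
    ends = sub.loc[
        (sub["log_lr"] < tau) | (sub["n_num_level"] < min_support), "h"
    ]
    return int(ends.min() - 1) if len(ends) else int(sub["h"].max())


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def summarize_evaluation(
    results: Mapping[str, HazardModelResult],
    curves: pd.DataFrame | None,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Render machine-readable tables and static plots.

    Writes ``hazards.csv`` (per covariate: hazard ratio, 95% CI, p, and
    the "excess hazard" HR - 1), a forest plot, and — when lead-time
    curves are supplied — ``leadtime.csv`` and the log-LR curve plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for name, res in results.items():
        s = res.summary.copy()
        s.insert(0, "model", name)
        s["excess_hazard"] = s["hr"] - 1.0
        rows.append(s)
    hazards = pd.concat(rows, ignore_index=True)
    paths["hazards"] = out_dir / "hazards.csv"
    hazards.to_csv(paths["hazards"], index=False)

    fig, ax = plt.subplots(figsize=(7, 0.5 + 0.45 * len(hazards)))
    y = np.arange(len(hazards))[::-1]
    ax.errorbar(
        hazards["hr"],
        y,
        xerr=[hazards["hr"] - hazards["ci_low"], hazards["ci_high"] - hazards["hr"]],
        fmt="o",
        color="black",
        capsize=3,
    )
    ax.axvline(1.0, color="grey", linestyle="--", linewidth=1)
    ax.set_yticks(y)
    ax.set_yticklabels(hazards["model"] + ": " + hazards["covariate"])
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (log scale), 95% CI")
    fig.tight_layout()
    paths["forest"] = out_dir / "forest.png"
    fig.savefig(paths["forest"], dpi=120)
    plt.close(fig)

    if curves is not None and len(curves):
        paths["leadtime"] = out_dir / "leadtime.csv"
        curves.to_csv(paths["leadtime"], index=False)
        fig, axes = plt.subplots(
            1, len(CATEGORY_LEVELS), figsize=(12, 3.5), sharey=True
        )
        for ax, level in zip(np.atleast_1d(axes), CATEGORY_LEVELS):
            for system, sub in curves[curves["level"] == level].groupby("system"):
                ax.plot(sub["h"], sub["log_lr"], label=system)
            ax.axhline(0.0, color="grey", linewidth=1)
            ax.set_title(f"level = {level}")
            ax.set_xlabel("hours before event, h")
        np.atleast_1d(axes)[0].set_ylabel("log L(x, h)")
        np.atleast_1d(axes)[0].legend()
        fig.tight_layout()
        paths["leadtime_plot"] = out_dir / "leadtime.png"
        fig.savefig(paths["leadtime_plot"], dpi=120)
        plt.close(fig)
    return paths
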