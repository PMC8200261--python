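"""End-to-end pipeline: simulate → filter → features → score → evaluate.

A single global seed fans out deterministically to per-stage substreams,
so rerunning with the same configuration reproduces every artifact
byte-for-byte; a JSON manifest records the configuration hash, stage
seeds, row counts and artifact digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .evaluation import (
    compute_lead_time_lr,
    composite_first_event,
    fit_time_varying_cox,
    summarize_evaluation,
    to_counting_process,
    warning_horizon,
)
from .features import apply_inclusion_filters, build_hourly_features, learn_all_profiles
from .io import (
    ENCOUNTERS_SCHEMA,
    EVENTS_SCHEMA,
    FEATURES_SCHEMA,
    OUTCOMES_SCHEMA,
    SCORES_SCHEMA,
    write_table,
)
from .scoring import fit_reference_scorer, score_series, split_encounters
from .simulate import simulate_cohort

logger = logging.getLogger(__name__)


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Stable, stage-specific substream seed (below 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute every stage and return the run manifest.

    Artifacts: encounters/events/outcomes/features/scores CSVs,
    hazards.csv + leadtime.csv + plots, and manifest.json.  The scorer is
    fitted on a train split of encounters; scores.csv and the evaluation
    cover the held-out test split.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- simulate ---------------------------------------------------------
    sim_cfg = config.sim.replace(seed=derive_stage_seed(config.seed, "simulate"))
    encounters, events, outcomes = simulate_cohort(sim_cfg)
    write_table(encounters, out / "encounters.csv", ENCOUNTERS_SCHEMA)
    write_table(events, out / "events.csv", EVENTS_SCHEMA)
    write_table(outcomes, out / "outcomes.csv", OUTCOMES_SCHEMA)
    counts.update(
        encounters=len(encounters), events=len(events), outcomes=len(outcomes)
    )
    logger.info("simulate: %d encounters, %d events", len(encounters), len(events))

    # --- filter + features ------------------------------------------------
    filtered, tally = apply_inclusion_filters(encounters, outcomes)
    kept_events = events[events["encounter_id"].isin(set(filtered["encounter_id"]))]
    profiles = learn_all_profiles(
        kept_events,
        threshold=config.features.common_threshold,
        min_events=config.features.min_events_for_profile,
        fallback_hours=tuple(config.sim.vitals_schedule) or (0, 4, 8, 12, 16, 20),
    )
    features = build_hourly_features(
        kept_events,
        filtered,
        profiles,
        window_hours=config.features.window_hours,
        outcomes=outcomes,
    )
    write_table(features, out / "features.csv", FEATURES_SCHEMA)
    counts.update(encounters_retained=len(filtered), feature_rows=len(features))

    # --- score ------------------------------------------------------------
    rng = np.random.default_rng(derive_stage_seed(config.seed, "scoring"))
    train_ids, test_ids = split_encounters(
        filtered["encounter_id"], config.scoring.train_fraction, rng
    )
    train_rows = features["encounter_id"].isin(train_ids)
    scorer = fit_reference_scorer(
        features[train_rows],
        outcomes[outcomes["encounter_id"].isin(train_ids)],
        horizon_hours=config.scoring.horizon_hours,
        cutpoint_quantiles=config.scoring.cutpoint_quantiles,
        l2_strength=config.scoring.l2_strength,
        min_event_encounters=config.scoring.min_event_encounters,
    )
    test_enc = filtered[filtered["encounter_id"].isin(test_ids)]
    test_events = kept_events[kept_events["encounter_id"].isin(test_ids)]
    scores = score_series(
        scorer,
        features[~train_rows],
        test_events,
        test_enc,
        outcomes,
        staleness_hours=config.scoring.staleness_hours,
    )
    write_table(scores, out / "scores.csv", SCORES_SCHEMA)
    counts.update(score_rows=len(scores), train_encounters=len(train_ids),
                  test_encounters=len(test_ids))

    # --- evaluate ---------------------------------------------------------
    first = composite_first_event(
        outcomes[outcomes["encounter_id"].isin(test_ids)], test_enc
    )

    def fit_with_ridge_fallback(records):
        # Small cohorts can leave a multi-indicator model near-separated;
        # a light L2 penalty is the standard stabilizer in that case.
        from .evaluation import CoxFitError

        for penalizer in (0.0, 0.01, 0.1):
            try:
                return fit_time_varying_cox(records, penalizer=penalizer), penalizer
            except CoxFitError:
                continue
        raise CoxFitError("time-varying Cox fit failed even with ridge penalty")

    results = {}
    penalizers = {}
    rec_concern = to_counting_process(scores, first, systems=("CONCERN",))
    results["concern_only"], penalizers["concern_only"] = fit_with_ridge_fallback(
        rec_concern
    )
    rec_all = to_counting_process(scores, first, systems=("CONCERN", "MEWS", "NEWS"))
    results["combined"], penalizers["combined"] = fit_with_ridge_fallback(rec_all)
    curves = compute_lead_time_lr(
        scores,
        first,
        horizons=config.evaluation.horizons,
        smoothing=config.evaluation.smoothing,
        convention=config.evaluation.horizon_convention,
    )
    paths = summarize_evaluation(results, curves, out)
    horizons = {
        system: warning_horizon(curves, system) for system in ("CONCERN", "MEWS", "NEWS")
    }
    counts.update(cox_events=results["combined"].n_events)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            "simulate": sim_cfg.seed,
            "scoring": derive_stage_seed(config.seed, "scoring"),
        },
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "row_counts": counts,
        "exclusion_tally": tally,
        "warning_horizons": horizons,
        "cox_penalizers": penalizers,
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*.csv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
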