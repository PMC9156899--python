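"""Table readers/writers, run configuration, and the end-to-end pipeline.

All tables are UTF-8 comma-separated CSV with a header row and dot decimals;
money is written in dollars.  A pipeline run is fully reproducible from
(config, master seed): every stage draws from a named substream of the
master seed, and a manifest records the config hash, seeds, row counts and
exclusion counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, simulate_cohort
from .estimation import fit_all
from .seeds import substream_seed
from .state import (
    PARAMETER_MAP,
    build_mood_days,
    fit_group_model,
    fit_mood_model,
    fit_repetition_model,
    lme_results_to_frame,
)
from .variance import compute_icc, downsample_random_days, downsample_week_mean

__all__ = [
    "CHOICE_COLUMNS",
    "RunConfig",
    "read_choices",
    "write_choices",
    "read_ratings",
    "write_ratings",
    "read_fits",
    "write_fits",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CHOICE_COLUMNS = [
    "subject_id", "group", "day", "task", "trial_index", "guaranteed", "v", "p", "A",
    "v_immediate", "v_delayed", "d_immediate", "d_delayed", "choice",
]
RATING_COLUMNS = ["subject_id", "group", "day", "prompt_index", "positive", "negative"]

_MONEY_COLUMNS = ("guaranteed", "v", "v_immediate", "v_delayed")


class ValidationError(ValueError):
    """A table violated its schema; the message lists offending rows."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_choices(path) -> pd.DataFrame:
    """Read and validate a trial-level choice table.

    Schema violations (probability outside [0, 1], non-binary choice,
    missing columns) raise :class:`ValidationError` naming the offending
    rows (1-based, excluding the header).  An empty file yields an empty
    table with a warning rather than an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty choice table", path)
        return pd.DataFrame(columns=CHOICE_COLUMNS)
    _require_columns(df, ["subject_id", "day", "task", "choice"], path)
    problems = []
    if "p" in df.columns:
        bad = df.index[(df["p"].notna()) & ((df["p"] < 0) | (df["p"] > 1))]
        problems += [f"row {i + 1}: p={df.loc[i, 'p']} outside [0,1]" for i in bad]
    if "A" in df.columns:
        bad = df.index[(df["A"].notna()) & ((df["A"] < 0) | (df["A"] > 1))]
        problems += [f"row {i + 1}: A={df.loc[i, 'A']} outside [0,1]" for i in bad]
    bad = df.index[~df["choice"].isin([0, 1])]
    problems += [f"row {i + 1}: non-binary choice {df.loc[i, 'choice']!r}" for i in bad]
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems[:20]))
    return df


def _write_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for c in _MONEY_COLUMNS:
        if c in out.columns:
            out[c] = out[c].map(lambda x: f"{x:.2f}" if pd.notna(x) else "")
    out.to_csv(path, index=False)


def write_choices(df: pd.DataFrame, path) -> None:
    _write_csv(df, path)


def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("%s: empty ratings table", path)
        return pd.DataFrame(columns=RATING_COLUMNS)
    _require_columns(df, ["subject_id", "day", "positive", "negative"], path)
    bad = df.index[
        (df["positive"] < 0) | (df["positive"] > 100) | (df["negative"] < 0) | (df["negative"] > 100)
    ]
    if len(bad):
        raise ValidationError(
            f"{path}: " + "; ".join(f"row {i + 1}: rating outside [0,100]" for i in bad[:20])
        )
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not df.empty:
        _require_columns(df, ["subject_id", "day", "task"], path)
    return df


def write_fits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run, serializable to YAML."""

    outdir: str = "artifacts"
    seed: int = 0
    simulate: bool = True
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    choices_path: str | None = None
    ratings_path: str | None = None
    convention: str = "immediate0"
    n_starts: int = 10
    min_trials: int = 20
    downsample: str = "none"  # none | weekmean | randomday
    state_models: tuple[str, ...] = ("repetition", "group", "mood")
    parameters: tuple[str, ...] = tuple(PARAMETER_MAP)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _cohort_config(overrides: dict) -> CohortConfig:
    base = CohortConfig()
    for key, value in overrides.items():
        if not hasattr(base, key):
            raise ValueError(f"unknown cohort config key {key!r}")
        current = getattr(base, key)
        if isinstance(current, dict) and isinstance(value, dict):
            current.update(value)
        else:
            setattr(base, key, value)
    return base


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate (optional) -> fit -> decompose -> state analysis.

    Writes choices.csv / ratings.csv / truth.csv (when simulating),
    fits.csv, icc.csv, lme_results.csv and manifest.json into
    ``config.outdir``; never mutates its inputs.  Returns the output
    directory.  If every day is excluded (e.g. ``min_trials`` above the task
    length) the run completes with empty outputs and says so in the
    manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_path = outdir / "events.jsonl"
    events = []

    def log_event(stage: str, **info) -> None:
        event = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"), "stage": stage, **info}
        events.append(event)
        logger.info("%s: %s", stage, info)

    # --- inputs ---------------------------------------------------------------
    if config.simulate:
        cc = _cohort_config(config.cohort)
        sim_seed = substream_seed(config.seed, "simulation")
        choices, ratings, truth = simulate_cohort(cc, seed=sim_seed)
        write_choices(choices, outdir / "choices.csv")
        write_ratings(ratings, outdir / "ratings.csv")
        truth.to_csv(outdir / "truth.csv", index=False)
        log_event("simulate", seed=sim_seed, n_choices=len(choices), n_ratings=len(ratings))
    else:
        if not config.choices_path:
            raise ValueError("choices_path required when simulate is false")
        choices = read_choices(config.choices_path)
        ratings = read_ratings(config.ratings_path) if config.ratings_path else pd.DataFrame(columns=RATING_COLUMNS)
        log_event("load", n_choices=len(choices), n_ratings=len(ratings))

    # --- fit ------------------------------------------------------------------
    fit_seed = substream_seed(config.seed, "fitting")
    fits = fit_all(
        choices,
        seed=fit_seed,
        convention=config.convention,
        min_trials=config.min_trials,
        n_starts=config.n_starts,
    )
    write_fits(fits, outdir / "fits.csv")
    n_converged = int(fits["converged"].sum()) if len(fits) else 0
    log_event(
        "fit",
        seed=fit_seed,
        n_fits=len(fits),
        n_nonconverged=len(fits) - n_converged,
        n_candidate_days=int(choices.groupby(["subject_id", "day", "task"]).ngroups) if len(choices) else 0,
    )

    # --- variance decomposition ----------------------------------------------
    icc_rows = []
    if len(fits):
        from .state import parameter_series

        for parameter in config.parameters:
            series = parameter_series(fits, parameter)
            if config.downsample == "weekmean":
                series = downsample_week_mean(series, value_cols=("value",), day_col="day").rename(
                    columns={"week": "day"}
                )
            elif config.downsample == "randomday":
                series = downsample_random_days(
                    series, seed=substream_seed(config.seed, "downsample", parameter), value_cols=("value",)
                )
            try:
                vd = compute_icc(series, "value")
            except ValueError as err:
                log_event("icc_skipped", parameter=parameter, reason=str(err))
                continue
            icc_rows.append(
                {
                    "parameter": parameter,
                    "grouping": vd.grouping,
                    "sigma2_between": vd.sigma2_between,
                    "sigma2_within": vd.sigma2_within,
                    "icc": vd.icc,
                    "n_subjects": vd.n_subjects,
                    "n_observations": vd.n_observations,
                    "singular": vd.singular,
                }
            )
    icc = pd.DataFrame(icc_rows)
    icc.to_csv(outdir / "icc.csv", index=False)
    log_event("decompose", n_parameters=len(icc), downsample=config.downsample)

    # --- state models ---------------------------------------------------------
    results = []
    if len(fits):
        mood_days = build_mood_days(ratings) if len(ratings) else None
        for parameter in config.parameters:
            try:
                if "repetition" in config.state_models:
                    results.append(fit_repetition_model(fits, parameter))
                if "group" in config.state_models:
                    results.append(fit_group_model(fits, parameter))
                if "mood" in config.state_models and mood_days is not None:
                    results.append(fit_mood_model(fits, mood_days, parameter))
            except (ValueError, np.linalg.LinAlgError) as err:
                log_event("state_skipped", parameter=parameter, reason=str(err))
    lme = lme_results_to_frame(results) if results else pd.DataFrame()
    lme.to_csv(outdir / "lme_results.csv", index=False)
    log_event("state", n_models=len(results))

    # --- manifest -------------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "master_seed": config.seed,
        "events": events,
        "empty_outputs": len(fits) == 0,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    events_path.write_text("\n".join(json.dumps(e) for e in events))
    return outdir
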