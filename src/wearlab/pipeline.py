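"""End-to-end pipeline: simulate (or load) -> score -> feedback -> analyze.

Every run writes its configuration, a manifest with a content hash of all
emitted tables, and the stage outputs as CSV into one artifact directory,
so that identical configuration and seed reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import replace
from pathlib import Path

import pandas as pd

from . import __version__
from .activity import aggregate_all
from .analysis import assemble_table, descriptive_table, person_mean_correlations, pre_post_tests, run_model_battery
from .config import RunConfig, SimulationConfig
from .feedback import build_cards, detect_emergencies
from .hrv import daily_summary, windows_from_minutes
from .simulate import (
    Cohort,
    apply_missingness,
    generate_cohort,
    read_minutes,
    read_participants,
    read_surveys,
    write_cohort,
)
from .sleep import score_nights
from .symptoms import code_surveys


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Raises with the failing stage's name on any stage error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    hashes: dict[str, str] = {}
    stage = "init"
    try:
        stage = "simulate"
        if config.input_dir is None:
            sim = replace(config.simulation, seed=config.seed)
            cohort = apply_missingness(generate_cohort(sim, render_minutes=True))
            paths = write_cohort(cohort, out)
            minutes, surveys, profiles = cohort.minutes, cohort.surveys, cohort.profiles
            for k, p in paths.items():
                hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        else:
            src = Path(config.input_dir)
            for name in ("participants.csv", "minutes.csv", "surveys.csv"):
                if not (src / name).exists():
                    raise FileNotFoundError(f"missing input file: {src / name}")
            profiles = read_participants(src / "participants.csv")
            minutes = read_minutes(src / "minutes.csv")
            surveys = read_surveys(src / "surveys.csv")

        stage = "sleep"
        sleep_nights = score_nights(minutes, profiles, config.rule1_direction)
        hashes["sleep_nights.csv"] = _write(sleep_nights, out / "sleep_nights.csv")

        stage = "hrv"
        hrv_windows = windows_from_minutes(minutes)
        hrv_daily = daily_summary(hrv_windows)
        hashes["hrv_windows.csv"] = _write(hrv_windows, out / "hrv_windows.csv")
        hashes["hrv_daily.csv"] = _write(hrv_daily, out / "hrv_daily.csv")

        stage = "activity"
        activity_daily = aggregate_all(minutes)
        hashes["activity_daily.csv"] = _write(activity_daily, out / "activity_daily.csv")

        stage = "symptoms"
        surveys = code_surveys(surveys)

        stage = "feedback"
        start_dates = surveys.groupby("participant_id")["date"].min()
        cards = build_cards(sleep_nights, hrv_daily, activity_daily, start_dates)
        alerts = detect_emergencies(minutes, activity_daily)
        hashes["feedback_daily.csv"] = _write(cards, out / "feedback_daily.csv")
        hashes["alerts.csv"] = _write(alerts, out / "alerts.csv")

        stage = "analyze"
        rows = assemble_table(
            sleep_nights, hrv_daily, activity_daily, surveys, profiles,
            skip_week1=config.skip_week1,
        )
        hashes["daily_rows.csv"] = _write(rows, out / "daily_rows.csv")
        results = run_model_battery(rows, n_quad=config.n_quad)
        hashes["model_results.csv"] = _write(results, out / "model_results.csv")
        corr_r, corr_p = person_mean_correlations(rows, profiles)
        hashes["person_correlations_r.csv"] = _write(
            corr_r.reset_index(names="variable"), out / "person_correlations_r.csv"
        )
        desc = descriptive_table(profiles, rows)
        hashes["descriptives.csv"] = _write(desc, out / "descriptives.csv")
        if {"gds_post", "psqi_post", "sus_post"} <= set(profiles.columns):
            pp = pre_post_tests(profiles)
            (out / "pre_post.json").write_text(json.dumps(pp, indent=2, default=float))
            hashes["pre_post.json"] = hashlib.sha256(
                (out / "pre_post.json").read_bytes()
            ).hexdigest()
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir", None)  # paths must not affect reproducibility
    cfg_dict.pop("input_dir", None)
    manifest = {
        "wearlab_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": hashes,
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def make_fixtures(size: str = "tiny", seed: int = 20220905, render_minutes: bool = True) -> Cohort:
    """Generate a packaged test cohort.

    ``tiny`` is 3 participants x 10 days (fast enough for unit tests);
    ``study_scale`` is the full study geometry, 25 participants x 8-40 days
    (mean 32.28).  ``render_minutes=False`` skips the minute streams and
    returns only the day-level tables.
    """
    if size == "tiny":
        cfg = SimulationConfig(n_participants=3, n_days=10, seed=seed)
    elif size == "study_scale":
        day_counts = _study_scale_day_counts()
        cfg = SimulationConfig(
            n_participants=25, n_days=33, day_counts=day_counts, seed=seed
        )
    else:
        raise ValueError(f"unknown fixture size {size!r}")
    return apply_missingness(generate_cohort(cfg, render_minutes=render_minutes))


def _study_scale_day_counts() -> list[int]:
    """25 day-counts in [8, 40] summing to 807 (mean 32.28)."""
    counts = [8] + [33] * 23 + [40]
    assert sum(counts) == 807 and len(counts) == 25
    return counts
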