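"""Individualized traffic-light health feedback and emergency alerts.

Each participant's first calendar week of wear establishes a personal
baseline (mean and sample SD) per domain.  A day's value is then colored:

* green — more than 1 SD above the baseline mean,
* yellow — within +/-1 SD (boundaries inclusive),
* red — more than 1 SD below the mean,
* gray — value missing or baseline invalid (< 2 week-1 days).

For the sleep domain (keyed on the sleep fragmentation index, where higher
means worse sleep) green and red are swapped.  Domains: ``stress_hf``
(daily mean HF power), ``sleep_sfi``, ``steps`` (daily step count), and
``activity`` (light + moderate + intense minutes).

Emergency alerts, evaluated independently per day: an inactive run longer
than 8 hours (> 480 minutes), any minute with heart rate below 30 bpm, or
any minute above 140 bpm — all strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

DOMAINS = ("stress_hf", "sleep_sfi", "steps", "activity")
INVERTED_DOMAINS = frozenset({"sleep_sfi"})

GREEN, YELLOW, RED, GRAY = "green", "yellow", "red", "gray"

HR_LOW_BPM = 30.0
HR_HIGH_BPM = 140.0
INACTIVITY_MIN = 480  # "over 8 hours", strict


@dataclass
class BaselineStats:
    participant_id: str
    domain: str
    mean: float
    sd: float
    n_days: int

    @property
    def valid(self) -> bool:
        return self.n_days >= 2 and np.isfinite(self.mean)


@dataclass
class EmergencyAlert:
    participant_id: str
    timestamp: object  # datetime of first crossing, or date for inactivity
    trigger: str  # inactivity_gt_8h | hr_low | hr_high
    value: float


def compute_baseline(values, participant_id: str = "", domain: str = "") -> BaselineStats:
    """Baseline mean and sample SD (n-1) over week-1 non-missing day values."""
    v = pd.Series(values, dtype=float).dropna().to_numpy()
    n = v.size
    if n < 2:
        return BaselineStats(participant_id, domain, np.nan, np.nan, n)
    return BaselineStats(
        participant_id, domain, float(v.mean()), float(v.std(ddof=1)), n
    )


def classify_day(value: float, baseline: BaselineStats, domain: str) -> str:
    """Traffic-light color of one day's value against a personal baseline."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    if value is None or not np.isfinite(value) or not baseline.valid:
        return GRAY
    lo, hi = baseline.mean - baseline.sd, baseline.mean + baseline.sd
    if lo <= value <= hi:  # boundaries inclusive to yellow
        return YELLOW
    high = value > hi
    if domain in INVERTED_DOMAINS:
        return RED if high else GREEN
    return GREEN if high else RED


def _domain_values(sleep_nights, hrv_daily, activity_daily) -> pd.DataFrame:
    """Long table participant_id/date/domain/value for the four domains.

    A day's sleep value is the fragmentation index of the night ending that
    morning (night_date = date - 1 day).
    """
    frames = []
    if len(sleep_nights):
        s = sleep_nights[sleep_nights["valid"]].copy()
        s["date"] = pd.to_datetime(s["night_date"]).dt.date + timedelta(days=1)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s["participant_id"],
                    "date": s["date"],
                    "domain": "sleep_sfi",
                    "value": s["sfi"].astype(float),
                }
            )
        )
    if len(hrv_daily):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": hrv_daily["participant_id"],
                    "date": pd.to_datetime(hrv_daily["date"]).dt.date
                    if not isinstance(hrv_daily["date"].iloc[0], date)
                    else hrv_daily["date"],
                    "domain": "stress_hf",
                    "value": hrv_daily["mean_hf"].astype(float),
                }
            )
        )
    if len(activity_daily):
        a = activity_daily
        adate = (
            pd.to_datetime(a["date"]).dt.date
            if not isinstance(a["date"].iloc[0], date)
            else a["date"]
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": a["participant_id"],
                    "date": adate,
                    "domain": "steps",
                    "value": a["steps"].astype(float),
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": a["participant_id"],
                    "date": adate,
                    "domain": "activity",
                    "value": (
                        a["light_min"] + a["moderate_min"] + a["intense_min"]
                    ).astype(float),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["participant_id", "date", "domain", "value"])
    return pd.concat(frames, ignore_index=True)


def compute_baselines(
    sleep_nights: pd.DataFrame,
    hrv_daily: pd.DataFrame,
    activity_daily: pd.DataFrame,
    start_dates: pd.Series,
) -> dict[tuple[str, str], BaselineStats]:
    """Week-1 baselines per (participant, domain).

    ``start_dates`` maps participant_id to the first day of participation;
    week 1 is the first 7 calendar days.
    """
    vals = _domain_values(sleep_nights, hrv_daily, activity_daily)
    out: dict[tuple[str, str], BaselineStats] = {}
    for (pid, dom), sub in vals.groupby(["participant_id", "domain"]):
        start = start_dates.get(pid)
        if start is None:
            continue
        week1 = sub[(sub["date"] >= start) & (sub["date"] < start + timedelta(days=7))]
        out[(pid, dom)] = compute_baseline(week1["value"], pid, dom)
    return out


def build_cards(
    sleep_nights: pd.DataFrame,
    hrv_daily: pd.DataFrame,
    activity_daily: pd.DataFrame,
    start_dates: pd.Series,
) -> pd.DataFrame:
    """The ``feedback_daily`` table: one row per participant-day with a
    color, value, and baseline mean/SD per domain."""
    vals = _domain_values(sleep_nights, hrv_daily, activity_daily)
    baselines = compute_baselines(sleep_nights, hrv_daily, activity_daily, start_dates)
    if not len(vals):
        return pd.DataFrame()
    wide = vals.pivot_table(
        index=["participant_id", "date"], columns="domain", values="value",
        aggfunc="first",
    ).reset_index()
    rows = []
    for _, r in wide.iterrows():
        pid = r["participant_id"]
        row = {"participant_id": pid, "date": r["date"]}
        for dom, col in (
            ("stress_hf", "stress"),
            ("sleep_sfi", "sleep"),
            ("steps", "steps"),
            ("activity", "activity"),
        ):
            value = r.get(dom, np.nan)
            b = baselines.get(
                (pid, dom), BaselineStats(pid, dom, np.nan, np.nan, 0)
            )
            row[f"{col}_value"] = value
            row[f"{col}_baseline_mean"] = b.mean
            row[f"{col}_baseline_sd"] = b.sd
            row[f"{col}_color"] = classify_day(value, b, dom)
        rows.append(row)
    return pd.DataFrame(rows)


def detect_emergencies(
    minutes: pd.DataFrame, activity_daily: pd.DataFrame
) -> pd.DataFrame:
    """The ``alerts`` table: at most one alert per trigger per day.

    Heart-rate triggers fire at the first minute crossing the threshold;
    the inactivity trigger fires on a day whose longest inactive run exceeds
    480 minutes.
    """
    alerts: list[EmergencyAlert] = []
    hr = minutes.dropna(subset=["heart_rate"])
    if len(hr):
        days = hr["timestamp"].dt.date
        for (pid, day), sub in hr.groupby(["participant_id", days], sort=True):
            low = sub[sub["heart_rate"] < HR_LOW_BPM]
            if len(low):
                first = low.iloc[0]
                alerts.append(
                    EmergencyAlert(pid, first["timestamp"], "hr_low", float(first["heart_rate"]))
                )
            high = sub[sub["heart_rate"] > HR_HIGH_BPM]
            if len(high):
                first = high.iloc[0]
                alerts.append(
                    EmergencyAlert(pid, first["timestamp"], "hr_high", float(first["heart_rate"]))
                )
    if len(activity_daily):
        inact = activity_daily[activity_daily["longest_inactive_run"] > INACTIVITY_MIN]
        for _, r in inact.iterrows():
            alerts.append(
                EmergencyAlert(
                    r["participant_id"], r["date"], "inactivity_gt_8h",
                    float(r["longest_inactive_run"]),
                )
            )
    return pd.DataFrame(
        [
            {
                "participant_id": a.participant_id,
                "timestamp": a.timestamp,
                "trigger": a.trigger,
                "value": a.value,
            }
            for a in alerts
        ],
        columns=["participant_id", "timestamp", "trigger", "value"],
    )
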