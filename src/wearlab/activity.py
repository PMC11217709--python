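"""Daily physical-activity aggregates from minute-level steps and intensity.

Intensity classes (sedentary/light/moderate/intense) are consumed as
device-assigned labels, not recomputed from accelerometry.  The longest
inactive run feeds the emergency rule (more than 8 hours of inactivity); by
default minutes with missing data count as inactive, since a device that is
off could itself signal an emergency.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

INTENSITY_CLASSES = ("sedentary", "light", "moderate", "intense")


@dataclass
class ActivityDaily:
    participant_id: str
    date: date
    steps_total: int
    light_min: int
    moderate_min: int
    intense_min: int
    longest_inactive_run: int
    worn_minutes: int

    @property
    def missing(self) -> bool:
        return self.worn_minutes == 0


def _longest_run(mask: np.ndarray) -> int:
    if mask.size == 0 or not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return int((edges[1::2] - edges[::2]).max())


def aggregate_daily(
    minutes: pd.DataFrame,
    participant_id: str,
    day: date,
    missing_counts_inactive: bool = True,
) -> ActivityDaily:
    """Aggregate one participant's calendar day [00:00, 24:00).

    ``worn_minutes`` counts minutes with a non-missing intensity class; a day
    with zero worn minutes is missing for activity.  The inactive run counts
    consecutive minutes with zero (or missing) steps and sedentary (or
    missing) intensity.
    """
    ts = minutes["timestamp"]
    sub = minutes[
        (minutes["participant_id"] == participant_id) & (ts.dt.date == day)
    ]
    return _aggregate_slice(sub, participant_id, day, missing_counts_inactive)


def _aggregate_slice(
    sub: pd.DataFrame,
    participant_id: str,
    day: date,
    missing_counts_inactive: bool,
) -> ActivityDaily:
    steps = pd.to_numeric(sub["steps"], errors="coerce")
    intensity = sub["intensity"]
    worn = intensity.isin(INTENSITY_CLASSES)
    counts = intensity[worn].value_counts()

    zero_steps = steps.fillna(0).to_numpy() == 0 if missing_counts_inactive else (
        steps.to_numpy() == 0
    )
    sedentary = (
        (~worn | (intensity == "sedentary")).to_numpy()
        if missing_counts_inactive
        else (intensity == "sedentary").to_numpy()
    )
    inactive = zero_steps & sedentary

    return ActivityDaily(
        participant_id=participant_id,
        date=day,
        steps_total=int(steps.fillna(0).sum()),
        light_min=int(counts.get("light", 0)),
        moderate_min=int(counts.get("moderate", 0)),
        intense_min=int(counts.get("intense", 0)),
        longest_inactive_run=_longest_run(inactive),
        worn_minutes=int(worn.sum()),
    )


def aggregate_all(minutes: pd.DataFrame, missing_counts_inactive: bool = True) -> pd.DataFrame:
    """The ``activity_daily`` table for every participant-day in the stream."""
    rows = []
    days = minutes["timestamp"].dt.date
    for (pid, day), sub in minutes.groupby(["participant_id", days], sort=True):
        a = _aggregate_slice(sub, pid, day, missing_counts_inactive)
        rows.append(
            {
                "participant_id": a.participant_id,
                "date": a.date,
                "steps": a.steps_total,
                "light_min": a.light_min,
                "moderate_min": a.moderate_min,
                "intense_min": a.intense_min,
                "longest_inactive_run": a.longest_inactive_run,
                "worn_minutes": a.worn_minutes,
            }
        )
    return pd.DataFrame(rows)
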