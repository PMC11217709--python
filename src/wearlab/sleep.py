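"""Nightly sleep-window extraction, actigraphy rescoring, and sleep metrics.

The minute-level sleep/wake classification produced by a wrist-worn device is
noisy: isolated "sleep" minutes appear during restless wake and vice versa.
The module applies a Webster-style rescoring scheme before locating sleep
onset/offset and computing total sleep time (TST), the sleep fragmentation
index (SFI, awakenings of more than one minute per minute of TST), sleep
efficiency (SE, percent of time in bed spent asleep), and the number of long
fragmentation episodes.

Rescoring rules, applied in order, each over the output of the previous:

1. If the previous 4 minutes were wake, the first minute of a sleep period is
   rescored.  Stated as "adjusted to sleep" this rule is a no-op, since the
   minute is already sleep; ``rule1_direction="webster"``
   applies the classic direction (rescored to wake) instead.
2. After at least 10 minutes of wake, the first 3 minutes of a sleep period
   are rescored to wake.
3. / 4.  A sleep period shorter than 6 minutes flanked by more than 15 minutes
   of wake on both sides is rescored to wake.
5. A sleep period shorter than 10 minutes flanked by more than 20 minutes of
   wake on both sides is rescored to wake.

Within one rule, decisions are simultaneous: every sleep period is judged
against the series as it stood when the rule started, and all adjustments are
applied together.  Missing minutes break runs — they are neither sleep nor
wake, so a wake run interrupted by a gap does not satisfy a flanking
condition across the gap.

The nightly observation window runs from 6 PM to noon the next day (1,080
minutes); for a participant with a reversed day/night cycle the window is
6 AM to midnight of the same date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

AWAKE = 0
ASLEEP = 1
MISSING = 2

CLASS_LABELS = {AWAKE: "awake", ASLEEP: "asleep", MISSING: "missing"}
LABEL_CLASSES = {v: k for k, v in CLASS_LABELS.items()}

#: minutes in the 6 PM -> noon observation window
WINDOW_MINUTES = 18 * 60

#: default definition of a "long fragmentation episode": a wake run of at
#: least this many minutes between sleep onset and offset
DEFAULT_LONG_EPISODE_MIN = 5

#: nights with more than this fraction of missing minutes between onset and
#: offset are flagged invalid
MAX_MISSING_FRACTION = 0.20


# ---------------------------------------------------------------------------
# run-length representation
# ---------------------------------------------------------------------------

Runs = list[tuple[int, int]]  # (class, length) pairs, lengths > 0


def encode_runs(series: np.ndarray) -> Runs:
    """Run-length encode a 1-D array of sleep classes."""
    a = np.asarray(series)
    if a.size == 0:
        return []
    change = np.flatnonzero(np.diff(a)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [a.size]))
    return [(int(a[s]), int(e - s)) for s, e in zip(starts, ends)]


def decode_runs(runs: Runs) -> np.ndarray:
    if not runs:
        return np.empty(0, dtype=np.int8)
    return np.repeat(
        np.fromiter((c for c, _ in runs), dtype=np.int8, count=len(runs)),
        [l for _, l in runs],
    )


def _merge(runs: Runs) -> Runs:
    out: Runs = []
    for c, l in runs:
        if l <= 0:
            continue
        if out and out[-1][0] == c:
            out[-1] = (c, out[-1][1] + l)
        else:
            out.append((c, l))
    return out


def _rule_initial_wake(runs: Runs, min_wake: int, n_convert: int) -> Runs:
    """Rules (1 webster) and (2): rescore the first ``n_convert`` minutes of a
    sleep period preceded by a wake run of at least ``min_wake`` minutes."""
    out: Runs = []
    for i, (c, l) in enumerate(runs):
        if (
            c == ASLEEP
            and i > 0
            and runs[i - 1][0] == AWAKE
            and runs[i - 1][1] >= min_wake
        ):
            k = min(n_convert, l)
            out.append((AWAKE, k))
            if l - k:
                out.append((ASLEEP, l - k))
        else:
            out.append((c, l))
    return _merge(out)


def _rule_isolated_bout(runs: Runs, sleep_lt: int, flank_gt: int) -> Runs:
    """Rules (3/4) and (5): rescore a sleep period of fewer than ``sleep_lt``
    minutes to wake when flanked on both sides by wake runs strictly longer
    than ``flank_gt`` minutes."""
    out: Runs = []
    for i, (c, l) in enumerate(runs):
        if (
            c == ASLEEP
            and l < sleep_lt
            and 0 < i < len(runs) - 1
            and runs[i - 1][0] == AWAKE
            and runs[i - 1][1] > flank_gt
            and runs[i + 1][0] == AWAKE
            and runs[i + 1][1] > flank_gt
        ):
            out.append((AWAKE, l))
        else:
            out.append((c, l))
    return _merge(out)


def rescore_runs(runs: Runs, rule1_direction: str = "as_printed") -> Runs:
    """Apply the full rescoring cascade to a run-length encoded night."""
    if rule1_direction not in ("as_printed", "webster"):
        raise ValueError(f"unknown rule1_direction: {rule1_direction!r}")
    r = _merge(runs)
    if rule1_direction == "webster":
        r = _rule_initial_wake(r, 4, 1)
    # "as_printed" adjusts the minute to the class it already has: no-op.
    r = _rule_initial_wake(r, 10, 3)
    r = _rule_isolated_bout(r, 6, 15)
    r = _rule_isolated_bout(r, 10, 20)
    return r


def onset_offset_runs(runs: Runs) -> tuple[int, int] | None:
    """Sleep onset/offset as (start, end) minute indices, both inclusive.

    Onset is the start of the first run of >= 10 consecutive sleep minutes;
    offset is the end of the last such run.  ``None`` when no qualifying run
    exists.
    """
    pos = 0
    onset = None
    offset = None
    for c, l in runs:
        if c == ASLEEP and l >= 10:
            if onset is None:
                onset = pos
            offset = pos + l - 1
        pos += l
    if onset is None:
        return None
    return onset, offset


@dataclass
class SleepMetrics:
    """Scored metrics for one night."""

    valid: bool
    time_in_bed: float = np.nan
    tst: float = np.nan
    onset: int | None = None  # minute index within the window
    offset: int | None = None
    n_awakenings: int = 0
    sfi: float = np.nan
    se: float = np.nan
    n_long_episodes: int = 0
    pct_missing: float = np.nan
    invalid_reason: str | None = None


def metrics_from_runs(
    runs: Runs,
    long_episode_min: int = DEFAULT_LONG_EPISODE_MIN,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> SleepMetrics:
    """Compute sleep metrics from an already rescored night.

    Awakenings are wake runs of at least 2 consecutive minutes ("more than
    1 minute") strictly between onset and offset.  Missing minutes inside the
    in-bed interval are excluded from TST and from awakening counts; a night
    with more than ``max_missing_fraction`` missing minutes in bed is invalid.
    """
    oo = onset_offset_runs(runs)
    if oo is None:
        return SleepMetrics(valid=False, invalid_reason="no_sleep_run")
    onset, offset = oo
    time_in_bed = offset - onset + 1

    tst = 0
    n_awak = 0
    n_long = 0
    n_missing = 0
    pos = 0
    for c, l in runs:
        start, end = pos, pos + l - 1
        pos += l
        if end < onset or start > offset:
            continue
        # onset/offset fall on sleep-run boundaries, so interior runs are
        # never clipped; clip defensively anyway
        length = min(end, offset) - max(start, onset) + 1
        if c == ASLEEP:
            tst += length
        elif c == AWAKE:
            if length >= 2:
                n_awak += 1
            if length >= long_episode_min:
                n_long += 1
        else:
            n_missing += 1 * length

    pct_missing = n_missing / time_in_bed
    if tst == 0:
        return SleepMetrics(
            valid=False, pct_missing=pct_missing, invalid_reason="zero_tst"
        )
    if pct_missing > max_missing_fraction:
        return SleepMetrics(
            valid=False,
            time_in_bed=time_in_bed,
            tst=tst,
            onset=onset,
            offset=offset,
            pct_missing=pct_missing,
            invalid_reason="missing_gt_20pct",
        )
    return SleepMetrics(
        valid=True,
        time_in_bed=float(time_in_bed),
        tst=float(tst),
        onset=onset,
        offset=offset,
        n_awakenings=n_awak,
        sfi=n_awak / tst,
        se=100.0 * tst / time_in_bed,
        n_long_episodes=n_long,
        pct_missing=pct_missing,
    )


def score_runs(
    runs: Runs,
    rule1_direction: str = "as_printed",
    long_episode_min: int = DEFAULT_LONG_EPISODE_MIN,
) -> SleepMetrics:
    """Rescore a run-length encoded night and compute its metrics."""
    return metrics_from_runs(
        rescore_runs(runs, rule1_direction), long_episode_min=long_episode_min
    )


# ---------------------------------------------------------------------------
# minute-array / timestamped API
# ---------------------------------------------------------------------------


@dataclass
class SleepWakeSeries:
    """One participant-night of minute-level sleep/wake classes.

    ``night_date`` is the date of the evening on which the window starts.
    """

    participant_id: str
    night_date: date
    start: datetime
    classes: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.classes)


def window_bounds(night_date: date, reversed_cycle: bool = False) -> tuple[datetime, datetime]:
    """Start (inclusive) and end (exclusive) of the nightly window."""
    d = datetime(night_date.year, night_date.month, night_date.day)
    if reversed_cycle:
        return d + timedelta(hours=6), d + timedelta(hours=24)
    return d + timedelta(hours=18), d + timedelta(hours=36)


def extract_window(
    minutes: pd.DataFrame,
    participant_id: str,
    night_date: date,
    reversed_cycle: bool = False,
) -> SleepWakeSeries:
    """Slice one nightly window out of a long-format minute table.

    ``minutes`` must have columns ``participant_id``, ``timestamp``
    (datetime64) and ``sleep_class`` (labels ``asleep``/``awake``, blank or
    NaN for missing).  Minutes absent from the table are filled as missing.
    """
    start, end = window_bounds(night_date, reversed_cycle)
    classes = np.full(WINDOW_MINUTES, MISSING, dtype=np.int8)
    sub = minutes[
        (minutes["participant_id"] == participant_id)
        & (minutes["timestamp"] >= start)
        & (minutes["timestamp"] < end)
    ]
    if len(sub):
        idx = (
            (sub["timestamp"] - start).dt.total_seconds().to_numpy() // 60
        ).astype(np.int64)
        lab = sub["sleep_class"].to_numpy(dtype=object)
        val = np.array(
            [LABEL_CLASSES.get(x, MISSING) if isinstance(x, str) else MISSING for x in lab],
            dtype=np.int8,
        )
        classes[idx] = val
    return SleepWakeSeries(participant_id, night_date, start, classes)


def rescore(series: SleepWakeSeries, rule1_direction: str = "as_printed") -> SleepWakeSeries:
    """Apply the rescoring cascade to a nightly series."""
    runs = rescore_runs(encode_runs(series.classes), rule1_direction)
    return SleepWakeSeries(
        series.participant_id, series.night_date, series.start, decode_runs(runs)
    )


def detect_onset_offset(series: SleepWakeSeries) -> tuple[int, int] | None:
    """Onset/offset minute indices within a rescored window, or None."""
    return onset_offset_runs(encode_runs(series.classes))


def compute_metrics(
    series: SleepWakeSeries,
    long_episode_min: int = DEFAULT_LONG_EPISODE_MIN,
) -> SleepMetrics:
    """Metrics of an already rescored nightly series."""
    return metrics_from_runs(
        encode_runs(series.classes), long_episode_min=long_episode_min
    )


def score_night(
    minutes: pd.DataFrame,
    participant_id: str,
    night_date: date,
    reversed_cycle: bool = False,
    rule1_direction: str = "as_printed",
    long_episode_min: int = DEFAULT_LONG_EPISODE_MIN,
) -> SleepMetrics:
    """Extract, rescore, and score one participant-night."""
    w = extract_window(minutes, participant_id, night_date, reversed_cycle)
    return compute_metrics(rescore(w, rule1_direction), long_episode_min)


def score_nights(
    minutes: pd.DataFrame,
    profiles: pd.DataFrame,
    rule1_direction: str = "as_printed",
    long_episode_min: int = DEFAULT_LONG_EPISODE_MIN,
) -> pd.DataFrame:
    """Score every available night for every participant.

    Nights are the evening dates spanned by each participant's stream (a
    night's window starts at 6 PM of its ``night_date``).  Returns the
    ``sleep_nights`` table.
    """
    rows = []
    rev = dict(zip(profiles["participant_id"], profiles.get("reversed_cycle", False)))
    for pid, sub in minutes.groupby("participant_id", sort=True):
        reversed_cycle = bool(rev.get(pid, False))
        first = sub["timestamp"].min().date()
        last = sub["timestamp"].max().date()
        d = first
        while d < last:
            w = extract_window(sub, pid, d, reversed_cycle)
            m = compute_metrics(rescore(w, rule1_direction), long_episode_min)
            start, _ = window_bounds(d, reversed_cycle)
            rows.append(
                {
                    "participant_id": pid,
                    "night_date": d,
                    "valid": m.valid,
                    "time_in_bed": m.time_in_bed,
                    "tst": m.tst,
                    "onset": (start + timedelta(minutes=m.onset)) if m.onset is not None else pd.NaT,
                    "offset": (start + timedelta(minutes=m.offset)) if m.offset is not None else pd.NaT,
                    "n_awakenings": m.n_awakenings,
                    "sfi": m.sfi,
                    "se": m.se,
                    "n_long_episodes": m.n_long_episodes,
                    "rule1_direction": rule1_direction,
                    "pct_missing": m.pct_missing,
                }
            )
            d += timedelta(days=1)
    return pd.DataFrame(rows)
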