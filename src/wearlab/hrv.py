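"""Heart-rate-variability metrics from minute-level heart rate.

A consumer wearable reports heart rate once per minute, not beat-to-beat.
The module reconstructs an approximate R-R interval series by assigning each
minute with rate ``h`` bpm ``round(h)`` identical intervals of ``60000/h``
milliseconds.  This is an explicit approximation — within-minute variability
is lost, so time-domain metrics reflect minute-to-minute variation only — and
every derived record carries a ``source`` flag saying so.  Synthetic
beat-level R-R series (see :mod:`wearlab.simulate`) exercise the same metric
code without the reconstruction artifact.

Metrics per non-overlapping clock-aligned 5-minute window:

* SDNN — population standard deviation of the intervals (ms);
* RMSSD — root mean square of successive interval differences (ms);
* VLF/LF/HF band powers (ms^2) from a periodogram of the evenly resampled
  (4 Hz, cubic interpolation) mean-removed interval series, with the HRV
  Task Force band edges VLF 0.0033-0.04 Hz, LF 0.04-0.15 Hz, HF
  0.15-0.40 Hz; and the LF/HF ratio.

Intervals are filtered before metric computation: values outside the
physiologically plausible 300-2000 ms band, and values deviating more than
20% from an 11-point running median, are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline

#: absolute plausibility band for R-R intervals, ms
RR_MIN_MS = 300.0
RR_MAX_MS = 2000.0

#: running-median filter: window width and relative deviation threshold
MEDIAN_WINDOW = 11
MEDIAN_REL_TOL = 0.20

#: frequency band edges, Hz (HRV Task Force)
VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: minimum filtered intervals for a valid 5-minute window
MIN_INTERVALS = 30

RESAMPLE_HZ = 4.0


@dataclass
class RrSeries:
    """An ordered R-R interval series (ms) within one window."""

    intervals: np.ndarray
    participant_id: str | None = None
    window_start: datetime | None = None
    n_removed: int = 0
    source: str = "minute_hr"  # "minute_hr" (reconstructed) or "beat"


@dataclass
class HrvWindow:
    """Time- and frequency-domain metrics for one 5-minute window."""

    valid: bool
    window_start: datetime | None = None
    n_intervals: int = 0
    sdnn: float = np.nan
    rmssd: float = np.nan
    vlf_power: float = np.nan
    lf_power: float = np.nan
    hf_power: float = np.nan
    lf_hf_ratio: float = np.nan
    source: str = "minute_hr"


def hr_to_rr(minute_hr, participant_id=None, window_start=None) -> RrSeries:
    """Reconstruct R-R intervals from per-minute heart rates (bpm).

    Each minute with rate ``h`` contributes ``round(h)`` intervals of
    ``60000/h`` ms.  Non-positive or missing minutes are skipped.
    """
    hr = np.asarray(minute_hr, dtype=float)
    chunks = []
    for h in hr:
        if not np.isfinite(h) or h <= 0:
            continue
        n = int(round(h))
        if n > 0:
            chunks.append(np.full(n, 60000.0 / h))
    iv = np.concatenate(chunks) if chunks else np.empty(0)
    return RrSeries(iv, participant_id, window_start, source="minute_hr")


def filter_rr(series: RrSeries) -> RrSeries:
    """Remove implausible and artifactual intervals.

    Drops intervals outside [300, 2000] ms, then intervals deviating more
    than 20% from the centered 11-point running median of the surviving
    series.  The number of removals is recorded on the result.
    """
    iv = np.asarray(series.intervals, dtype=float)
    n0 = iv.size
    iv = iv[(iv >= RR_MIN_MS) & (iv <= RR_MAX_MS)]
    if iv.size:
        med = (
            pd.Series(iv)
            .rolling(MEDIAN_WINDOW, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        iv = iv[np.abs(iv - med) <= MEDIAN_REL_TOL * med]
    return RrSeries(
        iv,
        series.participant_id,
        series.window_start,
        n_removed=n0 - iv.size,
        source=series.source,
    )


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    mask = (f > band[0]) & (f <= band[1])
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def spectral_powers(intervals: np.ndarray) -> tuple[float, float, float]:
    """VLF, LF, HF power (ms^2) of an R-R series.

    The irregularly spaced series (sample k occurs at the cumulative sum of
    the preceding intervals) is resampled to an even 4 Hz grid by cubic
    interpolation, mean-removed, and passed through a periodogram; band
    powers are trapezoidal integrals of the one-sided PSD.
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.size < 4:
        return 0.0, 0.0, 0.0
    t = np.concatenate(([0.0], np.cumsum(iv[:-1]))) / 1000.0  # s
    if t[-1] <= 0:
        return 0.0, 0.0, 0.0
    grid = np.arange(0.0, t[-1], 1.0 / RESAMPLE_HZ)
    if grid.size < 8:
        return 0.0, 0.0, 0.0
    # cubic interpolation needs strictly increasing sample times
    keep = np.concatenate(([True], np.diff(t) > 0))
    resampled = CubicSpline(t[keep], iv[keep])(grid)
    resampled = resampled - resampled.mean()
    f, psd = signal.periodogram(resampled, fs=RESAMPLE_HZ, window="boxcar")
    return (
        _band_power(f, psd, VLF_BAND),
        _band_power(f, psd, LF_BAND),
        _band_power(f, psd, HF_BAND),
    )


def window_metrics(series: RrSeries, min_intervals: int = MIN_INTERVALS) -> HrvWindow:
    """Compute SDNN, RMSSD, and spectral band powers for one window.

    SDNN uses the population convention (divide by n).  A window with fewer
    than ``min_intervals`` filtered intervals is returned invalid.
    """
    iv = np.asarray(series.intervals, dtype=float)
    if iv.size < min_intervals:
        return HrvWindow(
            valid=False,
            window_start=series.window_start,
            n_intervals=int(iv.size),
            source=series.source,
        )
    sdnn = float(np.std(iv))  # ddof=0
    rmssd = float(np.sqrt(np.mean(np.diff(iv) ** 2)))
    vlf, lf, hf = spectral_powers(iv)
    lf_hf = lf / hf if hf > 0 else np.nan
    return HrvWindow(
        valid=True,
        window_start=series.window_start,
        n_intervals=int(iv.size),
        sdnn=sdnn,
        rmssd=rmssd,
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=lf_hf,
        source=series.source,
    )


def windows_from_minutes(minutes: pd.DataFrame, min_intervals: int = MIN_INTERVALS) -> pd.DataFrame:
    """Compute the ``hrv_windows`` table from a long-format minute stream.

    Minutes are grouped into non-overlapping 5-minute windows aligned to
    clock boundaries (:00, :05, ...), around the clock.
    """
    rows = []
    df = minutes.dropna(subset=["heart_rate"])
    if len(df) == 0:
        return pd.DataFrame(
            columns=[
                "participant_id", "window_start", "n_intervals", "sdnn",
                "rmssd", "vlf", "lf", "hf", "lf_hf", "valid",
            ]
        )
    wstart = df["timestamp"].dt.floor("5min")
    for (pid, ws), sub in df.groupby(["participant_id", wstart], sort=True):
        rr = hr_to_rr(sub["heart_rate"].to_numpy(), pid, ws.to_pydatetime())
        m = window_metrics(filter_rr(rr), min_intervals)
        rows.append(
            {
                "participant_id": pid,
                "window_start": ws,
                "n_intervals": m.n_intervals,
                "sdnn": m.sdnn,
                "rmssd": m.rmssd,
                "vlf": m.vlf_power,
                "lf": m.lf_power,
                "hf": m.hf_power,
                "lf_hf": m.lf_hf_ratio,
                "valid": m.valid,
            }
        )
    return pd.DataFrame(rows)


def daily_summary(windows: pd.DataFrame) -> pd.DataFrame:
    """Unweighted daily means of the windowed metrics over valid windows.

    Returns the ``hrv_daily`` table; days with zero valid windows are absent
    (missing for HRV).
    """
    w = windows[windows["valid"]].copy()
    if len(w) == 0:
        return pd.DataFrame(
            columns=[
                "participant_id", "date", "mean_sdnn", "mean_rmssd",
                "mean_hf", "mean_lf_hf", "n_valid_windows",
            ]
        )
    w["date"] = pd.to_datetime(w["window_start"]).dt.date
    g = w.groupby(["participant_id", "date"], sort=True)
    out = g.agg(
        mean_sdnn=("sdnn", "mean"),
        mean_rmssd=("rmssd", "mean"),
        mean_hf=("hf", "mean"),
        mean_lf_hf=("lf_hf", "mean"),
        n_valid_windows=("valid", "size"),
    ).reset_index()
    return out
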