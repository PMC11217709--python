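"""Synthetic living-lab cohort generator.

Generates a cohort with the statistical structure the downstream analysis
assumes: person-level traits, nightly sleep/wake structure, daily HRV and
activity summaries, daily symptom reports coupled to within-person sleep
deviations, and day-level missingness.

The generative mechanism, per participant-day:

1.  A nightly sleep/wake sequence is constructed (bedtime around 10 PM,
    ~485 minutes in bed, a Poisson number of awakenings with lognormal
    durations) and then *scored by the package's own sleep module*; the
    scored SFI/SE/TST are the night's true covariates.  Defining truth this
    way keeps the generator and the analysis internally consistent — the
    target cohort means (TST ~320 min, SE ~66%, SFI ~0.02) imply few, long
    awakenings, which interact with the rescoring rules.
2.  The day's symptom binary is drawn from
    ``logit(p) = alpha_i + beta_sfi * sfi100_c + beta_se * se_c``
    where ``alpha_i`` is a person intercept (correlated with baseline
    depression), ``sfi100`` is the fragmentation index per 100 minutes of
    sleep, ``se`` is efficiency in percent, and ``_c`` is the deviation
    from the person's own mean (expanding, by default, since the person's
    true mean is unknown mid-stream).  By default the night *ending that
    morning* drives the day's report.
3.  Daily HRV and activity summaries are drawn from person-level
    distributions matched to the cohort's descriptive table; they carry no
    symptom coupling (null predictors).

Minute-level streams (heart rate, sleep class, steps, intensity) are
rendered on demand from the same nightly structures, so the pipeline's
sleep scoring reproduces the generator's truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import sleep as sleepmod
from . import symptoms as sym
from .config import SimulationConfig
from .sleep import ASLEEP, AWAKE, Runs

MISSING_DOMAINS = ("survey", "hrv", "sleep", "steps")


@dataclass
class Cohort:
    """A generated cohort: analysis-ready tables plus optional minutes."""

    config: SimulationConfig
    profiles: pd.DataFrame
    surveys: pd.DataFrame
    sleep_nights: pd.DataFrame
    hrv_daily: pd.DataFrame
    activity_daily: pd.DataFrame
    minutes: pd.DataFrame | None = None
    night_runs: dict = field(default_factory=dict, repr=False)
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# person-level profiles
# ---------------------------------------------------------------------------

_EDU_P = (0.56, 0.08, 0.20, 0.16)
_INCOME_P = (0.16, 0.64, 0.08, 0.12)


def _make_profiles(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_participants
    pid = [f"P{i + 1:02d}" for i in range(n)]
    age = np.clip(np.round(rng.normal(76.4, 4.23, n)), 65, 95).astype(int)
    sex = np.where(rng.random(n) < 0.76, "woman", "man")
    education = rng.choice([1, 2, 3, 4], size=n, p=_EDU_P)
    income = rng.choice([1, 2, 3, 4], size=n, p=_INCOME_P)
    n_chronic = np.clip(rng.poisson(4.2, n), 0, 12).astype(int)
    gds = np.clip(np.round(rng.normal(4.0, 3.0, n)), 0, 15).astype(int)
    psqi = np.clip(np.round(rng.normal(8.3, 2.5, n)), 0, 21).astype(int)
    sus_pre = np.clip(rng.normal(53.3, 24.5, n), 0, 100)
    gds_post = np.clip(gds + np.round(rng.normal(-1.0, 1.5, n)), 0, 15).astype(int)
    psqi_post = np.clip(psqi + np.round(rng.normal(-1.5, 2.0, n)), 0, 21).astype(int)
    sus_post = np.clip(sus_pre + rng.normal(6.35, 15.0, n), 0, 100)
    reversed_cycle = np.zeros(n, dtype=bool)
    if cfg.n_reversed_cycle > 0:
        idx = rng.choice(n, size=min(cfg.n_reversed_cycle, n), replace=False)
        reversed_cycle[idx] = True
    return pd.DataFrame(
        {
            "participant_id": pid,
            "age": age,
            "sex": sex,
            "education": education,
            "income_band": income,
            "n_chronic": n_chronic,
            "baseline_gds": gds,
            "baseline_psqi": psqi,
            "sus_pre": np.round(sus_pre, 1),
            "sus_post": np.round(sus_post, 1),
            "gds_post": gds_post,
            "psqi_post": psqi_post,
            "reversed_cycle": reversed_cycle,
        }
    )


# ---------------------------------------------------------------------------
# nightly sleep construction
# ---------------------------------------------------------------------------


def _construct_night(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    onset_mean_i: float,
    tib_mean_i: float,
    rate_i: float,
) -> Runs:
    """Build one 1,080-minute night as run-length pairs."""
    W = sleepmod.WINDOW_MINUTES
    pre = int(np.clip(round(rng.normal(onset_mean_i, cfg.bed_onset_sd_night)), 30, 600))
    tib = int(
        np.clip(
            round(rng.normal(tib_mean_i, cfg.tib_sd_night)),
            cfg.tib_min,
            W - pre - 30,
        )
    )
    k = int(rng.poisson(rate_i))
    bouts = []
    if k:
        bouts = np.clip(
            np.round(rng.lognormal(cfg.awake_bout_mu, cfg.awake_bout_sigma, k)), 1, 90
        ).astype(int)
        # keep at least ~12 sleep minutes per sleep run
        max_awake = tib - 12 * (k + 1)
        while k and bouts.sum() > max_awake:
            k -= 1
            bouts = bouts[:k]
            max_awake = tib - 12 * (k + 1)
    total_awake = int(np.sum(bouts)) if k else 0
    sleep_total = tib - total_awake
    # spread sleep minutes over k+1 runs, each at least 12 minutes
    base = 12
    extra = rng.multinomial(sleep_total - base * (k + 1), np.full(k + 1, 1.0 / (k + 1)))
    sleep_runs = base + extra
    runs: Runs = [(AWAKE, pre)]
    for j in range(k + 1):
        runs.append((ASLEEP, int(sleep_runs[j])))
        if j < k:
            runs.append((AWAKE, int(bouts[j])))
    tail = W - pre - tib
    if tail > 0:
        runs.append((AWAKE, tail))
    return runs


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(cfg: SimulationConfig, render_minutes: bool = False) -> Cohort:
    """Generate a complete cohort, deterministic given ``cfg.seed``.

    With ``render_minutes=True`` the minute-level streams are also rendered
    (heart rate, sleep class, steps, intensity), which is what the full
    pipeline consumes; without it, only the day-level tables are built,
    which is much faster and sufficient for Monte-Carlo work.  Nightly
    sleep truth is identical in both modes.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles = _make_profiles(cfg, rng)
    n = cfg.n_participants

    # shared person factor: fragmentation-prone sleepers (higher q) are
    # also more depressed on average, via sleep_person_loading below
    q_i = rng.normal(0, 1, n)

    # person intercepts, calibrated so the marginal prevalence matches
    z_gds = (profiles["baseline_gds"] - profiles["baseline_gds"].mean()) / max(
        profiles["baseline_gds"].std(ddof=0), 1e-9
    )
    rest = np.sqrt(max(1 - cfg.gds_loading**2 - cfg.sleep_person_loading**2, 0.0))
    t_i = (
        cfg.gds_loading * z_gds.to_numpy()
        + cfg.sleep_person_loading * q_i
        + rest * rng.normal(0, 1, n)
    )
    alpha0 = logit(cfg.prevalence) * np.sqrt(1 + 0.346 * cfg.sigma_person**2)
    alpha = alpha0 + cfg.sigma_person * t_i

    # person-level distributions
    onset_mean = rng.normal(cfg.bed_onset_mean, cfg.bed_onset_sd_person, n)
    tib_mean = rng.normal(cfg.tib_mean, cfg.tib_sd_person, n)
    awak_rate = cfg.awakenings_mean * np.exp(
        cfg.awakenings_sigma * q_i - 0.5 * cfg.awakenings_sigma**2
    )
    hr_mean = rng.normal(cfg.hr_mean, cfg.hr_mean_sd_person, n)
    lf_hf_pm = rng.normal(cfg.lf_hf_mean, cfg.lf_hf_sd_person, n)
    hf_logpm = rng.normal(cfg.hf_log_mean, cfg.hf_log_sd_person, n)
    sdnn_pm = np.clip(rng.normal(cfg.sdnn_mean, cfg.sdnn_sd_person, n), 20, None)
    rmssd_pm = np.clip(rng.normal(cfg.rmssd_mean, cfg.rmssd_sd_person, n), 2, None)
    steps_logpm = rng.normal(cfg.steps_log_median, cfg.steps_log_sd_person, n)
    light_pm = np.clip(rng.normal(cfg.light_mean, cfg.light_sd_person, n), 5, None)
    moderate_pm = np.clip(rng.normal(cfg.moderate_mean, cfg.moderate_sd_person, n), 0, None)
    intense_pm = np.clip(rng.normal(cfg.intense_mean, cfg.intense_sd_person, n), 0, None)

    night_runs: dict = {}
    sleep_rows = []
    hrv_rows = []
    act_rows = []
    survey_rows = []
    truth_rows = []

    for i, pid in enumerate(profiles["participant_id"]):
        nd = cfg.days_for(i)
        days = [cfg.start_date + timedelta(days=d) for d in range(nd)]

        # nights: evenings of day -1 .. nd-2 (the device is installed the
        # evening before the first survey day, so every day has a night
        # ending that morning)
        metrics = {}
        for d in range(-1, nd - 1):
            night_date = cfg.start_date + timedelta(days=d)
            runs = _construct_night(cfg, rng, onset_mean[i], tib_mean[i], awak_rate[i])
            night_runs[(pid, night_date)] = runs
            m = sleepmod.score_runs(runs)
            metrics[night_date] = m
            start, _ = sleepmod.window_bounds(
                night_date, bool(profiles["reversed_cycle"].iloc[i])
            )
            sleep_rows.append(
                {
                    "participant_id": pid,
                    "night_date": night_date,
                    "valid": m.valid,
                    "time_in_bed": m.time_in_bed,
                    "tst": m.tst,
                    "onset": start + timedelta(minutes=m.onset) if m.onset is not None else pd.NaT,
                    "offset": start + timedelta(minutes=m.offset) if m.offset is not None else pd.NaT,
                    "n_awakenings": m.n_awakenings,
                    "sfi": m.sfi,
                    "se": m.se,
                    "n_long_episodes": m.n_long_episodes,
                    "rule1_direction": "as_printed",
                    "pct_missing": m.pct_missing,
                }
            )

        # daily HRV / activity summaries (null predictors)
        for d, day in enumerate(days):
            hrv_rows.append(
                {
                    "participant_id": pid,
                    "date": day,
                    "mean_sdnn": max(rng.normal(sdnn_pm[i], cfg.sdnn_sd_day), 5.0),
                    "mean_rmssd": max(rng.normal(rmssd_pm[i], cfg.rmssd_sd_day), 1.0),
                    "mean_hf": float(np.exp(rng.normal(hf_logpm[i], cfg.hf_log_sd_day))),
                    "mean_lf_hf": max(rng.normal(lf_hf_pm[i], cfg.lf_hf_sd_day), 0.1),
                    "n_valid_windows": int(rng.integers(150, 280)),
                }
            )
            act_rows.append(
                {
                    "participant_id": pid,
                    "date": day,
                    "steps": int(np.exp(rng.normal(steps_logpm[i], cfg.steps_log_sd_day))),
                    "light_min": int(max(rng.normal(light_pm[i], cfg.light_sd_day), 0)),
                    "moderate_min": int(max(rng.normal(moderate_pm[i], cfg.moderate_sd_day), 0)),
                    "intense_min": int(max(rng.normal(intense_pm[i], cfg.intense_sd_day), 0)),
                    "longest_inactive_run": np.nan,  # defined by minute stream
                    "worn_minutes": 1440,
                }
            )

        # symptoms: coupled to the scored nightly sleep
        sfi_hist: list[float] = []
        se_hist: list[float] = []
        if cfg.centering == "true_mean":
            all_sfi = [m.sfi * 100 for m in metrics.values() if m.valid]
            all_se = [m.se for m in metrics.values() if m.valid]
            sfi_true_mean = float(np.mean(all_sfi)) if all_sfi else 0.0
            se_true_mean = float(np.mean(all_se)) if all_se else 0.0
        for d, day in enumerate(days):
            night = day - timedelta(days=1) if cfg.coupling == "previous_night" else day
            m = metrics.get(night)
            if m is not None and m.valid:
                x_sfi = m.sfi * 100.0
                x_se = m.se
                if cfg.centering == "expanding":
                    sfi_hist.append(x_sfi)
                    se_hist.append(x_se)
                    sfi_c = x_sfi - float(np.mean(sfi_hist))
                    se_c = x_se - float(np.mean(se_hist))
                else:
                    sfi_c = x_sfi - sfi_true_mean
                    se_c = x_se - se_true_mean
            else:
                sfi_c = 0.0
                se_c = 0.0
            eta = alpha[i] + cfg.beta_sfi * sfi_c + cfg.beta_se * se_c
            p = float(expit(eta))
            y = int(rng.random() < p)
            if cfg.coder_flip_prob > 0 and rng.random() < cfg.coder_flip_prob:
                y = 1 - y
            script = sym.build_script(day, rng)
            if y:
                second = int(rng.random() < 0.3)
                endors = [1, second]
                rng.shuffle(endors)
            else:
                endors = [0, 0]
            survey_rows.append(
                {
                    "participant_id": pid,
                    "date": day,
                    "greeting_item_id": script.greeting_item_id,
                    "phq_item_ids": f"{script.phq_item_ids[0]};{script.phq_item_ids[1]}",
                    "endorsements": f"{endors[0]};{endors[1]}",
                    "symptom_binary": float(y),
                }
            )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "date": day,
                    "sfi100_c": sfi_c,
                    "se_c": se_c,
                    "p": p,
                    "y": y,
                    "alpha": alpha[i],
                }
            )

    cohort = Cohort(
        config=cfg,
        profiles=profiles,
        surveys=pd.DataFrame(survey_rows),
        sleep_nights=pd.DataFrame(sleep_rows),
        hrv_daily=pd.DataFrame(hrv_rows),
        activity_daily=pd.DataFrame(act_rows),
        night_runs=night_runs,
        truth=pd.DataFrame(truth_rows),
    )
    if render_minutes:
        cohort.minutes = _render_minutes(cohort, rng, hr_mean)
        # longest inactive run is defined by the rendered stream
        from .activity import aggregate_all

        agg = aggregate_all(cohort.minutes)
        cohort.activity_daily = agg
    return cohort


# ---------------------------------------------------------------------------
# minute rendering
# ---------------------------------------------------------------------------


def _render_minutes(
    cohort: Cohort, rng: np.random.Generator, hr_mean: np.ndarray
) -> pd.DataFrame:
    """Render minute-level streams consistent with the day-level tables."""
    cfg = cohort.config
    frames = []
    act = cohort.activity_daily.set_index(["participant_id", "date"])
    for i, prow in cohort.profiles.iterrows():
        pid = prow["participant_id"]
        nd = cfg.days_for(i)
        # stream starts the morning the device is installed (6 AM of the
        # day before the first survey day), so even a reversed-cycle
        # sleeper's first window is fully covered
        t0 = datetime.combine(cfg.start_date - timedelta(days=1), time(6, 0))
        n_min = 18 * 60 + nd * 1440
        ts = pd.date_range(t0, periods=n_min, freq="min")

        sleep_class = np.full(n_min, AWAKE, dtype=np.int8)
        for d in range(-1, nd - 1):
            night_date = cfg.start_date + timedelta(days=d)
            runs = cohort.night_runs[(pid, night_date)]
            start, _ = sleepmod.window_bounds(night_date, bool(prow["reversed_cycle"]))
            offset = int((start - t0).total_seconds() // 60)
            seq = sleepmod.decode_runs(runs)
            if offset < 0:  # reversed-cycle window predates the stream
                seq = seq[-offset:]
                offset = 0
            end = min(offset + len(seq), n_min)
            sleep_class[offset:end] = seq[: end - offset]

        minute_of_day = (np.arange(n_min) + 6 * 60) % 1440
        hour = minute_of_day / 60.0
        hr = (
            hr_mean[i]
            + cfg.hr_amplitude * np.cos(2 * np.pi * (hour - 14.0) / 24.0)
            - cfg.hr_night_dip * (sleep_class == ASLEEP)
            + rng.normal(0, cfg.hr_noise_sd, n_min)
        )
        hr = np.clip(hr, *cfg.hr_clip)

        # steps: one bout per daytime 2-hour slot, plus brief steps in
        # nocturnal awakenings (getting out of bed registers on the sensor)
        steps = np.zeros(n_min, dtype=np.int64)
        slots = [(7, 9), (9, 11), (11, 13), (13, 15), (15, 17), (17, 19), (19, 21)]
        for d in range(-1, nd):  # the install day gets daytime bouts too
            day = cfg.start_date + timedelta(days=d)
            base = 18 * 60 + d * 1440  # minute index of 00:00 of day d
            try:
                total = int(act.loc[(pid, day), "steps"])
            except KeyError:
                total = 2000
            share = rng.dirichlet(np.full(len(slots), 1.5))
            for (h0, h1), frac in zip(slots, share):
                bout_len = int(rng.integers(10, 31))
                start_min = base + int(rng.integers(h0 * 60, h1 * 60 - bout_len))
                per_min = max(int(round(total * frac / bout_len)), 1)
                steps[start_min : start_min + bout_len] += per_min
        steps[sleep_class == ASLEEP] = 0
        # nocturnal awakenings: a few steps at the start of each wake bout
        awake_after_sleep = np.flatnonzero(
            (sleep_class[1:] == AWAKE) & (sleep_class[:-1] == ASLEEP)
        )
        for j in awake_after_sleep:
            steps[j + 1] += int(rng.integers(5, 30))

        intensity = np.where(
            sleep_class == ASLEEP,
            "sedentary",
            np.where(
                steps == 0,
                "sedentary",
                np.where(steps < 40, "light", np.where(steps < 90, "moderate", "intense")),
            ),
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "timestamp": ts,
                    "heart_rate": np.round(hr, 1),
                    "sleep_class": np.array(
                        [sleepmod.CLASS_LABELS[c] for c in sleep_class], dtype=object
                    ),
                    "steps": steps.astype(float),
                    "intensity": intensity,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def apply_missingness(
    cohort: Cohort,
    rates: dict | None = None,
    seed: int | None = None,
    exact: bool = False,
) -> Cohort:
    """Apply day-level missing-completely-at-random gaps per domain.

    Domains: ``survey`` (no chatbot response that day), ``sleep`` (the
    night ending that morning unusable), ``hrv`` (no usable heart-rate
    windows that day), ``steps`` (no activity record).  With
    ``exact=True``, exactly ``round(rate * n_days_total)`` participant-days
    are masked per domain (sampled without replacement), so the realized
    proportion equals the configured rate by construction.
    """
    cfg = cohort.config
    rates = dict(cfg.missing_rates if rates is None else rates)
    for k, v in rates.items():
        if k not in MISSING_DOMAINS:
            raise ValueError(f"unknown missingness domain {k!r}")
        if not 0 <= v <= 1:
            raise ValueError(f"missing rate for {k!r} outside [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1_000_003 if seed is None else seed)

    slots = [
        (prow["participant_id"], cfg.start_date + timedelta(days=d))
        for i, prow in cohort.profiles.iterrows()
        for d in range(cfg.days_for(i))
    ]
    n_slots = len(slots)
    masks: dict[str, set] = {}
    for dom in MISSING_DOMAINS:
        r = rates.get(dom, 0.0)
        if r <= 0:
            masks[dom] = set()
        elif exact:
            k = int(round(r * n_slots))
            idx = rng.choice(n_slots, size=k, replace=False)
            masks[dom] = {slots[j] for j in idx}
        else:
            draw = rng.random(n_slots) < r
            masks[dom] = {s for s, m in zip(slots, draw) if m}

    out = Cohort(
        config=cfg,
        profiles=cohort.profiles.copy(),
        surveys=cohort.surveys.copy(),
        sleep_nights=cohort.sleep_nights.copy(),
        hrv_daily=cohort.hrv_daily.copy(),
        activity_daily=cohort.activity_daily.copy(),
        minutes=None if cohort.minutes is None else cohort.minutes.copy(),
        night_runs=cohort.night_runs,
        truth=cohort.truth,
    )

    if masks["survey"]:
        key = list(zip(out.surveys["participant_id"], out.surveys["date"]))
        hit = np.array([k in masks["survey"] for k in key])
        out.surveys.loc[hit, "endorsements"] = ""
        out.surveys.loc[hit, "symptom_binary"] = np.nan

    if masks["sleep"] and len(out.sleep_nights):
        # a day missing sleep = the night ending that morning is unusable
        nights = {(p, d - timedelta(days=1)) for p, d in masks["sleep"]}
        key = list(zip(out.sleep_nights["participant_id"], out.sleep_nights["night_date"]))
        hit = np.array([k in nights for k in key])
        out.sleep_nights.loc[hit, ["tst", "sfi", "se", "time_in_bed", "pct_missing"]] = np.nan
        out.sleep_nights.loc[hit, "valid"] = False

    if masks["hrv"] and len(out.hrv_daily):
        key = list(zip(out.hrv_daily["participant_id"], out.hrv_daily["date"]))
        hit = np.array([k in masks["hrv"] for k in key])
        out.hrv_daily = out.hrv_daily.loc[~hit].reset_index(drop=True)

    if masks["steps"] and len(out.activity_daily):
        key = list(zip(out.activity_daily["participant_id"], out.activity_daily["date"]))
        hit = np.array([k in masks["steps"] for k in key])
        out.activity_daily = out.activity_daily.loc[~hit].reset_index(drop=True)

    if out.minutes is not None:
        mins = out.minutes
        day = mins["timestamp"].dt.date
        pid = mins["participant_id"]
        if masks["hrv"]:
            hit = pd.Series(list(zip(pid, day)), index=mins.index).isin(masks["hrv"])
            mins.loc[hit, "heart_rate"] = np.nan
        if masks["steps"]:
            hit = pd.Series(list(zip(pid, day)), index=mins.index).isin(masks["steps"])
            mins.loc[hit, "steps"] = np.nan
            mins.loc[hit, "intensity"] = np.nan
        if masks["sleep"]:
            rev = dict(
                zip(out.profiles["participant_id"], out.profiles["reversed_cycle"])
            )
            ts = mins["timestamp"]
            blank = np.zeros(len(mins), dtype=bool)
            for p, d in masks["sleep"]:
                night = d - timedelta(days=1)
                start, end = sleepmod.window_bounds(night, bool(rev.get(p, False)))
                blank |= ((pid == p) & (ts >= start) & (ts < end)).to_numpy()
            mins.loc[blank, "sleep_class"] = np.nan
    return out


def simulate(cfg: SimulationConfig, render_minutes: bool = False) -> Cohort:
    """Generate a cohort and apply the configured missingness."""
    return apply_missingness(generate_cohort(cfg, render_minutes=render_minutes))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def cohort_summary(cohort: Cohort) -> dict:
    """Day counts and realized per-domain missing-day proportions."""
    cfg = cohort.config
    n_days_total = sum(cfg.days_for(i) for i in range(cfg.n_participants))
    mean_days = round(n_days_total / cfg.n_participants, 2)
    out = {
        "n_participants": cfg.n_participants,
        "n_days_total": n_days_total,
        "mean_days_per_participant": mean_days,
    }
    out["missing_survey"] = float(cohort.surveys["symptom_binary"].isna().mean())
    # nights map 1:1 onto days (each day's measure is the night ending that
    # morning), so the invalid-night fraction is the missing-day fraction
    sn = cohort.sleep_nights
    out["missing_sleep"] = float(1.0 - sn["valid"].astype(bool).mean()) if len(sn) else np.nan
    n_hrv_days = len(cohort.hrv_daily)
    out["missing_hrv"] = float(1.0 - n_hrv_days / n_days_total)
    out["missing_steps"] = float(1.0 - len(cohort.activity_daily) / n_days_total)
    return out


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write participants.csv, surveys.csv and (if rendered) minutes.csv.

    Missing values are written as blank cells, never sentinel numbers.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}

    prof = cohort.profiles.copy()
    prof["reversed_cycle"] = prof["reversed_cycle"].astype(bool)
    paths["participants"] = d / "participants.csv"
    prof.to_csv(paths["participants"], index=False)

    sv = cohort.surveys.copy()
    sv["date"] = pd.to_datetime(sv["date"]).dt.strftime("%Y-%m-%d")
    sv["symptom_binary"] = sv["symptom_binary"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    paths["surveys"] = d / "surveys.csv"
    sv.to_csv(paths["surveys"], index=False)

    if cohort.minutes is not None:
        m = cohort.minutes.copy()
        m["timestamp"] = m["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
        m["steps"] = m["steps"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        paths["minutes"] = d / "minutes.csv"
        m.to_csv(paths["minutes"], index=False)
    return paths


def read_minutes(path: str | Path) -> pd.DataFrame:
    """Read a minutes.csv stream into the canonical in-memory form."""
    m = pd.read_csv(
        path,
        dtype={"participant_id": str, "sleep_class": str, "intensity": str},
        keep_default_na=False,
        na_values=[""],
    )
    m["timestamp"] = pd.to_datetime(m["timestamp"], format="%Y-%m-%dT%H:%M")
    m["heart_rate"] = pd.to_numeric(m["heart_rate"], errors="coerce")
    m["steps"] = pd.to_numeric(m["steps"], errors="coerce")
    return m


def read_surveys(path: str | Path) -> pd.DataFrame:
    sv = pd.read_csv(
        path,
        dtype={"participant_id": str, "phq_item_ids": str, "endorsements": str},
        keep_default_na=False,
        na_values=[],
    )
    sv["date"] = pd.to_datetime(sv["date"]).dt.date
    sv["symptom_binary"] = pd.to_numeric(
        sv["symptom_binary"].replace("", np.nan), errors="coerce"
    )
    return sv


def read_participants(path: str | Path) -> pd.DataFrame:
    prof = pd.read_csv(path, dtype={"participant_id": str})
    prof["reversed_cycle"] = prof["reversed_cycle"].astype(bool)
    return prof
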