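"""Day-level analysis table and multilevel models of daily depressive symptoms.

The analysis asks whether within-person deviations in digital biomarkers
(previous-night sleep quality, daily HRV, daily physical activity) predict
the binary daily depressive-symptom report, on the same day and on the next
day.  Each of 11 predictors is fit in its own random-intercept logistic
model (see :mod:`wearlab.glmm`), person-mean-centered at level 1 and
adjusted for grand-mean-centered age, sex, chronic-disease count, and
baseline depression at level 2.  Family-wise error over the 11 tests per
outcome is controlled by Holm-Bonferroni; a fixed 0.005 threshold is also
reported.

Conventions:

* a calendar day's sleep predictors come from the night ending that morning
  (the window that starts at 6 PM the previous evening);
* the first calendar week per participant is excluded (adaptation week), and
  person means for centering are taken over the remaining analysis days;
* the sleep fragmentation index enters the model per 0.01 units (awakenings
  per 100 minutes of sleep), sleep efficiency per percentage point;
* models are available-case: rows missing the predictor or the outcome are
  dropped per model, with no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import fit_random_intercept_logit

#: level-1 digital predictors, in reporting order
PREDICTORS = (
    "lf_hf", "hf", "sdnn", "rmssd",
    "tst", "sfi", "se",
    "steps", "light_min", "moderate_min", "intense_min",
)

#: multiplier taking a predictor from its stored unit to its analysis unit
PREDICTOR_SCALE = {"sfi": 100.0}

COVARIATES = ("age", "sex_w", "n_chronic", "baseline_gds")

OUTCOMES = ("same_day", "next_day")

FIXED_ALPHA = 0.005
FAMILY_ALPHA = 0.05


@dataclass
class ModelResult:
    predictor: str
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    n_obs: int
    n_participants: int
    sigma: float = np.nan
    significant_fixed: bool = False
    significant_holm: bool = False
    message: str = ""


def assemble_table(
    sleep_nights: pd.DataFrame,
    hrv_daily: pd.DataFrame,
    activity_daily: pd.DataFrame,
    surveys: pd.DataFrame,
    profiles: pd.DataFrame,
    skip_week1: bool = True,
) -> pd.DataFrame:
    """Build the analysis-ready day-level table.

    One row per participant-day, with the symptom binary, next-day symptom,
    raw and person-mean-centered predictors (``*_c``), and grand-mean-
    centered level-2 covariates (``*_gmc``).  Rows with a missing same-day
    outcome are retained (they still contribute predictors to lagged use).
    """
    sv = surveys[["participant_id", "date", "symptom_binary"]].copy()
    sv["date"] = pd.to_datetime(sv["date"]).dt.date
    if sv.duplicated(["participant_id", "date"]).any():
        raise ValueError("duplicate participant-date keys in surveys")

    frames = {"symptom": sv.set_index(["participant_id", "date"])}

    if len(sleep_nights):
        s = sleep_nights.copy()
        s.loc[~s["valid"].astype(bool), ["tst", "sfi", "se"]] = np.nan
        s["date"] = pd.to_datetime(s["night_date"]).dt.date + timedelta(days=1)
        s = s[["participant_id", "date", "tst", "sfi", "se"]]
        if s.duplicated(["participant_id", "date"]).any():
            raise ValueError("duplicate participant-date keys in sleep_nights")
        frames["sleep"] = s.set_index(["participant_id", "date"])

    if len(hrv_daily):
        h = hrv_daily.rename(
            columns={
                "mean_lf_hf": "lf_hf", "mean_hf": "hf",
                "mean_sdnn": "sdnn", "mean_rmssd": "rmssd",
            }
        ).copy()
        h["date"] = pd.to_datetime(h["date"]).dt.date
        h = h[["participant_id", "date", "lf_hf", "hf", "sdnn", "rmssd"]]
        if h.duplicated(["participant_id", "date"]).any():
            raise ValueError("duplicate participant-date keys in hrv_daily")
        frames["hrv"] = h.set_index(["participant_id", "date"])

    if len(activity_daily):
        a = activity_daily.copy()
        a["date"] = pd.to_datetime(a["date"]).dt.date
        a = a[["participant_id", "date", "steps", "light_min", "moderate_min", "intense_min"]]
        if a.duplicated(["participant_id", "date"]).any():
            raise ValueError("duplicate participant-date keys in activity_daily")
        frames["activity"] = a.set_index(["participant_id", "date"])

    # continuous day grid per participant, spanning every observed date
    grids = []
    all_dates = pd.concat(
        [f.reset_index()[["participant_id", "date"]] for f in frames.values()]
    )
    for pid, sub in all_dates.groupby("participant_id"):
        d0, d1 = sub["date"].min(), sub["date"].max()
        days = pd.date_range(d0, d1, freq="D").date
        grids.append(pd.DataFrame({"participant_id": pid, "date": days}))
    rows = pd.concat(grids, ignore_index=True).set_index(["participant_id", "date"])

    for f in frames.values():
        rows = rows.join(f, how="left")
    rows = rows.reset_index()
    for col in PREDICTORS:
        if col not in rows.columns:
            rows[col] = np.nan

    # next-day outcome: the following calendar day's symptom binary
    rows = rows.sort_values(["participant_id", "date"]).reset_index(drop=True)
    rows["symptom_next_day"] = rows.groupby("participant_id")["symptom_binary"].shift(-1)

    if skip_week1:
        # week 1 is anchored to the first survey day (study day 1)
        first_survey = sv.groupby("participant_id")["date"].min()
        first = rows["participant_id"].map(first_survey)
        keep = np.array(
            [pd.notna(f) and (d - f).days >= 7 for d, f in zip(rows["date"], first)]
        )
        rows = rows[keep].reset_index(drop=True)

    # person-mean centering over the analysis days
    for col in PREDICTORS:
        pm = rows.groupby("participant_id")[col].transform("mean")
        rows[f"{col}_c"] = rows[col] - pm

    # grand-mean-centered level-2 covariates (mean over participants)
    prof = profiles.set_index("participant_id")
    cov = pd.DataFrame(index=prof.index)
    cov["age"] = prof["age"].astype(float)
    cov["sex_w"] = (prof["sex"] == "woman").astype(float)
    cov["n_chronic"] = prof["n_chronic"].astype(float)
    cov["baseline_gds"] = prof["baseline_gds"].astype(float)
    present = rows["participant_id"].unique()
    cov = cov.loc[[p for p in cov.index if p in set(present)]]
    for c in COVARIATES:
        rows[f"{c}_gmc"] = rows["participant_id"].map(cov[c] - cov[c].mean())

    return rows


def fit_daily_model(
    rows: pd.DataFrame,
    predictor: str,
    outcome_kind: str = "same_day",
    n_quad: int = 10,
) -> ModelResult:
    """Fit one random-intercept logistic model for one predictor.

    The single level-1 predictor is the person-mean-centered daily value (on
    its analysis scale); the four level-2 covariates are always included.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    if outcome_kind not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome_kind!r}")
    ycol = "symptom_binary" if outcome_kind == "same_day" else "symptom_next_day"
    scale = PREDICTOR_SCALE.get(predictor, 1.0)

    cols = [f"{predictor}_c", ycol] + [f"{c}_gmc" for c in COVARIATES]
    d = rows[["participant_id"] + cols].dropna()
    counts = d.groupby("participant_id").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 participants with 2+ usable days")
    x = d[f"{predictor}_c"].to_numpy() * scale
    if np.std(x) == 0:
        raise ValueError("degenerate predictor")
    X = np.column_stack(
        [np.ones(len(d)), x] + [d[f"{c}_gmc"].to_numpy() for c in COVARIATES]
    )
    y = d[ycol].to_numpy(dtype=float)
    fit = fit_random_intercept_logit(X, y, d["participant_id"].to_numpy(), n_quad=n_quad)
    if fit.converged:
        b, lo, hi, p = fit.wald(1)
        with np.errstate(over="ignore"):  # a huge CI bound becomes inf
            ci_low, ci_high = float(np.exp(lo)), float(np.exp(hi))
        return ModelResult(
            predictor=predictor,
            outcome=outcome_kind,
            odds_ratio=float(np.exp(b)),
            ci_low=ci_low,
            ci_high=ci_high,
            p_value=float(p),
            converged=True,
            n_obs=fit.n_obs,
            n_participants=fit.n_groups,
            sigma=fit.sigma,
            significant_fixed=bool(p < FIXED_ALPHA),
        )
    return ModelResult(
        predictor=predictor,
        outcome=outcome_kind,
        odds_ratio=np.nan,
        ci_low=np.nan,
        ci_high=np.nan,
        p_value=np.nan,
        converged=False,
        n_obs=fit.n_obs,
        n_participants=fit.n_groups,
        sigma=fit.sigma,
        message="separation" if fit.separation else fit.message,
    )


def holm_bonferroni(p_values, alpha: float = FAMILY_ALPHA, m: int | None = None) -> np.ndarray:
    """Holm step-down rejection flags for a family of p-values.

    The smallest p-value is compared with ``alpha/m``, the next with
    ``alpha/(m-1)``, and so on, stopping at the first failure, so rejections
    are monotone (rejecting p(i) implies rejecting all smaller p-values).
    ``m`` defaults to the number of finite p-values but may be set larger
    (a family with tests reported elsewhere).  NaN entries are never
    rejected and do not count toward the family size.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = int(ok.sum())
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("family size m cannot be smaller than the number of tests")
    flags = np.zeros(p.size, dtype=bool)
    order = np.argsort(p[ok], kind="stable")
    idx = np.flatnonzero(ok)[order]
    for rank, j in enumerate(idx):
        if p[j] < alpha / (m - rank):
            flags[j] = True
        else:
            break
    return flags


def run_model_battery(rows: pd.DataFrame, n_quad: int = 10) -> pd.DataFrame:
    """All 22 models (11 predictors x 2 outcomes) with multiplicity flags.

    Holm-Bonferroni is applied within each outcome family of 11 tests at
    family alpha 0.05; ``significant_fixed`` additionally flags p < 0.005.
    Returns the ``model_results`` table.
    """
    results: list[ModelResult] = []
    for outcome in OUTCOMES:
        family: list[ModelResult] = []
        for pred in PREDICTORS:
            try:
                family.append(fit_daily_model(rows, pred, outcome, n_quad=n_quad))
            except ValueError as e:
                family.append(
                    ModelResult(
                        predictor=pred, outcome=outcome, odds_ratio=np.nan,
                        ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                        converged=False, n_obs=0, n_participants=0,
                        message=str(e),
                    )
                )
        flags = holm_bonferroni([m.p_value for m in family], FAMILY_ALPHA)
        for m, f in zip(family, flags):
            m.significant_holm = bool(f)
        results.extend(family)
    return pd.DataFrame(
        {
            "predictor": [m.predictor for m in results],
            "outcome": [m.outcome for m in results],
            "odds_ratio": [m.odds_ratio for m in results],
            "ci_low": [m.ci_low for m in results],
            "ci_high": [m.ci_high for m in results],
            "p_value": [m.p_value for m in results],
            "converged": [m.converged for m in results],
            "n_obs": [m.n_obs for m in results],
            "n_participants": [m.n_participants for m in results],
            "sigma": [m.sigma for m in results],
            "significant_fixed": [m.significant_fixed for m in results],
            "significant_holm": [m.significant_holm for m in results],
            "message": [m.message for m in results],
        }
    )


def person_mean_correlations(
    rows: pd.DataFrame, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among person-level means, pairwise complete.

    Variables: baseline depression (GDS), the person mean of daily symptoms,
    and person means of the 11 digital predictors.  Returns (r, p) frames;
    cells with fewer than 3 complete persons are NaN.
    """
    pm = rows.groupby("participant_id")[list(PREDICTORS) + ["symptom_binary"]].mean()
    pm = pm.rename(columns={"symptom_binary": "symptom_pm"})
    prof = profiles.set_index("participant_id")
    pm["baseline_gds"] = prof["baseline_gds"].astype(float)
    variables = ["baseline_gds", "symptom_pm"] + list(PREDICTORS)
    r = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((len(variables), len(variables))), index=variables, columns=variables)
    np.fill_diagonal(p.values, np.nan)
    for a, b in combinations(variables, 2):
        sub = pm[[a, b]].dropna()
        if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# pre/post and descriptive statistics
# ---------------------------------------------------------------------------


def _signrank_quantile(n: int, alpha: float) -> int:
    """Largest k with P(W+ <= k) <= alpha/2 under the null signed-rank
    distribution for n untied nonzero pairs (exact, by convolution)."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    cdf = np.cumsum(counts) / counts.sum()
    k = int(np.searchsorted(cdf, alpha / 2, side="right")) - 1
    return max(k, -1)


def wilcoxon_prepost(pre, post, level: float = 0.95) -> dict:
    """Wilcoxon signed-rank test of post - pre with a Hodges-Lehmann CI.

    Zero differences are dropped (Wilcoxon's convention); the test is exact
    for n <= 25 when there are no tied ranks, otherwise a normal
    approximation is used.  The CI endpoints come from Walsh averages and
    exact signed-rank critical values.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return {
            "test": "wilcoxon", "statistic": np.nan, "p": np.nan,
            "median_difference": 0.0, "ci_low": np.nan, "ci_high": np.nan,
            "n": 0, "note": "all differences zero: test undefined",
        }
    res = stats.wilcoxon(nz, method="auto")
    walsh = np.sort([(a + b) / 2 for i, a in enumerate(nz) for b in nz[i:]])
    k = _signrank_quantile(n, 1 - level)
    if k >= 0:
        lo, hi = walsh[k], walsh[len(walsh) - k - 1]
    else:  # n too small for the requested level: widest interval
        lo, hi = walsh[0], walsh[-1]
    return {
        "test": "wilcoxon",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_difference": float(np.median(d)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": int(n),
        "note": "",
    }


def paired_t_prepost(pre, post, level: float = 0.95) -> dict:
    """Paired t test of post - pre with the usual mean-difference CI."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    keep = np.isfinite(pre) & np.isfinite(post)
    d = post[keep] - pre[keep]
    n = d.size
    if np.all(d == 0):  # identical pre/post: no evidence of change
        tstat, pval = 0.0, 1.0
    else:
        res = stats.ttest_rel(post[keep], pre[keep])
        tstat, pval = float(res.statistic), float(res.pvalue)
    sem = d.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1) if n > 1 else np.nan
    return {
        "test": "paired_t",
        "statistic": tstat,
        "p": pval,
        "mean_difference": float(d.mean()),
        "ci_low": float(d.mean() - tcrit * sem),
        "ci_high": float(d.mean() + tcrit * sem),
        "df": int(n - 1),
        "n": int(n),
    }


OLDEST_CUTOFF_YEARS = 75  # "> 75" is the oldest group


def pre_post_tests(profiles: pd.DataFrame) -> dict:
    """Pre/post living-lab comparisons.

    Wilcoxon signed-rank for depression (GDS) and sleep quality (PSQI),
    paired t for usability (SUS), and a 2x2 mixed ANOVA (time x age group,
    oldest > 75 years vs 65-74) for SUS age moderation.
    """
    import pingouin as pg

    out = {
        "gds": wilcoxon_prepost(profiles["baseline_gds"], profiles["gds_post"]),
        "psqi": wilcoxon_prepost(profiles["baseline_psqi"], profiles["psqi_post"]),
        "sus": paired_t_prepost(profiles["sus_pre"], profiles["sus_post"]),
    }
    keep = profiles[["sus_pre", "sus_post", "age"]].dropna()
    if len(keep) >= 4 and keep["age"].gt(OLDEST_CUTOFF_YEARS).nunique() == 2:
        long = pd.DataFrame(
            {
                "subject": np.repeat(keep.index.to_numpy(), 2),
                "time": ["pre", "post"] * len(keep),
                "sus": np.column_stack([keep["sus_pre"], keep["sus_post"]]).ravel(),
                "age_group": np.repeat(
                    np.where(keep["age"] > OLDEST_CUTOFF_YEARS, "oldest", "younger"), 2
                ),
            }
        )
        aov = pg.mixed_anova(
            data=long, dv="sus", within="time", between="age_group", subject="subject"
        )
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
        out["sus_age_moderation"] = {
            "test": "mixed_anova_interaction",
            "F": float(inter["F"]),
            "df1": int(inter["DF1"]),
            "df2": int(inter["DF2"]),
            "p": float(inter[pcol]),
        }
    else:
        out["sus_age_moderation"] = {
            "test": "mixed_anova_interaction",
            "F": np.nan, "df1": 0, "df2": 0, "p": np.nan,
        }
    return out


GDS_RISK_CUTOFF = 5  # GDS >= 5: at risk for (mild) depression


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test (odds ratio, p) for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res[0]), float(res[1])


def descriptive_table(profiles: pd.DataFrame, rows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Baseline-depression group comparison (GDS >= 5 vs < 5).

    Continuous variables use Welch t tests; categorical variables use
    chi-square tests, falling back to Fisher's exact test for 2x2 tables
    with any expected cell below 5.
    """
    grp = profiles["baseline_gds"].astype(float) >= GDS_RISK_CUTOFF
    recs = []

    continuous = {"age": profiles["age"].astype(float)}
    for c in ("baseline_psqi", "sus_pre"):
        if c in profiles:
            continuous[c] = profiles[c].astype(float)
    if rows is not None and len(rows):
        pm = rows.groupby("participant_id")[list(PREDICTORS) + ["symptom_binary"]].mean()
        joined = profiles.set_index("participant_id").join(pm)
        grp_j = joined["baseline_gds"].astype(float) >= GDS_RISK_CUTOFF
        for c in list(PREDICTORS) + ["symptom_binary"]:
            continuous[f"person_mean_{c}"] = joined[c]
        grp_for = {f"person_mean_{c}": grp_j for c in list(PREDICTORS) + ["symptom_binary"]}
    else:
        grp_for = {}

    for name, vals in continuous.items():
        g = grp_for.get(name, grp)
        a = vals[~g].dropna()
        b = vals[g].dropna()
        if len(a) < 2 or len(b) < 2:
            recs.append({"variable": name, "test": "t", "statistic": np.nan, "p": np.nan})
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        recs.append(
            {
                "variable": name, "test": "t",
                "statistic": float(res.statistic), "p": float(res.pvalue),
                "mean_no": float(a.mean()), "mean_yes": float(b.mean()),
            }
        )

    for name in ("sex", "education", "income_band"):
        if name not in profiles:
            continue
        tab = pd.crosstab(profiles[name], grp)
        if tab.shape[1] < 2 or tab.shape[0] < 2:
            recs.append({"variable": name, "test": "chi2", "statistic": np.nan, "p": np.nan})
            continue
        expected = stats.contingency.expected_freq(tab.to_numpy())
        if tab.shape == (2, 2) and (expected < 5).any():
            orat, pval = fisher_exact_2x2(tab.to_numpy())
            recs.append(
                {"variable": name, "test": "fisher", "statistic": orat, "p": pval}
            )
        else:
            chi2 = stats.chi2_contingency(tab.to_numpy(), correction=False)
            recs.append(
                {"variable": name, "test": "chi2",
                 "statistic": float(chi2.statistic), "p": float(chi2.pvalue)}
            )
    return pd.DataFrame(recs)
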