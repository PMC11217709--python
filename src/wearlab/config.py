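"""Simulation and pipeline run configuration.

All generator defaults encode the study conditions of the 6-week living
lab the package models: 25 community-dwelling older adults observed for
about 33 days each, daily symptom prevalence near 0.37, nightly sleep with
roughly 480 minutes in bed at 66% efficiency and ~6 awakenings, and
day-level missingness at the observed per-domain rates (23% survey, 33.3%
HRV, 54.5% sleep, 36.9% steps).  Distributional forms for the sensor
streams are artifact choices (the source tables report only means and SDs);
they are documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import yaml

#: same-day within-person odds ratios the default coupling reproduces
DEFAULT_OR_SFI = 2.066  # per 0.01 SFI (one awakening per 100 min of sleep)
DEFAULT_OR_SE = 0.972  # per percentage point of sleep efficiency

DEFAULT_MISSING_RATES = {
    "survey": 0.23,
    "hrv": 0.333,
    "sleep": 0.545,
    "steps": 0.369,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic living-lab cohort generator."""

    n_participants: int = 25
    n_days: int = 33
    seed: int = 0
    start_date: date = date(2022, 9, 5)
    #: optional per-participant day counts (overrides ``n_days``)
    day_counts: list[int] | None = None

    # --- symptom-generating model -------------------------------------
    #: true within-person log-odds per analysis unit of the predictor
    beta_sfi: float = float(np.log(DEFAULT_OR_SFI))
    beta_se: float = float(np.log(DEFAULT_OR_SE))
    #: day-level symptom prevalence the person intercepts are calibrated to
    prevalence: float = 0.37
    #: SD of the person-level random intercept (logit scale)
    sigma_person: float = 1.0
    #: correlation loading of the intercept on standardized baseline GDS
    gds_loading: float = 0.4
    #: loading of the intercept on the person's sleep-fragmentation factor
    #: (persons who wake more often are more depressed on average, giving
    #: the between-person symptom/sleep-quality correlation)
    sleep_person_loading: float = 0.35
    #: which night drives the day's symptom: the night ending that morning
    #: ("previous_night") or the night starting that evening ("same_night")
    coupling: str = "previous_night"
    #: within-person centering used when generating symptoms: the expanding
    #: mean of days observed so far, or the person's true (full-sample) mean
    centering: str = "expanding"
    #: probability a coded day is flipped (coder noise; 0 disables)
    coder_flip_prob: float = 0.0

    # --- nightly sleep construction -----------------------------------
    bed_onset_mean: float = 240.0  # minutes after 6 PM (10 PM)
    bed_onset_sd_person: float = 40.0
    bed_onset_sd_night: float = 25.0
    tib_mean: float = 485.0  # minutes in bed
    tib_sd_person: float = 45.0
    tib_sd_night: float = 40.0
    tib_min: float = 120.0
    awakenings_mean: float = 6.5  # person-level Poisson rate of awakenings
    awakenings_sigma: float = 0.30  # lognormal spread of the person rate
    awake_bout_mu: float = 3.0  # ln-minutes; median bout ~20 min
    awake_bout_sigma: float = 0.5
    #: number of participants with a reversed day/night cycle
    n_reversed_cycle: int = 1

    # --- circadian heart rate (minute rendering) ----------------------
    hr_mean: float = 72.0
    hr_mean_sd_person: float = 5.0
    hr_amplitude: float = 5.0  # circadian sinusoid, bpm
    hr_night_dip: float = 8.0  # additional drop while asleep, bpm
    hr_noise_sd: float = 2.5
    hr_clip: tuple[float, float] = (40.0, 120.0)

    # --- daily HRV summaries (day-level mode) -------------------------
    lf_hf_mean: float = 5.94
    lf_hf_sd_person: float = 1.33
    lf_hf_sd_day: float = 0.8
    hf_log_mean: float = 3.0  # ln ms^2; person median ~20, mean ~26
    hf_log_sd_person: float = 0.8
    hf_log_sd_day: float = 0.3
    sdnn_mean: float = 103.0
    sdnn_sd_person: float = 41.9
    sdnn_sd_day: float = 15.0
    rmssd_mean: float = 9.32
    rmssd_sd_person: float = 3.87
    rmssd_sd_day: float = 2.0

    # --- daily physical activity --------------------------------------
    steps_log_median: float = 7.6  # ln steps; person median ~2000, mean ~3200
    steps_log_sd_person: float = 0.9
    steps_log_sd_day: float = 0.4
    light_mean: float = 130.0
    light_sd_person: float = 100.0
    light_sd_day: float = 25.0
    moderate_mean: float = 14.0
    moderate_sd_person: float = 19.0
    moderate_sd_day: float = 5.0
    intense_mean: float = 22.0
    intense_sd_person: float = 28.0
    intense_sd_day: float = 6.0

    # --- day-level missingness ----------------------------------------
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.n_days < 8:
            raise ValueError("n_days must be >= 8")
        if self.day_counts is not None:
            if len(self.day_counts) != self.n_participants:
                raise ValueError("day_counts length must equal n_participants")
            if min(self.day_counts) < 8:
                raise ValueError("every day count must be >= 8")
        for k, v in self.missing_rates.items():
            if k not in DEFAULT_MISSING_RATES:
                raise ValueError(f"unknown missingness domain {k!r}")
            if not 0 <= v <= 1:
                raise ValueError(f"missing rate for {k!r} outside [0, 1]")
        if self.gds_loading**2 + self.sleep_person_loading**2 > 1:
            raise ValueError("intercept loadings exceed unit variance")
        if self.coupling not in ("previous_night", "same_night"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.centering not in ("expanding", "true_mean"):
            raise ValueError(f"unknown centering {self.centering!r}")
        if isinstance(self.start_date, str):
            self.start_date = date.fromisoformat(self.start_date)

    def days_for(self, i: int) -> int:
        return self.day_counts[i] if self.day_counts is not None else self.n_days

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        d["hr_clip"] = list(self.hr_clip)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "hr_clip" in d:
            d["hr_clip"] = tuple(d["hr_clip"])
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration."""

    out_dir: str = "wearlab_run"
    input_dir: str | None = None  # read cohort CSVs from here; None = simulate
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    rule1_direction: str = "as_printed"
    skip_week1: bool = True
    n_quad: int = 10
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "sleep", "hrv", "activity", "symptoms", "feedback", "analyze",
        ]
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
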