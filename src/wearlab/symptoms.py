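"""Daily chatbot survey assembly and depressive-symptom day coding.

Each morning the chatbot asks one randomly chosen greeting item and two
randomly chosen (distinct) items from an 8-item depression pool — the
9-item Patient Health Questionnaire with the suicidality item removed.  A
day is coded symptomatic (1) if the participant endorses at least one asked
depression item, 0 if none, and missing if no response was recorded (never
coerced to 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

#: depression item pool (suicidality item excluded)
PHQ_ITEMS: dict[int, str] = {
    1: "Do you feel down, depressed, or hopeless today?",
    2: "Do you feel little interest or pleasure in doing things today?",
    3: "Have you had trouble falling or staying asleep, or sleeping too much today?",
    4: "Are you feeling tired or having little energy today?",
    5: "Have you experienced poor appetite or overeating today?",
    6: "Do you experience trouble concentrating on things today?",
    7: "Are you feeling bad about yourself or that you are a failure or have let yourself or your family down?",
    8: "Are you moving or speaking so slowly that other people could have noticed?",
}

GREETING_ITEMS: dict[int, str] = {
    1: "Did you sleep well last night?",
    2: "Have you eaten your meal?",
    3: "How are you feeling? Are you feeling pain in any part of your body?",
    4: "What are you planning to do today?",
    5: "Do you need to go to the hospital today?",
}


@dataclass(frozen=True)
class SurveyScript:
    """One day's chatbot script: a greeting plus two depression items."""

    date: date
    greeting_item_id: int
    phq_item_ids: tuple[int, int]

    def __post_init__(self):
        if self.greeting_item_id not in GREETING_ITEMS:
            raise ValueError(f"unknown greeting item {self.greeting_item_id}")
        a, b = self.phq_item_ids
        if a == b or a not in PHQ_ITEMS or b not in PHQ_ITEMS:
            raise ValueError(f"invalid depression item pair {self.phq_item_ids}")


def build_script(day: date, rng: np.random.Generator) -> SurveyScript:
    """Draw one greeting and two distinct depression items, uniformly."""
    greeting = int(rng.integers(1, len(GREETING_ITEMS) + 1))
    pair = rng.choice(sorted(PHQ_ITEMS), size=2, replace=False)
    return SurveyScript(day, greeting, (int(pair[0]), int(pair[1])))


def code_day(endorsements) -> float:
    """Symptom binary for one day: max of the 0/1 endorsements.

    Returns NaN (missing) when no responses were recorded.
    """
    vals = [int(v) for v in endorsements if v is not None and not pd.isna(v)]
    if not vals:
        return np.nan
    if any(v not in (0, 1) for v in vals):
        raise ValueError(f"endorsements must be 0/1, got {endorsements!r}")
    return float(max(vals))


def person_mean(symptom_binaries) -> float:
    """Proportion of symptomatic days over non-missing days.

    NaN when the participant has no coded days.
    """
    s = pd.Series(symptom_binaries, dtype=float).dropna()
    if len(s) == 0:
        return np.nan
    return float(s.mean())


def code_surveys(surveys: pd.DataFrame) -> pd.DataFrame:
    """(Re)code ``symptom_binary`` from the endorsement strings.

    ``surveys`` follows the surveys.csv schema: ``endorsements`` is a
    semicolon-separated 0/1 list, blank for an unanswered day.
    """
    out = surveys.copy()
    coded = []
    for v in out["endorsements"]:
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
            coded.append(np.nan)
        else:
            coded.append(code_day([int(x) for x in str(v).split(";")]))
    out["symptom_binary"] = coded
    return out


def person_means(surveys: pd.DataFrame) -> pd.Series:
    """Per-participant proportion of symptomatic days, indexed by id."""
    return surveys.groupby("participant_id")["symptom_binary"].apply(person_mean)
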