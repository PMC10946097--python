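"""Treatment-outcome derivation at the index date.

Three outcomes are compared between difficult and non-difficult-to-treat
groups: virologic suppression (last available HIV RNA < 50 copies/mL, among
persons with a viral load recorded in the past 12 months and not starting
therapy within the past 6 months) and satisfaction with physical and
psychological health (Likert 1-6 dichotomized at >= 5, from the most recent
questionnaire within 24 months). Self-reported missed doses are banded
0 / 1-2 / >=3 for descriptive tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Optional

import pandas as pd

from .records import Person

ADHERENCE_BANDS = ("0", "1-2", ">=3", "missing")


def dichotomize_satisfaction(likert: int) -> bool:
    """Likert 1-6 -> satisfied flag (>= 5 means "satisfied"/"very satisfied")."""
    v = int(likert)
    if not 1 <= v <= 6:
        raise ValueError(f"Likert value {likert!r} outside 1-6")
    return v >= 5


def suppression_outcome(
    person: Person,
    index_date: date,
    art_start_exclusion_days: int = 183,
    vl_window_days: int = 365,
    threshold: float = 50.0,
) -> tuple:
    """(eligible, suppressed-or-None) for the viral-suppression outcome.

    Persons whose first-ever therapy start falls within
    ``art_start_exclusion_days`` before the index date are ineligible.
    Suppression is judged on the last available measurement overall, but only
    for persons with at least one measurement inside the trailing
    ``vl_window_days`` window; otherwise the outcome is missing (None).
    A below-limit result counts as suppressed when its assay limit is at or
    below the threshold. Ties on the last date resolve pessimistically (any
    quantifiable value >= threshold on that day means not suppressed).
    """
    starts = [e.start_date for e in person.episodes]
    if starts:
        first = min(starts)
        if first > index_date or (index_date - first).days < art_start_exclusion_days:
            return False, None
    vls = [v for v in person.viral_loads if v.date <= index_date]
    if not vls:
        return True, None
    if not any((index_date - v.date).days < vl_window_days for v in vls):
        return True, None
    last_date = max(v.date for v in vls)
    last = [v for v in vls if v.date == last_date]
    suppressed = all(
        (v.below_limit and v.value_copies_per_ml <= threshold)
        or (not v.below_limit and v.value_copies_per_ml < threshold)
        for v in last
    )
    return True, suppressed


def pro_outcomes(
    person: Person, index_date: date, window_days: int = 730
) -> tuple:
    """(physical_satisfied, psychological_satisfied, adherence_band).

    Uses the most recent questionnaire within ``window_days`` of the index
    date; per-item missingness is allowed, so the two satisfaction flags can
    have different availability.
    """
    qs = [
        q
        for q in person.questionnaires
        if 0 <= (index_date - q.date).days < window_days
    ]
    if not qs:
        return None, None, "missing"
    q = max(qs, key=lambda q: q.date)
    phys = (
        dichotomize_satisfaction(q.physical_health)
        if q.physical_health is not None
        else None
    )
    psych = (
        dichotomize_satisfaction(q.psychological_health)
        if q.psychological_health is not None
        else None
    )
    m = q.missed_doses_last_week
    if m is None:
        band = "missing"
    elif m == 0:
        band = "0"
    elif m <= 2:
        band = "1-2"
    else:
        band = ">=3"
    return phys, psych, band


@dataclass
class OutcomeRecord:
    person_id: str
    eligible_suppression: bool
    suppressed: Optional[bool]
    eligible_pro: bool
    physical_satisfied: Optional[bool]
    psychological_satisfied: Optional[bool]
    adherence_band: str


def derive_outcomes(
    persons: Iterable[Person],
    index_date: date,
    art_start_exclusion_days: int = 183,
    vl_window_days: int = 365,
    suppression_threshold: float = 50.0,
    pro_window_days: int = 730,
) -> pd.DataFrame:
    """One outcome row per person (nullable-boolean columns for missingness)."""
    rows = []
    for p in persons:
        eligible, suppressed = suppression_outcome(
            p, index_date, art_start_exclusion_days, vl_window_days,
            suppression_threshold,
        )
        phys, psych, band = pro_outcomes(p, index_date, pro_window_days)
        has_recent_q = any(
            0 <= (index_date - q.date).days < pro_window_days
            for q in p.questionnaires
        )
        rows.append(
            {
                "person_id": p.person_id,
                "eligible_suppression": eligible,
                "suppressed": suppressed,
                "eligible_pro": has_recent_q,
                "physical_satisfied": phys,
                "psychological_satisfied": psych,
                "adherence_band": band,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "eligible_suppression",
            "suppressed",
            "eligible_pro",
            "physical_satisfied",
            "psychological_satisfied",
            "adherence_band",
        ],
    )
    for col in ("suppressed", "physical_satisfied", "psychological_satisfied"):
        df[col] = df[col].astype("boolean")
    for col in ("eligible_suppression", "eligible_pro"):
        df[col] = df[col].astype(bool)
    return df
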