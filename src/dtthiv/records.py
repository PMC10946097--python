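"""Longitudinal registry domain types and regimen/time arithmetic.

The registry stores one row per drug exposure interval
(:class:`RegimenEpisode`); a *regimen* — the set of drugs a person takes
simultaneously — is a derived object. :func:`build_regimens` reconstructs the
chronological sequence of maximal constant-drug-set intervals from the
per-drug episodes; everything downstream (current regimen at an index date,
non-booster drug counts, cumulative time on therapy, switch detection) is
defined on that sequence.

Date intervals are half-open ``[start, end)`` throughout: a regimen that ends
exactly on the index date is *not* current, and a day is on-treatment if it
lies in at least one episode interval. ``end_date=None`` means the exposure is
ongoing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional

from .catalog import DrugCatalog

DOSING_VALUES = ("QD", "BID", "OTHER", "UNKNOWN")

#: Interpreted per-drug resistance levels, ordered from least to most resistant.
RESISTANCE_LEVELS = ("susceptible", "low", "intermediate", "high")
RESISTANCE_ORDER = {lvl: i for i, lvl in enumerate(RESISTANCE_LEVELS)}


class RecordError(ValueError):
    """A structurally invalid registry record (bad dates, bad codes)."""


class OverlappingEpisodeWarning(UserWarning):
    """Two episodes of the same drug overlapped in time and were merged."""


@dataclass(frozen=True)
class RegimenEpisode:
    """One drug's dated exposure interval, with its dosing frequency."""

    person_id: str
    drug_code: str
    start_date: date
    end_date: Optional[date] = None  # None = ongoing
    dosing: str = "UNKNOWN"

    def __post_init__(self):
        if not isinstance(self.start_date, date):
            raise RecordError(f"{self.person_id}/{self.drug_code}: start_date is not a date")
        if self.end_date is not None:
            if not isinstance(self.end_date, date):
                raise RecordError(f"{self.person_id}/{self.drug_code}: end_date is not a date")
            if self.start_date > self.end_date:
                raise RecordError(
                    f"{self.person_id}/{self.drug_code}: start {self.start_date} "
                    f"after end {self.end_date}"
                )
        if self.dosing not in DOSING_VALUES:
            raise RecordError(f"{self.person_id}/{self.drug_code}: bad dosing {self.dosing!r}")

    def active_on(self, day: date) -> bool:
        return self.start_date <= day and (self.end_date is None or day < self.end_date)


@dataclass(frozen=True)
class Regimen:
    """A maximal interval over which the active drug set is constant."""

    drug_codes: frozenset
    start_date: date
    end_date: Optional[date] = None

    def contains(self, day: date) -> bool:
        return self.start_date <= day and (self.end_date is None or day < self.end_date)

    def duration_days(self, cap: Optional[date] = None) -> int:
        """Length of the interval in days, optionally truncated at ``cap``."""
        end = self.end_date
        if cap is not None:
            end = cap if end is None else min(end, cap)
        if end is None:
            raise ValueError("open-ended regimen needs a cap date")
        return max(0, (end - self.start_date).days)


@dataclass(frozen=True)
class ViralLoad:
    """Dated plasma HIV-RNA measurement in copies/mL.

    ``below_limit=True`` marks a "<limit" assay result; ``value_copies_per_ml``
    then holds the assay limit and the measurement is treated as below it.
    """

    person_id: str
    date: date
    value_copies_per_ml: float
    below_limit: bool = False

    def __post_init__(self):
        if self.value_copies_per_ml < 0:
            raise RecordError(f"{self.person_id}: negative viral load")

    def at_least(self, threshold: float) -> bool:
        """True when the measurement demonstrates RNA >= threshold copies/mL."""
        return (not self.below_limit) and self.value_copies_per_ml >= threshold


@dataclass(frozen=True)
class ResistanceResult:
    """One drug's interpreted resistance level from one dated test."""

    person_id: str
    test_date: date
    drug_code: str
    level: str

    def __post_init__(self):
        if self.level not in RESISTANCE_ORDER:
            raise RecordError(f"{self.person_id}/{self.drug_code}: bad level {self.level!r}")


@dataclass(frozen=True)
class Questionnaire:
    """Self-reported health items (Likert 1-6) and missed doses last week."""

    person_id: str
    date: date
    physical_health: Optional[int] = None
    psychological_health: Optional[int] = None
    missed_doses_last_week: Optional[int] = None

    def __post_init__(self):
        for name in ("physical_health", "psychological_health"):
            v = getattr(self, name)
            if v is not None and not 1 <= int(v) <= 6:
                raise RecordError(f"{self.person_id}: {name}={v} outside 1-6")
        if self.missed_doses_last_week is not None and self.missed_doses_last_week < 0:
            raise RecordError(f"{self.person_id}: negative missed doses")


@dataclass
class Person:
    """Demographics plus all longitudinal sub-records for one individual."""

    person_id: str
    sex_at_birth: str = "missing"  # man / woman / missing
    birth_date: Optional[date] = None
    first_positive_test_year: Optional[int] = None
    risk_group: str = "missing"  # heterosexual / MSM / IDU / other / missing
    born_in_sweden: Optional[bool] = None
    first_cd4: Optional[float] = None
    nadir_cd4: Optional[float] = None
    first_vl_log10: Optional[float] = None
    episodes: list = field(default_factory=list)
    viral_loads: list = field(default_factory=list)
    resistance: list = field(default_factory=list)
    questionnaires: list = field(default_factory=list)

    def sorted_viral_loads(self) -> list:
        return sorted(self.viral_loads, key=lambda v: v.date)

    def age_years(self, on: date) -> Optional[float]:
        if self.birth_date is None:
            return None
        return (on - self.birth_date).days / 365.25


CATEGORY_NAMES = (
    "advanced_resistance",
    "four_drug_regimen",
    "salvage_therapy",
    "recent_virologic_failure",
    "multi_switch_failure",
)


@dataclass(frozen=True)
class CategoryFlags:
    """The five (mutually non-exclusive) category memberships and their union."""

    advanced_resistance: bool
    four_drug_regimen: bool
    salvage_therapy: bool
    recent_virologic_failure: bool
    multi_switch_failure: bool

    @property
    def difficult(self) -> bool:
        return any(getattr(self, name) for name in CATEGORY_NAMES)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in CATEGORY_NAMES}
        d["difficult"] = self.difficult
        return d


def build_regimens(
    episodes: Iterable[RegimenEpisode], gap_tolerance_days: int = 0
) -> list:
    """Derive the chronological regimen sequence from per-drug episodes.

    Returns maximal half-open intervals of constant active drug set, excluding
    intervals where no drug is active (treatment gaps are not regimens).
    Adjacent intervals with identical drug sets separated by at most
    ``gap_tolerance_days`` days are merged; the conservative default of 0
    merges only touching intervals, so any real gap splits the sequence.

    Overlapping duplicate records for the same drug are merged with an
    :class:`OverlappingEpisodeWarning`.
    """
    eps = list(episodes)
    if not eps:
        return []
    pids = {e.person_id for e in eps}
    if len(pids) > 1:
        raise RecordError(f"episodes span multiple persons: {sorted(pids)}")

    # Merge intervals per drug; strict overlaps get a warning.
    by_drug: dict = {}
    for e in eps:
        by_drug.setdefault(e.drug_code, []).append((e.start_date, e.end_date))
    merged: dict = {}
    for code, ivals in by_drug.items():
        ivals.sort(key=lambda iv: (iv[0], iv[1] or date.max))
        out = [list(ivals[0])]
        overlap = False
        for s, t in ivals[1:]:
            _, pt = out[-1]
            if pt is None or s < pt:
                overlap = True
            if pt is None or s <= pt:
                out[-1][1] = None if (pt is None or t is None) else max(pt, t)
            else:
                out.append([s, t])
        if overlap:
            warnings.warn(
                f"overlapping episodes for drug {code} merged",
                OverlappingEpisodeWarning,
                stacklevel=2,
            )
        merged[code] = [(s, t) for s, t in out]

    points = sorted(
        {s for ivs in merged.values() for s, _ in ivs}
        | {t for ivs in merged.values() for _, t in ivs if t is not None}
    )

    def active_at(day: date) -> frozenset:
        return frozenset(
            code
            for code, ivs in merged.items()
            for s, t in ivs
            if s <= day and (t is None or day < t)
        )

    segs = []
    for i, t0 in enumerate(points):
        t1 = points[i + 1] if i + 1 < len(points) else None
        drugs = active_at(t0)
        if drugs:
            segs.append([t0, t1, drugs])

    tol = timedelta(days=gap_tolerance_days)
    out = []
    for s, t, drugs in segs:
        if (
            out
            and out[-1][2] == drugs
            and out[-1][1] is not None
            and s - out[-1][1] <= tol
        ):
            out[-1][1] = t
        else:
            out.append([s, t, drugs])
    return [Regimen(drug_codes=d, start_date=s, end_date=t) for s, t, d in out]


def current_regimen(
    person: Person, index_date: date, regimens: Optional[list] = None
):
    """The regimen whose half-open interval contains ``index_date``, or None."""
    regs = build_regimens(person.episodes) if regimens is None else regimens
    for r in regs:
        if r.contains(index_date):
            return r
    return None


def nonbooster_count(regimen: Regimen, catalog: DrugCatalog) -> int:
    """Number of distinct non-booster drugs in the regimen."""
    return sum(1 for code in regimen.drug_codes if not catalog.is_booster(code))


def art_duration_days(
    person: Person, index_date: date, regimens: Optional[list] = None
) -> int:
    """Cumulative days on therapy up to ``index_date`` (treatment gaps excluded)."""
    regs = build_regimens(person.episodes) if regimens is None else regimens
    total = 0
    for r in regs:
        if r.start_date >= index_date:
            continue
        end = index_date if r.end_date is None else min(r.end_date, index_date)
        total += max(0, (end - r.start_date).days)
    return total
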