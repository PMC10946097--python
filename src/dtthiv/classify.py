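"""The five difficult-to-treat HIV category rules.

A person is classified *difficult-to-treat* when they belong to at least one
of five mutually non-exclusive categories, each evaluated at an index date:

1. **Advanced resistance** — intermediate or high-level interpreted
   resistance to >= 2 antiretrovirals spanning >= 2 drug classes, cumulative
   over all tests ever recorded (archived resistance persists clinically).
2. **Four-drug regimen** — currently on >= 4 non-booster drugs, having been
   on a 2- or 3-drug regimen at some earlier time.
3. **Salvage therapy** — current regimen contains a last-resort agent
   (ibalizumab, fostemsavir, enfuvirtide, maraviroc, etravirine), or
   twice-daily dolutegravir, or twice-daily darunavir together with a
   pharmacokinetic booster.
4. **Recent virologic failure** — two viral loads >= 200 copies/mL at least
   90 days apart within the 365 days preceding the index date, in a person
   with >= 1826 cumulative days on therapy.
5. **Multiple switches following failure** — >= 2 consecutive regimens each
   "failed" (a viral load >= 50 copies/mL measured on the regimen on or after
   2008-01-01, followed by a regimen switch within 183 days of that
   measurement).

The month/year phrasings of the rules are fixed to day equivalents
(3 months -> 90 d, 6 months -> 183 d, 12 months -> 365 d, 5 years -> 1826 d)
so that results are reproducible; all of them are exposed on
:class:`RuleThresholds` for sensitivity runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional

import pandas as pd

from .catalog import DrugCatalog
from .records import (
    CATEGORY_NAMES,
    CategoryFlags,
    Person,
    RESISTANCE_ORDER,
    art_duration_days,
    build_regimens,
    current_regimen,
    nonbooster_count,
)

#: Drugs whose mere presence in the current regimen constitutes salvage therapy.
SALVAGE_DRUGS = frozenset({"IBA", "FTR", "ENF", "MVC", "ETR"})


@dataclass(frozen=True)
class RuleThresholds:
    """Day-unit equivalents and count thresholds behind the five rules."""

    vf_vl_threshold: float = 200.0  # copies/mL, recent-failure rule
    vf_min_days_apart: int = 90  # "at least 3 months apart"
    vf_window_days: int = 365  # "within the past 12 months"
    vf_min_art_days: int = 1826  # "on ART for >= 5 years"
    switch_vl_threshold: float = 50.0  # copies/mL, switch-after-failure rule
    switch_window_days: int = 183  # "switch within 6 months"
    failure_anchor: date = date(2008, 1, 1)  # earliest countable failing VL
    min_resistant_drugs: int = 2
    min_resistant_classes: int = 2
    min_resistance_level: str = "intermediate"
    four_dr_min_drugs: int = 4  # ">= 4" reading of "4-drug regimen"
    prior_regimen_sizes: tuple = (2, 3)


DEFAULT_THRESHOLDS = RuleThresholds()


def classify_advanced_resistance(
    person: Person,
    catalog: DrugCatalog,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Resistance >= intermediate to >= 2 drugs spanning >= 2 classes.

    Each drug contributes its maximum interpreted level over all tests ever
    recorded. Persons without any resistance result cannot qualify.
    """
    best: dict = {}
    for r in person.resistance:
        o = RESISTANCE_ORDER[r.level]
        if o > best.get(r.drug_code, -1):
            best[r.drug_code] = o
    min_o = RESISTANCE_ORDER[thresholds.min_resistance_level]
    # Resolve classes for every tested drug so unknown codes fail loudly.
    classes = {code: catalog.drug_class(code) for code in best}
    resistant = [code for code, o in best.items() if o >= min_o]
    if len(resistant) < thresholds.min_resistant_drugs:
        return False
    return len({classes[c] for c in resistant}) >= thresholds.min_resistant_classes


def classify_four_drug_regimen(
    person: Person,
    index_date: date,
    catalog: DrugCatalog,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    regimens: Optional[list] = None,
) -> bool:
    """Currently on >=4 non-booster drugs after an earlier 2- or 3-drug regimen."""
    regs = build_regimens(person.episodes) if regimens is None else regimens
    cur = current_regimen(person, index_date, regimens=regs)
    if cur is None or nonbooster_count(cur, catalog) < thresholds.four_dr_min_drugs:
        return False
    return any(
        nonbooster_count(r, catalog) in thresholds.prior_regimen_sizes
        for r in regs
        if r.start_date < cur.start_date
    )


def classify_salvage_therapy(
    person: Person,
    index_date: date,
    catalog: DrugCatalog,
    regimens: Optional[list] = None,
) -> bool:
    """Current regimen contains a salvage agent, BID DTG, or boosted BID DRV.

    Dosing is read from the episodes active on the index date; a missing
    dosing flag (UNKNOWN) is conservatively treated as not twice-daily.
    """
    cur = current_regimen(person, index_date, regimens=regimens)
    if cur is None:
        return False
    if cur.drug_codes & SALVAGE_DRUGS:
        return True

    def bid(code: str) -> bool:
        return any(
            e.drug_code == code and e.dosing == "BID" and e.active_on(index_date)
            for e in person.episodes
        )

    if "DTG" in cur.drug_codes and bid("DTG"):
        return True
    if (
        "DRV" in cur.drug_codes
        and bid("DRV")
        and any(catalog.is_booster(c) for c in cur.drug_codes)
    ):
        return True
    return False


def classify_recent_virologic_failure(
    person: Person,
    index_date: date,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    regimens: Optional[list] = None,
) -> bool:
    """Two VLs >= 200 copies/mL, >= 90 d apart, within the past year, on long ART.

    The 12-month window is half-open ``(index - 365 d, index]``; the spacing
    bound is inclusive (exactly 90 days apart qualifies).
    """
    window_start = index_date - timedelta(days=thresholds.vf_window_days)
    qual = sorted(
        v.date
        for v in person.viral_loads
        if v.at_least(thresholds.vf_vl_threshold)
        and window_start < v.date <= index_date
    )
    if len(qual) < 2 or (qual[-1] - qual[0]).days < thresholds.vf_min_days_apart:
        return False
    return (
        art_duration_days(person, index_date, regimens=regimens)
        >= thresholds.vf_min_art_days
    )


def classify_multi_switch_failure(
    person: Person,
    catalog: Optional[DrugCatalog] = None,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    regimens: Optional[list] = None,
) -> bool:
    """>= 2 consecutive regimens failed and were switched within 183 days.

    A regimen *fails* when some viral load >= 50 copies/mL, dated on or after
    2008-01-01, is measured while the person is on that regimen and the next
    regimen starts within 183 days of that measurement. The flag requires two
    failing regimens adjacent in the person's regimen sequence (treatment gaps
    between them are allowed).

    When a catalog is supplied, a "switch" means a change in the set of
    *non-booster* drugs: consecutive regimens differing only in boosters are
    collapsed before failure detection.
    """
    regs = build_regimens(person.episodes) if regimens is None else regimens
    if len(regs) < 3:
        return False

    if catalog is not None:
        def key(r):
            return frozenset(c for c in r.drug_codes if not catalog.is_booster(c))
    else:
        def key(r):
            return r.drug_codes

    groups: list = []
    for r in regs:
        if groups and key(groups[-1][0]) == key(r):
            groups[-1].append(r)
        else:
            groups.append([r])

    fail_vls = [
        v
        for v in person.viral_loads
        if v.at_least(thresholds.switch_vl_threshold)
        and v.date >= thresholds.failure_anchor
    ]

    def fails(gi: int) -> bool:
        if gi + 1 >= len(groups):
            return False  # no subsequent regimen, hence no switch
        next_start = groups[gi + 1][0].start_date
        for v in fail_vls:
            if (next_start - v.date).days <= thresholds.switch_window_days and any(
                seg.contains(v.date) for seg in groups[gi]
            ):
                return True
        return False

    flags = [fails(i) for i in range(len(groups))]
    return any(a and b for a, b in zip(flags, flags[1:]))


def classify_person(
    person: Person,
    index_date: date,
    catalog: DrugCatalog,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> CategoryFlags:
    """Evaluate all five category rules for one person at the index date."""
    regs = build_regimens(person.episodes)
    return CategoryFlags(
        advanced_resistance=classify_advanced_resistance(person, catalog, thresholds),
        four_drug_regimen=classify_four_drug_regimen(
            person, index_date, catalog, thresholds, regimens=regs
        ),
        salvage_therapy=classify_salvage_therapy(
            person, index_date, catalog, regimens=regs
        ),
        recent_virologic_failure=classify_recent_virologic_failure(
            person, index_date, thresholds, regimens=regs
        ),
        multi_switch_failure=classify_multi_switch_failure(
            person, catalog, thresholds, regimens=regs
        ),
    )


def classify_cohort(
    persons: Iterable[Person],
    index_date: date,
    catalog: DrugCatalog,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """One row of boolean category flags per person.

    Raises on duplicate person ids. The output row order follows the input
    order, so identical inputs yield identical output.
    """
    rows = []
    seen = set()
    for p in persons:
        if p.person_id in seen:
            raise ValueError(f"duplicate person_id: {p.person_id}")
        seen.add(p.person_id)
        flags = classify_person(p, index_date, catalog, thresholds)
        row = {"person_id": p.person_id}
        row.update(flags.as_dict())
        rows.append(row)
    cols = ["person_id", *CATEGORY_NAMES, "difficult"]
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=(object if c == "person_id" else bool)) for c in cols})
    return pd.DataFrame(rows, columns=cols)
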