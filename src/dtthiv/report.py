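"""Paper-style outputs: baseline-characteristics table, outcome table,
category intersections, per-category suppression, and the pipeline driver.

Display percentages are rounded half-up to integers; full precision is kept
in the CSV exports. Intersection cells below ``min_cell`` persons are masked
in display output (small-cell anonymity) but retained in the full export.
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import asdict
from datetime import date
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .catalog import DrugCatalog, default_catalog
from .classify import DEFAULT_THRESHOLDS, RuleThresholds, classify_cohort
from .io import load_tables, persons_from_tables
from .outcomes import ADHERENCE_BANDS, derive_outcomes
from .records import CATEGORY_NAMES, build_regimens, current_regimen
from .stats import (
    chi_squared,
    fit_outcome_models,
    mann_whitney,
    sensitivity_excluding_recent_vf,
)

CATEGORY_LABELS = {
    "advanced_resistance": "AR",
    "four_drug_regimen": "4DR",
    "salvage_therapy": "ST",
    "recent_virologic_failure": "VF12",
    "multi_switch_failure": "SW2",
}


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half-up (display convention)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def venn_counts(flags: pd.DataFrame, min_cell: int = 10) -> pd.DataFrame:
    """Counts for all 31 nonempty category subsets among difficult persons.

    ``subset`` identifies the exact combination of categories (e.g.
    ``AR+ST`` = advanced resistance AND salvage therapy, no other flags).
    ``display_count`` masks cells smaller than ``min_cell`` (pd.NA); the
    ``count`` column always holds the true value. Cells sum to the number of
    difficult persons.
    """
    f = flags[list(CATEGORY_NAMES)].astype(bool)
    rows = []
    for r in range(1, 6):
        for combo in itertools.combinations(CATEGORY_NAMES, r):
            mask = np.ones(len(f), dtype=bool)
            for c in CATEGORY_NAMES:
                col = f[c].to_numpy()
                mask &= col if c in combo else ~col
            count = int(mask.sum())
            rows.append(
                {
                    "subset": "+".join(CATEGORY_LABELS[c] for c in combo),
                    "n_categories": r,
                    "count": count,
                    "display_count": count if count >= min_cell else pd.NA,
                }
            )
    out = pd.DataFrame(rows)
    out["display_count"] = out["display_count"].astype("Int64")
    return out


def venn_dict(flags: pd.DataFrame) -> dict:
    """Mapping frozenset-of-categories -> exact-cell count (test-friendly)."""
    df = venn_counts(flags, min_cell=0)
    inv = {v: k for k, v in CATEGORY_LABELS.items()}
    return {
        frozenset(inv[p] for p in row.subset.split("+")): row.count
        for row in df.itertuples(index=False)
    }


def _group_masks(flags: pd.DataFrame) -> dict:
    d = flags["difficult"].astype(bool).to_numpy()
    masks = {"non_difficult": ~d, "difficult": d}
    for c in CATEGORY_NAMES:
        masks[c] = flags[c].astype(bool).to_numpy()
    return masks


#: variables reported only for the two main groups, mirroring register
#: practice of aggregating small sensitive cells
_SENSITIVE = {"risk_group", "adherence_band", "age_under_18"}


def _person_features(
    persons: Iterable, catalog: DrugCatalog, index_date: date,
    outcomes: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    rows = []
    for p in persons:
        cur = current_regimen(p, index_date, regimens=build_regimens(p.episodes))
        classes = (
            {catalog.drug_class(c) for c in cur.drug_codes if not catalog.is_booster(c)}
            if cur is not None
            else set()
        )
        age = p.age_years(index_date)
        rows.append(
            {
                "person_id": p.person_id,
                "sex_at_birth": p.sex_at_birth,
                "age_years": age,
                "age_under_18": None if age is None else age < 18,
                "first_positive_test_year": p.first_positive_test_year,
                "diagnosis_before_1995": (
                    None
                    if p.first_positive_test_year is None
                    else p.first_positive_test_year < 1995
                ),
                "first_cd4": p.first_cd4,
                "nadir_cd4": p.nadir_cd4,
                "first_vl_log10": p.first_vl_log10,
                "risk_group": p.risk_group,
                "born_in_sweden": p.born_in_sweden,
                "regimen_includes_NNRTI": "NNRTI" in classes,
                "regimen_includes_PI": "PI" in classes,
                "regimen_includes_INSTI": "INSTI" in classes,
                "regimen_includes_PI_and_INSTI": {"PI", "INSTI"} <= classes,
                "has_resistance_test": len(p.resistance) > 0,
            }
        )
    df = pd.DataFrame(rows)
    if outcomes is not None:
        df = df.merge(
            outcomes[["person_id", "adherence_band"]], on="person_id", how="left"
        )
    return df


_CONTINUOUS = [
    ("age_years", "Current age [years]"),
    ("first_positive_test_year", "Year of first positive HIV test"),
    ("first_cd4", "First CD4 count [cells/uL]"),
    ("nadir_cd4", "Nadir CD4 count [cells/uL]"),
    ("first_vl_log10", "First HIV RNA [log10 copies/mL]"),
]

_CATEGORICAL = [
    ("sex_at_birth", ["man", "woman", "missing"]),
    ("diagnosis_before_1995", [True, False]),
    ("risk_group", ["heterosexual", "MSM", "IDU", "other", "missing"]),
    ("born_in_sweden", [True, False]),
    ("regimen_includes_NNRTI", [True, False]),
    ("regimen_includes_PI", [True, False]),
    ("regimen_includes_INSTI", [True, False]),
    ("regimen_includes_PI_and_INSTI", [True, False]),
    ("has_resistance_test", [True, False]),
    ("adherence_band", list(ADHERENCE_BANDS)),
]


def table1(
    flags: pd.DataFrame,
    persons: Iterable,
    catalog: DrugCatalog,
    index_date: date,
    outcomes: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Baseline characteristics by group (long format).

    Continuous variables report median and interquartile range; categorical
    variables report counts and percentages with explicit missing rows. The
    p-value column compares difficult versus non-difficult persons
    (Mann-Whitney U for continuous, Pearson chi-squared for categorical) and
    is repeated on every row of the variable. Sensitive variables are
    reported for the two main groups only.
    """
    feats = _person_features(persons, catalog, index_date, outcomes)
    df = flags.merge(feats, on="person_id", validate="one_to_one")
    masks = _group_masks(df)
    rows = []

    for col, label in _CONTINUOUS:
        vals = pd.to_numeric(df[col], errors="coerce")
        a = vals[masks["difficult"]].dropna()
        b = vals[masks["non_difficult"]].dropna()
        p = mann_whitney(a, b)[1] if len(a) and len(b) else None
        for group, mask in masks.items():
            v = vals[mask].dropna()
            rows.append(
                {
                    "variable": label,
                    "level": "",
                    "group": group,
                    "n": int(mask.sum()),
                    "median": float(v.median()) if len(v) else None,
                    "q1": float(v.quantile(0.25)) if len(v) else None,
                    "q3": float(v.quantile(0.75)) if len(v) else None,
                    "count": None,
                    "pct": None,
                    "missing_n": int(mask.sum() - len(v)),
                    "p_value": p,
                }
            )

    for col, levels in _CATEGORICAL:
        if col not in df.columns:
            continue
        series = df[col]
        groups = (
            {k: masks[k] for k in ("non_difficult", "difficult")}
            if col in _SENSITIVE
            else masks
        )
        # chi-squared over observed non-missing levels, difficult vs not
        tab = []
        for mask in (masks["difficult"], masks["non_difficult"]):
            sub = series[mask]
            tab.append([int((sub == lv).sum()) for lv in levels])
        tab = np.array(tab)
        keep = tab.sum(axis=0) > 0
        p = None
        if keep.sum() >= 2 and tab[:, keep].sum(axis=1).min() > 0:
            p = chi_squared(tab[:, keep])[1]
        for group, mask in groups.items():
            sub = series[mask]
            n = int(mask.sum())
            observed = int(sub.isin(levels).sum())
            for lv in levels:
                cnt = int((sub == lv).sum())
                rows.append(
                    {
                        "variable": col,
                        "level": str(lv),
                        "group": group,
                        "n": n,
                        "median": None,
                        "q1": None,
                        "q3": None,
                        "count": cnt,
                        "pct": 100.0 * cnt / n if n else None,
                        "missing_n": n - observed,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)


def suppression_by_category(
    flags: pd.DataFrame, outcomes: pd.DataFrame
) -> pd.DataFrame:
    """Suppression rate for non-difficult, difficult overall, and each category.

    Persons contribute to every category they belong to, so category rows
    overlap; only the 31 disjoint intersection cells partition the difficult
    group.
    """
    df = flags.merge(outcomes, on="person_id", validate="one_to_one")
    assessed = (
        df["eligible_suppression"].astype(bool) & df["suppressed"].notna()
    ).to_numpy()
    supp = df["suppressed"].fillna(False).astype(bool).to_numpy()
    masks = _group_masks(df)
    rows = []
    for group, mask in masks.items():
        n_assessed = int((mask & assessed).sum())
        n_supp = int((mask & assessed & supp).sum())
        rows.append(
            {
                "group": group,
                "n_total": int(mask.sum()),
                "n_assessed": n_assessed,
                "n_suppressed": n_supp,
                "rate": n_supp / n_assessed if n_assessed else None,
            }
        )
    return pd.DataFrame(rows)


def table2(
    flags: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Treatment-outcome odds ratios (difficult vs non-difficult), wide format."""
    estimates = fit_outcome_models(flags, outcomes, covariates)
    by_outcome: dict = {}
    for est in estimates:
        row = by_outcome.setdefault(est.outcome, {"outcome": est.outcome})
        key = "adjusted" if est.adjusted else "crude"
        row[f"{key}_or"] = est.odds_ratio
        row[f"{key}_ci_low"] = est.ci_low
        row[f"{key}_ci_high"] = est.ci_high
        row[f"{key}_n"] = est.n_analyzed
        if est.counts is not None:
            a, b, c, d = est.counts
            row["difficult_with_outcome"] = a
            row["difficult_total"] = a + b
            row["difficult_pct"] = 100.0 * a / (a + b) if a + b else None
            row["non_difficult_with_outcome"] = c
            row["non_difficult_total"] = c + d
            row["non_difficult_pct"] = 100.0 * c / (c + d) if c + d else None
    return pd.DataFrame(list(by_outcome.values()))


def run_pipeline(
    input_dir: str,
    out_dir: str,
    index_date: date,
    catalog: Optional[DrugCatalog] = None,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
    min_cell: int = 10,
) -> dict:
    """classify -> outcomes -> tables/venn/figure data, with a run manifest.

    Reads the five registry tables from ``input_dir``, writes
    ``flags.csv``, ``table1.csv``, ``table2.csv``, ``venn_counts.csv``,
    ``suppression_by_category.csv``, ``sensitivity.csv`` and
    ``manifest.json`` to ``out_dir``, and returns the frames in a dict.
    """
    catalog = catalog or default_catalog()
    tables = load_tables(input_dir)
    persons = persons_from_tables(tables)
    flags = classify_cohort(persons, index_date, catalog, thresholds)
    outcomes = derive_outcomes(persons, index_date)
    covariates = pd.DataFrame(
        {
            "person_id": [p.person_id for p in persons],
            "sex_at_birth": [p.sex_at_birth for p in persons],
            "age_years": [p.age_years(index_date) for p in persons],
            "risk_group": [p.risk_group for p in persons],
        }
    )
    results = {
        "flags": flags,
        "outcomes": outcomes,
        "table1": table1(flags, persons, catalog, index_date, outcomes),
        "table2": table2(flags, outcomes, covariates),
        "venn_counts": venn_counts(flags, min_cell=min_cell),
        "suppression_by_category": suppression_by_category(flags, outcomes),
    }
    sens = sensitivity_excluding_recent_vf(flags, outcomes)
    results["sensitivity"] = pd.DataFrame(
        [
            {
                "n_difficult": sens.n_difficult,
                "n_non_difficult": sens.n_non_difficult,
                "rate_difficult": sens.rate_difficult,
                "rate_non_difficult": sens.rate_non_difficult,
                "p_value": sens.p_value,
                "odds_ratio": sens.or_estimate.odds_ratio if sens.or_estimate else None,
                "degenerate": sens.degenerate,
            }
        ]
    )

    os.makedirs(out_dir, exist_ok=True)
    for name, df in results.items():
        if name == "outcomes":
            continue
        df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False,
                  lineterminator="\n")
    n_excluded = int((~outcomes["eligible_suppression"]).sum())
    manifest = {
        "package_version": __version__,
        "index_date": index_date.isoformat(),
        "thresholds": {
            k: (v.isoformat() if isinstance(v, date) else v)
            for k, v in asdict(thresholds).items()
        },
        "n_persons": len(flags),
        "n_difficult": int(flags["difficult"].sum()),
        "n_excluded_recent_art_start": n_excluded,
        "min_cell": min_cell,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
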