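"""Reading and writing the five delimited-text registry tables.

All tables are UTF-8 CSV with a header row and ISO-8601 dates; missing values
are empty fields and booleans are written ``true``/``false``. The loader
validates the schema (required columns, parseable values) and cross-table
referential integrity (every child row must reference a person present in
``persons.csv``).

In memory the tables are pandas DataFrames in a *typed* form — ``datetime.date``
objects in date columns, ``pd.NA`` for missing values — which is also the
form the synthetic generator emits, so generated and loaded cohorts follow
the same code paths.
"""

from __future__ import annotations

import os
from datetime import date
from typing import Optional

import pandas as pd

from .records import (
    Person,
    Questionnaire,
    RegimenEpisode,
    ResistanceResult,
    ViralLoad,
)

TABLE_COLUMNS = {
    "persons": [
        "person_id", "sex_at_birth", "birth_date", "first_positive_test_year",
        "risk_group", "born_in_sweden", "first_cd4", "nadir_cd4",
        "first_vl_log10",
    ],
    "regimen_episodes": [
        "person_id", "drug_code", "start_date", "end_date", "dosing",
    ],
    "viral_loads": ["person_id", "date", "value_copies_per_ml", "below_limit"],
    "resistance": ["person_id", "test_date", "drug_code", "level"],
    "questionnaires": [
        "person_id", "date", "physical_health", "psychological_health",
        "missed_doses_last_week",
    ],
}

_DATE_COLUMNS = {
    "persons": ["birth_date"],
    "regimen_episodes": ["start_date", "end_date"],
    "viral_loads": ["date"],
    "resistance": ["test_date"],
    "questionnaires": ["date"],
}

_BOOL_COLUMNS = {
    "persons": ["born_in_sweden"],
    "viral_loads": ["below_limit"],
}


class SchemaError(ValueError):
    """A registry table violates the documented schema."""


def _parse_date(value) -> Optional[date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, date):
        return value
    try:
        return date.fromisoformat(str(value))
    except ValueError as e:
        raise SchemaError(f"bad date {value!r}") from e


def _parse_bool(value) -> Optional[bool]:
    if value is None or value == "" or (not isinstance(value, str) and pd.isna(value)):
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise SchemaError(f"bad boolean {value!r}")


def load_tables(input_dir: str) -> dict:
    """Load and validate the five registry tables from a directory."""
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        path = os.path.join(input_dir, f"{name}.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"required registry table missing: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{name}.csv missing columns: {missing}")
        df = df[cols].copy()
        for c in _DATE_COLUMNS.get(name, []):
            df[c] = df[c].map(_parse_date)
        for c in _BOOL_COLUMNS.get(name, []):
            df[c] = df[c].map(_parse_bool)
        tables[name] = df
    _coerce_numeric(tables)
    check_referential_integrity(tables)
    return tables


def _coerce_numeric(tables: dict) -> None:
    p = tables["persons"]
    p["first_positive_test_year"] = pd.to_numeric(
        p["first_positive_test_year"].replace("", None), errors="raise"
    ).astype("Int64")
    for c in ("first_cd4", "nadir_cd4", "first_vl_log10"):
        p[c] = pd.to_numeric(p[c].replace("", None), errors="raise").astype(float)
    v = tables["viral_loads"]
    v["value_copies_per_ml"] = pd.to_numeric(
        v["value_copies_per_ml"], errors="raise"
    ).astype(float)
    q = tables["questionnaires"]
    for c in ("physical_health", "psychological_health", "missed_doses_last_week"):
        q[c] = pd.to_numeric(q[c].replace("", None), errors="raise").astype("Int64")


def check_referential_integrity(tables: dict) -> None:
    ids = set(tables["persons"]["person_id"])
    if len(ids) != len(tables["persons"]):
        raise SchemaError("duplicate person_id in persons table")
    for name in ("regimen_episodes", "viral_loads", "resistance", "questionnaires"):
        orphan = set(tables[name]["person_id"]) - ids
        if orphan:
            raise SchemaError(
                f"{name}.csv references unknown person_ids: {sorted(orphan)[:5]}"
            )


def _serialize(df: pd.DataFrame, name: str) -> pd.DataFrame:
    out = df.copy()
    for c in _DATE_COLUMNS.get(name, []):
        out[c] = out[c].map(lambda d: d.isoformat() if isinstance(d, date) else "")
    for c in _BOOL_COLUMNS.get(name, []):
        out[c] = out[c].map(
            lambda b: "" if b is None or pd.isna(b) else str(bool(b)).lower()
        )
    return out


def write_tables(tables: dict, out_dir: str) -> None:
    """Write the typed tables as CSV (deterministic byte content)."""
    os.makedirs(out_dir, exist_ok=True)
    for name in TABLE_COLUMNS:
        _serialize(tables[name], name).to_csv(
            os.path.join(out_dir, f"{name}.csv"), index=False, lineterminator="\n"
        )


def _opt(value):
    if value is None:
        return None
    if not isinstance(value, (str, date, bool)) and pd.isna(value):
        return None
    return value


def persons_from_tables(tables: dict) -> list:
    """Assemble :class:`Person` objects from the typed tables."""
    by_person: dict = {}

    def bucket(pid):
        return by_person.setdefault(pid, ([], [], [], []))

    for r in tables["regimen_episodes"].itertuples(index=False):
        bucket(r.person_id)[0].append(
            RegimenEpisode(
                person_id=r.person_id,
                drug_code=r.drug_code,
                start_date=r.start_date,
                end_date=_opt(r.end_date),
                dosing=r.dosing,
            )
        )
    for r in tables["viral_loads"].itertuples(index=False):
        bucket(r.person_id)[1].append(
            ViralLoad(
                person_id=r.person_id,
                date=r.date,
                value_copies_per_ml=float(r.value_copies_per_ml),
                below_limit=bool(r.below_limit),
            )
        )
    for r in tables["resistance"].itertuples(index=False):
        bucket(r.person_id)[2].append(
            ResistanceResult(
                person_id=r.person_id,
                test_date=r.test_date,
                drug_code=r.drug_code,
                level=r.level,
            )
        )
    for r in tables["questionnaires"].itertuples(index=False):
        phys, psych, md = (
            _opt(r.physical_health),
            _opt(r.psychological_health),
            _opt(r.missed_doses_last_week),
        )
        bucket(r.person_id)[3].append(
            Questionnaire(
                person_id=r.person_id,
                date=r.date,
                physical_health=None if phys is None else int(phys),
                psychological_health=None if psych is None else int(psych),
                missed_doses_last_week=None if md is None else int(md),
            )
        )

    persons = []
    for r in tables["persons"].itertuples(index=False):
        eps, vls, res, qs = by_person.get(r.person_id, ([], [], [], []))
        year = _opt(r.first_positive_test_year)
        persons.append(
            Person(
                person_id=r.person_id,
                sex_at_birth=r.sex_at_birth or "missing",
                birth_date=_opt(r.birth_date),
                first_positive_test_year=None if year is None else int(year),
                risk_group=r.risk_group or "missing",
                born_in_sweden=_opt(r.born_in_sweden),
                first_cd4=_opt(r.first_cd4),
                nadir_cd4=_opt(r.nadir_cd4),
                first_vl_log10=_opt(r.first_vl_log10),
                episodes=eps,
                viral_loads=vls,
                resistance=res,
                questionnaires=qs,
            )
        )
    return persons
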