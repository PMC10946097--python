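"""Seeded synthetic HIV-registry generator with planted ground-truth labels.

The generator emulates the structure of a national HIV register: one row per
person with demographics, multi-decade per-drug regimen histories, sparse
(quarterly-to-biannual) viral-load series, per-drug interpreted resistance
calls for roughly two thirds of persons, and health-questionnaire coverage
for roughly half. Each person's category memberships are decided *first* and
the longitudinal history is then constructed to provably satisfy exactly the
planted flags under the classifier's documented conventions: plants meet
their rule with margin (e.g. two viral loads >= 200 copies/mL placed 95-240
days apart inside the final year on >= 1950 cumulative therapy days) and
non-plants violate every rule by margin (spacing, level, count, or timing).
The planted labels are emitted alongside the tables and are never read by
the classifier.

Default parameters mirror the marginals of the 2023 Swedish cohort the
package models: ~9.4% difficult-to-treat overall with category shares of
2.2/0.6/1.7/0.7/6.1%, 67% resistance-testing coverage, 48% questionnaire
coverage, and suppression probabilities of 0.84 (difficult) versus 0.95
(non-difficult). Within the difficult group, category co-membership follows
a maximum-entropy distribution fitted by iterative proportional fitting to
the category marginals, tilted by configurable pairwise enrichment factors
(recent failure strongly co-occurs with multiple switches; advanced
resistance with salvage therapy).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io import TABLE_COLUMNS
from .records import CATEGORY_NAMES

AR, FDR, ST, RVF, MSF = range(5)  # column order == CATEGORY_NAMES


class ConfigError(ValueError):
    """Scenario configuration is invalid or infeasible."""


def _default_prevalence() -> dict:
    # Category marginals of the modeled 2023 cohort (counts / 8531).
    return {
        "advanced_resistance": 188 / 8531,
        "four_drug_regimen": 51 / 8531,
        "salvage_therapy": 141 / 8531,
        "recent_virologic_failure": 59 / 8531,
        "multi_switch_failure": 519 / 8531,
    }


def _default_enrichment() -> dict:
    return {
        ("recent_virologic_failure", "multi_switch_failure"): 6.0,
        ("advanced_resistance", "salvage_therapy"): 3.0,
        ("advanced_resistance", "four_drug_regimen"): 2.0,
        ("four_drug_regimen", "salvage_therapy"): 2.0,
    }


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cohort."""

    n_persons: int = 2000
    index_date: date = date(2023, 4, 6)
    prevalence: dict = field(default_factory=_default_prevalence)
    difficult_prevalence: float = 799 / 8531
    overlap_enrichment: dict = field(default_factory=_default_enrichment)
    #: "difficult" is the overall suppression rate of the difficult group;
    #: "recent_virologic_failure" overrides the rate for that category (its
    #: members have, by definition, recent unsuppressed measurements), and the
    #: rate for the remaining difficult persons is solved so the overall
    #: difficult rate still meets its target.
    suppression_prob: dict = field(
        default_factory=lambda: {
            "difficult": 0.84,
            "non_difficult": 0.95,
            "recent_virologic_failure": 0.36,
        }
    )
    #: optional true crude OR for suppression; overrides the difficult-group
    #: probability via the non-difficult odds.
    suppression_or: Optional[float] = None
    physical_satisfaction_prob: dict = field(
        default_factory=lambda: {"difficult": 0.55, "non_difficult": 0.63}
    )
    psychological_satisfaction_prob: dict = field(
        default_factory=lambda: {"difficult": 0.64, "non_difficult": 0.66}
    )
    questionnaire_coverage: float = 0.48
    resistance_coverage: float = 0.67
    vl_interval_days: tuple = (90, 180)
    recent_starter_frac: float = 0.03  # started ART < 6 months before index
    stale_vl_frac: float = 0.02  # last viral load > 12 months before index
    seed: Optional[int] = None

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be non-negative")
        fracs = [
            self.difficult_prevalence, self.questionnaire_coverage,
            self.resistance_coverage, self.recent_starter_frac,
            self.stale_vl_frac, *self.prevalence.values(),
            *self.suppression_prob.values(),
            *self.physical_satisfaction_prob.values(),
            *self.psychological_satisfaction_prob.values(),
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if set(self.prevalence) != set(CATEGORY_NAMES):
            raise ConfigError("prevalence must name exactly the five categories")
        if self.difficult_prevalence > 0:
            for name, p in self.prevalence.items():
                if p > self.difficult_prevalence:
                    raise ConfigError(
                        f"category prevalence {name}={p} exceeds the difficult "
                        f"prevalence {self.difficult_prevalence}"
                    )
            if sum(self.prevalence.values()) < self.difficult_prevalence * (1 - 1e-9):
                raise ConfigError(
                    "category prevalences sum to less than the difficult "
                    "prevalence; the union cannot reach it"
                )
        if self.index_date < date(2014, 1, 1):
            raise ConfigError(
                "index_date must be 2014-01-01 or later (planted switch "
                "histories need room after the 2008 failure anchor)"
            )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "index_date" in raw:
            raw["index_date"] = date.fromisoformat(str(raw["index_date"]))
        if "overlap_enrichment" in raw:
            raw["overlap_enrichment"] = {
                tuple(sorted(k.split("+"))): float(v)
                for k, v in raw["overlap_enrichment"].items()
            }
        if "vl_interval_days" in raw:
            raw["vl_interval_days"] = tuple(raw["vl_interval_days"])
        return cls(**raw)


def subset_distribution(cfg: ScenarioConfig) -> tuple:
    """Distribution over the 31 nonempty category subsets, given difficult.

    Starts from independence at the conditional marginals q_i = p_i / p_diff,
    tilts each cell by the pairwise enrichment factors, and rescales by
    iterative proportional fitting so every conditional marginal is met
    exactly while the empty set has probability zero.
    """
    q = np.array(
        [cfg.prevalence[c] / cfg.difficult_prevalence for c in CATEGORY_NAMES]
    )
    enrich = {tuple(sorted(k)): v for k, v in cfg.overlap_enrichment.items()}
    masks = [m for m in range(1, 32)]
    w = np.zeros(len(masks))
    for j, m in enumerate(masks):
        members = [i for i in range(5) if m >> i & 1]
        p = 1.0
        for i in range(5):
            p *= q[i] if m >> i & 1 else (1 - q[i])
        for a, b in itertools.combinations(members, 2):
            key = tuple(sorted((CATEGORY_NAMES[a], CATEGORY_NAMES[b])))
            p *= enrich.get(key, 1.0)
        w[j] = p
    if w.sum() <= 0:
        raise ConfigError("infeasible overlap structure: no admissible subset")
    w /= w.sum()
    has = np.array([[m >> i & 1 for m in masks] for i in range(5)], dtype=bool)
    for _ in range(2000):
        err = 0.0
        for i in range(5):
            m_in = w[has[i]].sum()
            m_out = w[~has[i]].sum()
            if q[i] > 0 and m_in == 0:
                raise ConfigError(
                    f"infeasible overlap structure for {CATEGORY_NAMES[i]}"
                )
            err = max(err, abs(m_in - q[i]))
            if m_in > 0:
                w[has[i]] *= q[i] / m_in
            if m_out > 0:
                w[~has[i]] *= (1 - q[i]) / m_out
        if err < 1e-12:
            break
    else:
        raise ConfigError("overlap calibration did not converge; check enrichment factors")
    return np.array(masks), w / w.sum()


# ---------------------------------------------------------------------------
# drug pools for history construction (all deliberately non-salvage:
# no ETR/ENF/MVC/IBA/FTR, and DTG/DRV only ever once-daily outside plants)

_BACKBONES_OLD = (("AZT", "3TC"), ("D4T", "3TC"), ("DDI", "3TC"), ("ABC", "3TC"), ("TDF", "FTC"))
_BACKBONES_NEW = (("TDF", "FTC"), ("TAF", "FTC"), ("ABC", "3TC"), ("TDF", "3TC"))
_ANCHORS_OLD = (("EFV",), ("NVP",), ("LPV", "RTV"), ("ATV", "RTV"), ("RAL",))
_ANCHORS_NEW = (
    ("DTG",), ("BIC",), ("RAL",), ("RPV",), ("DOR",), ("EFV",),
    ("DRV", "RTV"), ("DRV", "COBI"), ("ATV", "COBI"),
)
_BOOSTERS = frozenset({"RTV", "COBI"})
_BID_DRUGS = frozenset({"AZT", "LPV"})  # ordinary twice-daily agents; never salvage


def _dosing(code: str, year: int) -> str:
    if year < 1998:
        return "UNKNOWN"
    return "BID" if code in _BID_DRUGS else "QD"


def _nonbooster(combo) -> frozenset:
    return frozenset(c for c in combo if c not in _BOOSTERS)


def _pick_combo(rng, year: int, exclude: set) -> tuple:
    """A 3-drug (+optional booster) combination whose non-booster set avoids
    every set in ``exclude``."""
    backbones = _BACKBONES_OLD if year < 2008 else _BACKBONES_NEW
    anchors = _ANCHORS_OLD if year < 2008 else _ANCHORS_NEW
    for _ in range(50):
        bb = backbones[rng.integers(len(backbones))]
        an = anchors[rng.integers(len(anchors))]
        combo = tuple(bb) + tuple(an)
        if len(set(combo)) == len(combo) and _nonbooster(combo) not in exclude:
            return combo
    raise RuntimeError("could not draw a distinct regimen")  # pragma: no cover

_SALVAGE_KINDS = ("drv_bid", "etr", "dtg_bid")
_SALVAGE_WEIGHTS = np.array([90, 39, 35], dtype=float) / 164.0  # cohort split


def _current_combo(rng, flags) -> tuple:
    """The (drug, dosing) tuple of the regimen active at the index date.

    Salvage plants get one of the three common salvage patterns; 4-drug
    plants get >= 4 non-booster drugs; everyone else gets a standard 2-3 drug
    combination.
    """
    bb = _BACKBONES_NEW[rng.integers(len(_BACKBONES_NEW))]
    backbone = [(c, "QD") for c in bb]
    if flags[ST]:
        kind = _SALVAGE_KINDS[rng.choice(3, p=_SALVAGE_WEIGHTS)]
        booster = "RTV" if rng.random() < 0.6 else "COBI"
        if kind == "drv_bid":
            combo = [("DRV", "BID"), (booster, "QD")] + backbone
            if flags[FDR]:
                combo.append(("DTG", "QD"))
        elif kind == "etr":
            combo = [("ETR", "BID")] + backbone
            if flags[FDR]:
                combo.append(("DTG", "QD"))
        else:  # dtg_bid
            combo = [("DTG", "BID")] + backbone
            if flags[FDR]:
                combo += [("DRV", "QD"), (booster, "QD")]
        return tuple(combo)
    if flags[FDR]:
        booster = "RTV" if rng.random() < 0.6 else "COBI"
        return tuple([("DRV", "QD"), (booster, "QD"), ("DTG", "QD")] + backbone)
    if rng.random() < 0.10:  # modern 2-drug maintenance
        return (("DTG", "QD"), ("3TC", "QD"))
    combo = _pick_combo(rng, 2020, exclude=set())
    return tuple((c, _dosing(c, 2020)) for c in combo)


def _plain_history(rng, art_start, index, flags, current_combo, allow_gap):
    """Regimen segments for persons without a planted switch-failure block."""
    cur_nb = frozenset(c for c, _ in current_combo if c not in _BOOSTERS)
    latest_switch = index - timedelta(days=430 if flags[RVF] else 60)
    earliest_switch = art_start + timedelta(days=400)
    years = (index - art_start).days / 365.25
    if earliest_switch >= latest_switch:
        k = 0
    else:
        k = int(rng.poisson(max(years - 1, 0.0) / 7.0))
        if flags[FDR]:
            k = max(k, 1)
        k = min(k, 6)
    span = (latest_switch - earliest_switch).days if k else 0
    k = min(k, span)
    switch_days = sorted(rng.choice(span, size=k, replace=False)) if k else []
    boundaries = [earliest_switch + timedelta(days=int(d)) for d in switch_days]
    segments = []
    prev_nb = None
    start = art_start
    for b in boundaries:
        combo = _pick_combo(
            rng, start.year, exclude={cur_nb} | ({prev_nb} if prev_nb else set())
        )
        seg = tuple((c, _dosing(c, start.year)) for c in combo)
        segments.append((start, b, seg))
        prev_nb = _nonbooster(combo)
        start = b
    if allow_gap and segments and rng.random() < 0.05:
        # open a short treatment interruption before the current regimen
        gap = int(rng.uniform(30, 250))
        start = min(start + timedelta(days=gap), index - timedelta(days=30))
    segments.append((start, None, current_combo))
    return segments, []


def _msf_history(rng, art_start, index, flags, current_combo):
    """Segments plus failing viral loads for a planted switch-failure block.

    Each failing regimen R_j carries a viral load >= 50 copies/mL (dated on
    or after 2008-01-01) followed by the next regimen start within 30-150
    days; the block ends >= 430 days before the index date so it can never
    double as a recent virologic failure.
    """
    cur_nb = frozenset(c for c, _ in current_combo if c not in _BOOSTERS)
    m = int(rng.integers(2, 4))  # failing regimens
    latest_block_start = index - timedelta(days=430 + m * 460)
    block_start = art_start + timedelta(days=int(rng.uniform(300, 700)))
    block_start = max(block_start, date(2008, 1, 1))
    block_start = min(block_start, latest_block_start)
    assert block_start > art_start

    segments = []
    prev_nb = None

    def next_combo(start):
        nonlocal prev_nb
        combo = _pick_combo(
            rng, start.year, exclude={cur_nb} | ({prev_nb} if prev_nb else set())
        )
        prev_nb = _nonbooster(combo)
        return tuple((c, _dosing(c, start.year)) for c in combo)

    segments.append((art_start, block_start, next_combo(art_start)))
    s = block_start
    fail_vls = []
    for _ in range(m):
        v_day = s + timedelta(days=int(rng.uniform(40, 280)))
        switch = v_day + timedelta(days=int(rng.uniform(30, 150)))
        segments.append((s, switch, next_combo(s)))
        value = float(np.round(10 ** rng.uniform(1.8, 4.5), 0))
        fail_vls.append((v_day, max(value, 60.0)))
        s = switch
    segments.append((s, None, current_combo))
    return segments, fail_vls


def _loguniform(rng, lo, hi):
    return float(np.round(10 ** rng.uniform(np.log10(lo), np.log10(hi)), 0))


def _assay_limit(day: date) -> float:
    return 50.0 if day.year < 2005 else 20.0


def generate_cohort(config: ScenarioConfig, seed: Optional[int] = None) -> tuple:
    """Generate the five registry tables plus the planted-label table.

    Returns ``(tables, labels)`` where ``tables`` matches the loader's typed
    form and ``labels`` holds each person's intended category flags and
    intended outcomes. Identical (config, seed) pairs produce byte-identical
    CSV output through :func:`dtthiv.io.write_tables`.
    """
    cfg = replace(config)
    if all(p == 0 for p in cfg.prevalence.values()):
        cfg.difficult_prevalence = 0.0
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ConfigError("a seed is required (config.seed or the seed argument)")
    rng = np.random.default_rng(seed)
    n = cfg.n_persons
    index = cfg.index_date

    # --- planted category flags -------------------------------------------
    flags = np.zeros((n, 5), dtype=bool)
    if n and cfg.difficult_prevalence > 0:
        difficult = rng.random(n) < cfg.difficult_prevalence
        masks, probs = subset_distribution(cfg)
        chosen = rng.choice(masks, size=int(difficult.sum()), p=probs)
        flags[difficult] = [[m >> i & 1 for i in range(5)] for m in chosen]
    difficult = flags.any(axis=1)

    # --- vectorized demographics ------------------------------------------
    woman = rng.random(n) < np.where(difficult, 0.45, 0.39)
    sex_missing = rng.random(n) < 0.0025
    age = np.clip(rng.normal(np.where(difficult, 53.0, 50.5), 12.0), 20.0, 88.0)
    diag_year = np.clip(
        rng.normal(np.where(difficult, 2002.0, 2008.5), 8.0), 1985, index.year
    )
    first_cd4 = np.clip(
        np.exp(rng.normal(np.log(np.where(difficult, 295.0, 370.0)), 0.75)), 1, 2000
    ).round(0)
    nadir_cd4 = np.minimum(
        first_cd4,
        np.clip(
            np.exp(rng.normal(np.log(np.where(difficult, 120.0, 246.0)), 0.85)),
            1, 1500,
        ).round(0),
    )
    first_vl = np.clip(
        rng.normal(np.where(difficult, 4.7, 4.4), 1.1), 1.3, 7.2
    ).round(1)
    risk_cum_nd = np.cumsum([0.51, 0.32, 0.04, 0.115, 0.015])
    risk_cum_d = np.cumsum([0.54, 0.28, 0.04, 0.135, 0.005])
    risk_levels = np.array(["heterosexual", "MSM", "IDU", "other", "missing"])
    u = rng.random(n)
    risk = np.where(
        difficult,
        risk_levels[np.searchsorted(risk_cum_d, u)],
        risk_levels[np.searchsorted(risk_cum_nd, u)],
    )
    born_se = rng.random(n) < np.where(difficult, 0.31, 0.33)
    born_missing = rng.random(n) < 0.01
    year_missing = rng.random(n) < 0.018
    cd4_missing = rng.random(n) < 0.004
    fvl_missing = rng.random(n) < 0.002

    # --- outcome intents ---------------------------------------------------
    p_nd = cfg.suppression_prob["non_difficult"]
    if cfg.suppression_or is not None:
        odds = cfg.suppression_or * p_nd / (1 - p_nd)
        p_d = odds / (1 + odds)
    else:
        p_d = cfg.suppression_prob["difficult"]
    # category override: recent-failure members suppress at their own rate;
    # the rest of the difficult group compensates so the overall difficult
    # rate still equals its target in expectation
    p_rvf = cfg.suppression_prob.get("recent_virologic_failure", p_d)
    share_d = cfg.difficult_prevalence
    share_rvf = cfg.prevalence["recent_virologic_failure"]
    if share_d > share_rvf > 0 and p_rvf != p_d:
        p_base = (p_d * share_d - p_rvf * share_rvf) / (share_d - share_rvf)
        p_base = min(max(p_base, 0.0), 1.0)
    else:
        p_base = p_d
    p_person = np.where(
        difficult, np.where(flags[:, RVF], p_rvf, p_base), p_nd
    )
    supp_intent = rng.random(n) < p_person
    recent_starter = (~difficult) & (rng.random(n) < cfg.recent_starter_frac)
    stale_vl = (
        (~difficult) & ~recent_starter & (rng.random(n) < cfg.stale_vl_frac)
    )
    has_q = rng.random(n) < cfg.questionnaire_coverage
    old_q_only = (~has_q) & (rng.random(n) < 0.04)
    phys_sat = rng.random(n) < np.where(
        difficult,
        cfg.physical_satisfaction_prob["difficult"],
        cfg.physical_satisfaction_prob["non_difficult"],
    )
    psych_sat = rng.random(n) < np.where(
        difficult,
        cfg.psychological_satisfaction_prob["difficult"],
        cfg.psychological_satisfaction_prob["non_difficult"],
    )
    phys_item_missing = rng.random(n) < 0.003
    psych_item_missing = rng.random(n) < 0.003
    adh_cum_d = np.cumsum([0.82, 0.14, 0.04])
    adh_cum_nd = np.cumsum([0.883, 0.104, 0.013])
    u = rng.random(n)
    adh_band = np.where(
        difficult, np.searchsorted(adh_cum_d, u), np.searchsorted(adh_cum_nd, u)
    ).clip(0, 2)
    # resistance testing: plants always tested; the base rate among everyone
    # else is solved so the configured cohort-wide coverage holds on average.
    p_ar = cfg.prevalence["advanced_resistance"]
    p_d_other = max(cfg.difficult_prevalence - p_ar, 0.0)
    p_nd_share = 1 - cfg.difficult_prevalence
    base = cfg.resistance_coverage - p_ar - 0.9 * p_d_other
    base = min(max(base / p_nd_share, 0.0), 1.0) if p_nd_share > 0 else 0.0
    u = rng.random(n)
    tested = np.where(
        flags[:, AR], True, np.where(difficult, u < 0.9, u < base)
    )

    # --- per-person history construction -----------------------------------
    person_rows, episode_rows, vl_rows, res_rows, q_rows, label_rows = (
        [], [], [], [], [], []
    )
    pid_width = max(6, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{pid_width}d}"
        f = flags[i]
        diag = date(int(diag_year[i]), 1, 1) + timedelta(
            days=int(rng.uniform(0, 364))
        )
        art_start = diag + timedelta(days=int(rng.uniform(30, 400)))
        if recent_starter[i]:
            art_start = index - timedelta(days=int(rng.uniform(10, 175)))
        if f[RVF]:
            art_start = min(art_start, index - timedelta(days=1950))
        if f[MSF]:
            art_start = min(art_start, index - timedelta(days=2400))
        if f[FDR] or f[ST]:
            art_start = min(art_start, index - timedelta(days=600))
        if stale_vl[i]:
            art_start = min(art_start, index - timedelta(days=1000))
        art_start = min(art_start, index - timedelta(days=10))
        diag = min(diag, art_start - timedelta(days=20))
        # anyone who started therapy < 6 months before the index date is
        # excluded from the suppression analysis, so their intended outcome
        # is undefined regardless of how they were sampled
        is_recent = (index - art_start).days < 183

        current = _current_combo(rng, f)
        if f[MSF]:
            segments, fail_vls = _msf_history(rng, art_start, index, f, current)
        else:
            segments, fail_vls = _plain_history(
                rng, art_start, index, f, current, allow_gap=not difficult[i]
            )

        for seg_start, seg_end, combo in segments:
            for code, dosing in combo:
                episode_rows.append((pid, code, seg_start, seg_end, dosing))

        # viral loads ------------------------------------------------------
        vls = [(diag, float(np.round(10 ** first_vl[i], 0)), False)]
        decline_day = art_start + timedelta(days=int(rng.uniform(20, 80)))
        if decline_day < index:
            vls.append((decline_day, float(int(rng.uniform(51, 190))), False))
        t = art_start + timedelta(days=int(rng.uniform(120, 200)))
        if stale_vl[i]:
            routine_end = index - timedelta(days=int(rng.uniform(400, 900)))
        else:
            routine_end = index - timedelta(days=int(rng.uniform(70, 170)))
        lo, hi = cfg.vl_interval_days
        while t <= routine_end:
            vls.append((t, _assay_limit(t), True))
            t += timedelta(days=int(rng.uniform(lo, hi)))
        for day, value in fail_vls:
            vls.append((day, value, False))
        if f[RVF]:
            t1 = index - timedelta(days=int(rng.uniform(270, 355)))
            t2 = min(
                t1 + timedelta(days=int(rng.uniform(95, 240))),
                index - timedelta(days=70),
            )
            vls.append((t1, _loguniform(rng, 220, 80000), False))
            vls.append((t2, _loguniform(rng, 220, 80000), False))
        if stale_vl[i]:
            supp_label = None
        elif is_recent:
            supp_label = None  # excluded from the suppression analysis
            vls.append(
                (index - timedelta(days=int(rng.uniform(3, 9))),
                 _loguniform(rng, 25, 5000), False)
            )
        elif supp_intent[i]:
            day = index - timedelta(days=int(rng.uniform(3, 60)))
            vls.append((day, _assay_limit(day), True))
            supp_label = True
        else:
            day = index - timedelta(days=int(rng.uniform(3, 60)))
            vls.append((day, _loguniform(rng, 60, 20000), False))
            supp_label = False
        vls.sort(key=lambda r: r[0])
        vl_rows.extend((pid, d, v, bl) for d, v, bl in vls if d <= index)

        # resistance -------------------------------------------------------
        if tested[i]:
            span = max((index - art_start).days - 60, 30)
            tdate = art_start + timedelta(days=int(rng.uniform(30, span + 30)))
            tdate = min(tdate, index)
            if f[AR]:
                pairs = (
                    (("3TC", "high"), ("EFV", "high")),
                    (("3TC", "high"), ("NVP", "intermediate")),
                    (("FTC", "high"), ("LPV", "intermediate")),
                    (("AZT", "intermediate"), ("EFV", "high")),
                    (("TDF", "intermediate"), ("RAL", "high")),
                )[rng.integers(5)]
                res = list(pairs)
                if rng.random() < 0.5:
                    res.append(("FTC", "high"))
                res.append(("DRV", "susceptible"))
            else:
                u2 = rng.random()
                if u2 < 0.60:
                    res = [("3TC", "susceptible"), ("EFV", "susceptible"),
                           ("DRV", "susceptible")]
                elif u2 < 0.85:  # archived single-class resistance
                    res = [("3TC", "high"), ("FTC", "high"),
                           ("DRV", "susceptible")]
                else:  # a single drug at intermediate level
                    res = [("EFV", "intermediate"), ("3TC", "low"),
                           ("DRV", "susceptible")]
            res_rows.extend((pid, tdate, code, lvl) for code, lvl in res)

        # questionnaires -----------------------------------------------------
        phys_label = psych_label = None
        if has_q[i]:
            qd = index - timedelta(days=int(rng.uniform(0, 700)))
            phys = None if phys_item_missing[i] else int(
                rng.integers(5, 7) if phys_sat[i] else rng.integers(1, 5)
            )
            psych = None if psych_item_missing[i] else int(
                rng.integers(5, 7) if psych_sat[i] else rng.integers(1, 5)
            )
            missed = (0, int(rng.integers(1, 3)), int(rng.integers(3, 10)))[
                int(adh_band[i])
            ]
            q_rows.append((pid, qd, phys, psych, missed))
            phys_label = None if phys is None else bool(phys >= 5)
            psych_label = None if psych is None else bool(psych >= 5)
        elif old_q_only[i]:
            qd = index - timedelta(days=int(rng.uniform(760, 1500)))
            q_rows.append((pid, qd, int(rng.integers(1, 7)),
                           int(rng.integers(1, 7)), int(rng.integers(0, 3))))

        birth = index - timedelta(days=int(age[i] * 365.25))
        person_rows.append(
            (
                pid,
                "missing" if sex_missing[i] else ("woman" if woman[i] else "man"),
                birth,
                None if year_missing[i] else diag.year,
                str(risk[i]),
                None if born_missing[i] else bool(born_se[i]),
                None if cd4_missing[i] else float(first_cd4[i]),
                None if cd4_missing[i] else float(nadir_cd4[i]),
                None if fvl_missing[i] else float(first_vl[i]),
            )
        )
        label_rows.append(
            (pid, *[bool(v) for v in f], bool(difficult[i]), supp_label,
             phys_label, psych_label)
        )

    tables = {
        "persons": pd.DataFrame(person_rows, columns=TABLE_COLUMNS["persons"]),
        "regimen_episodes": pd.DataFrame(
            episode_rows, columns=TABLE_COLUMNS["regimen_episodes"]
        ),
        "viral_loads": pd.DataFrame(
            vl_rows, columns=TABLE_COLUMNS["viral_loads"]
        ),
        "resistance": pd.DataFrame(res_rows, columns=TABLE_COLUMNS["resistance"]),
        "questionnaires": pd.DataFrame(
            q_rows, columns=TABLE_COLUMNS["questionnaires"]
        ),
    }
    tables["persons"]["first_positive_test_year"] = pd.array(
        tables["persons"]["first_positive_test_year"], dtype="Int64"
    )
    for col in ("physical_health", "psychological_health", "missed_doses_last_week"):
        tables["questionnaires"][col] = pd.array(
            tables["questionnaires"][col], dtype="Int64"
        )
    labels = pd.DataFrame(
        label_rows,
        columns=["person_id", *CATEGORY_NAMES, "difficult", "suppressed",
                 "physical_satisfied", "psychological_satisfied"],
    )
    return tables, labels


def generate_adversarial_histories(index_date: date = date(2023, 4, 6)) -> tuple:
    """Hand-constructed boundary cases with hand-derived expected flags.

    Each case sits exactly on (or one day off) a rule threshold: viral loads
    90 vs 89 days apart, values 200 vs 199, switches 183 vs 184 days after a
    failing measurement, exactly 1826 vs 1825 cumulative therapy days,
    regimens of exactly four non-booster drugs with and without a prior 2-3
    drug regimen, and twice-daily darunavir with and without a booster.

    Returns ``(tables, expected)`` in the same typed-table form as
    :func:`generate_cohort`; ``expected`` has one row of intended flags per
    case, derived by hand from the documented conventions.
    """
    idx = index_date
    persons, episodes, vls, res = [], [], [], []
    expected = []

    def day(back: int) -> date:
        return idx - timedelta(days=back)

    def add(pid, eps, vl_list=(), res_list=(), **flags):
        persons.append((pid, "man", date(1975, 6, 15), 2000, "heterosexual",
                        True, 400.0, 250.0, 4.5))
        episodes.extend(eps)
        vls.extend(vl_list)
        res.extend(res_list)
        row = {name: False for name in CATEGORY_NAMES}
        row.update(flags)
        expected.append({"person_id": pid, **row,
                         "difficult": any(row.values())})

    def regimen(pid, codes, start, end=None, dosing=None):
        return [(pid, c, start, end, (dosing or {}).get(c, "QD")) for c in codes]

    std = ("DTG", "TDF", "FTC")

    # recent virologic failure: spacing boundary (>= 90 days qualifies)
    add("B01", regimen("B01", std, day(3000)),
        [("B01", day(200), 250.0, False), ("B01", day(110), 400.0, False)],
        recent_virologic_failure=True)
    add("B02", regimen("B02", std, day(3000)),
        [("B02", day(200), 250.0, False), ("B02", day(111), 400.0, False)])
    # value boundary (>= 200 qualifies)
    add("B03", regimen("B03", std, day(3000)),
        [("B03", day(300), 200.0, False), ("B03", day(150), 200.0, False)],
        recent_virologic_failure=True)
    add("B04", regimen("B04", std, day(3000)),
        [("B04", day(300), 199.0, False), ("B04", day(150), 199.0, False)])
    # therapy-duration boundary (>= 1826 days qualifies)
    add("B05", regimen("B05", std, day(1826)),
        [("B05", day(300), 250.0, False), ("B05", day(100), 300.0, False)],
        recent_virologic_failure=True)
    add("B06", regimen("B06", std, day(1825)),
        [("B06", day(300), 250.0, False), ("B06", day(100), 300.0, False)])
    # window boundary: a VL exactly 365 days before the index is outside
    add("B07", regimen("B07", std, day(3000)),
        [("B07", day(365), 500.0, False), ("B07", day(100), 500.0, False)])

    # multiple switches after failure: switch-gap boundary (<= 183 qualifies)
    def switch_case(pid, gap, anchor_shift=0, expect=True):
        s1 = date(2015, 1, 1) + timedelta(days=anchor_shift)
        v1 = s1 + timedelta(days=120)
        e1 = v1 + timedelta(days=gap)
        v2 = e1 + timedelta(days=90)
        e2 = v2 + timedelta(days=gap)
        eps = (
            regimen(pid, ("EFV", "AZT", "3TC"), s1, e1)
            + regimen(pid, ("LPV", "RTV", "TDF", "FTC"), e1, e2)
            + regimen(pid, std, e2)
        )
        add(pid, eps,
            [(pid, v1, 60.0, False), (pid, v2, 70.0, False)],
            multi_switch_failure=expect)

    switch_case("B08", gap=183, expect=True)
    switch_case("B09", gap=184, expect=False)
    # both failing VLs before the 2008 anchor do not count
    switch_case("B10", gap=100, anchor_shift=-365 * 9, expect=False)

    # four-drug regimen: needs >= 4 non-booster drugs now AND a 2-3 drug past
    four = ("DRV", "RTV", "DTG", "TDF", "FTC")  # 4 non-booster
    add("B11", regimen("B11", std, day(3000), day(1000))
        + regimen("B11", four, day(1000)),
        four_drug_regimen=True)
    add("B12", regimen("B12", ("EFV", "AZT", "3TC", "ABC"), day(3000), day(1000))
        + regimen("B12", four, day(1000)))  # never on a 2-3 drug regimen
    add("B13", regimen("B13", std, day(3000), day(1000))
        + regimen("B13", ("DRV", "RTV", "TDF", "FTC"), day(1000)))  # only 3 now

    # salvage therapy: BID darunavir needs a booster; BID dolutegravir counts
    add("B14", regimen("B14", ("DRV", "RTV", "TDF", "FTC"), day(1000),
                       dosing={"DRV": "BID"}),
        salvage_therapy=True)
    add("B15", regimen("B15", ("DRV", "TDF", "FTC"), day(1000),
                       dosing={"DRV": "BID"}))
    add("B16", regimen("B16", ("DTG", "3TC"), day(1000),
                       dosing={"DTG": "BID"}),
        salvage_therapy=True)
    add("B17", regimen("B17", ("DTG", "3TC"), day(1000),
                       dosing={"DTG": "UNKNOWN"}))
    add("B18", regimen("B18", ("ETR", "TDF", "FTC"), day(1000)),
        salvage_therapy=True)
    # a regimen ending exactly on the index date is no longer current
    add("B19", regimen("B19", ("ETR", "TDF", "FTC"), day(1000), idx))

    # advanced resistance: >= 2 drugs at >= intermediate across >= 2 classes
    add("B20", regimen("B20", std, day(1000)),
        res_list=[("B20", day(500), "3TC", "high"),
                  ("B20", day(500), "EFV", "intermediate")],
        advanced_resistance=True)
    add("B21", regimen("B21", std, day(1000)),
        res_list=[("B21", day(500), "3TC", "high"),
                  ("B21", day(500), "FTC", "high")])  # one class only
    add("B22", regimen("B22", std, day(1000)),
        res_list=[("B22", day(500), "EFV", "low"),
                  ("B22", day(500), "DRV", "low")])  # below intermediate
    add("B23", regimen("B23", std, day(1000)),
        res_list=[("B23", day(500), "DRV", "high")])  # a single drug
    # cumulative across tests: one drug per test, two tests
    add("B24", regimen("B24", std, day(1000)),
        res_list=[("B24", day(900), "3TC", "high"),
                  ("B24", day(400), "EFV", "high")],
        advanced_resistance=True)

    tables = {
        "persons": pd.DataFrame(persons, columns=TABLE_COLUMNS["persons"]),
        "regimen_episodes": pd.DataFrame(
            episodes, columns=TABLE_COLUMNS["regimen_episodes"]
        ),
        "viral_loads": pd.DataFrame(
            [(p, d, v, bl) for p, d, v, bl in vls],
            columns=TABLE_COLUMNS["viral_loads"],
        ),
        "resistance": pd.DataFrame(res, columns=TABLE_COLUMNS["resistance"]),
        "questionnaires": pd.DataFrame(
            columns=TABLE_COLUMNS["questionnaires"]
        ),
    }
    tables["persons"]["first_positive_test_year"] = pd.array(
        tables["persons"]["first_positive_test_year"], dtype="Int64"
    )
    for col in ("physical_health", "psychological_health", "missed_doses_last_week"):
        tables["questionnaires"][col] = pd.array(
            tables["questionnaires"][col], dtype="Int64"
        )
    return tables, pd.DataFrame(expected)
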