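"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately re-derive results by brute force
(day-by-day scans, all-pairs searches, exact permutation enumeration) so the
implementation under test is checked against an independent path.
"""

from __future__ import annotations

from datetime import date, timedelta
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from dtthiv import Person, RegimenEpisode, ViralLoad, default_catalog

INDEX = date(2023, 4, 6)

# boosters excluded: oracle histories keep drug sets == non-booster sets
ORACLE_DRUGS = ["DTG", "TDF", "FTC", "EFV", "3TC", "ABC", "DRV", "RAL", "AZT", "NVP"]


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture
def index_date():
    return INDEX


def episodes_from_segments(pid, segments):
    """One episode per drug per segment; segments are (start, end, drugs)."""
    return [
        RegimenEpisode(person_id=pid, drug_code=d, start_date=s, end_date=e)
        for s, e, drugs in segments
        for d in sorted(drugs)
    ]


def random_segments(rng, index=INDEX, allow_gaps=True):
    """A random regimen history as explicit ground-truth segments.

    Consecutive segments always differ in drug set, so rebuilding regimens
    from the emitted episodes reproduces exactly these intervals.
    """
    n_seg = int(rng.integers(1, 6))
    start = index - timedelta(days=int(rng.integers(400, 3000)))
    segments = []
    t = start
    prev = None
    for j in range(n_seg):
        for _ in range(50):
            drugs = frozenset(
                rng.choice(ORACLE_DRUGS, size=int(rng.integers(1, 5)), replace=False)
            )
            if drugs != prev:
                break
        dur = int(rng.integers(60, 900))
        end = t + timedelta(days=dur)
        is_last = j == n_seg - 1
        if is_last and rng.random() < 0.7:
            end = None  # ongoing
        segments.append((t, end, drugs))
        prev = drugs
        if end is None:
            break
        t = end
        if allow_gaps and rng.random() < 0.3:
            t = t + timedelta(days=int(rng.integers(1, 300)))
    return segments


def random_viral_loads(rng, pid, index=INDEX, span_days=3200, n_max=15):
    vls = []
    for _ in range(int(rng.integers(0, n_max))):
        d = index - timedelta(days=int(rng.integers(0, span_days)))
        kind = rng.random()
        if kind < 0.4:
            vls.append(ViralLoad(pid, d, 20.0, below_limit=True))
        else:
            value = float(rng.choice([30, 49, 50, 60, 150, 199, 200, 250, 1000, 50000]))
            vls.append(ViralLoad(pid, d, value, below_limit=False))
    return vls


def random_person(rng, pid="X1", index=INDEX):
    """Random history plus its ground-truth segments."""
    segments = random_segments(rng, index)
    person = Person(
        person_id=pid,
        episodes=episodes_from_segments(pid, segments),
        viral_loads=random_viral_loads(rng, pid, index),
    )
    return person, segments


# --- independent oracles ----------------------------------------------------

def day_sweep_day_sets(episodes, horizon):
    """Active drug set for every day from the earliest start to ``horizon``."""
    if not episodes:
        return []
    first = min(e.start_date for e in episodes)
    out = []
    d = first
    while d < horizon:
        out.append(frozenset(e.drug_code for e in episodes if e.active_on(d)))
        d += timedelta(days=1)
    return out


def art_days_oracle(episodes, index):
    """Brute-force day count of on-treatment time before the index date."""
    return sum(1 for s in day_sweep_day_sets(episodes, index) if s)


def recent_vf_oracle(person, index, art_days):
    """All-pairs search for the recent-virologic-failure rule."""
    window = [
        v
        for v in person.viral_loads
        if (not v.below_limit)
        and v.value_copies_per_ml >= 200
        and timedelta(days=0) <= index - v.date < timedelta(days=365)
    ]
    for v1, v2 in combinations(window, 2):
        if abs((v1.date - v2.date).days) >= 90 and art_days >= 1826:
            return True
    return False


def multi_switch_oracle(segments, viral_loads):
    """Adjacent-pairs enumeration for the switch-after-failure rule."""
    def fails(i):
        if i + 1 >= len(segments):
            return False
        next_start = segments[i + 1][0]
        s, e, _ = segments[i]
        for v in viral_loads:
            if v.below_limit or v.value_copies_per_ml < 50:
                continue
            if v.date < date(2008, 1, 1):
                continue
            if s <= v.date and (e is None or v.date < e):
                if (next_start - v.date).days <= 183:
                    return True
        return False

    flags = [fails(i) for i in range(len(segments))]
    return any(a and b for a, b in zip(flags, flags[1:]))


def exact_mann_whitney_p(a, b):
    """Exact two-sided permutation p-value for the Mann-Whitney U statistic."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = rankdata(pooled)
    mu = na * len(b) / 2

    def u_for(idx):
        return ranks[list(idx)].sum() - na * (na + 1) / 2

    dev = abs(u_for(range(na)) - mu)
    count = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(u_for(idx) - mu) >= dev - 1e-9:
            count += 1
    return count / total
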