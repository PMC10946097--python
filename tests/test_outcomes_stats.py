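"""Outcome derivation and the statistical machinery behind the group tables."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from dtthiv import (
    Person,
    Questionnaire,
    RegimenEpisode,
    ViralLoad,
    chi_squared,
    derive_outcomes,
    dichotomize_satisfaction,
    mann_whitney,
    odds_ratio_2x2,
    pro_outcomes,
    suppression_outcome,
)
from dtthiv.stats import (
    fit_outcome_models,
    sensitivity_excluding_recent_vf,
)

from conftest import INDEX, exact_mann_whitney_p


def person(vls=(), episodes=(), qs=(), pid="P1"):
    return Person(pid, episodes=list(episodes), viral_loads=list(vls),
                  questionnaires=list(qs))


def art(start_days_before, pid="P1"):
    return [RegimenEpisode(pid, "DTG", INDEX - timedelta(days=start_days_before))]


def vl(days_before, value, below=False, pid="P1"):
    return ViralLoad(pid, INDEX - timedelta(days=days_before), value, below)


class TestSuppressionOutcome:
    def test_below_limit_recent_vl_is_suppressed(self):
        p = person([vl(60, 20, below=True)], art(2000))
        assert suppression_outcome(p, INDEX) == (True, True)

    def test_high_last_vl_not_suppressed(self):
        p = person([vl(200, 20, below=True), vl(60, 320)], art(2000))
        assert suppression_outcome(p, INDEX) == (True, False)

    def test_recent_art_start_excluded(self):
        p = person([vl(30, 20, below=True)], art(90))
        assert suppression_outcome(p, INDEX) == (False, None)

    def test_exclusion_boundary_183_days(self):
        assert suppression_outcome(person([vl(30, 20, True)], art(183)), INDEX)[0]
        assert not suppression_outcome(person([vl(30, 20, True)], art(182)), INDEX)[0]

    def test_no_recent_vl_is_missing(self):
        p = person([vl(400, 20, below=True)], art(2000))
        assert suppression_outcome(p, INDEX) == (True, None)

    def test_last_vl_judged_even_if_older_vl_higher(self):
        p = person([vl(300, 100000), vl(30, 20, below=True)], art(2000))
        assert suppression_outcome(p, INDEX) == (True, True)

    def test_below_limit_above_threshold_not_suppressed(self):
        # a "<400" result does not demonstrate RNA < 50
        p = person([vl(30, 400, below=True)], art(2000))
        assert suppression_outcome(p, INDEX) == (True, False)


class TestProOutcomes:
    def test_dichotomization(self):
        assert dichotomize_satisfaction(5) and dichotomize_satisfaction(6)
        assert not dichotomize_satisfaction(4)
        with pytest.raises(ValueError):
            dichotomize_satisfaction(7)

    def test_window_and_item_missingness(self):
        q_old = Questionnaire("P1", INDEX - timedelta(days=800), 6, 6, 0)
        q_new = Questionnaire("P1", INDEX - timedelta(days=100), 5, None, 2)
        p = person(qs=[q_old, q_new])
        phys, psych, band = pro_outcomes(p, INDEX)
        assert phys is True and psych is None and band == "1-2"
        phys, psych, band = pro_outcomes(person(qs=[q_old]), INDEX)
        assert phys is None and psych is None and band == "missing"

    def test_most_recent_questionnaire_wins(self):
        qs = [
            Questionnaire("P1", INDEX - timedelta(days=600), 2, 2, 5),
            Questionnaire("P1", INDEX - timedelta(days=50), 6, 6, 0),
        ]
        assert pro_outcomes(person(qs=qs), INDEX) == (True, True, "0")


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0

    def test_identical_groups_p_near_one(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_matches_exact_permutation_p(self):
        rng = np.random.default_rng(12345)
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(0.8, 1, 8)
            _, p = mann_whitney(a, b)
            assert abs(p - exact_mann_whitney_p(a, b)) < 0.02

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        u1, p1 = mann_whitney(a, b)
        u2, p2 = mann_whitney(np.exp(a), np.exp(b))
        assert u1 == u2 and p1 == pytest.approx(p2)


class TestChiSquared:
    def test_homogeneous_table_zero_statistic(self):
        stat, p = chi_squared([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # sum (O-E)^2/E with margins 30/30 and 30/30: every E = 15
        stat, _ = chi_squared([[20, 10], [10, 20]])
        assert stat == pytest.approx(20 / 3)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 60, size=4)
            stat, _ = chi_squared([[a, b], [c, d]])
            n = a + b + c + d
            closed = (a * d - b * c) ** 2 * n / (
                (a + b) * (c + d) * (a + c) * (b + d)
            )
            assert stat == pytest.approx(closed)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[0, 0], [5, 3]])


class TestOddsRatio:
    def test_null_table(self):
        est = odds_ratio_2x2(10, 10, 10, 10)
        assert est.odds_ratio == pytest.approx(1.0)

    def test_arithmetic(self):
        est = odds_ratio_2x2(20, 10, 10, 20)
        assert est.odds_ratio == pytest.approx(4.0)

    def test_zero_cell_rejected(self):
        with pytest.raises(ValueError, match="zero cell"):
            odds_ratio_2x2(0, 10, 10, 10)

    def test_ci_brackets_estimate_on_random_tables(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 80, size=4)
            est = odds_ratio_2x2(a, b, c, d)
            assert est.ci_low <= est.odds_ratio <= est.ci_high


def _toy_analysis_frames(rng, n=600, p_exposed=0.3, p_out_exposed=0.4,
                         p_out_unexposed=0.6):
    """Simple flag/outcome/covariate frames, independent of the cohort generator."""
    exposed = rng.random(n) < p_exposed
    outcome = rng.random(n) < np.where(exposed, p_out_exposed, p_out_unexposed)
    pid = [f"P{i}" for i in range(n)]
    flags = pd.DataFrame(
        {
            "person_id": pid,
            "advanced_resistance": exposed,
            "four_drug_regimen": False,
            "salvage_therapy": False,
            "recent_virologic_failure": False,
            "multi_switch_failure": False,
            "difficult": exposed,
        }
    )
    outcomes = pd.DataFrame(
        {
            "person_id": pid,
            "eligible_suppression": True,
            "suppressed": pd.array(outcome, dtype="boolean"),
            "eligible_pro": False,
            "physical_satisfied": pd.array([None] * n, dtype="boolean"),
            "psychological_satisfied": pd.array([None] * n, dtype="boolean"),
            "adherence_band": "missing",
        }
    )
    covariates = pd.DataFrame(
        {
            "person_id": pid,
            "sex_at_birth": rng.choice(["man", "woman"], n),
            "age_years": rng.uniform(20, 80, n),
            "risk_group": rng.choice(["heterosexual", "MSM", "IDU", "other"], n),
        }
    )
    return flags, outcomes, covariates


class TestOutcomeModels:
    def test_crude_logistic_equals_2x2(self):
        rng = np.random.default_rng(10)
        flags, outcomes, cov = _toy_analysis_frames(rng)
        ests = fit_outcome_models(flags, outcomes, cov)
        crude = [e for e in ests if e.outcome == "viral_suppression" and not e.adjusted][0]
        direct = odds_ratio_2x2(*crude.counts)
        assert crude.odds_ratio == pytest.approx(direct.odds_ratio, rel=1e-6)
        assert crude.ci_low == pytest.approx(direct.ci_low, rel=1e-4)
        assert crude.ci_high == pytest.approx(direct.ci_high, rel=1e-4)

    def test_permuted_exposure_gives_null_or(self):
        rng = np.random.default_rng(14)
        flags, outcomes, cov = _toy_analysis_frames(rng, n=4000)
        perm = rng.permutation(flags["difficult"].to_numpy())
        flags["difficult"] = perm
        ests = fit_outcome_models(flags, outcomes, cov)
        crude = [e for e in ests if not e.adjusted][0]
        assert 0.75 < crude.odds_ratio < 1.33

    def test_adjusted_log_or_recovery(self):
        # logistic data generated with a true adjusted log-OR of -1.0
        rng = np.random.default_rng(22)
        n = 5000
        exposed = rng.random(n) < 0.3
        age = rng.uniform(25, 75, n)
        woman = rng.random(n) < 0.4
        logit = 0.5 - 1.0 * exposed + 0.01 * (age - 50) + 0.2 * woman
        outcome = rng.random(n) < 1 / (1 + np.exp(-logit))
        flags, outcomes, cov = _toy_analysis_frames(rng, n)
        flags["difficult"] = exposed
        outcomes["suppressed"] = pd.array(outcome, dtype="boolean")
        cov["age_years"] = age
        cov["sex_at_birth"] = np.where(woman, "woman", "man")
        ests = fit_outcome_models(flags, outcomes, cov)
        adjusted = [e for e in ests if e.outcome == "viral_suppression" and e.adjusted][0]
        assert abs(np.log(adjusted.odds_ratio) - (-1.0)) < 0.15

    def test_pro_missingness_shrinks_n(self):
        rng = np.random.default_rng(30)
        flags, outcomes, cov = _toy_analysis_frames(rng)
        phys = pd.array(rng.random(len(flags)) < 0.6, dtype="boolean")
        phys[rng.random(len(flags)) < 0.2] = pd.NA
        outcomes["physical_satisfied"] = phys
        ests = fit_outcome_models(flags, outcomes, cov)
        crude_phys = [
            e for e in ests
            if e.outcome == "physical_health_satisfaction" and not e.adjusted
        ][0]
        assert crude_phys.n_analyzed == int(pd.Series(phys).notna().sum())


class TestSensitivityAnalysis:
    def test_all_difficult_recent_vf_is_degenerate(self):
        rng = np.random.default_rng(40)
        flags, outcomes, _ = _toy_analysis_frames(rng, n=200)
        flags["recent_virologic_failure"] = flags["difficult"]
        res = sensitivity_excluding_recent_vf(flags, outcomes)
        assert res.degenerate
        assert res.n_difficult == 0

    def test_no_recent_vf_identical_to_main(self):
        rng = np.random.default_rng(41)
        flags, outcomes, _ = _toy_analysis_frames(rng, n=500)
        res = sensitivity_excluding_recent_vf(flags, outcomes)
        crude = fit_outcome_models(flags, outcomes)[0]
        assert res.or_estimate.counts == crude.counts
        assert res.or_estimate.odds_ratio == pytest.approx(crude.odds_ratio, rel=1e-6)


class TestDeriveOutcomes:
    def test_columns_and_missingness(self):
        persons = [
            person([vl(30, 20, below=True)], art(2000), pid="A"),
            person([vl(30, 5000)], art(90), pid="B"),  # recent starter
            person([], art(2000), pid="C"),  # no viral load at all
        ]
        df = derive_outcomes(persons, INDEX)
        df = df.set_index("person_id")
        assert bool(df.loc["A", "suppressed"]) is True
        assert df.loc["B", "eligible_suppression"] == False  # noqa: E712
        assert pd.isna(df.loc["B", "suppressed"])
        assert pd.isna(df.loc["C", "suppressed"])
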