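"""The five category rules: worked examples, oracles, and invariants."""

from datetime import date, timedelta
from itertools import combinations

import numpy as np
import pytest

from dtthiv import (
    Person,
    RegimenEpisode,
    ResistanceResult,
    ViralLoad,
    art_duration_days,
    classify_advanced_resistance,
    classify_cohort,
    classify_four_drug_regimen,
    classify_multi_switch_failure,
    classify_person,
    classify_recent_virologic_failure,
    classify_salvage_therapy,
)
from dtthiv.catalog import UnknownDrugError

from conftest import (
    INDEX,
    multi_switch_oracle,
    random_person,
    random_viral_loads,
    recent_vf_oracle,
)


def person_with(episodes=(), vls=(), res=(), pid="P1"):
    return Person(pid, episodes=list(episodes), viral_loads=list(vls),
                  resistance=list(res))


def regimen_eps(drugs, start, end=None, pid="P1", dosing=None):
    return [
        RegimenEpisode(pid, d, start, end, (dosing or {}).get(d, "QD"))
        for d in drugs
    ]


def res(drug, level, day=date(2015, 1, 1), pid="P1"):
    return ResistanceResult(pid, day, drug, level)


def vl(days_before_index, value, below=False, pid="P1"):
    return ViralLoad(pid, INDEX - timedelta(days=days_before_index), value, below)


class TestAdvancedResistance:
    @pytest.mark.parametrize(
        "results, expected",
        [
            ([("EFV", "high"), ("3TC", "high")], True),  # NNRTI + NRTI
            ([("3TC", "high"), ("FTC", "intermediate")], False),  # one class
            ([("EFV", "low"), ("DRV", "low")], False),  # below intermediate
            ([("EFV", "intermediate"), ("DRV", "intermediate")], True),
            ([], False),  # never tested
        ],
    )
    def test_examples(self, catalog, results, expected):
        p = person_with(res=[res(d, lv) for d, lv in results])
        assert classify_advanced_resistance(p, catalog) is expected

    def test_cumulative_over_tests(self, catalog):
        p = person_with(
            res=[
                res("3TC", "high", date(2009, 1, 1)),
                res("EFV", "high", date(2016, 1, 1)),
            ]
        )
        assert classify_advanced_resistance(p, catalog)

    def test_unknown_drug_errors(self, catalog):
        p = person_with(res=[res("QQQ", "high"), res("3TC", "high")])
        with pytest.raises(UnknownDrugError):
            classify_advanced_resistance(p, catalog)

    def test_matches_pairwise_oracle_on_random_level_maps(self, catalog):
        drugs = ["3TC", "FTC", "TDF", "EFV", "NVP", "DRV", "LPV", "DTG", "RAL"]
        levels = ["susceptible", "low", "intermediate", "high"]
        rng = np.random.default_rng(21)
        for _ in range(200):
            chosen = rng.choice(drugs, size=rng.integers(0, 7), replace=False)
            results = [res(d, levels[rng.integers(4)]) for d in chosen]
            p = person_with(res=results)
            strong = {r.drug_code for r in results
                      if r.level in ("intermediate", "high")}
            oracle = any(
                catalog.drug_class(a) != catalog.drug_class(b)
                for a, b in combinations(strong, 2)
            )
            assert classify_advanced_resistance(p, catalog) is oracle

    def test_adding_result_never_revokes(self, catalog):
        rng = np.random.default_rng(2)
        drugs = ["3TC", "FTC", "EFV", "DRV", "DTG"]
        levels = ["susceptible", "low", "intermediate", "high"]
        for _ in range(100):
            results = [
                res(d, levels[rng.integers(4)])
                for d in rng.choice(drugs, size=rng.integers(0, 5), replace=False)
            ]
            p = person_with(res=results)
            before = classify_advanced_resistance(p, catalog)
            extra = res(drugs[rng.integers(5)], levels[rng.integers(4)],
                        date(2020, 1, 1))
            p2 = person_with(res=results + [extra])
            if before:
                assert classify_advanced_resistance(p2, catalog)


class TestFourDrugRegimen:
    def test_four_now_after_triple(self, catalog):
        eps = regimen_eps({"DTG", "3TC", "TDF"}, date(2015, 1, 1), date(2020, 1, 1)) \
            + regimen_eps({"DRV", "RTV", "DTG", "TDF", "FTC"}, date(2020, 1, 1))
        assert classify_four_drug_regimen(person_with(eps), INDEX, catalog)

    def test_lifelong_four_drug_false(self, catalog):
        eps = regimen_eps({"EFV", "AZT", "3TC", "ABC"}, date(2000, 1, 1),
                          date(2020, 1, 1)) \
            + regimen_eps({"DRV", "RTV", "DTG", "TDF", "FTC"}, date(2020, 1, 1))
        assert not classify_four_drug_regimen(person_with(eps), INDEX, catalog)

    def test_current_triple_false(self, catalog):
        eps = regimen_eps({"DTG", "3TC", "TDF"}, date(2015, 1, 1))
        assert not classify_four_drug_regimen(person_with(eps), INDEX, catalog)

    def test_boosters_not_counted(self, catalog):
        # DRV+RTV+TDF+FTC is a 3-drug regimen despite 4 components
        eps = regimen_eps({"DTG", "3TC"}, date(2015, 1, 1), date(2020, 1, 1)) \
            + regimen_eps({"DRV", "RTV", "TDF", "FTC"}, date(2020, 1, 1))
        assert not classify_four_drug_regimen(person_with(eps), INDEX, catalog)


class TestSalvageTherapy:
    @pytest.mark.parametrize(
        "drugs, dosing, expected",
        [
            ({"ETR", "DTG", "TDF"}, {}, True),  # etravirine listed
            ({"DTG", "3TC"}, {}, False),  # QD dolutegravir
            ({"DTG", "3TC"}, {"DTG": "BID"}, True),
            ({"DTG", "3TC"}, {"DTG": "UNKNOWN"}, False),
            ({"DRV", "RTV", "TDF", "FTC"}, {"DRV": "BID"}, True),  # boosted BID
            ({"DRV", "TDF", "FTC"}, {"DRV": "BID"}, False),  # unboosted BID
            ({"DRV", "COBI", "TDF", "FTC"}, {"DRV": "BID"}, True),
            ({"ENF", "DRV", "RTV"}, {}, True),
            ({"MVC", "DTG", "TDF", "FTC"}, {}, True),
        ],
    )
    def test_examples(self, catalog, drugs, dosing, expected):
        p = person_with(regimen_eps(drugs, date(2020, 1, 1), dosing=dosing))
        assert classify_salvage_therapy(p, INDEX, catalog) is expected

    def test_past_salvage_regimen_does_not_count(self, catalog):
        eps = regimen_eps({"ETR", "TDF", "FTC"}, date(2010, 1, 1), date(2015, 1, 1)) \
            + regimen_eps({"DTG", "3TC"}, date(2015, 1, 1))
        assert not classify_salvage_therapy(person_with(eps), INDEX, catalog)


class TestRecentVirologicFailure:
    ART_10Y = regimen_eps({"DTG", "TDF", "FTC"}, INDEX - timedelta(days=3650))

    def test_qualifying_pair_on_long_art(self):
        p = person_with(self.ART_10Y, [vl(300, 250), vl(100, 400)])
        assert classify_recent_virologic_failure(p, INDEX)

    def test_spacing_below_90_days_fails(self):
        p = person_with(self.ART_10Y, [vl(160, 250), vl(100, 400)])
        assert not classify_recent_virologic_failure(p, INDEX)

    def test_short_art_fails(self):
        eps = regimen_eps({"DTG", "TDF", "FTC"}, INDEX - timedelta(days=3 * 365))
        p = person_with(eps, [vl(300, 250), vl(100, 400)])
        assert not classify_recent_virologic_failure(p, INDEX)

    def test_below_limit_results_never_qualify(self):
        p = person_with(self.ART_10Y, [vl(300, 400, below=True), vl(100, 400)])
        assert not classify_recent_virologic_failure(p, INDEX)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            p, _ = random_person(rng)
            art = art_duration_days(p, INDEX)  # checked against day oracle elsewhere
            assert classify_recent_virologic_failure(p, INDEX) is recent_vf_oracle(
                p, INDEX, art
            )

    def test_adding_viral_load_never_revokes(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p, _ = random_person(rng)
            before = classify_recent_virologic_failure(p, INDEX)
            extra = random_viral_loads(rng, p.person_id, n_max=3)
            p2 = Person(p.person_id, episodes=p.episodes,
                        viral_loads=p.viral_loads + extra)
            if before:
                assert classify_recent_virologic_failure(p2, INDEX)


class TestMultiSwitchFailure:
    def build(self, gap1, gap2, year=2015):
        s1 = date(year, 1, 1)
        v1 = s1 + timedelta(days=100)
        e1 = v1 + timedelta(days=gap1)
        v2 = e1 + timedelta(days=60)
        e2 = v2 + timedelta(days=gap2)
        eps = (
            regimen_eps({"EFV", "AZT", "3TC"}, s1, e1)
            + regimen_eps({"LPV", "RTV", "TDF", "FTC"}, e1, e2)
            + regimen_eps({"DTG", "TDF", "FTC"}, e2)
        )
        vls = [
            ViralLoad("P1", v1, 120.0),
            ViralLoad("P1", v2, 80.0),
        ]
        return person_with(eps, vls)

    def test_two_consecutive_failures(self, catalog):
        assert classify_multi_switch_failure(self.build(60, 120), catalog)

    def test_non_consecutive_failures_false(self, catalog):
        # first regimen fails, second is suppressed for years, third fails
        s1 = date(2010, 1, 1)
        e1 = date(2010, 6, 1)
        e2 = date(2018, 1, 1)
        e3 = date(2018, 7, 1)
        eps = (
            regimen_eps({"EFV", "AZT", "3TC"}, s1, e1)
            + regimen_eps({"LPV", "RTV", "TDF", "FTC"}, e1, e2)
            + regimen_eps({"RAL", "TDF", "FTC"}, e2, e3)
            + regimen_eps({"DTG", "TDF", "FTC"}, e3)
        )
        vls = [
            ViralLoad("P1", date(2010, 4, 1), 120.0),  # fails the 1st regimen
            ViralLoad("P1", date(2018, 6, 1), 80.0),  # fails the 3rd regimen
        ]
        assert not classify_multi_switch_failure(person_with(eps, vls), catalog)

    def test_pre_2008_failures_not_counted(self, catalog):
        assert not classify_multi_switch_failure(self.build(60, 120, year=2004),
                                                 catalog)

    def test_booster_only_change_is_not_a_switch(self, catalog):
        # ritonavir swapped for cobicistat within 183 d of a failing VL:
        # the non-booster set is unchanged, so no failure-switch occurs
        s1 = date(2015, 1, 1)
        e1 = date(2016, 1, 1)
        e2 = date(2017, 1, 1)
        eps = (
            regimen_eps({"DRV", "RTV", "TDF", "FTC"}, s1, e1)
            + regimen_eps({"DRV", "COBI", "TDF", "FTC"}, e1, e2)
            + regimen_eps({"DTG", "TDF", "FTC"}, e2)
        )
        vls = [
            ViralLoad("P1", e1 - timedelta(days=30), 120.0),
            ViralLoad("P1", e2 - timedelta(days=30), 90.0),
        ]
        assert not classify_multi_switch_failure(person_with(eps, vls), catalog)
        # without booster collapsing the first transition would look like a switch
        assert classify_multi_switch_failure(person_with(eps, vls), catalog=None)

    def test_matches_adjacent_pairs_oracle(self, catalog):
        rng = np.random.default_rng(31)
        for _ in range(300):
            p, segments = random_person(rng)
            assert classify_multi_switch_failure(p, catalog) is multi_switch_oracle(
                segments, p.viral_loads
            )


class TestClassifyPersonAndCohort:
    def test_no_rule_met(self, catalog):
        p = person_with(regimen_eps({"DTG", "3TC"}, date(2018, 1, 1)))
        flags = classify_person(p, INDEX, catalog)
        assert not flags.difficult
        assert not any(flags.as_dict().values())

    def test_single_flag_sets_difficult(self, catalog):
        p = person_with(
            regimen_eps({"DTG", "3TC"}, date(2018, 1, 1)),
            res=[res("3TC", "high"), res("EFV", "high")],
        )
        flags = classify_person(p, INDEX, catalog)
        assert flags.difficult
        assert flags.advanced_resistance
        assert sum(flags.as_dict()[c] for c in flags.as_dict() if c != "difficult") == 1

    def test_empty_cohort(self, catalog):
        df = classify_cohort([], INDEX, catalog)
        assert len(df) == 0
        assert "difficult" in df.columns

    def test_duplicate_person_id_rejected(self, catalog):
        p = person_with(regimen_eps({"DTG", "3TC"}, date(2018, 1, 1)))
        with pytest.raises(ValueError, match="duplicate"):
            classify_cohort([p, p], INDEX, catalog)

    def test_difficult_equals_union_of_flags(self, catalog):
        rng = np.random.default_rng(13)
        persons = [random_person(rng, pid=f"P{i}")[0] for i in range(60)]
        df = classify_cohort(persons, INDEX, catalog)
        union = df[list(df.columns[1:6])].any(axis=1)
        assert (df["difficult"] == union).all()

    def test_deterministic_output(self, catalog):
        rng = np.random.default_rng(19)
        persons = [random_person(rng, pid=f"P{i}")[0] for i in range(30)]
        a = classify_cohort(persons, INDEX, catalog)
        b = classify_cohort(persons, INDEX, catalog)
        assert a.equals(b)
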