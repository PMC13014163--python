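"""Cohort builder: long-stay rule, eligibility, periods, category cutpoints."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from appersist.cohort import (FacilityYear, StayInterval, assemble_analysis_table,
                              apply_eligibility, assign_policy_period,
                              derive_facility_covariates, qualify_long_stay,
                              quarters_between)
from appersist.errors import DataInconsistencyError
from appersist.exposure import EpisodeRules
from appersist.pipeline import extract_episodes
from appersist.simulate import SimulationConfig, generate_dispensings, generate_world
from helpers import long_stay_oracle


def stay(entry_off: int, exit_off: int, pid="p1", fac="F1") -> StayInterval:
    base = date(2011, 1, 1).toordinal()
    return StayInterval(pid, fac, date.fromordinal(base + entry_off),
                        date.fromordinal(base + exit_off))


class TestLongStay:
    def test_single_continuous_stay_qualifies_on_day_101(self, rules):
        got = qualify_long_stay([stay(0, 101)], rules)
        assert got == date.fromordinal(date(2011, 1, 1).toordinal() + 100)  # the 101st day
        assert qualify_long_stay([stay(0, 100)], rules) is None  # exactly 100 days: not >100

    @pytest.mark.parametrize("stays, qualifies", [
        ([stay(0, 60), stay(71, 131)], False),   # 11 days outside breaks the rule
        ([stay(0, 60), stay(70, 120)], True),    # 10 days outside, 110 NH days
    ])
    def test_days_outside_boundary(self, rules, stays, qualifies):
        got = qualify_long_stay(stays, rules)
        assert (got is not None) == qualifies
        if qualifies:
            # 60 days, 10 outside, then 41 more NH days reach 101
            assert got == date.fromordinal(stays[1].entry_date.toordinal() + 40)

    def test_overlapping_stays_rejected(self, rules):
        with pytest.raises(DataInconsistencyError):
            qualify_long_stay([stay(0, 50), stay(40, 90)], rules)

    def test_matches_day_walk_oracle_on_random_calendars(self, rules):
        rng = np.random.default_rng(31)
        for _ in range(200):
            stays, cursor = [], 0
            for _ in range(int(rng.integers(1, 5))):
                cursor += int(rng.integers(0, 20))
                length = int(rng.integers(1, 120))
                stays.append(stay(cursor, cursor + length))
                cursor += length
            assert qualify_long_stay(stays, rules) == long_stay_oracle(stays, rules)


class TestPolicyPeriods:
    @pytest.mark.parametrize("d, period", [
        (date(2012, 3, 31), "pre_partnership"),
        (date(2012, 4, 1), "post_partnership"),
        (date(2014, 12, 31), "post_partnership"),
        (date(2015, 1, 1), "post_five_star"),
        (date(2010, 1, 1), "pre_partnership"),
        (date(2017, 12, 31), "post_five_star"),
    ])
    def test_boundary_dates(self, d, period):
        assert assign_policy_period(d) == period

    def test_outside_study_window_is_an_error(self):
        with pytest.raises(ValueError):
            assign_policy_period(date(2009, 12, 31))
        with pytest.raises(ValueError):
            assign_policy_period(date(2018, 1, 1))

    def test_periods_partition_the_window(self):
        start, end = date(2010, 1, 1).toordinal(), date(2017, 12, 31).toordinal()
        seen = {assign_policy_period(date.fromordinal(o)) for o in range(start, end + 1, 13)}
        assert seen == {"pre_partnership", "post_partnership", "post_five_star"}


class TestFacilityCategories:
    @pytest.mark.parametrize("black, medicaid, staffing, expected", [
        (4.99, 62.5, 2.99, ("low", "low", "low")),
        (5.0, 62.51, 3.0, ("intermediate", "high", "mid")),
        (15.0, 0.0, 4.1, ("intermediate", "low", "mid")),
        (15.01, 100.0, 4.11, ("high", "high", "high")),
    ])
    def test_cutpoints(self, black, medicaid, staffing, expected):
        fy = FacilityYear("F1", 2013, black, medicaid, "for_profit", staffing)
        cats = derive_facility_covariates(fy)
        assert (cats["pct_black_cat"], cats["pct_medicaid_cat"], cats["staffing_cat"]) == expected

    def test_every_valid_percent_maps_to_exactly_one_label(self):
        for v in np.linspace(0, 100, 401):
            cats = derive_facility_covariates(
                FacilityYear("F1", 2013, v, v, "for_profit", v / 20))
            assert cats["pct_black_cat"] in ("low", "intermediate", "high")
            assert cats["pct_medicaid_cat"] in ("low", "high")
            assert cats["staffing_cat"] in ("low", "mid", "high")

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            FacilityYear("F1", 2013, -1.0, 50.0, "for_profit", 3.5)


class TestEligibility:
    def _resident(self, **overrides):
        rec = {
            "person_id": "p1", "birth_date": date(1940, 1, 1),
            "dementia_onset_date": date(2010, 6, 1), "exclusionary_dx": False,
            "medicare_advantage": False,
        }
        rec.update(overrides)
        return rec

    def _spans(self):
        return {"AB": [(date(2009, 1, 1), date(2020, 1, 1))],
                "D": [(date(2009, 1, 1), date(2020, 1, 1))]}

    def test_all_criteria_met(self, rules):
        ok, reasons = apply_eligibility(self._resident(), self._spans(), date(2012, 6, 1),
                                        rules, date(2011, 1, 1), date(2011, 4, 12))
        assert ok and reasons == []

    @pytest.mark.parametrize("overrides, admission, reason", [
        ({"birth_date": date(1947, 1, 2)}, date(2011, 1, 1), "age_under_65"),
        ({"dementia_onset_date": date(2013, 1, 1)}, date(2011, 1, 1), "no_dementia_by_index"),
        ({"exclusionary_dx": True}, date(2011, 1, 1), "exclusionary_diagnosis"),
        ({"medicare_advantage": True}, date(2011, 1, 1), "medicare_advantage"),
    ])
    def test_single_failures_are_named(self, rules, overrides, admission, reason):
        ok, reasons = apply_eligibility(self._resident(**overrides), self._spans(),
                                        date(2012, 6, 1), rules, admission, date(2011, 4, 12))
        assert not ok and reasons == [reason]

    def test_enrollment_gap_detected(self, rules):
        spans = {"AB": [(date(2009, 1, 1), date(2012, 5, 1))],
                 "D": [(date(2009, 1, 1), date(2020, 1, 1))]}
        ok, reasons = apply_eligibility(self._resident(), spans, date(2012, 6, 1),
                                        rules, date(2011, 1, 1), date(2011, 4, 12))
        assert reasons == ["enrollment_gap"]

    def test_long_stay_must_precede_index(self, rules):
        ok, reasons = apply_eligibility(self._resident(), self._spans(), date(2012, 6, 1),
                                        rules, date(2011, 1, 1), date(2012, 6, 1))
        assert reasons == ["not_long_stay_by_index"]

    def test_missing_birth_date_is_an_error(self, rules):
        with pytest.raises(ValueError, match="birth_date"):
            apply_eligibility(self._resident(birth_date=None), self._spans(),
                              date(2012, 6, 1), rules, date(2011, 1, 1), date(2011, 4, 12))


def test_quarters_after_first_anchors_at_study_start():
    start = date(2010, 1, 1)
    assert quarters_between(start, date(2010, 2, 15)) == 0
    assert quarters_between(start, date(2010, 4, 1)) == 1
    assert quarters_between(start, date(2012, 4, 1)) == 9
    assert quarters_between(start, date(2017, 12, 31)) == 31


class TestAssembleAnalysisTable:
    @pytest.fixture(scope="class")
    def world_and_tables(self):
        cfg = SimulationConfig(seed=99, n_residents=400, n_facilities=25)
        world = generate_world(cfg)
        claims = generate_dispensings(cfg, world)
        episodes = extract_episodes(claims, world.tables["stays"], world.tables["deaths"],
                                    world.tables["enrollment"], EpisodeRules(),
                                    cfg.study_start, cfg.study_end)
        return cfg, world, episodes

    def test_empty_episode_table_gives_empty_output_with_header(self, world_and_tables, rules):
        cfg, world, episodes = world_and_tables
        table, drops = assemble_analysis_table(
            episodes.iloc[0:0], world.tables["residents"], world.tables["stays"],
            world.tables["facility_years"], world.tables["enrollment"], rules)
        assert table.empty and list(table.columns)[:3] == ["person_id", "index_date", "outcome"]
        assert drops == {}

    def test_row_count_matches_independent_recount(self, world_and_tables, rules):
        """The assembled table contains exactly the episodes an independent
        filter (re-deriving eligibility from the raw tables) accepts."""
        cfg, world, episodes = world_and_tables
        table, drops = assemble_analysis_table(
            episodes, world.tables["residents"], world.tables["stays"],
            world.tables["facility_years"], world.tables["enrollment"], rules,
            cfg.study_start, cfg.study_end)
        assert len(table) + sum(drops.values()) == len(episodes)

        residents = world.tables["residents"].set_index("person_id")
        stays = world.tables["stays"]
        enroll = world.tables["enrollment"]
        expected = 0
        for ep in episodes.itertuples(index=False):
            res = residents.loc[ep.person_id]
            st = stays[stays.person_id == ep.person_id]
            admission = st.entry_date.min()
            age_ok = (admission - res.birth_date).days / 365.25 >= 65
            ls = qualify_long_stay([StayInterval(ep.person_id, r.facility_id,
                                                 r.entry_date, r.exit_date)
                                    for r in st.itertuples(index=False)], rules)
            in_stay = ((st.entry_date <= ep.index_date) & (ep.index_date < st.exit_date)).any()
            en = enroll[enroll.person_id == ep.person_id]
            washout_start = date.fromordinal(ep.index_date.toordinal() - rules.washout_days)
            enrolled = all(
                ((en.part == part) & (en.start_date <= washout_start)
                 & (en.end_date > ep.index_date)).any()
                for part in ("AB", "D"))
            if (age_ok and res.dementia_onset_date <= ep.index_date
                    and not res.exclusionary_dx and not res.medicare_advantage
                    and enrolled and ls is not None and ls < ep.index_date and in_stay):
                expected += 1
        assert len(table) == expected

    def test_order_independence(self, world_and_tables, rules):
        cfg, world, episodes = world_and_tables
        args = (world.tables["residents"], world.tables["stays"],
                world.tables["facility_years"], world.tables["enrollment"], rules,
                cfg.study_start, cfg.study_end)
        a, _ = assemble_analysis_table(episodes, *args)
        shuffled = episodes.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b, _ = assemble_analysis_table(shuffled, *args)
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_exactly_one_status_per_row_and_valid_labels(self, world_and_tables, rules):
        cfg, world, episodes = world_and_tables
        table, _ = assemble_analysis_table(
            episodes, world.tables["residents"], world.tables["stays"],
            world.tables["facility_years"], world.tables["enrollment"], rules,
            cfg.study_start, cfg.study_end)
        assert not table.empty
        assert ((table.event + table.competing) <= 1).all()
        assert table.period.isin(["pre_partnership", "post_partnership", "post_five_star"]).all()
        assert table.pct_black_cat.isin(["low", "intermediate", "high"]).all()
        assert table.time.between(1, 180).all()
        assert (table.quarters_after_first >= 0).all()
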