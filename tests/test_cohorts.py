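"""Cohort-window detection, plant assignment, pulse classification, blending,
juvenile response, parameter extraction, and rule-based mortality attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelpcohorts.cohorts import (
    CohortWindow,
    assign_plants,
    attribute_mortality,
    classify_pulse,
    cohort_parameters,
    detect_blending,
    detect_cohort_windows,
    juvenile_response,
)
from kelpcohorts.algal_states import pool_guilds, scale_features

from conftest import make_census_frame, simple_plant


class TestDetectWindows:
    def test_gap_splits_windows(self):
        w = detect_cohort_windows([2000.0, 2000.25, 2000.5, 2002.0, 2002.25])
        assert len(w) == 2
        assert (w[0].start, w[0].end) == (2000.0, 2000.5)
        assert (w[1].start, w[1].end) == (2002.0, 2002.25)

    def test_no_internal_gap_single_extended_window(self):
        w = detect_cohort_windows([2000.0, 2000.75, 2001.5])
        assert len(w) == 1
        assert w[0].span == pytest.approx(1.5)
        assert w[0].extended

    def test_single_recruit_singleton_window(self):
        w = detect_cohort_windows([2005.25])
        assert len(w) == 1
        assert w[0].start == w[0].end == 2005.25
        assert not w[0].extended

    def test_empty_input_empty_result(self):
        assert detect_cohort_windows([]) == []

    def test_exact_one_year_gap_splits(self):
        w = detect_cohort_windows([2000.0, 2001.0])
        assert len(w) == 2

    def test_windows_cannot_be_merged_or_split(self):
        """Merging consecutive windows would violate the gap rule; splitting a
        window at its largest internal gap would create a gap < 1 yr."""
        rng = np.random.default_rng(4)
        dates = np.sort(rng.choice(np.arange(1990, 2020, 0.25), size=120, replace=True))
        windows = detect_cohort_windows(dates)
        for a, b in zip(windows, windows[1:]):
            assert b.start - a.end >= 1.0 - 1e-9
        for w in windows:
            inside = dates[(dates >= w.start) & (dates <= w.end)]
            if len(inside) > 1:
                assert np.max(np.diff(inside)) < 1.0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 119), min_size=1, max_size=60))
    def test_property_window_partition_is_maximal(self, quarters):
        """For arbitrary quarterly recruitment dates: windows are disjoint,
        time-ordered, separated by >= 1 yr, and internally gap-free (< 1 yr)."""
        dates = np.sort(2000.0 + 0.25 * np.array(quarters, dtype=float))
        windows = detect_cohort_windows(dates)
        assert [w.cohort_number for w in windows] == list(range(1, len(windows) + 1))
        for a, b in zip(windows, windows[1:]):
            assert b.start - a.end >= 1.0 - 1e-9
        covered = 0
        for w in windows:
            inside = dates[(dates >= w.start - 1e-9) & (dates <= w.end + 1e-9)]
            covered += len(inside)
            if len(inside) > 1:
                assert np.max(np.diff(inside)) < 1.0
        assert covered == len(dates)

    def test_planted_pulses_recovered(self, planted_site):
        truth = planted_site["truth"]
        plants = planted_site["plants"]
        windows = detect_cohort_windows([p.recruit_date for p in plants], "S01")
        assert len(windows) == len(truth.windows)
        rosters, unassigned = assign_plants(windows, plants)
        assert not unassigned
        correct = sum(
            1 for p in plants
            if truth.memberships[p.plant_id] == int(p.cohort_id.split("-")[-1]) - 1
        )
        assert correct == len(plants)


class TestAssignPlants:
    def test_boundary_inclusive(self):
        w = [CohortWindow("S", 1, 2000.0, 2000.5)]
        p = simple_plant(recruit=2000.0, last=2001.0)
        rosters, unassigned = assign_plants(w, [p])
        assert rosters["S-1"] == [p] and not unassigned

    def test_outside_all_windows_reported(self):
        w = [CohortWindow("S", 1, 2000.0, 2000.5), CohortWindow("S", 2, 2003.0, 2003.5)]
        p = simple_plant(recruit=2001.5, last=2002.0)
        rosters, unassigned = assign_plants(w, [p])
        assert unassigned == [p]

    def test_overlapping_windows_rejected(self):
        w = [CohortWindow("S", 1, 2000.0, 2001.5), CohortWindow("S", 2, 2001.0, 2002.0)]
        with pytest.raises(ValueError, match="overlapping"):
            assign_plants(w, [])

    def test_roster_sizes_conserve_plants(self, planted_site):
        plants = planted_site["plants"]
        windows = detect_cohort_windows([p.recruit_date for p in plants], "S01")
        rosters, unassigned = assign_plants(windows, plants)
        assert sum(len(r) for r in rosters.values()) + len(unassigned) == len(plants)


class TestClassifyPulse:
    def _roster(self, n_first, n_late, start=2000.0):
        roster = [simple_plant(f"p{i}", recruit=start, last=start + 2) for i in range(n_first)]
        roster += [simple_plant(f"q{i}", recruit=start + 1.25, last=start + 2.5)
                   for i in range(n_late)]
        window = CohortWindow("S", 1, start, start + 1.25)
        return roster, window

    @pytest.mark.parametrize("n_first,n_late,expected", [
        (9, 1, "pulsed"),    # 0.9 >= 0.8
        (7, 3, "trickled"),  # 0.7 < 0.8
        (8, 2, "pulsed"),    # inclusive boundary: exactly 80%
    ])
    def test_first_year_fraction_rule(self, n_first, n_late, expected):
        roster, window = self._roster(n_first, n_late)
        assert classify_pulse(roster, window) == expected

    def test_neighbor_too_close_forces_trickled(self):
        roster, window = self._roster(10, 0)
        near = CohortWindow("S", 2, window.end + 0.5, window.end + 0.75)
        assert classify_pulse(roster, window, next_window=near) == "trickled"

    def test_translation_invariance(self):
        for shift in (0.0, 7.25, -13.5):
            roster, window = self._roster(8, 2, start=2000.0 + shift)
            assert classify_pulse(roster, window) == "pulsed"

    def test_empty_roster_rejected(self):
        with pytest.raises(ValueError):
            classify_pulse([], CohortWindow("S", 1, 2000.0, 2000.0))


class TestDetectBlending:
    def _setup(self, survivor_last, survivor_dead=True):
        w1 = CohortWindow("S", 1, 2000.0, 2000.5)
        w2 = CohortWindow("S", 2, 2004.0, 2004.25)
        p1 = simple_plant("a", recruit=2000.0, last=survivor_last, dead=survivor_dead)
        p2 = simple_plant("b", recruit=2004.0, last=2005.0)
        rosters = {"S-1": [p1], "S-2": [p2]}
        return [w1, w2], rosters

    def test_first_cohort_never_blended(self):
        windows, rosters = self._setup(2001.0)
        assert detect_blending(windows, rosters)["S-1"] is False

    def test_predecessor_long_dead_not_blended(self):
        windows, rosters = self._setup(2001.0)
        assert detect_blending(windows, rosters)["S-2"] is False

    def test_single_survivor_blends(self):
        windows, rosters = self._setup(2004.5)
        assert detect_blending(windows, rosters)["S-2"] is True


class TestJuvenileResponse:
    def _census(self, juv_by_date):
        rows = [{"site_id": "S", "transect_id": 1, "quadrat_id": 1, "date": d,
                 "macro_juvenile": j} for d, j in juv_by_date.items()]
        return make_census_frame(rows)

    def test_juveniles_after_dieoff_true(self):
        # predecessor: 10 plants all dead by last=2001.0 -> death midpoint 2001.125
        pred = [simple_plant(f"p{i}", recruit=2000.0, last=2001.0) for i in range(10)]
        w = CohortWindow("S", 2, 2003.0, 2003.25)
        census = self._census({2001.0: 0, 2001.25: 12, 2001.5: 5})
        assert juvenile_response(w, pred, census) is True

    def test_no_juveniles_false(self):
        pred = [simple_plant(f"p{i}", recruit=2000.0, last=2001.0) for i in range(10)]
        w = CohortWindow("S", 2, 2003.0, 2003.25)
        census = self._census({2001.0: 3, 2001.25: 0, 2001.5: 0, 2002.25: 9})
        assert juvenile_response(w, pred, census) is False

    def test_dieoff_never_reached_not_applicable(self):
        pred = [simple_plant(f"p{i}", recruit=2000.0, last=2004.0, dead=False)
                for i in range(10)]
        w = CohortWindow("S", 2, 2003.0, 2003.25)
        assert juvenile_response(w, pred, self._census({2001.0: 0})) is None

    def test_missing_predecessor_rejected(self):
        w = CohortWindow("S", 2, 2003.0, 2003.25)
        with pytest.raises(ValueError):
            juvenile_response(w, [], self._census({2001.0: 0}))


def _env_pair(t0=1999.0, t1=2010.0, temp=14.0, energy=1000.0):
    t = np.arange(t0, t1, 1 / 52)
    temperature = pd.DataFrame({"time": t, "temperature": np.full(len(t), float(temp))})
    waves = pd.DataFrame({"time": t, "energy": np.full(len(t), float(energy)),
                          "hs_weekly_max": 1.0, "t_coincident": 10.0})
    return temperature, waves


class TestCohortParameters:
    def _site_census(self):
        rows = []
        for i, d in enumerate(np.arange(1999.0, 2006.0, 0.25)):
            rows.append({"site_id": "S", "transect_id": 1, "quadrat_id": 1, "date": d,
                         "macro_preadult": 4 if d <= 2000.0 else 0,
                         "macro_juvenile": 7 if d <= 2000.0 else 1,
                         "psu_density": 1.0, "rsu_density": 0.1})
        return make_census_frame(rows)

    def _scaled(self, census):
        scaled, _ = scale_features(pool_guilds(census))
        return scaled

    def test_all_singles(self):
        w = CohortWindow("S", 1, 2000.0, 2000.0)
        roster = [simple_plant(f"p{i}", recruit=2000.0, last=2000.0) for i in range(3)]
        census = self._site_census()
        temp, waves = _env_pair()
        row = cohort_parameters(w, roster, census, self._scaled(census), temp, waves)
        assert row["singles"] == row["N"] == 3

    def test_per_plant_max_stipes(self):
        w = CohortWindow("S", 1, 2000.0, 2000.0)
        roster = [simple_plant("p1", recruit=2000.0, last=2000.5, stipes=[4, 9, 6])]
        census = self._site_census()
        temp, waves = _env_pair()
        row = cohort_parameters(w, roster, census, self._scaled(census), temp, waves)
        assert row["st_max_mn"] == 9.0

    def test_lifespans_and_km_quantiles(self):
        w = CohortWindow("S", 1, 2000.0, 2000.0)
        # lifespans (midpoint): last 2000.875 -> 1.0; last 2002.875 -> 3.0
        roster = [simple_plant("p1", recruit=2000.0, last=2000.875),
                  simple_plant("p2", recruit=2000.0, last=2002.875)]
        census = self._site_census()
        temp, waves = _env_pair()
        row = cohort_parameters(w, roster, census, self._scaled(census), temp, waves)
        assert row["life_mn"] == pytest.approx(2.0)
        # documented convention: smallest event time with S(t) <= 1 - p
        assert row["km_q50"] == pytest.approx(1.0)
        assert row["km_q95"] == pytest.approx(3.0)
        assert row["km_q25"] <= row["km_q50"] <= row["km_q75"] <= row["km_q95"]

    def test_pre_onset_census_window(self):
        w = CohortWindow("S", 1, 2000.25, 2000.5)
        roster = [simple_plant("p1", recruit=2000.25, last=2001.0)]
        census = self._site_census()
        temp, waves = _env_pair()
        row = cohort_parameters(w, roster, census, self._scaled(census), temp, waves)
        assert row["PA"] == 4      # pre-adult peak in the year before onset
        assert row["juveniles_1yr"] == 7
        assert row["decade"] == "2000s"

    def test_env_coverage_shortfall_errors(self):
        w = CohortWindow("S", 1, 2000.0, 2000.0)
        roster = [simple_plant("p1", recruit=2000.0, last=2001.0)]
        census = self._site_census()
        temp, waves = _env_pair(t0=2005.0, t1=2006.0)
        with pytest.raises(ValueError, match="window"):
            cohort_parameters(w, roster, census, self._scaled(census), temp, waves)

    def test_previously_existing_adults_counted(self):
        w1 = CohortWindow("S", 1, 2000.0, 2000.25)
        w2 = CohortWindow("S", 2, 2003.0, 2003.25)
        old = [simple_plant(f"o{i}", recruit=2000.0, last=2002.75) for i in range(4)]
        old += [simple_plant("o9", recruit=2000.0, last=2001.0)]  # dead well before
        roster = [simple_plant("n1", recruit=2003.0, last=2004.0)]
        rosters = {"S-1": old, "S-2": roster}
        census = self._site_census()
        temp, waves = _env_pair()
        row = cohort_parameters(w2, roster, census, self._scaled(census), temp, waves,
                                all_windows=[w1, w2], all_rosters=rosters)
        # the 4 plants alive into [2002, 2003) count; the early death does not
        assert row["Ad"] == 4


class TestAttributeMortality:
    def _roster(self, n=10):
        return [simple_plant(f"p{i}", recruit=2000.0, last=2001.0) for i in range(n)]

    def test_waves_only(self):
        temp, waves = _env_pair(temp=13.0, energy=8000.0)
        census = make_census_frame([{"site_id": "S", "transect_id": 1, "quadrat_id": 1,
                                     "date": 2001.0}])
        assert attribute_mortality(self._roster(), temp, waves, census) == "waves"

    def test_no_rule_fires_not_known(self):
        temp, waves = _env_pair(temp=13.0, energy=1000.0)
        census = make_census_frame([{"site_id": "S", "transect_id": 1, "quadrat_id": 1,
                                     "date": 2001.0}])
        assert attribute_mortality(self._roster(), temp, waves, census) == "not known"

    def test_purple_urchins_fire(self):
        # terminal phase for all deaths at midpoint 2001.125 is [2001.125, 2001.375]
        temp, waves = _env_pair(temp=13.0, energy=1000.0)
        census = make_census_frame([{"site_id": "S", "transect_id": 1, "quadrat_id": 1,
                                     "date": 2001.25, "psu_density": 3.0}])
        assert attribute_mortality(self._roster(), temp, waves, census) == "sea urchins"

    def test_heat_and_waves_combined(self):
        temp, waves = _env_pair(temp=19.5, energy=8000.0)
        census = make_census_frame([{"site_id": "S", "transect_id": 1, "quadrat_id": 1,
                                     "date": 2001.0}])
        assert attribute_mortality(self._roster(), temp, waves, census) == "heat/waves"

    def test_small_cohort(self):
        temp, waves = _env_pair()
        census = make_census_frame([{"site_id": "S", "transect_id": 1, "quadrat_id": 1,
                                     "date": 2001.0}])
        assert attribute_mortality(self._roster(3), temp, waves, census) == "small cohort"
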