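"""Followers, mortality, utilization and critical events."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from comotraj.outcomes import (
    OutcomeData,
    compute_outcomes,
    detect_critical_events,
    diagnosis_mortality,
    diverging_ratios,
    followers,
    hospitalization_stats,
    trajectory_mortality,
)
from comotraj.records import stays_frame, to_events
from comotraj.trajectories import Trajectory, classify_all

from conftest import make_stay


def T(tid, *tuples):
    return Trajectory(id=tid, tuples=frozenset(tuples))


def make_data(stays):
    ev = to_events(stays)
    st_ = stays_frame(stays)
    return OutcomeData(ev, st_)


class TestTrajectoryMortality:
    def test_single_diagnosis(self):
        assert trajectory_mortality([0.1]) == pytest.approx(0.1)

    def test_two_diagnoses_expand_formula(self):
        assert trajectory_mortality([0.1, 0.2]) == pytest.approx(0.26)

    def test_degenerate_cases(self):
        assert trajectory_mortality([]) == 0.0
        assert trajectory_mortality([0.0, 0.0]) == 0.0
        assert trajectory_mortality([1.0]) == 1.0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_exactly_one_death_below_at_least_one_death(self, ms):
        m = trajectory_mortality(ms)
        at_least_one = 1 - np.prod([1 - x for x in ms])
        assert 0.0 <= m <= at_least_one + 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            trajectory_mortality([1.5])


class TestFollowers:
    def setup_method(self):
        # P1 holds both tuples, P2 one of two, P3 one of four
        self.stays = [
            make_stay("P1", age=40, adm="2005-01-01", rel="2005-01-03",
                      codes=("I10", "E66")),
            make_stay("P2", age=40, adm="2005-02-01", rel="2005-02-02",
                      codes=("I10",)),
            make_stay("P3", age=40, adm="2005-03-01", rel="2005-03-02",
                      codes=("I10",)),
        ]
        self.data = make_data(self.stays)

    def test_half_is_inclusive(self):
        traj = T("t", ("I10", 5), ("E66", 5))
        fol = followers(traj, self.data, 5)
        assert fol == {"P1", "P2", "P3"}  # 1 of 2 tuples = exactly 50%

    def test_below_half_is_out(self):
        traj = T("t", ("I10", 5), ("E66", 5), ("N18", 5), ("K51", 5))
        assert followers(traj, self.data, 5) == {"P1"}  # P2: 1/4 < 50%

    def test_requires_presence_in_age_group(self):
        traj = T("t", ("I10", 5))
        assert followers(traj, self.data, 6) == frozenset()

    def test_only_tuples_up_to_age_group_count(self):
        # future tuples must not penalize followers at earlier ages
        traj = T("t", ("I10", 5), ("N18", 7), ("K51", 7), ("E84", 7))
        assert followers(traj, self.data, 5) == {"P1", "P2", "P3"}

    @given(st.integers(0, 3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_removing_unheld_tuples_never_shrinks_followers(self, drop):
        # Removal of a tuple no patient holds can only raise everyone's
        # held fraction.  (Removing a *held* tuple can push a patient
        # from exactly-half below the inclusive boundary, so followers
        # are not monotone under arbitrary removals.)
        tuples = [("I10", 5), ("E66", 5), ("N18", 5), ("K51", 5)]
        full = T("f", *tuples)
        unheld = [t for t in tuples if t[0] not in ("I10", "E66")]
        removed = unheld[drop % len(unheld)]
        smaller = T("s", *[t for t in tuples if t != removed])
        assert followers(full, self.data, 5) <= followers(
            smaller, self.data, 5)

    def test_future_tuples_do_not_shrink_followers(self):
        base = T("f", ("I10", 5), ("E66", 5))
        extended = T("s", ("I10", 5), ("E66", 5), ("N18", 7), ("K51", 7))
        assert followers(base, self.data, 5) == followers(
            extended, self.data, 5)


class TestMortalityAndUtilization:
    def test_diagnosis_mortality_fraction(self):
        stays = [make_stay(f"P{i}", age=40, codes=("I10",),
                           rtype="death" if i < 7 else "discharge")
                 for i in range(100)]
        data = make_data(stays)
        assert diagnosis_mortality(data, "I10", 5) == pytest.approx(0.07)

    def test_no_carriers_is_none(self):
        data = make_data([make_stay()])
        assert diagnosis_mortality(data, "E84", 5) is None

    def test_hospitalization_means(self):
        stays = [
            make_stay("P1", age=40, adm="2005-01-01", rel="2005-01-04"),
            make_stay("P1", age=40, adm="2005-06-01", rel="2005-06-05"),
            make_stay("P2", age=40, adm="2005-01-01", rel="2005-01-01",
                      codes=("I10", "E66", "N18", "K51")),
        ]
        data = make_data(stays)
        traj = T("t", ("I10", 5))
        days, n_stays, n_dx = hospitalization_stats(traj, data, 5)
        # P1: 3+4 days over 2 stays, 1 dx; P2: same-day stay floored to 1
        assert days == pytest.approx((7 + 1) / 2)
        assert n_stays == pytest.approx(1.5)
        assert n_dx == pytest.approx((1 + 4) / 2)

    def test_empty_followers_reported_missing_not_zero(self):
        data = make_data([make_stay()])
        traj = T("t", ("E84", 5))
        days, n_stays, n_dx = hospitalization_stats(traj, data, 5)
        assert np.isnan(days) and np.isnan(n_stays) and np.isnan(n_dx)


class TestRatiosAndCriticalEvents:
    def _outcomes(self):
        return pd.DataFrame([
            {"trajectory_id": "A", "age_group": 3, "n_followers": 50,
             "mortality": 0.0, "mean_days": 5.0, "mean_stays": 2.0,
             "mean_dx": 3.0},
            {"trajectory_id": "A", "age_group": 4, "n_followers": 40,
             "mortality": 0.2, "mean_days": 6.0, "mean_stays": 2.0,
             "mean_dx": 4.0},
            {"trajectory_id": "B", "age_group": 3, "n_followers": 60,
             "mortality": 0.0, "mean_days": 5.0, "mean_stays": 2.0,
             "mean_dx": 3.0},
            {"trajectory_id": "B", "age_group": 4, "n_followers": 55,
             "mortality": 0.02, "mean_days": 6.2, "mean_stays": 2.1,
             "mean_dx": 3.9},
        ])

    def test_ratio_table_values(self):
        ratios = diverging_ratios("A", "B", self._outcomes())
        row4 = ratios[ratios["age_group"] == 4].iloc[0]
        assert row4["ratio_mortality"] == pytest.approx(10.0)
        assert row4["ratio_mean_days"] == pytest.approx(6.0 / 6.2)

    def test_ratio_reciprocal_under_swap(self):
        r_ab = diverging_ratios("A", "B", self._outcomes())
        r_ba = diverging_ratios("B", "A", self._outcomes())
        pd.testing.assert_frame_equal(r_ab, r_ba)  # order fixed by id

    def test_zero_denominator_is_missing(self):
        out = self._outcomes()
        out.loc[(out.trajectory_id == "B") & (out.age_group == 4),
                "mortality"] = 0.0
        ratios = diverging_ratios("A", "B", out)
        assert np.isnan(ratios[ratios.age_group == 4].iloc[0]["ratio_mortality"])

    def test_critical_event_flagging(self):
        x = T("A", ("G47", 3), ("I10", 3), ("E11", 4))
        y = T("B", ("G47", 3), ("I10", 3), ("G25", 4))
        relations, _ = classify_all([x, y])
        events = detect_critical_events(relations, self._outcomes(), [x, y],
                                        threshold=1.5)
        assert len(events) == 1
        ev = events[0]
        assert ev.split_layer == 3
        assert ev.flagged  # mortality ratio 10 at layer 4

    def test_equal_outcomes_not_flagged(self):
        out = self._outcomes()
        out.loc[out.trajectory_id == "B",
                ["mortality", "mean_days", "mean_stays", "mean_dx"]] = \
            out.loc[out.trajectory_id == "A",
                    ["mortality", "mean_days", "mean_stays",
                     "mean_dx"]].to_numpy()
        x = T("A", ("G47", 3), ("E11", 4))
        y = T("B", ("G47", 3), ("G25", 4))
        relations, _ = classify_all([x, y])
        events = detect_critical_events(relations, out, [x, y], threshold=1.5)
        assert events and not events[0].flagged

    def test_non_diverging_pairs_never_flagged(self):
        x = T("A", ("I10", 3))
        y = T("B", ("E66", 4))
        relations, _ = classify_all([x, y])
        assert detect_critical_events(relations, self._outcomes(),
                                      [x, y]) == []

    def test_compute_outcomes_table_shape(self):
        stays = [
            make_stay("P1", age=40, codes=("I10", "E66")),
            make_stay("P1", age=50, adm="2011-01-01", rel="2011-01-05",
                      codes=("N18",), rtype="death"),
            make_stay("P2", age=40, codes=("I10",)),
        ]
        data = make_data(stays)
        traj = T("t", ("I10", 5), ("N18", 6))
        out = compute_outcomes([traj], data)
        assert list(out["age_group"]) == [5, 6]
        assert out.iloc[0]["n_followers"] == 2
        # P1 is the only N18 carrier at layer 6 and died there
        assert out.iloc[1]["mortality"] == pytest.approx(1.0)
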