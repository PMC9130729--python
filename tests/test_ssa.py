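"""The event-driven engine: exactness against the mean-field oracle,
structural invariants, lineage bookkeeping and the death checkpoint."""

import numpy as np
import pytest

from nscdyn.core import DivisionProportions, RateSet, init_labeled_cohort
from nscdyn.oracle import expected_divisions, expected_trajectory
from nscdyn.ssa import (
    CellLedger,
    DeathModel,
    TrainingSchedule,
    divisions_per_lineage,
    estimate_division_proportions,
    simulate_cohort,
    survival_fraction,
)

ZERO_RATES = RateSet(0, 0, 0, 0, 0, 0)


def test_zero_rates_keep_counts_constant(cohort1000):
    traj, ledger = simulate_cohort(cohort1000, ZERO_RATES, horizon=30.0, seed=0)
    assert (traj.r == cohort1000.r0).all()
    assert (traj.o == cohort1000.o0).all()
    assert (traj.n == cohort1000.n0).all()
    assert divisions_per_lineage(ledger) == 1.0


def test_unit_learning_factor_is_identity(cohort1000, rates):
    """A lambda=1 schedule consumes the same random stream as no schedule."""
    sched = TrainingSchedule([(3.0, 14.0)], learning_factor=1.0, rescue_factor=1.0)
    a, _ = simulate_cohort(cohort1000, rates, schedule=sched, horizon=30.0, seed=11)
    b, _ = simulate_cohort(cohort1000, rates, schedule=None, horizon=30.0, seed=11)
    assert (a.o == b.o).all() and (a.n == b.n).all() and (a.times == b.times).all()


def test_control_ensemble_matches_mean_field(cohort1000, rates):
    """20 replicates of the 30-day control run sit within 3 Monte-Carlo SEs
    of the closed-form expectation (r=500, o~520, n~1331 per P0=1000)."""
    oracle = expected_trajectory(cohort1000, rates, None, 30.0)
    ends = np.array(
        [simulate_cohort(cohort1000, rates, horizon=30.0, seed=500 + i)[0].counts_at(30.0)
         for i in range(20)],
        dtype=float,
    )
    assert (ends[:, 0] == cohort1000.r0).all()
    for j, expect in ((1, oracle.o(30.0)), (2, oracle.n(30.0))):
        mean = ends[:, j].mean()
        se = ends[:, j].std(ddof=1) / np.sqrt(len(ends))
        assert abs(mean - expect) < 3 * se + 1e-9, (j, mean, expect, se)


def test_reservoir_constant_and_neurons_monotone_without_death(cohort1000, rates):
    sched = TrainingSchedule([(3.0, 14.0)])
    for schedule in (None, sched):
        traj, _ = simulate_cohort(cohort1000, rates, schedule=schedule, horizon=30.0, seed=3)
        assert (traj.r == cohort1000.r0).all()
        assert (np.diff(traj.n) >= 0).all()
        assert (traj.n == traj.n_created).all()


def test_same_seed_reproduces_bit_identical_trajectories(cohort1000, rates):
    kwargs = dict(
        schedule=TrainingSchedule([(12.0, 30.0)]),
        death=DeathModel(),
        horizon=30.0,
        seed=42,
        record_events=True,
    )
    a, la = simulate_cohort(cohort1000, rates, **kwargs)
    b, lb = simulate_cohort(cohort1000, rates, **kwargs)
    assert (a.o == b.o).all() and (a.n == b.n).all()
    assert a.events == b.events
    assert (la.division_count == lb.division_count).all()
    assert (la.neuron_alive == lb.neuron_alive).all()


class TestDivisionsPerLineage:
    def test_control_mean_near_published_value(self, cohort1000, rates):
        """~1.7 chained divisions per lineage over 30 days (oracle 1.727)."""
        expect = expected_divisions(cohort1000, rates, None, 30.0)
        vals = [
            divisions_per_lineage(
                simulate_cohort(cohort1000, rates, horizon=30.0, seed=900 + i)[1]
            )
            for i in range(20)
        ]
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expect) < 3 * se + 1e-9
        assert 1.6 < mean < 1.9

    def test_longer_horizon_strictly_increases_divisions(self, cohort1000, rates):
        short = [
            divisions_per_lineage(
                simulate_cohort(cohort1000, rates, horizon=30.0, seed=50 + i)[1]
            )
            for i in range(5)
        ]
        long = [
            divisions_per_lineage(
                simulate_cohort(cohort1000, rates, horizon=60.0, seed=50 + i)[1]
            )
            for i in range(5)
        ]
        assert np.mean(long) > np.mean(short)

    def test_empty_ledger_rejected(self):
        ledger = CellLedger(
            division_count=np.array([], dtype=np.int64),
            neuron_birth=np.array([]),
            neuron_lineage=np.array([], dtype=np.int64),
            neuron_alive=np.array([], dtype=bool),
            neuron_resolved=np.array([], dtype=bool),
        )
        with pytest.raises(ValueError, match="empty ledger"):
            divisions_per_lineage(ledger)


class TestSurvivalFraction:
    def test_zero_death_probability_gives_full_survival(self, cohort1000, rates):
        death = DeathModel(p_death=0.0)
        a, _ = simulate_cohort(cohort1000, rates, death=death, horizon=30.0, seed=1)
        b, _ = simulate_cohort(cohort1000, rates, death=None, horizon=30.0, seed=1)
        assert survival_fraction(a, b, 30.0) == 100.0

    def test_certain_death_after_checkpoint_kills_all(self):
        # pure-neuron cohort, no dynamics: everyone is past the age-1 checkpoint
        cohort = init_labeled_cohort(100, DivisionProportions(0.0, 0.0, 0.0, 1.0))
        death = DeathModel(checkpoint_age=1.0, p_death=1.0)
        a, _ = simulate_cohort(cohort, ZERO_RATES, death=death, horizon=30.0, seed=1)
        b, _ = simulate_cohort(cohort, ZERO_RATES, death=None, horizon=30.0, seed=1)
        assert survival_fraction(a, b, 30.0) == 0.0

    def test_missing_when_no_neurons_exist(self):
        cohort = init_labeled_cohort(100, DivisionProportions(1.0, 0.0, 0.0, 0.0))
        a, _ = simulate_cohort(cohort, ZERO_RATES, death=DeathModel(), horizon=5.0, seed=1)
        b, _ = simulate_cohort(cohort, ZERO_RATES, death=None, horizon=5.0, seed=1)
        assert survival_fraction(a, b, 5.0) is None

    def test_calendar_cull_spares_neurons_born_after_day_15(self, cohort1000, rates):
        """In calendar mode a single day-15 cull resolves everyone alive then;
        later-born neurons never face a draw, so with p_death=1 the neuron
        count can only grow after day 15."""
        death = DeathModel(p_death=1.0, mode="calendar")
        traj, ledger = simulate_cohort(cohort1000, rates, death=death, horizon=30.0, seed=8)
        day15 = int(np.searchsorted(traj.times, 15.0))
        assert traj.n[day15] == 0
        assert (np.diff(traj.n[day15:]) >= 0).all()
        assert ledger.neuron_resolved[ledger.neuron_birth < 15.0].all()
        assert not ledger.neuron_resolved[ledger.neuron_birth >= 15.0].any()

    def test_calendar_and_age_modes_agree_on_mean_survival(self, cohort1000, rates):
        """Both checkpoint readings have the same expected survival; their
        20-pair means differ by well under the published SD."""
        means = []
        for mode in ("age", "calendar"):
            death = DeathModel(mode=mode)
            vals = []
            for i in range(20):
                a, _ = simulate_cohort(cohort1000, rates, death=death, horizon=30.0,
                                       seed=300 + i)
                b, _ = simulate_cohort(cohort1000, rates, death=None, horizon=30.0,
                                       seed=300 + i)
                vals.append(survival_fraction(a, b, 30.0))
            means.append(np.mean(vals))
        assert abs(means[0] - means[1]) < 3.0

    def test_invalid_checkpoint_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            DeathModel(mode="cohort")

    def test_paired_runs_share_their_division_history(self, cohort1000, rates):
        """Death draws come from a separate stream, so a death-on run and its
        death-off pair produce the same neurons; survival is a pure ratio."""
        a, _ = simulate_cohort(cohort1000, rates, death=DeathModel(), horizon=30.0, seed=77)
        b, _ = simulate_cohort(cohort1000, rates, death=None, horizon=30.0, seed=77)
        assert (a.n_created == b.n_created).all()
        assert (a.o == b.o).all()


class TestDivisionCensus:
    def test_only_reservoir_divisions(self):
        res = estimate_division_proportions(
            RateSet(0.01, 0.02, 0, 0, 0, 0), r_init=1000, duration=50.0, seed=0
        )
        assert res.as_tuple() == (1.0, 0.0, 0.0, 0.0)

    def test_census_agrees_with_analytic_formula(self, rates):
        from nscdyn.core import division_proportions_analytic

        res = estimate_division_proportions(
            rates, r_init=4000, duration=200.0, seed=2, min_divisions=10_000
        )
        assert res.n_divisions >= 10_000
        analytic = division_proportions_analytic(rates)
        for got, want, se in zip(
            res.proportions,
            (analytic.d1, analytic.d3, analytic.d4, analytic.d5),
            res.standard_errors,
        ):
            assert abs(got - want) < 3 * se + 1e-9

    def test_sparse_census_carries_warning(self):
        res = estimate_division_proportions(
            RateSet(0.001, 0.02, 0, 0, 0, 0), r_init=10, duration=30.0, seed=0
        )
        assert res.warning is not None and "unreliable" in res.warning


class TestScheduleValidation:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TrainingSchedule([(3.0, 14.0), (10.0, 20.0)])

    def test_window_past_horizon_rejected(self, cohort1000, rates):
        sched = TrainingSchedule([(12.0, 40.0)])
        with pytest.raises(ValueError, match="horizon"):
            simulate_cohort(cohort1000, rates, schedule=sched, horizon=30.0, seed=0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="invalid training window"):
            TrainingSchedule([(5.0, 5.0)])

    def test_nonpositive_horizon_rejected(self, cohort1000, rates):
        with pytest.raises(ValueError, match="horizon"):
            simulate_cohort(cohort1000, rates, horizon=0.0, seed=0)
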