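"""Scenario battery orchestration, increase ratios and comparison utilities."""

import numpy as np
import pytest

from nscdyn.core import RateSet
from nscdyn.scenarios import (
    ScenarioSpec,
    default_battery,
    long_run_additivity,
    neuronal_increase_ratio,
    permutation_test,
    run_battery,
    run_scenario,
    scenario_seed,
    welch_ttest,
)
from nscdyn.ssa import DeathModel, TrainingSchedule

ZERO_RATES = RateSet(0, 0, 0, 0, 0, 0)


def test_zero_rate_control_endpoint_equals_initial_cohort():
    spec = ScenarioSpec("control", replicates=5, p0=200)
    summary = run_scenario(spec, rates=ZERO_RATES, master_seed=0)
    # p0=200 with the published proportions: n0 = 200*(0.32 + 0.14) = 92
    assert (summary.endpoint_neurons == 92).all()


def test_battery_results_invariant_to_scenario_order():
    specs = [
        ScenarioSpec("control", replicates=3, p0=200),
        ScenarioSpec("trained", schedule=TrainingSchedule([(3.0, 14.0)]),
                     replicates=3, p0=200),
    ]
    fwd = run_battery(specs, master_seed=5)
    rev = run_battery(specs[::-1], master_seed=5)
    for name in ("control", "trained"):
        assert (fwd[name].endpoint_neurons == rev[name].endpoint_neurons).all()
        assert (fwd[name].seeds == rev[name].seeds).all()


def test_scenario_seeds_derive_from_name_and_master():
    assert scenario_seed(1, "control") != scenario_seed(1, "trained")
    assert scenario_seed(1, "control") == scenario_seed(1, "control")
    assert 0 <= scenario_seed(2**20, "x" * 50) < 2**31


def test_duplicate_scenario_names_rejected():
    specs = [ScenarioSpec("same", replicates=1, p0=100)] * 2
    with pytest.raises(ValueError, match="duplicate"):
        run_battery(specs, master_seed=0)


def test_session_block_windows_follow_weekly_protocol():
    from nscdyn.scenarios import session_block_windows

    assert session_block_windows(3.0, 2) == [(3.0, 8.0), (10.0, 15.0)]
    assert session_block_windows(12.0, 3, clip=30.0) == [
        (12.0, 17.0), (19.0, 24.0), (26.0, 30.0),
    ]
    with pytest.raises(ValueError):
        session_block_windows(0.0, 0)
    # windows are valid schedule input
    TrainingSchedule(session_block_windows(3.0, 2))


def test_session_block_battery_uses_split_windows():
    specs = {s.name: s for s in default_battery(session_blocks=True)}
    assert specs["trained_3_14"].schedule.windows == ((3.0, 8.0), (10.0, 15.0))
    assert len(specs["trained_12_30"].schedule.windows) == 3


def test_default_battery_contains_the_published_conditions():
    names = {s.name for s in default_battery()}
    assert {"control", "trained_3_14", "trained_12_30", "control_death",
            "trained_12_30_2xlambda_death", "control_2xk_death",
            "control_death_500d"} <= names
    long = next(s for s in default_battery() if s.name == "control_death_500d")
    assert long.horizon == 500.0 and long.death is not None


class TestIncreaseRatio:
    def test_identical_conditions_give_unit_ratio(self):
        spec = ScenarioSpec("control", replicates=4, p0=200)
        s = run_scenario(spec, master_seed=1)
        out = neuronal_increase_ratio(s, s, n_boot=100, seed=0)
        assert out["ratio"] == 1.0
        assert out["ci_low"] <= 1.0 <= out["ci_high"]

    def test_zero_control_mean_rejected(self):
        spec = ScenarioSpec("control", replicates=3, p0=100)
        # a cohort with only reservoir daughters and no dynamics has no neurons
        from nscdyn.core import DivisionProportions

        s = run_scenario(spec, rates=ZERO_RATES,
                         d=DivisionProportions(1.0, 0.0, 0.0, 0.0), master_seed=0)
        with pytest.raises(ValueError, match="zero"):
            neuronal_increase_ratio(s, s)

    def test_mismatched_horizons_rejected(self):
        a = run_scenario(ScenarioSpec("a", replicates=2, p0=100), master_seed=0)
        b = run_scenario(ScenarioSpec("b", horizon=60.0, replicates=2, p0=100),
                         master_seed=0)
        with pytest.raises(ValueError, match="horizon"):
            neuronal_increase_ratio(b, a)

    def test_training_raises_ratio_above_one(self):
        control = run_scenario(ScenarioSpec("control", replicates=5, p0=500),
                               master_seed=2)
        trained = run_scenario(
            ScenarioSpec("trained_12_30", schedule=TrainingSchedule([(12.0, 30.0)]),
                         replicates=5, p0=500),
            master_seed=2,
        )
        out = neuronal_increase_ratio(trained, control, n_boot=200, seed=0)
        assert out["ratio"] > 1.3


class TestLongRunAdditivity:
    def test_zero_rates_are_not_additive(self):
        spec = ScenarioSpec("flat", horizon=500.0, death=DeathModel(),
                            replicates=3, p0=200)
        additive, traj = long_run_additivity(spec, rates=ZERO_RATES, master_seed=0)
        assert not additive
        assert traj["n"][-1] <= traj["n"][0]

    def test_requires_death_enabled(self):
        spec = ScenarioSpec("nodeath", horizon=500.0, replicates=1, p0=100)
        with pytest.raises(ValueError, match="death"):
            long_run_additivity(spec)

    def test_certain_early_death_bounds_neurons_by_young_cohort(self):
        # p_death=1 with a 1-day checkpoint: at day 500 only neurons younger
        # than 1 day can be alive
        spec = ScenarioSpec(
            "lethal", horizon=500.0,
            death=DeathModel(checkpoint_age=1.0, p_death=1.0),
            replicates=3, p0=500,
        )
        summary = run_scenario(spec, master_seed=1)
        assert summary.endpoint_neurons.max() < 20


class TestComparisonUtilities:
    def test_welch_matches_hand_computed_values(self):
        # samples (1,2,3) vs (2,4,6): t = -2/sqrt(5/3), df = 50/17
        out = welch_ttest([1, 2, 3], [2, 4, 6])
        assert out["t"] == pytest.approx(-2 / np.sqrt(5 / 3), abs=1e-9)
        assert out["df"] == pytest.approx(50 / 17, abs=1e-9)

    def test_permutation_test_on_shifted_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        b = rng.normal(2, 1, 40)
        out = permutation_test(a, b, n_perm=500, seed=1)
        assert out["p"] < 0.01
        same = permutation_test(a, a, n_perm=500, seed=1)
        assert same["p"] > 0.9
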