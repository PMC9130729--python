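"""Named simulation conditions, replicate orchestration and endpoint summaries.

A battery is a list of scenario specifications — control, training windows
(3-14 and 12-30 days post-labeling), death on/off, doubled learning factor,
doubled division/differentiation rates, a 500-day long run — each executed
for a fixed number of seeded replicates.  Replicate seeds derive from the
master seed and the scenario *name* (CRC32), so results are invariant to the
order in which scenarios run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DEFAULT_RATES, DivisionProportions, RateSet, init_labeled_cohort
from .ssa import (
    DeathModel,
    TrainingSchedule,
    Trajectory,
    divisions_per_lineage,
    simulate_cohort,
    survival_fraction,
)

__all__ = [
    "ScenarioSpec",
    "ScenarioSummary",
    "session_block_windows",
    "default_battery",
    "run_scenario",
    "run_battery",
    "neuronal_increase_ratio",
    "long_run_additivity",
    "welch_ttest",
    "permutation_test",
    "scenario_seed",
]

DEFAULT_P0 = 1000
DEFAULT_REPLICATES = 20

# contiguous calendar training windows (days post-labeling)
WINDOW_3_14 = (3.0, 14.0)
WINDOW_12_30 = (12.0, 30.0)


def session_block_windows(
    start: float,
    n_blocks: int,
    days_on: float = 5.0,
    days_off: float = 2.0,
    clip: float | None = None,
) -> list[tuple[float, float]]:
    """Weekly training blocks (default 5 days on, 2 off) as schedule windows.

    Mirrors the behavioral protocol's session structure; an alternative to
    the contiguous calendar windows used by default.  ``clip`` truncates the
    last block at the simulation horizon.
    """
    if n_blocks < 1:
        raise ValueError("need at least one training block")
    period = days_on + days_off
    windows = [
        (start + b * period, start + b * period + days_on) for b in range(n_blocks)
    ]
    if clip is not None:
        windows = [(a, min(b, clip)) for a, b in windows if a < clip]
    return windows


def scenario_seed(master_seed: int, name: str) -> int:
    """Base seed for a scenario: master + CRC32(name), folded below 2^31.

    Replicate i then uses base + i, so a battery's results do not depend on
    scenario execution order.
    """
    return (int(master_seed) + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class ScenarioSpec:
    """One named simulation condition."""

    name: str
    horizon: float = 30.0
    schedule: TrainingSchedule | None = None
    death: DeathModel | None = None
    rate_multiplier: float = 1.0        # doubles k1, k3..k6 for the "2X k_i" condition
    replicates: int = DEFAULT_REPLICATES
    p0: int = DEFAULT_P0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.rate_multiplier <= 0:
            raise ValueError("rate_multiplier must be positive")

    def effective_rates(self, rates: RateSet) -> RateSet:
        if self.rate_multiplier == 1.0:
            return rates
        return rates.scaled(self.rate_multiplier)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "horizon": self.horizon,
            "schedule": self.schedule.to_dict() if self.schedule else None,
            "death": self.death.to_dict() if self.death else None,
            "rate_multiplier": self.rate_multiplier,
            "replicates": self.replicates,
            "p0": self.p0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            name=d["name"],
            horizon=float(d.get("horizon", 30.0)),
            schedule=(
                TrainingSchedule.from_dict(d["schedule"]) if d.get("schedule") else None
            ),
            death=DeathModel.from_dict(d["death"]) if d.get("death") else None,
            rate_multiplier=float(d.get("rate_multiplier", 1.0)),
            replicates=int(d.get("replicates", DEFAULT_REPLICATES)),
            p0=int(d.get("p0", DEFAULT_P0)),
        )


@dataclass
class ScenarioSummary:
    """Per-replicate endpoints for one condition, plus their summaries.

    All summary statistics are recomputable from the stored per-replicate
    arrays; the mean trajectory is kept for plotting and the long-run check.
    """

    name: str
    endpoint_neurons: np.ndarray
    neuron_fraction: np.ndarray
    divisions: np.ndarray
    seeds: np.ndarray
    spec: ScenarioSpec
    mean_trajectory: dict[str, np.ndarray] = field(default_factory=dict)
    survival_pct: np.ndarray | None = None

    @property
    def mean_neurons(self) -> float:
        return float(self.endpoint_neurons.mean())

    @property
    def sd_neurons(self) -> float:
        return float(self.endpoint_neurons.std(ddof=1)) if len(self.endpoint_neurons) > 1 else 0.0

    def to_record(self) -> dict:
        rec = {
            "name": self.name,
            "replicates": len(self.endpoint_neurons),
            "mean_neurons": self.mean_neurons,
            "sd_neurons": self.sd_neurons,
            "mean_neuron_fraction": float(self.neuron_fraction.mean()),
            "mean_divisions": float(self.divisions.mean()),
            "endpoint_neurons": [int(x) for x in self.endpoint_neurons],
            "seeds": [int(s) for s in self.seeds],
            "spec": self.spec.to_dict(),
        }
        if self.survival_pct is not None:
            rec["mean_survival_pct"] = float(np.mean(self.survival_pct))
            rec["sd_survival_pct"] = float(np.std(self.survival_pct, ddof=1))
        return rec


def run_scenario(
    spec: ScenarioSpec,
    rates: RateSet = DEFAULT_RATES,
    d: DivisionProportions | None = None,
    master_seed: int = 0,
    keep_trajectories: bool = False,
) -> ScenarioSummary:
    """Run one condition for its configured number of seeded replicates.

    The cohort defaults to the published census proportions (0.5, 0.11,
    0.32, 0.07), which for p0=1000 gives the canonical (500, 1040, 460)
    labeled split.
    """
    eff_rates = spec.effective_rates(rates)
    if d is None:
        d = DivisionProportions()
    cohort = init_labeled_cohort(spec.p0, d)
    base = scenario_seed(master_seed, spec.name)

    endpoints, fractions, divisions, seeds = [], [], [], []
    trajectories: list[Trajectory] = []
    traj_sum: dict[str, np.ndarray] = {}
    for i in range(spec.replicates):
        seed = base + i
        traj, ledger = simulate_cohort(
            cohort, eff_rates, schedule=spec.schedule, death=spec.death,
            horizon=spec.horizon, seed=seed,
        )
        r_end, o_end, n_end = traj.counts_at(spec.horizon)
        endpoints.append(n_end)
        fractions.append(n_end / (r_end + o_end + n_end))
        divisions.append(divisions_per_lineage(ledger))
        seeds.append(seed)
        if keep_trajectories:
            trajectories.append(traj)
        if not traj_sum:
            traj_sum = {
                "day": traj.times.copy(),
                "r": traj.r.astype(float).copy(),
                "o": traj.o.astype(float).copy(),
                "n": traj.n.astype(float).copy(),
            }
        else:
            traj_sum["r"] += traj.r
            traj_sum["o"] += traj.o
            traj_sum["n"] += traj.n

    for key in ("r", "o", "n"):
        traj_sum[key] = traj_sum[key] / spec.replicates

    summary = ScenarioSummary(
        name=spec.name,
        endpoint_neurons=np.asarray(endpoints, dtype=np.int64),
        neuron_fraction=np.asarray(fractions),
        divisions=np.asarray(divisions),
        seeds=np.asarray(seeds, dtype=np.int64),
        spec=spec,
        mean_trajectory=traj_sum,
    )
    if keep_trajectories:
        summary.trajectories = trajectories  # type: ignore[attr-defined]
    return summary


def run_battery(
    specs: list[ScenarioSpec],
    rates: RateSet = DEFAULT_RATES,
    master_seed: int = 0,
) -> dict[str, ScenarioSummary]:
    """Run every scenario in the battery; names must be unique."""
    names = [s.name for s in specs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate scenario names in battery: {sorted(dupes)}")
    return {s.name: run_scenario(s, rates=rates, master_seed=master_seed) for s in specs}


def default_battery(
    replicates: int = DEFAULT_REPLICATES,
    p0: int = DEFAULT_P0,
    learning_factor: float = 3.0,
    include_long_run: bool = True,
    session_blocks: bool = False,
) -> list[ScenarioSpec]:
    """The standard condition battery.

    {control, trained 3-14, trained 12-30} x {death off, death on}, the
    doubled-learning-factor and doubled-rates variants (death on and off),
    and a 500-day control long run with death.  ``session_blocks`` swaps the
    contiguous calendar windows for the behavioral protocol's 5-days-on /
    2-days-off session structure (2 blocks from day 3, 3 blocks from day 12).
    """
    death = DeathModel()
    if session_blocks:
        win_314 = session_block_windows(3.0, 2)
        win_1230 = session_block_windows(12.0, 3, clip=30.0)
    else:
        win_314 = [WINDOW_3_14]
        win_1230 = [WINDOW_12_30]
    sched_314 = TrainingSchedule(win_314, learning_factor=learning_factor)
    sched_1230 = TrainingSchedule(win_1230, learning_factor=learning_factor)
    sched_314_2x = TrainingSchedule(win_314, learning_factor=2 * learning_factor)
    sched_1230_2x = TrainingSchedule(win_1230, learning_factor=2 * learning_factor)

    def spec(name, **kw):
        return ScenarioSpec(name=name, replicates=replicates, p0=p0, **kw)

    battery = [
        spec("control"),
        spec("trained_3_14", schedule=sched_314),
        spec("trained_12_30", schedule=sched_1230),
        spec("control_death", death=death),
        spec("trained_3_14_death", schedule=sched_314, death=death),
        spec("trained_12_30_death", schedule=sched_1230, death=death),
        spec("trained_3_14_2xlambda", schedule=sched_314_2x),
        spec("trained_12_30_2xlambda", schedule=sched_1230_2x),
        spec("trained_3_14_2xlambda_death", schedule=sched_314_2x, death=death),
        spec("trained_12_30_2xlambda_death", schedule=sched_1230_2x, death=death),
        spec("control_2xk", rate_multiplier=2.0),
        spec("trained_3_14_2xk", schedule=sched_314, rate_multiplier=2.0),
        spec("trained_12_30_2xk", schedule=sched_1230, rate_multiplier=2.0),
        spec("control_2xk_death", rate_multiplier=2.0, death=death),
        spec("trained_3_14_2xk_death", schedule=sched_314, rate_multiplier=2.0, death=death),
        spec("trained_12_30_2xk_death", schedule=sched_1230, rate_multiplier=2.0, death=death),
    ]
    if include_long_run:
        battery.append(spec("control_death_500d", horizon=500.0, death=death))
    return battery


def neuronal_increase_ratio(
    trained: ScenarioSummary,
    control: ScenarioSummary,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Trained/control endpoint-neuron ratio with a bootstrap interval.

    Resamples replicates with replacement within each condition and reports
    the percentile interval of the ratio of means.
    """
    if trained.spec.horizon != control.spec.horizon:
        raise ValueError("increase ratio requires matching horizons")
    if control.mean_neurons == 0:
        raise ValueError("control endpoint mean is zero; ratio undefined")
    ratio = trained.mean_neurons / control.mean_neurons
    rng = np.random.default_rng(seed)
    t_arr, c_arr = trained.endpoint_neurons, control.endpoint_neurons
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tm = rng.choice(t_arr, size=len(t_arr)).mean()
        cm = rng.choice(c_arr, size=len(c_arr)).mean()
        boots[b] = tm / cm if cm > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return {
        "ratio": float(ratio),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "trained_mean": trained.mean_neurons,
        "control_mean": control.mean_neurons,
    }


def long_run_additivity(
    spec: ScenarioSpec,
    rates: RateSet = DEFAULT_RATES,
    master_seed: int = 0,
    reference_day: float = 30.0,
) -> tuple[bool, dict[str, np.ndarray]]:
    """Whether the ensemble-mean alive neuron count keeps growing long-term.

    Returns True when the mean labeled-neuron count at the horizon exceeds
    the count at ``reference_day`` — i.e. adult neurogenesis keeps adding
    neurons to the circuit rather than saturating, even with the death
    checkpoint on.
    """
    if spec.death is None or not spec.death.enabled:
        raise ValueError("long-run additivity is defined with neuronal death enabled")
    summary = run_scenario(spec, rates=rates, master_seed=master_seed)
    traj = summary.mean_trajectory
    n_ref = float(np.interp(reference_day, traj["day"], traj["n"]))
    n_end = float(traj["n"][-1])
    return n_end > n_ref, traj


def welch_ttest(a, b) -> dict:
    """Welch two-sample t-test on endpoint samples (unequal variances)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return {"t": float(res.statistic), "p": float(res.pvalue), "df": float(res.df)}


def permutation_test(a, b, n_perm: int = 10000, seed: int = 0) -> dict:
    """Two-sided permutation test on the difference of means."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    res = stats.permutation_test(
        (a, b),
        lambda x, y: np.mean(x) - np.mean(y),
        permutation_type="independent",
        n_resamples=n_perm,
        rng=np.random.default_rng(seed),
    )
    return {"diff": float(np.mean(a) - np.mean(b)), "p": float(res.pvalue)}
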