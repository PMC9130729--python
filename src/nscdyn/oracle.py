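"""Closed-form expected trajectories of the labeled cohort.

The labeled counts obey a linear system on every interval of constant
rates.  The reservoir is constant, and with effective rates k_i' (= k_i
times the learning factor inside a training window, k2 never modulated)

    do/dt = k1'*r0 - beta*o,      beta = k2 + k5' + k6' - k3',
    dn/dt = (k4' + 2*k5' + k6')*o,

so on a segment [ta, tb) with o(ta) = oa:

    o(t)  = o* + (oa - o*)*exp(-beta*(t - ta)),   o* = k1'*r0/beta,
    int o = o*(t - ta) + (oa - o*)*(1 - exp(-beta*(t - ta)))/beta,
    n(t)  = n(ta) + (k4' + 2*k5' + k6') * int o.

These piecewise solutions are exact for the mean of the stochastic process
(the propensities are linear), which is what makes the oracle a strict
validation target for ensemble averages of the event-driven engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabeledCohort, RateSet, UnstableNetworkError
from .ssa import DeathModel, TrainingSchedule

__all__ = ["ExpectedTrajectory", "expected_trajectory", "expected_divisions",
           "expected_survival_fraction"]


@dataclass(frozen=True)
class _Segment:
    t0: float
    t1: float
    lam: float
    beta: float
    o_star: float
    o_at_t0: float
    n_at_t0: float
    int_o_before: float   # integral of o from 0 to t0

    k1_r: float = 0.0   # k1_eff * r0, used only in the beta -> 0 limit

    def o(self, t: float) -> float:
        dt = t - self.t0
        if self.beta == 0.0:
            return self.o_at_t0 + self.k1_r * dt
        return self.o_star + (self.o_at_t0 - self.o_star) * np.exp(-self.beta * dt)

    def int_o(self, t: float) -> float:
        """Integral of o over [t0, t]."""
        dt = t - self.t0
        if self.beta == 0.0:
            return self.o_at_t0 * dt + 0.5 * self.k1_r * dt * dt
        return self.o_star * dt + (self.o_at_t0 - self.o_star) * (
            1.0 - np.exp(-self.beta * dt)
        ) / self.beta


@dataclass
class ExpectedTrajectory:
    """Piecewise closed-form expectations r(t), o(t), n(t) and integral of o."""

    r0: float
    segments: list[_Segment]
    rates: RateSet
    horizon: float

    def r(self, t) -> np.ndarray | float:
        return np.full_like(np.asarray(t, dtype=float), self.r0) if np.ndim(t) else self.r0

    def _segment_at(self, t: float) -> _Segment:
        for seg in self.segments:
            if seg.t0 <= t <= seg.t1 and (t < seg.t1 or seg is self.segments[-1]):
                return seg
        if t == self.segments[-1].t1:
            return self.segments[-1]
        raise ValueError(f"time {t} outside [0, {self.horizon}]")

    def o(self, t: float) -> float:
        return float(self._segment_at(t).o(t))

    def integral_o(self, t: float) -> float:
        seg = self._segment_at(t)
        return float(seg.int_o_before + seg.int_o(t))

    def n(self, t: float) -> float:
        seg = self._segment_at(t)
        lam = seg.lam
        c = lam * (self.rates.k4 + 2 * self.rates.k5 + self.rates.k6)
        return float(seg.n_at_t0 + c * seg.int_o(t))

    def neuron_fraction(self, t: float) -> float:
        n = self.n(t)
        return n / (self.r0 + self.o(t) + n)

    def tabulate(self, times) -> dict[str, np.ndarray]:
        times = np.asarray(times, dtype=float)
        return {
            "day": times,
            "r": np.full_like(times, self.r0),
            "o": np.array([self.o(t) for t in times]),
            "n": np.array([self.n(t) for t in times]),
        }


def _effective(rates: RateSet, lam: float) -> tuple[float, float]:
    """(beta, o_star_coeff) for a segment with learning factor lam."""
    beta = rates.k2 + lam * (rates.k5 + rates.k6 - rates.k3)
    return beta, lam * rates.k1


def expected_trajectory(
    cohort: LabeledCohort,
    rates: RateSet,
    schedule: TrainingSchedule | None = None,
    horizon: float = 30.0,
) -> ExpectedTrajectory:
    """Exact expected counts of the labeled cohort over [0, horizon]."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    bounds = [0.0, float(horizon)]
    if schedule is not None:
        schedule.validate_horizon(horizon)
        bounds += [b for b in schedule.boundaries() if 0 < b < horizon]
    bounds = sorted(set(bounds))

    segments: list[_Segment] = []
    o_cur = float(cohort.o0)
    n_cur = float(cohort.n0)
    int_o = 0.0
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        lam = (
            schedule.learning_factor
            if schedule is not None and schedule.contains(t0)
            else 1.0
        )
        beta, k1_eff = _effective(rates, lam)
        if beta < 0:
            raise UnstableNetworkError(
                f"no stable operative pool on [{t0}, {t1}): effective "
                f"k2 + k5 + k6 - k3 = {beta:.6g} is negative"
            )
        # beta == 0 (e.g. all rates zero) falls back to the linear limit
        o_star = k1_eff * cohort.r0 / beta if beta > 0 else 0.0
        seg = _Segment(
            t0=t0, t1=t1, lam=lam, beta=beta, o_star=o_star,
            o_at_t0=o_cur, n_at_t0=n_cur, int_o_before=int_o,
            k1_r=k1_eff * cohort.r0,
        )
        segments.append(seg)
        c = lam * (rates.k4 + 2 * rates.k5 + rates.k6)
        n_cur = n_cur + c * seg.int_o(t1)
        int_o += seg.int_o(t1)
        o_cur = seg.o(t1)

    return ExpectedTrajectory(
        r0=float(cohort.r0), segments=segments, rates=rates, horizon=float(horizon)
    )


def expected_divisions(
    cohort: LabeledCohort,
    rates: RateSet,
    schedule: TrainingSchedule | None = None,
    horizon: float = 30.0,
) -> float:
    """Expected mean divisions per labeling lineage after ``horizon`` days.

    1 + [ k1*r0*(lambda-weighted elapsed time) + (k3+k4+k5)*(lambda-weighted
    integral of o) ] / p0 — the labeling division itself counts as 1.
    """
    traj = expected_trajectory(cohort, rates, schedule, horizon)
    total = 0.0
    for seg in traj.segments:
        total += seg.lam * rates.k1 * cohort.r0 * (seg.t1 - seg.t0)
        total += seg.lam * (rates.k3 + rates.k4 + rates.k5) * seg.int_o(seg.t1)
    return 1.0 + total / cohort.p0


def expected_survival_fraction(
    cohort: LabeledCohort,
    rates: RateSet,
    death: DeathModel,
    schedule: TrainingSchedule | None = None,
    horizon: float = 30.0,
) -> float:
    """Deterministic approximation of the surviving-neuron percentage.

    Expected survivors = (1 - p_eff) x (expected neuron mass whose age-15
    checkpoint has passed by ``horizon``) + (neurons still younger than the
    checkpoint age).  The rescue-modulated p_eff is applied piecewise over
    birth intervals whose checkpoint day falls inside a training window.
    Used for validation bands only; headline outputs come from simulation.
    """
    traj = expected_trajectory(cohort, rates, schedule, horizon)
    latest_resolved_birth = horizon - death.checkpoint_age
    if latest_resolved_birth < 0:
        return 100.0
    # cut birth axis at points where the checkpoint-day window membership flips
    cuts = {0.0, latest_resolved_birth}
    if schedule is not None:
        for a, b in schedule.windows:
            for x in (a - death.checkpoint_age, b - death.checkpoint_age):
                if 0 < x < latest_resolved_birth:
                    cuts.add(x)
    cuts_sorted = sorted(cuts)
    n_of = traj.n
    survivors = 0.0
    # mass born at exactly t=0 (the n0 cohort) resolves with p_eff at age 15
    p0_eff = death.p_death
    if schedule is not None and schedule.contains(death.checkpoint_age):
        p0_eff /= schedule.rescue_factor
    survivors += (1 - p0_eff) * cohort.n0
    for a, b in zip(cuts_sorted[:-1], cuts_sorted[1:]):
        mass = n_of(b) - n_of(a)
        mid_checkpoint = (a + b) / 2 + death.checkpoint_age
        p = death.p_death
        if schedule is not None and schedule.contains(mid_checkpoint):
            p /= schedule.rescue_factor
        survivors += (1 - p) * mass
    unresolved = n_of(horizon) - n_of(latest_resolved_birth)
    survivors += unresolved
    return 100.0 * survivors / n_of(horizon)
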