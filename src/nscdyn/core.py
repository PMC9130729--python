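"""Reaction network, equilibrium algebra and labeled-cohort initialization.

The model tracks two neural-stem-cell pools in the adult zebrafish pallium —
a self-renewing *reservoir* pool (rNSC) and a neurogenic *operative* pool
(oNSC) — plus the neurons (n) they produce, through six first-order
reactions:

    1) rNSC -> rNSC + oNSC   (rate k1, per day)   division
    2) oNSC -> death         (rate k2)
    3) oNSC -> oNSC + oNSC   (rate k3)            division
    4) oNSC -> oNSC + n      (rate k4)            division
    5) oNSC -> n + n         (rate k5)            division
    6) oNSC -> n             (rate k6)            direct differentiation

Reaction 1 does not consume the reservoir cell, and no reaction kills
reservoir cells, so the reservoir pool is structurally constant.  Mass
balance for the operative pool is

    do/dt = k1*r - (k2 + k5 + k6 - k3)*o,

whose stationary state, when the loss term beta = k2 + k5 + k6 - k3 is
positive, is o_eq = (k1/beta)*r_eq.  With the published rates this ratio is
exactly 1/4.

A thymidine-analog (BrdU/EdU) pulse labels cells in S-phase: each *labeling
division* produces two labeled daughters whose identities depend on which
reaction fired.  Given the steady-state proportions d1, d3, d4, d5 of
division events by reaction type, a cohort of P0 labeling divisions starts
as

    r(0) = P0*d1,  o(0) = P0*(d1 + 2*d3 + d4),  n(0) = P0*(d4 + 2*d5),

which conserves r(0) + o(0) + n(0) = 2*P0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "RateSet",
    "DivisionProportions",
    "LabeledCohort",
    "EquilibriumState",
    "UnstableNetworkError",
    "DEFAULT_RATES",
    "equilibrium_ratio",
    "division_proportions_analytic",
    "init_labeled_cohort",
]


class UnstableNetworkError(ValueError):
    """Raised when the operative pool has no finite stable equilibrium."""


@dataclass(frozen=True)
class RateSet:
    """Per-day rates of the six NSC reactions."""

    k1: float = 0.007
    k2: float = 0.017
    k3: float = 0.006
    k4: float = 0.018
    k5: float = 0.004
    k6: float = 0.013

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5", "k6"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be non-negative, got {getattr(self, name)}")

    @property
    def stability_denominator(self) -> float:
        """beta = k2 + k5 + k6 - k3; positive iff the operative pool is stable."""
        return self.k2 + self.k5 + self.k6 - self.k3

    def scaled(self, factor: float, *, include_k2: bool = False) -> "RateSet":
        """Multiply the division/differentiation rates (k1, k3..k6) by ``factor``.

        k2 (death of operative NSCs) is left unchanged unless ``include_k2``:
        learning modulates proliferation and differentiation, not oNSC loss.
        """
        return RateSet(
            k1=self.k1 * factor,
            k2=self.k2 * factor if include_k2 else self.k2,
            k3=self.k3 * factor,
            k4=self.k4 * factor,
            k5=self.k5 * factor,
            k6=self.k6 * factor,
        )

    def to_dict(self) -> dict[str, float]:
        return {f"k{i}": getattr(self, f"k{i}") for i in range(1, 7)}

    @classmethod
    def from_dict(cls, d: dict) -> "RateSet":
        missing = [f"k{i}" for i in range(1, 7) if f"k{i}" not in d]
        if missing:
            raise KeyError(f"rate config missing keys: {', '.join(missing)}")
        return cls(**{f"k{i}": float(d[f"k{i}"]) for i in range(1, 7)})


DEFAULT_RATES = RateSet()


@dataclass(frozen=True)
class DivisionProportions:
    """Fractions of division events by reaction type (reactions 1, 3, 4, 5).

    Reactions 2 (death) and 6 (direct differentiation) are not divisions and
    carry no proportion.  The published census values are d1=0.5, d3=0.11,
    d4=0.32, d5=0.07.
    """

    d1: float = 0.5
    d3: float = 0.11
    d4: float = 0.32
    d5: float = 0.07

    def __post_init__(self) -> None:
        vals = (self.d1, self.d3, self.d4, self.d5)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError(f"division proportions must lie in [0, 1], got {vals}")
        total = sum(vals)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"division proportions must sum to 1, got {total}")

    def to_dict(self) -> dict[str, float]:
        return {"d1": self.d1, "d3": self.d3, "d4": self.d4, "d5": self.d5}

    @classmethod
    def from_dict(cls, d: dict) -> "DivisionProportions":
        missing = [k for k in ("d1", "d3", "d4", "d5") if k not in d]
        if missing:
            raise KeyError(f"division-proportion config missing keys: {', '.join(missing)}")
        return cls(**{k: float(d[k]) for k in ("d1", "d3", "d4", "d5")})


@dataclass(frozen=True)
class EquilibriumState:
    """Stationary operative-to-reservoir ratio, and a reference reservoir size."""

    ratio_o_to_r: float
    r_eq: float = 1.0

    @property
    def o_eq(self) -> float:
        return self.ratio_o_to_r * self.r_eq


@dataclass(frozen=True)
class LabeledCohort:
    """Labeled cell counts immediately after the labeling pulse.

    ``p0`` labeling divisions produce 2*p0 labeled daughters split into
    reservoir NSCs (r0), operative NSCs (o0) and neurons (n0).  The
    per-lineage composition counts (m1, m3, m4, m5: how many lineages arose
    from each division reaction) are kept so the stochastic engine can assign
    every labeled cell to its lineage of origin.
    """

    r0: int
    o0: int
    n0: int
    p0: int
    m1: int = field(default=0, repr=False)
    m3: int = field(default=0, repr=False)
    m4: int = field(default=0, repr=False)
    m5: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if min(self.r0, self.o0, self.n0) < 0 or self.p0 <= 0:
            raise ValueError("cohort counts must be non-negative with p0 > 0")
        if self.r0 + self.o0 + self.n0 != 2 * self.p0:
            raise ValueError(
                f"labeled cohort must total 2*p0 = {2 * self.p0}, "
                f"got {self.r0 + self.o0 + self.n0}"
            )

    @property
    def total(self) -> int:
        return self.r0 + self.o0 + self.n0

    def to_dict(self) -> dict[str, int]:
        return {"r0": self.r0, "o0": self.o0, "n0": self.n0, "p0": self.p0}


def equilibrium_ratio(rates: RateSet) -> EquilibriumState:
    """Stationary operative-to-reservoir ratio o_eq / r_eq.

    The reservoir is constant (dr/dt = 0), and the operative pool obeys
    do/dt = k1*r - beta*o with beta = k2 + k5 + k6 - k3.  A finite stable
    equilibrium requires beta > 0; the ratio is then k1/beta.

    Raises
    ------
    UnstableNetworkError
        If beta <= 0 (operative pool grows without bound or is marginal).
    """
    beta = rates.stability_denominator
    if beta <= 0:
        raise UnstableNetworkError(
            "no stable equilibrium: k2 + k5 + k6 - k3 = "
            f"{beta:.6g} is not positive"
        )
    return EquilibriumState(ratio_o_to_r=rates.k1 / beta)


def division_proportions_analytic(rates: RateSet) -> DivisionProportions:
    """Steady-state division proportions from equilibrium event rates.

    At equilibrium the four division reactions fire at rates proportional to
    (k1*r_eq, k3*o_eq, k4*o_eq, k5*o_eq); normalizing these weights gives the
    expected fractions of division events by type.  With the published rates
    this evaluates to (0.5, 0.10714, 0.32143, 0.07143), the exact values
    behind the published census (0.5, 0.11, 0.32, 0.07).
    """
    eq = equilibrium_ratio(rates)
    w = (
        rates.k1 * 1.0,           # r_eq normalized to 1
        rates.k3 * eq.ratio_o_to_r,
        rates.k4 * eq.ratio_o_to_r,
        rates.k5 * eq.ratio_o_to_r,
    )
    total = sum(w)
    if total == 0:
        raise ValueError("no division activity: all division weights are zero")
    return DivisionProportions(*(x / total for x in w))


def init_labeled_cohort(p0: int, d: DivisionProportions) -> LabeledCohort:
    """Labeled cohort after one labeling division per lineage.

    Evaluates r0 = p0*d1, o0 = p0*(d1 + 2*d3 + d4), n0 = p0*(d4 + 2*d5).
    Rounding policy: the number of lineages of each division type is the
    largest-remainder integer apportionment of p0 over (d1, d3, d4, d5);
    (r0, o0, n0) follow from the per-type daughter identities, which makes
    conservation r0 + o0 + n0 = 2*p0 exact for every input.  For p0 that
    makes p0*d_i integral (e.g. 100 or 1000 with the published proportions)
    this coincides with direct evaluation of the formulas.
    """
    if p0 <= 0:
        raise ValueError(f"p0 must be a positive number of labeling divisions, got {p0}")
    props = (d.d1, d.d3, d.d4, d.d5)
    raw = [p0 * x for x in props]
    m = [int(x) for x in raw]
    short = p0 - sum(m)
    # largest fractional remainders get the leftover lineages
    order = sorted(range(4), key=lambda i: raw[i] - m[i], reverse=True)
    for i in order[:short]:
        m[i] += 1
    m1, m3, m4, m5 = m
    r0 = m1                     # reaction 1: one reservoir + one operative daughter
    o0 = m1 + 2 * m3 + m4       # reactions 1, 3, 4 contribute operative daughters
    n0 = m4 + 2 * m5            # reactions 4, 5 contribute neuron daughters
    return LabeledCohort(r0=r0, o0=o0, n0=n0, p0=p0, m1=m1, m3=m3, m4=m4, m5=m5)


def save_params(path: str | Path, rates: RateSet, d: DivisionProportions | None = None) -> None:
    """Write rates (and optionally division proportions) as flat YAML/JSON."""
    path = Path(path)
    payload: dict[str, float] = rates.to_dict()
    if d is not None:
        payload.update(d.to_dict())
    text = (
        json.dumps(payload, indent=2)
        if path.suffix == ".json"
        else yaml.safe_dump(payload, sort_keys=False)
    )
    path.write_text(text)


def load_rates(path: str | Path) -> RateSet:
    """Read a RateSet from a flat YAML or JSON key-value file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key-value mapping")
    return RateSet.from_dict(data)
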