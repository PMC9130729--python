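#!/usr/bin/env python
"""Equilibrium structure of the NSC network and the division-event census.

Establishes the two facts everything downstream builds on: (1) with the
published rates the operative pool settles at exactly one quarter of the
reservoir pool, and (2) at that equilibrium the division events split
~0.50 / 0.11 / 0.32 / 0.07 across the four division reactions, which fixes
the composition of a BrdU-labeled cohort.

Writes results/01_census.csv and prints the comparison.
"""

import sys
from pathlib import Path

import pandas as pd

from nscdyn.core import (
    DEFAULT_RATES,
    DivisionProportions,
    division_proportions_analytic,
    equilibrium_ratio,
    init_labeled_cohort,
)
from nscdyn.ssa import estimate_division_proportions

SEED = 0
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    eq = equilibrium_ratio(DEFAULT_RATES)
    print(f"operative/reservoir equilibrium ratio: {eq.ratio_o_to_r:g}")

    analytic = division_proportions_analytic(DEFAULT_RATES)
    census = estimate_division_proportions(
        DEFAULT_RATES, r_init=4000, duration=200.0, seed=SEED,
        o_init=1000, min_divisions=10_000,
    )
    published = DivisionProportions()
    rows = []
    for name, a, c, se, p in zip(
        ("d1", "d3", "d4", "d5"),
        (analytic.d1, analytic.d3, analytic.d4, analytic.d5),
        census.proportions,
        census.standard_errors,
        (published.d1, published.d3, published.d4, published.d5),
    ):
        rows.append({"proportion": name, "analytic": a, "census": c,
                     "census_se": se, "published": p})
        print(f"  {name}: census {c:.4f} +/- {se:.4f}  analytic {a:.4f}  "
              f"published {p}")
    pd.DataFrame(rows).to_csv(OUT / "01_census.csv", index=False)
    print(f"census of {census.n_divisions} division events "
          f"-> {OUT / '01_census.csv'}")

    cohort = init_labeled_cohort(1000, published)
    print(f"labeled cohort per 1000 labeling divisions: "
          f"r={cohort.r0} o={cohort.o0} n={cohort.n0}")


if __name__ == "__main__":
    sys.exit(main())
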