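# Methods

## The model

`nscdyn` simulates the fate of a cohort of thymidine-analog-labeled
(BrdU/EdU) neural stem cells in the adult zebrafish pallium.  Two stem-cell
pools are distinguished: a *reservoir* pool of deeply quiescent,
self-renewing cells (rNSC, count `r`) and an *operative* pool of neurogenic
cells (oNSC, count `o`) that feeds the neuron compartment (`n`).  Six
first-order reactions, with per-day rates taken from prior intra-vital
lineage-tracing work, define the network:

| # | reaction              | rate (1/day) | division? |
|---|-----------------------|--------------|-----------|
| 1 | rNSC → rNSC + oNSC    | k1 = 0.007   | yes       |
| 2 | oNSC → ∅              | k2 = 0.017   | no        |
| 3 | oNSC → oNSC + oNSC    | k3 = 0.006   | yes       |
| 4 | oNSC → oNSC + n       | k4 = 0.018   | yes       |
| 5 | oNSC → n + n          | k5 = 0.004   | yes       |
| 6 | oNSC → n              | k6 = 0.013   | no        |

Reaction 1 does not consume the reservoir cell and nothing kills reservoir
cells, so `r` is structurally constant; this is encoded as an invariant, not
a simulated reaction.  Mass balance for the operative pool is

    do/dt = k1·r − β·o,   β = k2 + k5 + k6 − k3,

stable whenever β > 0, with stationary ratio o*/r = k1/β = 0.25 for the
rates above.  (The published form of this equation has k2 and k3 swapped in
the loss term, which contradicts the published equilibrium o = r/4; the
mass-balance form is adopted here.)

At equilibrium the four division reactions fire at rates proportional to
(k1·r, k3·o, k4·o, k5·o), giving division-event proportions
d = (0.5, 0.107, 0.321, 0.071), published rounded as (0.5, 0.11, 0.32,
0.07).  A labeling pulse marks `P0` divisions, each producing two labeled
daughters, so the cohort starts at

    r(0) = P0·d1,  o(0) = P0·(d1 + 2·d3 + d4),  n(0) = P0·(d4 + 2·d5),

i.e. (500, 1040, 460) for P0 = 1000.  Rounding policy: the number of
lineages of each division type is a largest-remainder apportionment of P0
over d; daughter identities then determine (r0, o0, n0), making the
conservation r0 + o0 + n0 = 2·P0 exact for every input.  P0 is not stated in
the source; 1000 is the package default and is exposed everywhere as a
parameter, and endpoint counts are interpretable per-P0.

## Learning modulation and the death checkpoint

Training is a set of non-overlapping half-open calendar windows `[a, b)`.
Inside a window the division/differentiation rates k1, k3, k4, k5, k6 are
multiplied by the learning factor λ (default 3, the published estimate); k2,
the death of operative NSCs, is never modulated — learning boosts
proliferation, and neuronal survival has its own mechanism.  The default
windows are the two published training periods, contiguous intervals
[3, 14) and [12, 30) days post-labeling; a session-block mode (5 days on, 2
off, mirroring the behavioral protocol) is available via
`session_block_windows` and `default_battery(session_blocks=True)`, default
off.

Each labeled neuron makes a single Bernoulli survival decision when it
reaches the checkpoint age of 15 days (the `n(0)` cohort is newborn at
labeling, age 0).  The death probability defaults to **0.45**: the study
reports the checkpoint parameter as 0.550, but its own reported outcomes —
a ~45% loss of labeled cells between 4 and 32 dpl motivating the
checkpoint, and 67.1 ± 5.4% neuron survival at 30 days in control
simulations — identify 0.550 as the *surviving* fraction.  Under the
age-based rule the closed-form expectation is 67.2% survival with death
probability 0.45 versus 59.9% with 0.550, so the complement is used as the
default and the constant `PUBLISHED_CHECKPOINT_SURVIVAL = 0.550` is kept
alongside.  Passing `p_death=0.550` reproduces the literal reading.  If a
neuron's checkpoint day falls inside a training window the probability is
divided by the rescue factor (default 10, "up to ten times").

Checkpoint semantics are a genuine open point: the default is age-based
(each neuron draws at age 15); `DeathModel(mode="calendar")` implements the
alternative single day-15 cull of all neurons alive then.  Both have the
same expected survival at day 30; they differ in timing and in who faces
the draw for neurons born after day 15 (`calendar` spares them).

## Stochastic engine

The engine is an exact continuous-time Markov simulation (Gillespie direct
method) at the population level: next-event times from the total
propensity, category chosen proportionally, with piecewise-constant rates.
The exponential clock is re-drawn at window boundaries and daily sampling
stops, which is exact by memorylessness.  Neuron checkpoints change no
propensity (neurons fire no reactions), so they never interrupt the event
clock: they are resolved lazily as simulated time passes them, from a
dedicated random sub-stream.  Consequences:

- same seed ⇒ bit-identical trajectories, event logs and ledgers;
- a λ=1, rescue=1 schedule consumes the same stream as no schedule and
  yields identical runs;
- paired death-on/death-off runs with the same seed share an identical
  division history (common random numbers), so the paired survival
  statistic `100·n_with/n_without` has no between-run noise in its
  denominator.

Per-cell identity is kept only where the science needs it.  Every labeled
cell belongs to one of the P0 labeling lineages; each division event
(reactions 1, 3, 4, 5) increments its lineage's division counter, which
starts at 1 for the labeling division itself.  Neurons record birth time,
lineage, and checkpoint status.  Reservoir cells are drawn uniformly for
reaction 1; operative cells uniformly for reactions 2–6, implemented as a
swap-pop list of lineage ids.

Replicate seeds are `base + i` with `base = (master_seed +
crc32(scenario_name)) mod 2³¹`, so battery results are independent of the
order scenarios run in; each run's seed is split via `SeedSequence.spawn`
into the event stream and the death-draw stream.

## Mean-field oracle

Because all propensities are linear, the expectation of the stochastic
process obeys the same linear ODEs exactly, and these solve in closed form
segment by segment:

    o(t)  = o* + (o(ta) − o*)·e^(−β·(t−ta)),   o* = λk1·r0/β,
    n(t)  = n(ta) + λ(k4 + 2k5 + k6)·∫ o dt,

with β = k2 + λ(k5 + k6 − k3) on a segment with learning factor λ (β = 0
falls back to the linear limit, so an all-zero network is handled; β < 0
raises an error naming the interval).  Expected divisions per lineage are
1 + [λk1·r0·Δt + λ(k3+k4+k5)·∫o dt]/P0 accumulated over segments.  For the
control condition this gives n(30) = 1.331·P0, a neuron fraction of 56.6%
(published "~60%") and 1.727 divisions per lineage (published "~1.7").  A
deterministic survival approximation (survivors = (1−p_eff)·checkpoint-
resolved mass + younger mass, with p_eff pieced over birth intervals) is
used for validation bands only; headline outputs always come from
simulation.  The oracle is itself validated against `scipy.solve_ivp` at
tolerance 1e-8, and 1000-replicate SSA ensembles match it within 3 standard
errors at days 10/20/30 in control and trained conditions.

## Pseudo-experimental count generator

The study's per-fish BrdU⁺NeuN⁺ counts are available only as group
mean ± SE (rMP: Control 57.73 ± 26.00 N=5, Trained 204.50 ± 56.36 N=7;
cLP: Control 44.39 ± 12.71 N=5, Trained 112.28 ± 16.41 N=7; the 12–30 dpl
experiment).  The generator draws counts from a zero-truncated normal whose
*truncated* distribution is moment-matched to the target mean and SD
(SD = SE·√n): the standardized truncation point solves CV(α) = target CV by
Brent's method, then the scale matches the mean.  A zero-truncated normal
cannot exceed CV ≈ 1 (its exponential limit); for targets at or past the
bound — rMP Control has CV = 1.007 — the shape is capped at the limit
(α = 30, achievable CV 0.9989), the mean is still matched exactly, and the
achieved SD (shortfall < 1% for rMP Control) is recorded in the table's
metadata.  The truncated-normal family was chosen over a lognormal for
transparency of the moment match; with n = 5–7 fish per group either family
is observationally equivalent at these CVs.

What the emulator does and does not show: passing calibration tests means
the generated tables reproduce the published summary statistics, so the
model-vs-data ratio comparison is exercised end-to-end; it says nothing
about the true per-fish count distribution, per-section counting structure,
or any covariate the published summaries do not cover.

## Scenario battery and statistics

The default battery is {control, trained 3–14, trained 12–30} × {death
off, on}, the 2×λ and 2×k_i variants (the latter doubling k1, k3–k6 but not
k2, mirroring "division/differentiation rates"), and a 500-day control long
run with death.  Endpoints per replicate: day-30 neuron count, neuron
fraction, divisions per lineage, and paired survival where applicable.  The
learning effect is summarized as the ratio of trained to control mean
endpoint neurons with a percentile bootstrap over replicates; ratios are
reported against the matching baseline (plain control for λ variants, the
2×k control for 2×k variants), covering both normalizations.  Shipped
comparisons are a Welch t-test and a permutation test on endpoint means;
the original two-way ANOVA with Šidák post-hocs belongs to the experimental
analysis and is out of scope.

Reference values at the default study conditions (P0=1000, N=20, master
seed 0): without death the two windows gain similarly (1.45× vs 1.58×);
with death the late window pulls ahead (1.35× vs 2.31×) because only
checkpoints of the 12–30 window fall inside training and get rescued; the
2×λ + death condition reaches 3.40×, closest to the data ratio (~3.5–3.7×
from the published group means), reproducing the study's conclusion that
learning needs both boosted chained proliferation and death rescue.

## Numerical and design choices

- **Problem sizes.** Default P0 = 1000 labeling divisions, 20 replicates
  per condition (the published simulation N), 30-day horizon, 500 days for
  the long run.  The steady-state census runs r = 4000, o = 1000 for 200
  days (extended until ≥10⁴ division events).  Validation ensembles use
  1000 replicates so that twelve simultaneous 3-SE checks have a small
  joint false-alarm probability.
- **Ties and degenerate inputs.** Zero total propensity simply advances to
  the next sampling stop; an all-zero rate set yields constant
  trajectories.  A census with zero divisions raises; one with fewer than
  100 attaches a warning rather than failing.  Survival is reported as
  missing (None) when the no-death pair has no neurons.
- **Rounding.** Cohort counts use largest-remainder apportionment (exact
  conservation); reported proportions are raw double precision, rounded
  only at I/O.
- **Serialization.** All run inputs (rates, cohort size, schedule, death
  model, replicates, master seed) round-trip through one YAML/JSON
  document; every CLI output directory contains the config echo and seeds
  needed to regenerate it.

## Limitations

- The model tracks only the labeled cohort; the unlabeled background
  population, spatial structure, migration, and progenitor substates are
  out of scope by design.
- Rates k1–k6 are constants from prior work in a different experimental
  context; no inference from data is attempted, and the model's documented
  undershoot of the experimental increase ratio plausibly traces to them,
  to λ, or to the death parameterization.
- The checkpoint parameter reconciliation (death probability 0.45) rests on
  internal consistency of the published outcomes, not on access to the
  original simulation code; both readings are available as parameters.
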