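# Methods

## The model

`neurodup` asks a minimal question about redundant neural circuitry: given a
structure made of K0 unreliable submodules, when does it pay to build one
copy, two copies, or none?  The two copies are conveniently called *left*
and *right* (bilateral counterparts), but nothing in the mathematics
requires bilateral symmetry — any pair of duplicated circuits is covered.

Each structure keeps a fraction κ_L (left) and κ_R (right) of its K0
submodules active.  An active submodule computes its task incorrectly with
probability ε, independently of everything else.  A task is implemented
successfully if at least one active copy of its submodule computes
correctly, so the per-task success probability is

    p(κ_L, κ_R, ε) = (1−ε)[κ_L(1−κ_R) + (1−κ_L)κ_R] + (1−ε²) κ_L κ_R .

The three bracketed events are: only the left copy active and correct, only
the right copy active and correct, both active and not both wrong.

Benefits accrue in two scenarios:

* **Uncooperative** — every task pays b on its own.  Expected benefit
  B = b·p·K0.
* **Cooperative** — the tasks jointly support an emergent phenotype worth
  b·K0, paid only when *all* K0 tasks succeed.  Expected benefit
  B̃ = b·K0·p^K0.  The reward scales with the phenotype's complexity (K0)
  and the success requirement is conjunctive, so the whole per-task success
  probability p — including its (1−ε) reliability factor — is raised to
  the K0-th power.  This grouping makes the cooperative benefit reduce
  exactly to the uncooperative one at K0 = 1, which the test suite uses as
  a built-in consistency check.

Two costs oppose the benefits:

* **Coordination cost** C = c·κ_L·κ_R·K0 — integrating duplicated outputs
  costs c per task that both copies activate; it vanishes when either
  structure is silent.
* **Activation cost** Ĉ = ĉ·(1−ε)·(κ_L+κ_R)·K0 — each active module costs
  ĉ·(1−ε).  More reliable modules (lower ε) are assumed metabolically more
  expensive; the dependence is taken linear for simplicity (nonlinear
  variants are out of scope).

The normalized (per-K0) utilities are

    ρ  = b(1−ε)[κ_L(1−κ_R) + (1−κ_L)κ_R + (1+ε)κ_Lκ_R] − cκ_Lκ_R − ĉ(1−ε)(κ_L+κ_R)
    ρ̃  = b·p^K0 − cκ_Lκ_R − ĉ(1−ε)(κ_L+κ_R) .

## Parameters

| symbol | meaning | domain | default |
|---|---|---|---|
| b | fitness benefit per implemented task (dimensionless) | > 0 | 1 (sets the scale) |
| c | coordination cost per doubly-active task | ≥ 0 | swept |
| ĉ | activation cost scale per active module | ≥ 0 | 0.1 |
| ε | per-module failure probability | [0, 1] | swept |
| K0 | tasks (= submodules) per structure | integer ≥ 1 | 10 for cooperative diagrams |

b = 1 is a choice of units, and ĉ = 0.1 the reference fixed cost; both are
recorded in every grid's metadata.  K0 only matters in the cooperative
scenario; 10 is the package default, chosen so that the third phase (build
nothing) is clearly developed — every structural property checked by the
tests holds for any K0 ≥ 2.

## Optimization and phases

κ_L, κ_R are treated as continuous in [0, 1] by default; a discrete mode
(`Activation.validate_discrete`) restricts them to multiples of 1/K0 for
fidelity to the underlying module counts.  The continuous relaxation is
what makes the absence of graded optima a meaningful claim.

Both utilities are multilinear in (κ_L, κ_R) up to the p^K0 term, and their
maxima over the unit square sit at corners.  The package does not prove
this symbolically; it verifies it numerically (`verify_corner_optimality`:
max over a 101×101 κ grid ≤ max over the four corners + 1e-9, checked on
1000 random parameter draws per run).  Given corner optimality the optimum
is one of three *phases*:

* NONE — κ = (0,0) optimal (utility 0),
* SINGLE — κ = (1,0) or (0,1) (exactly degenerate by symmetry, reported as
  one label),
* DUPLICATED — κ = (1,1).

Ties within an absolute tolerance of 1e-12 break toward fewer active
structures: a structure with zero net advantage is not built.  The
tolerance is far below any utility difference of interest and far above
float rounding of these O(1) expressions.

## Phase boundaries

Comparing corner utilities gives closed-form critical coordination costs.
Uncooperative: duplication beats a single structure iff

    c < c* = (1−ε)(bε − ĉ) ,

so for b = 1, ĉ = 0.1 the duplicated region is the lens 0 ≤ c < c*(ε),
widest at intermediate ε — redundancy pays when modules are unreliable
enough to need a backup but reliable enough that the backup works.  With
b > ĉ a single structure always has positive utility, so the uncooperative
diagram has exactly two phases.

Cooperative: with q₁ = (1−ε)^K0 and q₂ = (1−ε²)^K0,

    single viable   iff  b·q₁ > ĉ(1−ε)
    c₁ = b(q₂ − q₁) − ĉ(1−ε)      (duplicated vs single)
    c₂ = b·q₂ − 2ĉ(1−ε)           (duplicated vs none)

The all-or-nothing reward makes q₁ collapse rapidly with K0, opening a
third phase where nothing is worth building, and enlarging the duplicated
region at moderate ε (a single structure cannot deliver the phenotype, but
a redundant pair can).  The closed forms apply the same 1e-12 tie-break as
the classifier, so boundary cells that tie exactly resolve identically in
both routes; the brute-force sweep and the closed forms are required to
agree on every cell, and the label flip along c to bracket the analytic
threshold within one grid step.

## Transition maps

Superposing the uncooperative diagram (pre-adaptation) with the cooperative
one (emergent phenotype) labels each (ε, c) cell with the evolutionary path
implied if the environment begins rewarding the conjunction of tasks:

| pre → post | label |
|---|---|
| any → NONE | NO_EMERGENCE |
| SINGLE → SINGLE | LATERAL_TO_LATERAL |
| SINGLE → DUPLICATED | LATERAL_TO_BILATERAL |
| DUPLICATED → DUPLICATED | BILATERAL_TO_BILATERAL |
| DUPLICATED → SINGLE | BILATERAL_TO_LATERAL |
| NONE → non-NONE | DENOVO |

Under the default parameters only the first four occur.
BILATERAL_TO_LATERAL never appears — at fixed (ε, c) this trade-off never
lateralizes an existing bilateral structure, because the conjunctive reward
only increases the value of redundancy; observing such a transition would
require the emergence itself to move ε or c.  DENOVO (nothing optimal
before, something after) requires b ≤ ĉ or ε → 1 in the pre-layer and is an
extrapolation label of this package, not a prediction of the model; both
counts are computed and reported rather than assumed.  The grids being
superposed must share axes, b and ĉ exactly; K0 may differ because the
cooperative K0 is a property of the emergent phenotype.

`trace_path` reports the ordered sequence of regions along a user-given
(ε, c) polyline, sampled at grid resolution.  It is illustrative; no claim
is made about any particular published trajectory.

## Monte Carlo oracle

`simulate_benefit` / `simulate_utility` resample the generative story
directly: per replicate, each of the K0 tasks draws left/right activation
as Bernoulli(κ_L), Bernoulli(κ_R) and failure as Bernoulli(ε) per active
module; a task succeeds if an active module survives.  Uncooperative
benefit is b × (successful tasks); cooperative is b·K0 × 1{all succeed}.
Costs enter as their deterministic expected values (the cost expressions
are written directly in κ), which changes only the variance of simulated
utilities, never their mean.  The RNG is numpy's PCG64 (`default_rng`);
the generator name and seed are stored in every `SimResult`, and identical
inputs and seed reproduce results bit-for-bit.

The Bernoulli-activation reading treats κ as the probability that a
randomly selected module is active.  A deterministic mode activating
exactly round(κ·K0) modules is also provided; the two have identical means
at the corner activations where all phase decisions live, and differ in
variance (and in means at fractional κ in the cooperative scenario, where
p^K0 is nonlinear in the activation pattern).

Agreement with the closed forms is judged by z = (mean − closed)/SE with a
4-SE band.  Two degenerate cases need care.  A constant sample has SE
exactly 0 (numpy's `std` would report ~1e-17 summation noise, which the
summarizer truncates to 0).  And when the cooperative success probability
p^K0 is tiny, all replicates can legitimately come out 0 while the closed
form is positive; the z-ratio is then undefined.  In that case `zscore`
returns the smallest |z| attainable by any per-replicate distribution that
is bounded by the replicate range, has the closed-form mean, and could
have produced the constant sample — z = √(n·q/(1−q)) with
q = |diff|/range — which correctly passes an all-zero sample when the
expected success count n·p^K0 is of order one, and still diverges for a
genuinely wrong implementation.  A 4-SE band across the suite's ~80
comparisons still fails falsely about 0.5% of the time, so stochastic
tests retry once with a second fixed seed before failing.

## Numerical choices

- Tie tolerance 1e-12 (absolute, utilities are O(1)); corner-optimality
  verification at resolution 101 with tol 1e-9 — dense enough to expose an
  interior optimum of these smooth low-degree surfaces, cheap enough to run
  thousands of times.
- Default diagram axes: ε ∈ [0.005, 0.995], 199 points; c ∈ [0, 1], 201
  points.  The range contains every analytic boundary at b = 1, ĉ = 0.1 and
  avoids the degenerate ε ∈ {0, 1} edges, which remain fully supported when
  requested explicitly.
- p^K0 with p = 0 and K0 ≥ 1 is 0; K0 is validated integral so no
  fractional powers arise.
- Grid labels are stored as int8 with a fixed encoding (0=NONE, 1=SINGLE,
  2=DUPLICATED; transitions 0–5 in the table's order) and round-trip
  losslessly through the TSV format (axes written with `format_float_positional`,
  unique shortest representation).
- Utilities print at 12 significant digits in the CLI so regressions are
  diff-able.

## Problem sizes

The shipped checks use 199×201 diagram grids, 101×101 activation grids
with 1000 random parameter draws for corner optimality, and 100,000
Monte Carlo replicates for 20 draws per scenario and quantity; the whole
verification pipeline completes in a few seconds on one core.

## Limitations

- The corner-optimality claim is verified numerically on random draws and
  dense grids, not proven symbolically.
- Linear cost weighting throughout; Pareto-style multi-objective treatment
  and nonlinear activation-cost laws are out of scope.
- The model is a static optimum comparison: no population dynamics,
  learning, or explicit evolutionary process sits on top of the utilities.
- The synthetic stochastic layer emulates exactly the model's independence
  assumptions (independent module failures, independent per-task
  activation).  Passing Monte Carlo checks therefore validates the algebra,
  not the biological realism of those assumptions — correlated failures,
  heterogeneous module reliabilities and shared metabolic budgets are all
  outside the model.
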