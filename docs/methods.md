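# Methods

This document records the mathematical models, the exact ILP formulations,
the numerical conventions, and the synthetic-instance generators implemented
in `splitdiv`, together with their assumptions and limitations.

## 1. Split systems and split diversity

A taxon set `X = {s_1, …, s_n}` is held in a `TaxonSet` with a fixed label
order. A **split** `σ = A|B` is a bipartition of `X` into two non-empty
sides, stored as an `n`-bit membership vector. Because `A|B` and `B|A` are
the same split, every split is canonicalized so that the first taxon carries
bit 0; all-zero or all-one vectors are rejected (`DegenerateSplitError`).
Both side bitmasks are precomputed so that "σ separates subset W" reduces to
two integer AND tests.

A **split system** `(Σ, λ)` is a set of splits with positive weights;
duplicate splits merge by weight addition. The **split diversity** of a
subset `W ⊆ X` is

```
SD(W) = Σ_{σ ∈ Σ : σ separates ≥ 2 taxa of W} λ(σ),
```

where σ separates W when both sides of σ intersect W.

**Trees.** Every edge of an unrooted phylogenetic tree induces the split of
taxa below it versus the rest; the split's weight is the branch length. The
two edges incident to the root of a rooted binary tree induce the *same*
split, so their lengths merge — a tree with `n` leaves therefore yields at
most `2n − 3` splits. Missing branch lengths are treated as 0 (with a
warning). On a single tree's split system, `SD(W)` equals Faith's PD of `W`
(the length of the minimal subtree spanning `W`); the package verifies this
identity exhaustively in the test suite against an independent PD
implementation that unions leaf-to-leaf paths with `networkx`.

**Tree collections.** `aggregate_trees` pools the splits of a collection
sharing one taxon set, with three weight modes: `mean` (average branch
length, absent = 0), `sum`, and `frequency` (fraction of trees containing
the split). Mismatched taxon sets are an error that names the symmetric
difference.

## 2. Food webs, viability, diet viability

A food web is a directed graph with arrows predator → prey. Taxa without
prey are **basal**. Webs are validated for (a) self-loops (error), (b)
cycles (warning by default, error with `strict_dag=True`), and (c)
reachability of the basal set via a fixed-point iteration (a predator none
of whose prey can themselves be sustained is reported).

A subset `S` is **viable** when every non-basal taxon in `S` has at least
one prey in `S`.

A `DietMatrix` attaches to each predator `j` a row of diet proportions
`w_ji ≥ 0` over its prey, each row summing to 1 (tolerance
`DIET_SUM_TOL = 1e-6`). The **diet score** of predator `j` in `S` is
`δ_j(S) = Σ_{i ∈ S} w_ji` (basal taxa score 1 by convention). `S` is
**d%-viable** when `δ_j(S) ≥ d/100` for every predator `j ∈ S`; the
predicate allows slack `D_VIABLE_SLACK = 1e-12` — strictly a float-roundoff
allowance, far below any meaningful diet proportion, so it cannot mask a
genuine violation. As `d → 0⁺`, d%-viability degenerates to plain viability
restricted to positive-weight prey; the constant `EPSILON_D = 1e-7`
represents that limit.

## 3. ILP layer

All optimization problems are solved exactly with `scipy.optimize.milp`
(the HiGHS branch-and-bound solver). A thin `ILPModel` layer accumulates
named binary variables, linear constraints, and fixings, converts them to a
sparse constraint matrix, and can also serialize to LP format for
inspection. Solver feasibility tolerances are tightened to `1e-9`
(`mip_feasibility_tolerance`, `primal_feasibility_tolerance`): the HiGHS
default of `1e-6` is loose enough to let fractional-looking solutions
violate small-coefficient diet constraints.

For every problem, a brute-force enumeration oracle over all subsets
(bitmask-based, practical up to ~20 taxa / ~15 areas) provides an
independent optimum; the acceptance tests check ILP-vs-oracle equality on
hundreds of seeded instances.

## 4. Reserve selection

**Data.** A `Landscape` has `m` areas with costs `c_i`, a presence matrix
`r_ij ∈ {0,1}` (taxon `j` present in area `i`), a symmetric boundary-length
matrix `b` with `b_ii` the perimeter of area `i` and `b_ij` the boundary
shared between areas `i` and `j`, a fencing price `β` per unit boundary
length, and an optional per-area urban flag. Validation warns when
`b_ii < Σ_j b_ij` (an area cannot share more boundary than its perimeter).
The fence length of a selection is `Σ_{i sel} b_ii − 2 Σ_{i<j sel} b_ij`:
shared internal boundaries need no fence.

**Model.** Binary `x_i` (area selected), `z_ij` for adjacent pairs
(both endpoints selected), `y_σ` per split (split counted). Minimize

```
Σ_i c_i x_i + β ( Σ_i b_ii x_i − 2 Σ_{i<j} b_ij z_ij )
```

subject to

- `z_ij ≤ x_i`, `z_ij ≤ x_j` — since `z` has a negative objective
  coefficient (for `β > 0`) the solver pushes it up, so the lower-bound
  constraint `z_ij ≥ x_i + x_j − 1` is redundant and omitted by default
  (`strict_z=True` adds it, used in tests);
- for each split σ and each of its two sides: `y_σ ≤ Σ_{i covers side} x_i`,
  where area `i` covers a side when it hosts at least one taxon of that
  side. A side no area covers forces `y_σ = 0` (with a warning);
- the diversity target `Σ_σ λ(σ) y_σ ≥ (p/100) Σ_σ λ(σ)`.

**Exact thresholds.** Split weights enter the target constraint as scaled
integers (`round(λ × 10⁶)`, `WEIGHT_SCALE = 10**6`), and the right-hand side
is `ceil(p·total/100 − 1e-6)`. This makes the `p%` threshold exact for
weights with up to six decimal digits and immune to floating-point
accumulation; the `1e-6` guard keeps an exactly attainable integer target
from being rounded up.

`solve_reserve` pre-checks feasibility at `p = 100` (a positive-weight split
with an entirely uncoverable side is a certificate of infeasibility,
reported with the affected taxa), and post-verifies every solution by
recomputing SD of the covered taxa independently of the solver's `y`
variables.

**Minimum representation.** At `p = 100` and `β = 0`, on a split system
containing all trivial splits, the problem reduces to minimum-cost set
cover (every taxon covered). `minimum_representation` solves that set-cover
ILP directly; the reduction is verified in the acceptance tests.

## 5. Viable taxon selection

Binary `v_i` (taxon selected), `y_σ` per split. Maximize `Σ_σ λ(σ) y_σ`
subject to

- budget `Σ_i v_i ≤ k` (forced taxa can optionally be exempted from the
  budget via `forced_exempt_from_k`);
- for each split side: `y_σ ≤ Σ_{i ∈ side} v_i`;
- viability: for each predator `j`, `v_j ≤ Σ_{i ∈ prey(j)} v_i`;
- or d%-viability: `Σ_i w_ji v_i ≥ (d/100) v_j`, linearized as
  `(d/100) v_j − Σ_i w_ji v_i ≤ 0`;
- forced taxa fixed to 1.

**The ε threshold.** When `d/100 < 1e-6` the weighted constraint would sit
below the solver's feasibility tolerance and become vacuous. The model
therefore substitutes the mathematically equivalent limit form
`v_j ≤ Σ_{i ∈ prey(j), w_ji > 0} v_i` — plain viability restricted to
positive-weight prey. This is what makes the `d = EPSILON_D` reduction to
Problem "viable selection" hold to machine precision.

`solve_taxon` pre-checks forced predators whose candidate prey cannot
possibly satisfy their constraint and returns an infeasibility certificate
naming them; every returned selection is re-checked against the independent
`is_viable` / `is_d_viable` predicates before being reported.

`unconstrained_gap` quantifies what viability costs: it solves the same
budgeted SD maximization without viability constraints, reports the relative
SD gap to the viable optimum, and lists the prey-less predators the
unconstrained optimum would have selected.

## 6. Economic sweep and break-even analysis

Given a landscape with urban/rural flags, `with_urban_ratio(ρ)` scales urban
base costs by ρ. For a grid of ratios, `cost_ratio_sweep` re-solves reserve
selection at each ρ and merges consecutive grid points with identical
selections into `SweepInterval`s. Each interval carries a `CostLine`
`cost(ρ) = intercept + slope·ρ`, with slope the sum of the selected urban
base costs. The optimal-cost curve is the lower envelope of these lines:
piecewise linear and concave, with non-increasing slopes, terminating in a
zero-slope segment once the optimum is purely rural (assuming rural areas
alone can cover all taxa).

`accumulated_cost_crossover` finds where the *accumulated* (integrated over
the price trajectory) cost of keeping the early, urban-containing optimum
overtakes that of switching to the final rural-only optimum:

- `discrete` mode sums per-step costs along the ratio grid until the running
  totals cross;
- `analytic` mode integrates the two cost lines and solves the resulting
  quadratic for its admissible root (≥ start of the trajectory, with the
  difference positive just after the root).

The two modes agree within one grid step; both are reported by the
acceptance script.

## 7. Synthetic generators

All generators are driven by a single integer seed and are bit-reproducible
(`random.Random` / `numpy.random.default_rng`). Defaults in `SynthSpec`:

| knob | default | meaning |
|---|---|---|
| `n_taxa` | 20 | taxa |
| `n_trees` | 100 | replicates in a collection |
| `nni_moves` | 2 | NNI rearrangements per replicate |
| `length_jitter_sigma` | 0.3 | lognormal σ multiplying each branch length |
| `grid` | 6 | landscape is `grid × grid` unit cells |
| `occupancy` | 0.8 | per-cell presence probability inside a range rectangle |
| `max_range` | 3 | max range-rectangle side (clamped to `grid`) |
| `urban_block` | 2 | side of the urban corner block |
| `unit_price` | 1.0 | cost per unit cell |
| `layers` | 3 | trophic layers in the food web |
| `connectance` | 0.5 | probability of each cross-layer prey link |
| `diet_concentration` | 1.0 | symmetric Dirichlet parameter for diet rows |

- **Tree collections** (`gen_tree_collection`): a Yule-style base topology
  with exponential branch lengths; each replicate applies NNI moves and
  multiplicative lognormal length noise — a caricature of bootstrap
  replicates, not a statistically calibrated bootstrap.
- **Grid landscapes** (`gen_landscape`): unit cells (perimeter 4, shared
  edges 1, 4-neighbourhood), clustered rectangular species ranges, urban
  corner block. Cost heterogeneity beyond urban/rural is absent by design.
- **Strip landscapes** (`gen_strip_landscape`): `m` cells in a row with
  integer costs — deliberately tiny geometries for exhaustive enumeration
  cross-checks.
- **Food webs** (`gen_foodweb`): round-robin layer assignment (hence
  acyclic), every consumer guaranteed ≥ 1 prey, Dirichlet diet rows
  renormalized to sum to 1 exactly.

These emulate the *structure* the methods assume (conflicting tree
collections, spatial boundary geometry, acyclic webs with proportion diets);
they do not emulate any particular empirical system.

## 8. Numerical conventions (summary)

| constant | value | role |
|---|---|---|
| `WEIGHT_SCALE` | 10⁶ | scaled-integer split weights in the p% constraint |
| p% rhs guard | 1e-6 | `ceil(p·total/100 − 1e-6)` — exact attainability |
| solver tolerances | 1e-9 | HiGHS MIP/primal feasibility |
| `DIET_SUM_TOL` | 1e-6 | diet rows must sum to 1 within this |
| `D_VIABLE_SLACK` | 1e-12 | roundoff slack in the d%-viability predicate |
| `EPSILON_D` | 1e-7 | the d → 0⁺ limit value |
| ε-constraint switch | d/100 < 1e-6 | weighted constraint replaced by limit form |

`D_VIABLE_SLACK` must stay far below `EPSILON_D / 100` (it is 10⁻³ of it);
otherwise the ε-limit predicate becomes vacuously true.

**Tie-breaking.** Optima need not be unique; tests compare objective values,
never selected sets, except where a predicate must hold of whatever set the
solver returns.

## 9. Problem sizes and limits

The ILPs comfortably handle hundreds of areas/taxa and thousands of splits
on one CPU; the enumeration oracles cap at ~20 taxa / ~15 areas and exist
only for verification. Split systems are stored densely per split (bitmasks
over `n` taxa), which is appropriate for `n` up to a few thousand. The
sweep's structural guarantees (concavity, terminal flat segment) assume
rural areas alone can cover every taxon; when they cannot, the final
interval may retain urban areas and a positive slope, which the sweep
reports as-is.
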