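# Methods

## Model and feasible set

A metabolic network is given by its stoichiometric matrix N (m internal
metabolites × n reactions), per-reaction reversibilities and flux bounds,
and optionally extra linear constraints G r ≤ h.  The feasible set is the
flux polyhedron P = {x | A x ≤ b} assembled row-wise as: the steady-state
block N x = 0 (stored as designated *equality* rows rather than ±N
inequality pairs — smaller LPs and better conditioning; an expansion to
the all-inequality form is provided for interoperability), one row per
*finite* bound, and the G block.  Infinite bounds never become rows and
are never replaced by large finite numbers, so unboundedness detection is
exact.  When every bound is infinite and G is empty, b = 0 and P is the
flux cone.  Reaction order is file order; all vectors are positional.

## Rate and yield optimization

Rate optimization max cᵀx over P is a plain LP, solved with HiGHS
(`scipy.optimize.linprog`); infeasibility and unboundedness are reported
as statuses, never exceptions or surrogate values.

Yield optimization max cᵀx/dᵀx over P> = {x ∈ P | dᵀx > 0} is a
linear-fractional program.  With the substitution x′ = x/dᵀx, t = 1/dᵀx
it is equivalent to the LP max cᵀx′ over
P′ = {(x′, t) | A x′ ≤ t b, dᵀx′ = 1, t ≥ 0}: same optimal value,
solutions with t > 0 back-transform to x = x′/t ∈ P>, and solutions with
t = 0 are recession directions of P along which the optimum is approached.
The solver distinguishes four outcomes:

* `infeasible_domain` — the auxiliary LP is infeasible, or the maximal
  feasible t is 0 (no point of P has positive denominator);
* `unbounded` — the auxiliary LP is unbounded, which happens exactly when
  some feasible direction has cᵀu > 0 with dᵀu = 0 (an ill-posed
  denominator, e.g. product synthesis from an unaccounted substrate);
* `optimal_attained` — either the first optimum already has t* > 0, or
  re-solving with t pinned to a probe value t̃ = min(1, t_max/2)
  reproduces the optimal value, in which case the probe witness is
  returned.  The probe value must merely be strictly inside the feasible
  t-range; the midpoint (capped at 1) keeps it away from both the
  degenerate t = 0 face and the numerically delicate extreme of t_max.
  Objective equality is tested at relative tolerance 1e-7;
* `optimal_not_attained` — the probe objective falls short; the t = 0
  optimizer is returned as the limit direction (it satisfies A u ≤ 0,
  dᵀu = 1).

Witness vectors are not unique (optimal faces are typically
higher-dimensional); only objective values and the stated witness
properties are API contracts.  When several optimal bases exist both at
t = 0 and t > 0, the t > 0 witness is returned — the finite-flux
representative is the one of practical interest.

Flux coupling analysis reuses the LFP machinery: the extremes of xᵢ/xⱼ
over {x ∈ P | xⱼ > 0} are yield optimizations with c = ±eᵢ, d = eⱼ.
A pair is fully coupled if min = max (finite, nonzero), partially coupled
if both extremes are finite and nonzero but different, directionally
coupled if exactly one extreme is zero or infinite, and uncoupled
otherwise.  A reversible denominator is analyzed one orientation at a
time (the ratio needs a sign convention); reactions with identically zero
flux are reported as `blocked` rather than uncoupled.  The zero threshold
for declaring a ratio bound zero is 1e-9, the LP noise floor.

## Elementary flux vectors

EFVs generalize elementary flux modes from flux cones to flux polyhedra:
they are the conformally non-decomposable vectors of the homogenized cone
{(x, t) | A x ≤ t b, t ≥ 0}.  Generators with t > 0 (normalized to t = 1)
span the polytope part of P; generators with t = 0 span the recession
cone; every x ∈ P is a convex sum of the former plus a conical sum of the
latter.  The zero vector is itself a generator whenever the polyhedron is
inhomogeneous and contains it; for a flux cone the enumeration returns
exactly the EFMs (all unbounded), the polytope part being the origin.

Enumeration lifts the homogenized cone to standard form
{y ≥ 0 | M y = 0} by splitting each sign-unrestricted coordinate into a
positive and a negative part and adding one slack variable per
inhomogeneous inequality row; sign restrictions already present as unit
rows are absorbed into the orthant instead of slack-ified.  On that form
the classic double description method applies: start from the unit rays
of the orthant, process one equality at a time, keep rays on the
hyperplane plus combinations of adjacent positive/negative pairs
(combinatorial adjacency test).  Conformal decompositions of the original
cone correspond exactly to sums in the lifted orthant cone, so the
extreme rays of the lift map onto the EFVs once the artifact two-cycles
of the splitting (rays using both directions of one split coordinate) are
removed.  This split-and-filter route was chosen over a native
signed-support pivoting scheme because its correctness argument is a
four-line bijection and the filter is exact; a cross-validating oracle
(exhaustive support search over the kernel) covers it in the tests.

All pivoting uses exact rational arithmetic (`fractions.Fraction`;
incoming floats are rationalized with denominator limit 1e9, exact for
the small-rational models this is intended for).  Bounded generators are
reported at t = 1, unbounded ones scaled to the smallest integer vector.
Floats appear only in annotations (rates cᵀx, yields, classifications).
Guards refuse networks with more than 64 reactions or runs exceeding 1e6
intermediate rays — double description is exponential in the worst case
and genome-scale enumeration is explicitly out of scope.

### Optimal solution sets

With bounded generators vᵢ (i ∈ I, including the origin for cones) and
unbounded generators uⱼ (j ∈ J), and Id, Jd the subsets with positive
denominator:

* the yield maximum over P> equals max over Id ∪ Jd of the generator
  yields;
* it is **not attained** iff Id = I and the best bounded yield is
  strictly below the best unbounded one (then the supremum is approached
  along the corresponding recession direction);
* when attained, x is yield-optimal iff it decomposes into generators
  with optimal or undefined yield, with convex weights on the bounded
  part and total weight on the optimal-yield generators strictly
  positive.  The strict inequality is LP-tested as ≥ 1e-9.

Rate-optimal sets follow the simpler LP picture: optimal bounded
generators plus any recession generator on which the objective vanishes;
a positive objective value on an unbounded generator means the LP is
unbounded and is raised as such.

## Phase planes and yield spaces

The projection of P onto two rate axes (phase plane / production
envelope) is computed exactly as the convex hull of the projected
generators (recession generators with nonzero projection become rays) or
approximately by boundary sampling: compute the feasible range of axis 1,
sweep an inclusive grid of n + 1 slices (default n = 20, which resolves
these polygons to plotting accuracy), and minimize/maximize axis 2 on
each slice.  Points are emitted lower branch left-to-right then upper
branch right-to-left, a closed polygon trace.  Slices that come back
infeasible at the extreme grid values from round-off are nudged inward by
1e-9 of the axis range before being declared infeasible.

The yield space is *not* a projection (yields are nonlinear), but it is
convex: the yield pair of a convex combination lies on the segment
between the endpoint yield pairs (with a reweighted parameter depending
only on the shared denominator).  Its closure is the convex hull of the
yield pairs of defined-yield generators; vectors with undefined yield
(internal cycles, the zero vector) have no image.  Sampling a yield space
runs the identical sweep over the auxiliary polyhedron P′, on which both
yields are the linear forms cᵀx′ — the sole structural difference from
phase-plane sampling.

Fiber maps connect the two pictures: the yield interval over a
phase-plane point is computed by LFPs over the fiber (rates pinned by
equality rows), and the rate interval over a yield-space point by LPs
over the preimage cut out by the homogeneous rows (c − y d)ᵀx = 0.
Interval endpoints are flagged open when they are only approached — for
yields via the LFP attainment test, for rates when the endpoint is
realized only with zero denominator (e.g. the origin of the half-open
segment that a pure-biomass yield point projects to).

## Strain design

Design specifications are conjunctions of inequalities over annotated
rates and yields, split into a target region (behaviors to eliminate) and
a desired region (behaviors to preserve).  Generators with undefined
yield cannot satisfy a yield constraint and therefore never fall in a
region that references one — internal cycles and the zero vector come out
neutral, which matches their role: they are unaffected by and irrelevant
to the design objective.  Boundary cases follow the inequality operators
verbatim (designs usually place the cutting line so that desired
behaviors sit non-strictly above it).

A constrained minimal cut set must intersect the support of every target
generator while leaving at least one desired generator untouched.  Every
such set is an inclusion-minimal transversal of the target supports
(supersets only make preservation harder), so the implementation runs
Berge's incremental minimal-transversal algorithm with a cardinality cap
and then filters by the preservation condition — exact at the intended
scale, no heuristics.  Reversible reactions are hit regardless of flux
direction, since a knockout removes both.  A consequence surfaced in the
tests: the zero flux vector has empty support and can never be cut, so
knockouts alone can never enforce a nonzero production *rate* (only
enforced lower bounds — upregulation — can, as in the S6 scenario).
Returned cut sets are verified by re-enumerating the mutant and
re-partitioning its generators.

## Example network and random-network generator

The bundled 6-metabolite / 11-reaction network is small enough for every
computation to be checked by hand yet rich enough to separate rate- from
yield-optimality: it contains parallel substrate-to-biomass routes, an
overflow route with substrate coefficient 2 (the only non-unit
coefficient), a pure-waste route, and a thermodynamically infeasible
internal cycle kept deliberately as the canonical undefined-yield
generator.  Scenarios S1–S3 add an uptake bound and a capacity bound;
S4–S6 are engineering variants (knockouts and one enforced lower bound).

`random_network` produces sparse integer networks with a guaranteed
uptake and excretion reaction, one or two substrates/products per
internal reaction with coefficients in {1, 2}, and a 20% reversibility
rate — the regime where exhaustive oracles (support search for EFMs,
subset search for cut sets, EFM-ratio analysis for coupling) stay cheap.
These networks emulate the combinatorial structure of small metabolic
models, not their biology: no compartments, no gene–protein–reaction
rules, no mass consistency beyond integer stoichiometry, and no realistic
degree distribution.  Green tests on them certify the algebra and the
solver plumbing, not predictive power on curated genome-scale models.

## Numerical choices and limitations

* Feasibility tolerance 1e-6 absolute (double-precision LP default),
  configurable per call.
* LFP attainment: relative objective tolerance 1e-7; homogenization
  variable treated as zero below 1e-9.
* Membership and decomposition LPs use HiGHS feasibility tolerances of
  1e-7; enumeration itself is exact and tolerance-free.
* Degenerate hulls (all images collinear) fall back to the extreme
  segment instead of a polygon.
* Only 2-D phase planes and yield spaces are computed; ℓ-dimensional
  objective/yield spaces exist in the data model but have no sampler.
* Enumeration-based analyses (EFVs, cut sets, exact hulls) are limited to
  small networks by design; the LP/LFP layer (optimization, coupling,
  variability, sampling) scales to genome-scale models through HiGHS.
* General LFPs with affine numerator/denominator offsets are not
  supported: metabolic yields have none, and the homogeneity is what
  makes the theory above work.
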