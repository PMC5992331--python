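# yieldopt

Yield (*vs.* rate) optimization and elementary-flux-vector analysis for
constraint-based metabolic models.

## Why

Flux-balance analysis (FBA) maximizes a linear *rate* objective cᵀr over
the feasible steady-state flux vectors

P = { r ∈ ℝⁿ | N r = 0, r_lb ≤ r ≤ r_ub, G r ≤ h },

and is the workhorse of constraint-based modeling.  Metabolic *yields*,
however — product formed per substrate consumed, Y(r) = cᵀr / dᵀr — are
ratios of rates, and maximizing a ratio under arbitrary linear constraints
is not an LP.  Fixing the substrate uptake and maximizing the product rate
only recovers the optimal yield in special cases; in general, rate-optimal
and yield-optimal flux distributions differ.  `yieldopt` treats yield
maximization properly as a linear-fractional program (LFP)

max Y(r) = cᵀr / dᵀr  over  P ∩ { r | dᵀr > 0 },

solved through the equivalent LP over the auxiliary polyhedron

P′ = { (r′, t) | A r′ ≤ t b, dᵀr′ = 1, t ≥ 0 },

with back-transformation r = r′/t, including the degenerate cases: empty
domain, unbounded yield (ill-posed denominators), and suprema that are
approached along recession directions but never attained at finite fluxes.

On top of the two optimizers the package provides

* **flux coupling analysis** — extremal flux ratios rᵢ/rⱼ as LFPs,
  classifying reaction pairs as fully / partially / directionally /
  un-coupled;
* **elementary flux modes and vectors (EFMs/EFVs)** — exact
  double-description enumeration (rational arithmetic) of the generators
  of flux cones and flux polyhedra, and the characterization of
  rate-optimal and yield-optimal solution sets as convex/conical sums of
  optimal and undefined-yield generators, including an LP membership test;
* **phase planes / production envelopes and yield spaces** — exact convex
  hulls of projected/mapped generators, boundary sampling for either
  (yield spaces are sampled over the auxiliary polyhedron, where yields
  are linear), and fiber maps between the two pictures;
* **constrained minimal cut sets** — partition of annotated EFVs into
  target / desired / neutral behaviors and exact minimal-hitting-set
  knockout design with verification by re-enumeration.

Intended users are systems-biology and metabolic-engineering researchers
working with small to medium stoichiometric models (enumeration is exact
and guarded; the LP/LFP solvers alone also handle genome-scale models).

## Worked example

The bundled example network (6 metabolites, 11 reactions, reversible
R11) takes up substrate S through R1 and makes B(iomass, excreted by R4)
and byproducts P and Q.  Scenario S3 bounds the uptake (r1 ≤ 10) and one
internal route (r5 ≤ 5):

```python
import numpy as np
from yieldopt import *
from yieldopt.fixtures import scenario

model, s3 = scenario("S3")
e = lambda rid: np.eye(model.n_reactions)[model.reaction_index(rid)]

rate = maximize_rate(s3, e("R4"))
print("max r4 :", rate.status, rate.objective_value)

spec = YieldSpec(e("R4"), e("R1"))          # biomass yield r4/r1
res = maximize_yield(s3, spec)
print("max Y  :", res.status, res.optimal_yield, "at r1 =", res.x[0])

gen = enumerate_efvs(s3)
print("EFVs   :", len(gen), "(", sum(g.kind == 'bounded' for g in gen), "bounded )")
print("attained:", yield_attained(gen, spec))
opt, best, addable = rate_optimal_set(gen, e("R4"))
print("rate-optimal generators:", opt, "value", best)
```

prints

```
max r4 : optimal 7.5
max Y  : optimal_attained 1.0 at r1 = 5.0
EFVs   : 13 ( 12 bounded )
attained: (True, 1.0)
rate-optimal generators: [4, 5] value 7.5
```

The maximal biomass *rate* is 7.5 (reached only at full uptake r1 = 10,
where the r5 bottleneck forces the overflow route that co-produces P),
while the maximal biomass *yield* is 1 and is attained — but only at
uptake rates r1 ≤ 5.  Rate- and yield-optimal flux distributions are
therefore disjoint in this scenario, the point the toolkit exists to make
computable.  The 13 elementary flux vectors include the internal cycle
(unbounded, undefined yield) and the zero vector; exactly two bounded
generators span the rate-optimal face.

The same functionality is available from the shell:

```
yieldopt fixtures --out fig1.json
yieldopt optimize --model fig1.json --scenario s3.json --objective-yield R4/R1
yieldopt efv      --model fig1.json --scenario s3.json --rate R4 --yield-spec R4/R1
yieldopt space    --model fig1.json --scenario s3.json --type pp --axes R4,R3 --n 20
yieldopt design   --model fig1.json --scenario s2.json --design design.json --verify
```

where a scenario file is JSON such as
`{"bounds": {"R1": [null, 10], "R5": [null, 5]}}`.

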