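"""Elementary flux modes / vectors and optimal-set characterization.

For a flux cone {x | S x = 0, x_irr >= 0} the elementary flux modes (EFMs)
are the support-minimal (conformally non-decomposable) nonzero flux vectors;
every feasible flux distribution is a conical sum of EFMs.  For a flux
*polyhedron* P = {x | A x <= b} the generalization are elementary flux
vectors (EFVs): the conformally non-decomposable vectors of the homogenized
cone {(x, t) | A x <= t b, t >= 0}.  Generators with t > 0 (normalized to
t = 1) span the polytope part of P, generators with t = 0 span its
recession cone, and every x in P decomposes as

    x = sum_i alpha_i v_i + sum_j beta_j u_j,   alpha >= 0, sum alpha = 1,
                                                beta >= 0.

Enumeration runs the double description method on the lifted cone
{y >= 0 | M y = 0} obtained by splitting sign-unrestricted coordinates and
introducing one slack per inhomogeneous inequality; artifact two-cycles of
the splitting are filtered out exactly.  All pivoting is done in exact
rational arithmetic (fractions.Fraction); floats appear only in annotation.

Theorems implemented here characterize the rate- and yield-optimal solution
sets in terms of the generators: the yield optimum over P> equals the best
defined-yield generator value; it is *not attained* exactly when every
bounded generator has positive denominator and a strictly better yield
exists among the unbounded generators; and when attained, the optimal set
consists of convex/conical sums of optimal-yield and undefined-yield
generators with positive total weight on the optimal ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel, Polyhedron, YieldSpec, ValidationError, \
    build_polyhedron
from .optimize import UNDEFINED, INFINITE, yield_value

__all__ = [
    "Generator",
    "GeneratorSet",
    "OptimalPartition",
    "enumerate_efvs",
    "enumerate_efms",
    "annotate",
    "yield_attained",
    "classify_optimal",
    "is_yield_optimal",
    "rate_optimal_set",
    "EnumerationGuardError",
]

# epsilon standing in for the strict inequality "sum of optimal weights > 0"
# in the membership LP (strict inequalities are not LP-expressible)
MEMBERSHIP_EPS = 1e-9

MAX_REACTIONS = 64
MAX_INTERMEDIATE_RAYS = 10 ** 6


class EnumerationGuardError(RuntimeError):
    """Problem exceeds the configured enumeration size guard."""


@dataclass
class Generator:
    """One enumerated generator (EFM/EFV) with optional annotations."""

    x: np.ndarray                      # float view, length n
    x_exact: tuple                     # Fractions, length n
    kind: str                          # bounded | unbounded
    support: frozenset = None          # indices of nonzero fluxes
    rate: Optional[float] = None
    yield_status: Optional[str] = None  # defined | undefined | infinite
    yield_value: Optional[float] = None

    def __post_init__(self):
        if self.support is None:
            self.support = frozenset(
                i for i, v in enumerate(self.x_exact) if v != 0)

    @property
    def is_zero(self) -> bool:
        return not self.support


@dataclass
class GeneratorSet:
    generators: list
    polyhedron: Polyhedron

    @property
    def bounded(self):
        return [g for g in self.generators if g.kind == "bounded"]

    @property
    def unbounded(self):
        return [g for g in self.generators if g.kind == "unbounded"]

    def __len__(self):
        return len(self.generators)

    def __iter__(self):
        return iter(self.generators)


@dataclass
class OptimalPartition:
    """Theorem-2 index partition of the generators (into .generators)."""

    I_star: list = field(default_factory=list)   # bounded, optimal yield
    I_u: list = field(default_factory=list)      # bounded, undefined yield
    J_star: list = field(default_factory=list)   # unbounded, optimal yield
    J_u: list = field(default_factory=list)      # unbounded, undefined yield
    optimal_yield: float = None


# ---------------------------------------------------------------------------
# exact double description on {y >= 0 | M y = 0}
# ---------------------------------------------------------------------------

def _primitive(ray):
    """Scale a rational ray to the smallest integer vector."""
    from math import gcd

    dens = [v.denominator for v in ray if v != 0]
    if not dens:
        return ray
    lcm = 1
    for d in dens:
        lcm = lcm * d // gcd(lcm, d)
    ints = [v * lcm for v in ray]
    g = 0
    for v in ints:
        g = gcd(g, int(v))
    return tuple(Fraction(int(v) // g) for v in ints)


def _dd_orthant(rows, dim, max_rays=MAX_INTERMEDIATE_RAYS):
    """Extreme rays of {y in R^dim, y >= 0 | row . y = 0 for each row}.

    Classic double description with the combinatorial adjacency test:
    starting from the unit rays of the orthant, each equality constraint
    splits the rays by sign and keeps conical combinations of adjacent
    positive/negative pairs.  Rays stay support-minimal throughout because
    every intermediate cone is an orthant-subspace intersection.
    """
    rays = [tuple(Fraction(int(i == k)) for i in range(dim))
            for k in range(dim)]
    for row in rows:
        vals = [sum(r[i] * row[i] for i in range(dim) if row[i] != 0)
                for r in rays]
        zero = [r for r, v in zip(rays, vals) if v == 0]
        pos = [(r, v) for r, v in zip(rays, vals) if v > 0]
        neg = [(r, v) for r, v in zip(rays, vals) if v < 0]
        supports = [frozenset(i for i, x in enumerate(r) if x != 0)
                    for r in rays]
        new = list(zero)
        for rp, vp in pos:
            sp = frozenset(i for i, x in enumerate(rp) if x != 0)
            for rn, vn in neg:
                sn = frozenset(i for i, x in enumerate(rn) if x != 0)
                union = sp | sn
                # adjacency: no third ray's support fits inside the union
                adjacent = True
                for r, s in zip(rays, supports):
                    if r is rp or r is rn:
                        continue
                    if s <= union:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = tuple(vp * rn[i] - vn * rp[i] for i in range(dim))
                new.append(_primitive(combo))
        if len(new) > max_rays:
            raise EnumerationGuardError(
                f"intermediate ray count {len(new)} exceeds the guard "
                f"({max_rays}); enumeration at this scale is out of scope")
        rays = new
    return rays


def _rational(x, max_den=10 ** 9):
    f = Fraction(float(x)).limit_denominator(max_den)
    return f


# ---------------------------------------------------------------------------
# EFV / EFM enumeration
# ---------------------------------------------------------------------------

def enumerate_efvs(poly: Polyhedron, max_reactions: int = MAX_REACTIONS,
                   max_rays: int = MAX_INTERMEDIATE_RAYS) -> GeneratorSet:
    """Enumerate the elementary flux vectors of a flux polyhedron.

    The zero vector is included as a bounded generator whenever the
    polyhedron is inhomogeneous (has at least one nonzero right-hand side)
    and contains the origin; for a flux cone the enumeration reduces to the
    EFMs, all unbounded.
    """
    n = poly.n
    if n > max_reactions:
        raise EnumerationGuardError(
            f"{n} reactions exceed the enumeration guard ({max_reactions})")

    # classify rows: unit inequality rows with b = 0 are sign restrictions
    nonneg = poly.nonneg.copy()
    nonpos = np.zeros(n, dtype=bool)
    eq_mask = np.zeros(poly.n_rows, dtype=bool)
    eq_mask[list(poly.eq_rows)] = True
    used = np.zeros(poly.n_rows, dtype=bool)
    for r in range(poly.n_rows):
        if eq_mask[r]:
            continue
        nz = np.nonzero(poly.A[r])[0]
        if len(nz) == 1 and poly.b[r] == 0:
            j = nz[0]
            if poly.A[r, j] < 0:
                nonneg[j] = True
            else:
                nonpos[j] = True
            used[r] = True

    # column layout of the lifted orthant cone
    col_of_pos = {}
    col_of_neg = {}
    cols = 0
    for j in range(n):
        if nonneg[j] and nonpos[j]:
            # variable fixed to zero; give it one column and an equality row
            col_of_pos[j] = cols
            cols += 1
        elif nonneg[j]:
            col_of_pos[j] = cols
            cols += 1
        elif nonpos[j]:
            col_of_neg[j] = cols
            cols += 1
        else:
            col_of_pos[j] = cols
            col_of_neg[j] = cols + 1
            cols += 2
    t_col = cols
    cols += 1

    def lift_row(a, bval):
        """row over lifted columns encoding a.x - b*t (+ slack later)."""
        row = [Fraction(0)] * cols
        for j in range(n):
            aj = _rational(a[j])
            if aj == 0:
                continue
            if j in col_of_pos:
                row[col_of_pos[j]] += aj
            if j in col_of_neg:
                row[col_of_neg[j]] -= aj
        row[t_col] -= _rational(bval)
        return row

    slack_rows = []
    eq_rows = []
    for r in range(poly.n_rows):
        if used[r]:
            continue
        row = lift_row(poly.A[r], poly.b[r])
        if eq_mask[r]:
            eq_rows.append(row)
        else:
            slack_rows.append(row)
    # variables pinned to zero by opposing sign rows
    for j in range(n):
        if nonneg[j] and nonpos[j]:
            row = [Fraction(0)] * cols
            row[col_of_pos[j]] = Fraction(1)
            eq_rows.append(row)
    # append slack columns
    n_slack = len(slack_rows)
    total = cols + n_slack
    rows = []
    for row in eq_rows:
        rows.append(tuple(row + [Fraction(0)] * n_slack))
    for k, row in enumerate(slack_rows):
        ext = row + [Fraction(0)] * n_slack
        ext[cols + k] = Fraction(1)
        rows.append(tuple(ext))

    rays = _dd_orthant(rows, total, max_rays=max_rays)

    generators = []
    is_cone = poly.is_cone
    for ray in rays:
        # drop artifact two-cycles of the reversible split
        futile = any(
            j in col_of_pos and j in col_of_neg
            and ray[col_of_pos[j]] != 0 and ray[col_of_neg[j]] != 0
            for j in range(n))
        if futile:
            continue
        x = []
        for j in range(n):
            v = Fraction(0)
            if j in col_of_pos:
                v += ray[col_of_pos[j]]
            if j in col_of_neg:
                v -= ray[col_of_neg[j]]
            x.append(v)
        t = ray[t_col]
        if t > 0:
            xb = tuple(v / t for v in x)
            if is_cone and all(v == 0 for v in xb):
                continue  # a cone's polytope part is just the origin
            generators.append(Generator(
                x=np.array([float(v) for v in xb]),
                x_exact=xb, kind="bounded"))
        else:
            xe = _primitive(tuple(x))
            if all(v == 0 for v in xe):
                continue
            generators.append(Generator(
                x=np.array([float(v) for v in xe]),
                x_exact=xe, kind="unbounded"))
    generators.sort(key=lambda g: (g.kind, sorted(g.support)))
    return GeneratorSet(generators, poly)


def enumerate_efms(model: MetabolicModel, **kwargs) -> GeneratorSet:
    """EFMs of the model's flux cone (steady state + irreversibility only)."""
    cone = build_polyhedron(_strip_bounds(model))
    return enumerate_efvs(cone, **kwargs)


def _strip_bounds(model: MetabolicModel) -> MetabolicModel:
    m = model.copy()
    m.lb = np.where(m.reversible, -np.inf, 0.0)
    m.ub = np.full(m.n_reactions, np.inf)
    m.G = np.zeros((0, m.n_reactions))
    m.h = np.zeros(0)
    return m


# ---------------------------------------------------------------------------
# annotation and optimal-set theorems
# ---------------------------------------------------------------------------

def annotate(gen: GeneratorSet, rate=None, spec: YieldSpec = None) -> GeneratorSet:
    """Attach rate values c.x and yield status/value to each generator."""
    for g in gen:
        if rate is not None:
            g.rate = float(np.asarray(rate) @ g.x)
        if spec is not None:
            y = yield_value(g.x, spec)
            if y == UNDEFINED:
                g.yield_status, g.yield_value = "undefined", None
            elif y == INFINITE:
                g.yield_status, g.yield_value = "infinite", None
            else:
                g.yield_status, g.yield_value = "defined", float(y)
    return gen


def _yields(gen: GeneratorSet, spec: YieldSpec):
    out = []
    for g in gen:
        out.append(yield_value(g.x, spec))
    return out


def yield_attained(gen: GeneratorSet, spec: YieldSpec):
    """Decide attainment of the yield maximum and return (attained, Y*).

    The bounded generators (plus the origin, which is always part of a
    cone's polytope) play the role of the polytope generators v_i, the
    unbounded ones of the recession-cone generators u_j.  The maximum is not
    attained exactly when every v_i has positive denominator and the best
    yield among those v_i is strictly below the best among the u_j.
    """
    ys = _yields(gen, spec)
    if any(y == INFINITE for y in ys):
        raise ValidationError(
            "a generator has infinite yield: Y is unbounded on P>")
    bounded_idx = [k for k, g in enumerate(gen.generators)
                   if g.kind == "bounded"]
    unbounded_idx = [k for k, g in enumerate(gen.generators)
                     if g.kind == "unbounded"]
    implicit_zero = gen.polyhedron.is_cone  # origin, undefined yield
    Id = [k for k in bounded_idx
          if float(spec.d @ gen.generators[k].x) > 0]
    Jd = [k for k in unbounded_idx
          if float(spec.d @ gen.generators[k].x) > 0]
    yi = [ys[k] for k in Id]
    yj = [ys[k] for k in Jd]
    if not yi and not yj:
        raise ValidationError("P> is empty: no generator has d.x > 0")
    best_i = max(yi) if yi else -math.inf
    best_j = max(yj) if yj else -math.inf
    all_bounded_in_domain = (len(Id) == len(bounded_idx)) and not implicit_zero
    not_attained = all_bounded_in_domain and best_i < best_j
    return (not not_attained), max(best_i, best_j)


def classify_optimal(gen: GeneratorSet, spec: YieldSpec,
                     tol: float = 1e-9) -> OptimalPartition:
    """Theorem-2 partition of generators once the maximum is attained."""
    attained, y_star = yield_attained(gen, spec)
    if not attained:
        raise ValidationError(
            "yield maximum is not attained; see yield_attained")
    part = OptimalPartition(optimal_yield=y_star)
    ys = _yields(gen, spec)
    for k, g in enumerate(gen.generators):
        y = ys[k]
        if g.kind == "bounded":
            if y == UNDEFINED:
                part.I_u.append(k)
            elif y != INFINITE and abs(y - y_star) <= tol * max(1, abs(y_star)):
                part.I_star.append(k)
        else:
            if y == UNDEFINED:
                part.J_u.append(k)
            elif y != INFINITE and abs(y - y_star) <= tol * max(1, abs(y_star)):
                part.J_star.append(k)
    return part


def is_yield_optimal(gen: GeneratorSet, spec: YieldSpec, x,
                     tol: float = 1e-7) -> bool:
    """Membership test for the yield-optimal solution set.

    Decides by LP whether x decomposes into optimal/undefined-yield
    generators with convex weights on the bounded part and total weight at
    least MEMBERSHIP_EPS on the optimal-yield generators.
    """
    part = classify_optimal(gen, spec)
    x = np.asarray(x, dtype=float).reshape(-1)
    n = gen.polyhedron.n
    cols = part.I_star + part.I_u + part.J_star + part.J_u
    n_bounded = len(part.I_star) + len(part.I_u)
    implicit_zero = gen.polyhedron.is_cone
    V = np.array([gen.generators[k].x for k in cols]).T if cols else \
        np.zeros((n, 0))
    n_var = len(cols) + (1 if implicit_zero else 0)
    if implicit_zero:
        V = np.hstack([V, np.zeros((n, 1))])
    A_eq = np.vstack([V, np.zeros((1, n_var))])
    A_eq[n, :n_bounded] = 1.0
    if implicit_zero:
        A_eq[n, -1] = 1.0  # origin counts toward the convex combination
    b_eq = np.concatenate([x, [1.0]])
    # sum of weights on optimal-yield generators >= eps
    a_opt = np.zeros(n_var)
    a_opt[:len(part.I_star)] = -1.0
    a_opt[n_bounded:n_bounded + len(part.J_star)] = -1.0
    res = linprog(np.zeros(n_var), A_ub=a_opt.reshape(1, -1),
                  b_ub=[-MEMBERSHIP_EPS], A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * n_var, method="highs",
                  options={"primal_feasibility_tolerance": tol})
    return res.status == 0


def rate_optimal_set(gen: GeneratorSet, c, tol: float = 1e-9):
    """Bounded generators achieving the maximal rate c.x.

    Returns (optimal_indices, optimal_value, addable_recession_indices):
    every rate-optimal flux vector is a convex sum of the optimal bounded
    generators plus a conical sum of recession generators on which the
    objective vanishes.  Raises if some unbounded generator improves the
    objective (the LP is then unbounded).
    """
    c = np.asarray(c, dtype=float).reshape(-1)
    for k, g in enumerate(gen.generators):
        if g.kind == "unbounded" and float(c @ g.x) > tol:
            raise ValidationError(
                f"rate objective is positive on unbounded generator {k}: "
                "rate unbounded")
    bounded = [(k, float(c @ g.x)) for k, g in enumerate(gen.generators)
               if g.kind == "bounded"]
    if gen.polyhedron.is_cone:
        bounded.append((None, 0.0))  # the origin
    if not bounded:
        raise ValidationError("polyhedron has no bounded part")
    best = max(v for _, v in bounded)
    opt = [k for k, v in bounded
           if k is not None and abs(v - best) <= tol * max(1, abs(best))]
    addable = [k for k, g in enumerate(gen.generators)
               if g.kind == "unbounded" and abs(float(c @ g.x)) <= tol]
    return opt, best, addable


def decompose(gen: GeneratorSet, x, tol: float = 1e-7) -> bool:
    """Feasibility of the generator decomposition of x (Minkowski form)."""
    x = np.asarray(x, dtype=float).reshape(-1)
    n = gen.polyhedron.n
    bounded = [k for k, g in enumerate(gen.generators) if g.kind == "bounded"]
    cols = bounded + [k for k, g in enumerate(gen.generators)
                      if g.kind == "unbounded"]
    implicit_zero = gen.polyhedron.is_cone
    V = np.array([gen.generators[k].x for k in cols]).T if cols else \
        np.zeros((n, 0))
    n_var = len(cols) + (1 if implicit_zero else 0)
    if implicit_zero:
        V = np.hstack([V, np.zeros((n, 1))])
    A_eq = np.vstack([V, np.zeros((1, n_var))])
    A_eq[n, :len(bounded)] = 1.0
    if implicit_zero:
        A_eq[n, -1] = 1.0
    b_eq = np.concatenate([x, [1.0]])
    res = linprog(np.zeros(n_var), A_eq=A_eq, b_eq=b_eq,
                  bounds=[(0, None)] * n_var, method="highs",
                  options={"primal_feasibility_tolerance": tol})
    return res.status == 0
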