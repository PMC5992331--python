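"""Rate optimization (LP) and yield optimization (linear-fractional program).

Rate optimization is ordinary flux-balance analysis: maximize a linear form
c.x over the flux polyhedron P.  Yield optimization maximizes the *ratio*
Y(x) = c.x / d.x over P> = {x in P | d.x > 0}, a linear-fractional program.
Via the Charnes-Cooper substitution x' = x / d.x, t = 1 / d.x the LFP is
equivalent to the LP

    max c.x'  over  P' = {(x', t) | A x' <= t b, d.x' = 1, t >= 0},

with identical optimal value.  Solutions with t > 0 back-transform to
x = x'/t in P>; solutions with t = 0 are recession directions along which
the optimal yield is only approached (it is then "not attained").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .model import Polyhedron, YieldSpec, ValidationError

__all__ = [
    "LPResult",
    "YieldResult",
    "maximize_rate",
    "build_auxiliary",
    "maximize_yield",
    "yield_value",
    "flux_variability",
    "UNDEFINED",
    "INFINITE",
]

# tags returned by yield_value when the denominator vanishes
UNDEFINED = "undefined"
INFINITE = "infinite"

# relative tolerance for the attainment test (equality of LP objectives)
ATTAINMENT_RTOL = 1e-7
# absolute threshold below which the homogenization variable t counts as zero
T_ZERO_TOL = 1e-9


@dataclass
class LPResult:
    status: str                    # optimal | unbounded | infeasible
    objective_value: Optional[float] = None
    x: Optional[np.ndarray] = None


@dataclass
class YieldResult:
    status: str   # optimal_attained | optimal_not_attained | unbounded | infeasible_domain
    optimal_yield: Optional[float] = None
    x: Optional[np.ndarray] = None              # witness in P>, iff attained
    limit_direction: Optional[np.ndarray] = None  # recession dir, iff not attained
    t_star: Optional[float] = None


def _solve(poly: Polyhedron, c_max: np.ndarray) -> LPResult:
    """Maximize c.x over poly with the HiGHS backend."""
    A_ub, b_ub, A_eq, b_eq = poly.ineq_eq_split()
    res = linprog(
        -np.asarray(c_max, dtype=float),
        A_ub=A_ub if A_ub.size else None, b_ub=b_ub if b_ub.size else None,
        A_eq=A_eq if A_eq.size else None, b_eq=b_eq if b_eq.size else None,
        bounds=[(None, None)] * poly.n, method="highs",
    )
    if res.status == 0:
        return LPResult("optimal", float(-res.fun), np.asarray(res.x))
    if res.status == 2:
        return LPResult("infeasible")
    if res.status == 3:
        return LPResult("unbounded")
    raise RuntimeError(f"LP solver failure (HiGHS status {res.status}): "
                       f"{res.message}")


def maximize_rate(poly: Polyhedron, c) -> LPResult:
    """FBA: maximize the linear rate objective c.x over the polyhedron.

    Unboundedness (the objective is positive on some recession direction) is
    reported as such, never approximated by a large finite value.
    """
    return _solve(poly, np.asarray(c, dtype=float))


def build_auxiliary(poly: Polyhedron, spec: YieldSpec) -> Polyhedron:
    """The Charnes-Cooper polyhedron P' over (x', t).

    Rows: A x' - t b <= 0 (equalities preserved), the normalization
    d.x' = 1 (equality), and t >= 0.
    """
    p, n = poly.A.shape
    A = np.zeros((p + 2, n + 1))
    b = np.zeros(p + 2)
    A[:p, :n] = poly.A
    A[:p, n] = -poly.b
    A[p, :n] = spec.d
    b[p] = 1.0
    A[p + 1, n] = -1.0      # -t <= 0
    eq = tuple(poly.eq_rows) + (p,)
    nonneg = np.concatenate([poly.nonneg, [True]])
    return Polyhedron(A, b, eq_rows=eq, nonneg=nonneg)


def maximize_yield(poly: Polyhedron, spec: YieldSpec,
                   tol: float = ATTAINMENT_RTOL) -> YieldResult:
    """Maximize Y(x) = c.x/d.x over P> = {x in P | d.x > 0}.

    Solves the auxiliary LP; if its optimum sits at t = 0 only, the feasible
    range of t is probed (re-solving at a fixed t~ = min(1, t_max/2)) to
    decide whether the optimal yield is attained at finite fluxes or only
    approached along a recession direction.
    """
    n = poly.n
    aux = build_auxiliary(poly, spec)
    c_aux = np.concatenate([spec.c, [0.0]])
    first = _solve(aux, c_aux)
    if first.status == "infeasible":
        return YieldResult("infeasible_domain")
    if first.status == "unbounded":
        # ill-posed denominator: product synthesis without substrate uptake
        return YieldResult("unbounded", optimal_yield=np.inf)
    opt = first.objective_value
    xt = first.x
    t_star = float(xt[n])
    if t_star > T_ZERO_TOL:
        return YieldResult("optimal_attained", optimal_yield=opt,
                           x=xt[:n] / t_star, t_star=t_star)

    # LP optimum found at t = 0: decide attainment
    e_t = np.zeros(n + 1)
    e_t[n] = 1.0
    t_range = _solve(aux, e_t)
    t_max = np.inf if t_range.status == "unbounded" else t_range.objective_value
    if t_max <= T_ZERO_TOL:
        # no point of P has positive denominator
        return YieldResult("infeasible_domain")
    probe = min(1.0, t_max / 2.0)
    row = np.zeros(n + 1)
    row[n] = 1.0
    fixed = aux.with_rows(row, [probe], equality=True)
    second = _solve(fixed, c_aux)
    if second.status == "optimal" and \
            abs(second.objective_value - opt) <= tol * max(1.0, abs(opt)):
        t2 = second.x[n]
        return YieldResult("optimal_attained", optimal_yield=opt,
                           x=second.x[:n] / t2, t_star=t_star)
    return YieldResult("optimal_not_attained", optimal_yield=opt,
                       limit_direction=xt[:n], t_star=t_star)


def yield_value(x, spec: YieldSpec, tol: float = 1e-9):
    """Evaluate Y(x) = c.x/d.x.

    Returns the ratio when the denominator is nonzero; the tag ``UNDEFINED``
    when numerator and denominator both vanish (e.g. internal cycles, the
    zero vector); the tag ``INFINITE`` when only the denominator vanishes.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    num = float(spec.c @ x)
    den = float(spec.d @ x)
    if abs(den) > tol:
        return num / den
    if abs(num) <= tol:
        return UNDEFINED
    return INFINITE


def flux_variability(poly: Polyhedron, index: int):
    """Min and max of x_index over the polyhedron (inf for unbounded)."""
    if not (0 <= index < poly.n):
        raise IndexError(f"reaction index {index} out of range")
    e = np.zeros(poly.n)
    e[index] = 1.0
    hi = _solve(poly, e)
    if hi.status == "infeasible":
        raise ValidationError("polyhedron is infeasible")
    lo = _solve(poly, -e)
    vmax = np.inf if hi.status == "unbounded" else hi.objective_value
    vmin = -np.inf if lo.status == "unbounded" else -lo.objective_value
    return (vmin, vmax)
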