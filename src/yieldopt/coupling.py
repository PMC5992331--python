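"""Flux coupling analysis via linear-fractional programs.

Two fluxes r_i and r_j are coupled according to the extremal values of the
ratio r_i/r_j over the feasible set (restricted to r_j > 0):

* fully coupled        -- min = max, finite and nonzero (fixed proportion)
* partially coupled    -- min != max, both finite and nonzero
* directionally coupled -- exactly one of min/max is zero or infinite
* uncoupled            -- min = 0 and max = infinite

The ratio bounds are yield maximizations with c = +/- e_i and d = e_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Polyhedron, YieldSpec, ValidationError
from .optimize import flux_variability, maximize_yield

__all__ = ["CouplingClass", "ratio_bounds", "classify", "classify_all",
           "BLOCKED"]

BLOCKED = "blocked"

# LP noise floor below which a ratio bound counts as zero
ZERO_TOL = 1e-9


@dataclass
class CouplingClass:
    label: str                    # fully | partially | directionally | uncoupled | blocked
    ratio_min: Optional[float] = None   # may be 0.0 or np.inf
    ratio_max: Optional[float] = None


def ratio_bounds(poly: Polyhedron, i: int, j: int, orientation: int = 1):
    """Extremal values of x_i/x_j over {x in poly | x_j > 0}.

    A reversible denominator reaction is analyzed one orientation at a time
    (``orientation`` = +1 or -1 restricts the sign of x_j); the ratio is then
    taken with respect to the oriented flux.  Returns ``BLOCKED`` if x_j is
    identically zero on the (oriented) polyhedron.
    """
    if i == j:
        return (1.0, 1.0)
    n = poly.n
    sign = 1.0 if orientation >= 0 else -1.0
    work = poly
    vmin, vmax = flux_variability(poly, j)
    if sign > 0 and vmin < -ZERO_TOL or sign < 0 and vmax > ZERO_TOL:
        row = np.zeros(n)
        row[j] = -sign
        work = poly.with_rows(row, [0.0])
        vmin, vmax = flux_variability(work, j)
    extent = vmax if sign > 0 else -vmin
    if extent <= ZERO_TOL:
        return BLOCKED

    d = np.zeros(n)
    d[j] = sign
    e_i = np.zeros(n)
    e_i[i] = 1.0

    def one_sided(c):
        res = maximize_yield(work, YieldSpec(c, d))
        if res.status == "unbounded":
            return np.inf
        if res.status in ("optimal_attained", "optimal_not_attained"):
            return res.optimal_yield
        raise ValidationError(f"ratio LFP returned status {res.status}")

    hi = one_sided(e_i)
    lo = -one_sided(-e_i)
    if np.isfinite(lo) and abs(lo) <= ZERO_TOL:
        lo = 0.0
    if np.isfinite(hi) and abs(hi) <= ZERO_TOL:
        hi = 0.0
    return (lo, hi)


def classify(bounds) -> CouplingClass:
    """Map ratio bounds to a coupling class."""
    if bounds == BLOCKED:
        return CouplingClass(BLOCKED)
    lo, hi = bounds
    lo_degenerate = (lo == 0.0) or not np.isfinite(lo)
    hi_degenerate = (hi == 0.0) or not np.isfinite(hi)
    if lo_degenerate and hi_degenerate:
        return CouplingClass("uncoupled", lo, hi)
    if lo_degenerate != hi_degenerate:
        return CouplingClass("directionally", lo, hi)
    if abs(hi - lo) <= ZERO_TOL * max(1.0, abs(hi)):
        return CouplingClass("fully", lo, hi)
    return CouplingClass("partially", lo, hi)


def classify_all(poly: Polyhedron) -> dict:
    """Coupling classification for every unordered reaction pair.

    Returns {(i, j): CouplingClass} for i < j, based on the directed ratio
    bounds of x_i/x_j (forward orientation of the denominator).  Blocked
    reactions are reported as ``blocked`` pairs, not as uncoupled.
    """
    n = poly.n
    blocked = []
    for j in range(n):
        vmin, vmax = flux_variability(poly, j)
        if max(abs(vmin), abs(vmax)) <= ZERO_TOL:
            blocked.append(j)
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            if i in blocked or j in blocked:
                out[(i, j)] = CouplingClass(BLOCKED)
                continue
            out[(i, j)] = classify(ratio_bounds(poly, i, j))
    return out
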