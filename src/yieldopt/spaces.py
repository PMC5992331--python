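"""Phase planes / production envelopes and yield spaces.

A phase plane (PP; "production envelope" in strain design) is the
projection of the flux polyhedron onto two rate axes.  A yield space (YS)
is the image of P> under two yield maps sharing one denominator; it is a
convex set even though the yield maps are nonlinear.  Both can be obtained

* exactly, as convex hulls of the projected (PP) or mapped (YS)
  generators — undefined-yield generators such as internal cycles and the
  zero vector have no image in the YS; or
* approximately, by boundary sampling: sweep a grid over the feasible
  range of the first axis and minimize/maximize the second axis on each
  slice.  For the YS the very same sweep runs over the Charnes-Cooper
  auxiliary polyhedron, where both yields become linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Polyhedron, YieldSpec, ValidationError
from .optimize import (_solve, build_auxiliary, maximize_yield,
                       UNDEFINED, yield_value)

__all__ = [
    "BoundarySample",
    "HullPolygon",
    "sample_phase_plane",
    "sample_yield_space",
    "hull_from_generators",
    "map_pp_point_to_ys",
    "map_ys_point_to_pp",
    "Interval",
]

DEFAULT_N = 20
# inward perturbation of degenerate endpoint slices, relative to axis range
SLICE_NUDGE = 1e-9


@dataclass
class BoundarySample:
    """Sampled 2-D boundary: lower branch left-to-right then upper branch
    right-to-left (a closed polygon trace ready for plotting)."""

    axis1_spec: object
    axis2_spec: object
    points: list                     # [(axis1, axis2), ...]
    n: int
    infeasible_slices: list = field(default_factory=list)
    witnesses: list = field(default_factory=list)   # flux vectors, one per point

    @property
    def lower(self):
        k = len(self.points) // 2
        return self.points[:k]

    @property
    def upper(self):
        k = len(self.points) // 2
        return list(reversed(self.points[k:]))


@dataclass
class HullPolygon:
    """Convex polygon (vertices counter-clockwise), possibly with recession
    rays attached when the projection is unbounded."""

    vertices: np.ndarray
    rays: np.ndarray = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if self.rays is None:
            self.rays = np.zeros((0, 2))
        self.rays = np.asarray(self.rays, dtype=float).reshape(-1, 2)

    def contains(self, point, tol: float = 1e-9) -> bool:
        """Point-in-polygon test for the bounded hull (rays ignored)."""
        pts = self.vertices
        if len(pts) == 0:
            return False
        if len(pts) == 1:
            return bool(np.allclose(pts[0], point, atol=tol))
        p = np.asarray(point, dtype=float)
        if len(pts) == 2:
            a, b = pts
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0, 1)
            return bool(np.linalg.norm(a + t * ab - p) <= 10 * tol)
        for k in range(len(pts)):
            a, b = pts[k], pts[(k + 1) % len(pts)]
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            if cross < -tol * max(1.0, np.abs(pts).max()):
                return False
        return True


def _sweep(poly: Polyhedron, c1: np.ndarray, c2: np.ndarray, n: int,
           axis1_spec, axis2_spec) -> BoundarySample:
    """Shared slice-sweep of a 2-D projection of an arbitrary polyhedron."""
    lo_res = _solve(poly, -c1)
    hi_res = _solve(poly, c1)
    if lo_res.status == "infeasible":
        raise ValidationError("polyhedron is infeasible")
    if lo_res.status == "unbounded" or hi_res.status == "unbounded":
        raise ValidationError(
            "axis-1 objective is unbounded; project a bounded pair instead")
    lo, hi = -lo_res.objective_value, hi_res.objective_value
    span = hi - lo
    grid = [lo + span * k / n for k in range(n + 1)] if span > 0 else [lo]

    lower, upper = [], []
    wit_lo, wit_hi = [], []
    infeasible = []
    for k, g in enumerate(grid):
        sliced = poly.with_rows(c1, [g], equality=True)
        down = _solve(sliced, -c2)
        up = _solve(sliced, c2)
        if down.status == "infeasible" or up.status == "infeasible":
            # vertex slices can fail from round-off; nudge inward once
            g2 = g + SLICE_NUDGE * max(span, 1.0) * (1 if k == 0 else -1)
            sliced = poly.with_rows(c1, [g2], equality=True)
            down = _solve(sliced, -c2)
            up = _solve(sliced, c2)
            if down.status == "infeasible" or up.status == "infeasible":
                infeasible.append(k)
                continue
        vlo = -np.inf if down.status == "unbounded" else -down.objective_value
        vhi = np.inf if up.status == "unbounded" else up.objective_value
        lower.append((g, vlo))
        upper.append((g, vhi))
        wit_lo.append(None if down.x is None else down.x)
        wit_hi.append(None if up.x is None else up.x)
    points = lower + list(reversed(upper))
    witnesses = wit_lo + list(reversed(wit_hi))
    return BoundarySample(axis1_spec, axis2_spec, points, n,
                          infeasible_slices=infeasible, witnesses=witnesses)


def sample_phase_plane(poly: Polyhedron, c1, c2,
                       n: int = DEFAULT_N) -> BoundarySample:
    """Boundary sample of the projection of poly on (c1.x, c2.x)."""
    c1 = np.asarray(c1, dtype=float).reshape(-1)
    c2 = np.asarray(c2, dtype=float).reshape(-1)
    return _sweep(poly, c1, c2, n, c1, c2)


def sample_yield_space(poly: Polyhedron, spec1: YieldSpec, spec2: YieldSpec,
                       n: int = DEFAULT_N) -> BoundarySample:
    """Boundary sample of the yield space spanned by two yields sharing a
    denominator.  All slice LPs run over the auxiliary polyhedron
    {(x', t) | A x' <= t b, d.x' = 1, t >= 0}, on which both yields are the
    linear forms c.x'.  Witnesses are reported in auxiliary coordinates
    (scale by 1/t to recover fluxes; every witness has d.x > 0 by the
    normalization row)."""
    if not np.array_equal(spec1.d, spec2.d):
        raise ValidationError("yield-space axes must share one denominator")
    aux = build_auxiliary(poly, spec1)
    probe = maximize_yield(poly, spec1)
    if probe.status == "infeasible_domain":
        raise ValidationError("P> is empty: no flux vector has d.x > 0")
    if probe.status == "unbounded":
        raise ValidationError(
            "unbounded yield: ill-posed model or ill-posed yields")
    c1 = np.concatenate([spec1.c, [0.0]])
    c2 = np.concatenate([spec2.c, [0.0]])
    return _sweep(aux, c1, c2, n, spec1, spec2)


def hull_from_generators(gen, axes) -> HullPolygon:
    """Exact PP or YS as the convex hull of generator images.

    ``axes`` is either ("rate", c1, c2) or ("yield", spec1, spec2).  Rate
    axes: bounded generators project to points, unbounded ones with nonzero
    projection contribute recession rays.  Yield axes: only defined-yield
    generators are mapped (cycles and the zero vector have no image)."""
    kind = axes[0]
    points = []
    rays = []
    if kind == "rate":
        _, c1, c2 = axes
        c1 = np.asarray(c1, dtype=float)
        c2 = np.asarray(c2, dtype=float)
        for g in gen:
            p = (float(c1 @ g.x), float(c2 @ g.x))
            if g.kind == "bounded":
                points.append(p)
            else:
                if abs(p[0]) > 1e-12 or abs(p[1]) > 1e-12:
                    rays.append(p)
                else:
                    points.append((0.0, 0.0))  # cycle projects to the origin
        if gen.polyhedron.is_cone:
            points.append((0.0, 0.0))
    elif kind == "yield":
        _, spec1, spec2 = axes
        if not np.array_equal(spec1.d, spec2.d):
            raise ValidationError(
                "yield-space axes must share one denominator")
        for g in gen:
            y1 = yield_value(g.x, spec1)
            y2 = yield_value(g.x, spec2)
            if isinstance(y1, str) or isinstance(y2, str):
                continue  # undefined / infinite yields have no YS image
            points.append((float(y1), float(y2)))
        if not points:
            raise ValidationError("no generator has a defined yield")
    else:
        raise ValueError(f"unknown axes kind {kind!r}")
    return HullPolygon(_hull_vertices(points), np.array(rays).reshape(-1, 2))


def _hull_vertices(points) -> np.ndarray:
    pts = np.unique(np.asarray(points, dtype=float).reshape(-1, 2), axis=0)
    if len(pts) <= 2:
        return pts
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:
        # collinear points: return the extreme pair along the spread axis
        spread = np.ptp(pts, axis=0)
        k = int(np.argmax(spread))
        order = np.argsort(pts[:, k])
        return pts[[order[0], order[-1]]]


@dataclass
class Interval:
    lo: float
    hi: float
    lo_closed: bool = True
    hi_closed: bool = True


def map_pp_point_to_ys(poly: Polyhedron, pp_point, c1, c2,
                       spec1: YieldSpec, spec2: YieldSpec):
    """Yield intervals of the fiber of flux vectors over one PP point.

    Fixes the two rate axes to ``pp_point`` and minimizes/maximizes each
    yield over the fiber as LFPs.  Endpoint openness reflects the
    attainment test: an endpoint only approached in the limit is open."""
    c1 = np.asarray(c1, dtype=float).reshape(-1)
    c2 = np.asarray(c2, dtype=float).reshape(-1)
    fiber = poly.with_rows(np.vstack([c1, c2]), list(pp_point), equality=True)
    probe = _solve(fiber, np.zeros(poly.n))
    if probe.status == "infeasible":
        raise ValidationError(f"empty fiber over PP point {tuple(pp_point)}")
    out = []
    for spec in (spec1, spec2):
        hi = maximize_yield(fiber, spec)
        lo = maximize_yield(fiber, YieldSpec(-spec.c, spec.d))
        if hi.status == "infeasible_domain" or lo.status == "infeasible_domain":
            raise ValidationError("fiber does not meet P>")
        out.append(Interval(
            lo=-lo.optimal_yield, hi=hi.optimal_yield,
            lo_closed=lo.status == "optimal_attained",
            hi_closed=hi.status == "optimal_attained"))
    return out


def map_ys_point_to_pp(poly: Polyhedron, ys_point, spec1: YieldSpec,
                       spec2: YieldSpec, c1, c2):
    """Rate intervals of the preimage of one YS point.

    The preimage {x in P> | Y1(x) = y1, Y2(x) = y2} is cut out by the
    homogeneous rows (c - y d).x = 0; rate bounds over it are computed over
    the closure (d.x >= 0) and an endpoint is flagged open when it is only
    realized at d.x = 0 (e.g. the origin of a half-open segment)."""
    y1, y2 = ys_point
    rows = np.vstack([spec1.c - y1 * spec1.d, spec2.c - y2 * spec2.d])
    closure = poly.with_rows(rows, [0.0, 0.0], equality=True)
    out = []
    d = spec1.d
    for c in (c1, c2):
        c = np.asarray(c, dtype=float).reshape(-1)
        res_hi = _solve(closure, c)
        res_lo = _solve(closure, -c)
        if res_hi.status == "infeasible":
            raise ValidationError(f"empty preimage of YS point {tuple(ys_point)}")
        hi = np.inf if res_hi.status == "unbounded" else res_hi.objective_value
        lo = -np.inf if res_lo.status == "unbounded" else -res_lo.objective_value
        # openness: is the endpoint only realized with zero denominator?
        def closed_at(val, sense_c):
            ext = closure.with_rows(sense_c, [val], equality=True)
            den_max = _solve(ext, d)
            if den_max.status == "unbounded":
                return True
            return den_max.objective_value > 1e-9

        out.append(Interval(
            lo=lo, hi=hi,
            lo_closed=bool(np.isfinite(lo)) and closed_at(lo, c),
            hi_closed=bool(np.isfinite(hi)) and closed_at(hi, c)))
    return out
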