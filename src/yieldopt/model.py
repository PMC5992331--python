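"""Metabolic models and flux polyhedra.

A metabolic network with ``m`` internal metabolites and ``n`` reactions is
described by its stoichiometric matrix ``S`` (m x n), per-reaction
reversibilities and flux bounds, and optionally extra linear inequality
constraints ``G r <= h`` (e.g. capacity or resource-allocation constraints).

The feasible steady-state flux vectors form the *flux polyhedron*

    P = {x | S x = 0,  lb <= x <= ub,  G x <= h},

represented here as a :class:`Polyhedron` ``{x | A x <= b}`` with designated
equality rows for the steady-state block.  When all bounds are infinite and
there are no extra constraints, P is the *flux cone* (b = 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetabolicModel",
    "Polyhedron",
    "YieldSpec",
    "ValidationError",
    "load_model",
    "save_model",
    "build_polyhedron",
    "feasible",
]

DEFAULT_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a model or polyhedron violates a structural invariant."""


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class MetabolicModel:
    """A stoichiometric model with bounds and extra linear constraints.

    Vectors are positionally indexed against ``reaction_ids`` (file order).
    Infinite bounds are genuine ``inf`` sentinels, never large finite numbers,
    so that unboundedness detection stays exact.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    reversible: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    G: np.ndarray = None
    h: np.ndarray = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.G is None:
            self.G = np.zeros((0, self.n_reactions))
        if self.h is None:
            self.h = np.zeros(0)
        self.G = np.asarray(self.G, dtype=float).reshape(-1, self.n_reactions)
        self.h = np.asarray(self.h, dtype=float).reshape(-1)
        self.validate()

    # -- basic introspection -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def validate(self) -> None:
        m, n = self.S.shape
        if m != self.n_metabolites or n != self.n_reactions:
            raise ValidationError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})"
            )
        for arr, name in ((self.reversible, "reversible"), (self.lb, "lb"),
                          (self.ub, "ub")):
            if arr.shape != (n,):
                raise ValidationError(f"{name} has wrong length")
        bad = np.where(self.lb > self.ub)[0]
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ValidationError(f"lb > ub for reaction {rid!r}")
        bad = np.where(~self.reversible & (self.lb < 0))[0]
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ValidationError(
                f"irreversible reaction {rid!r} has negative lower bound"
            )
        if self.G.shape[0] != self.h.shape[0]:
            raise ValidationError("G and h have mismatched row counts")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            reversible=self.reversible.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            G=self.G.copy(),
            h=self.h.copy(),
        )

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        def _num(v):
            if math.isinf(v):
                return None
            return v

        reactions = []
        for j, rid in enumerate(self.reaction_ids):
            stoich = {
                self.metabolite_ids[i]: self.S[i, j]
                for i in range(self.n_metabolites)
                if self.S[i, j] != 0
            }
            reactions.append({
                "id": rid,
                "reversible": bool(self.reversible[j]),
                "lb": _num(self.lb[j]),
                "ub": _num(self.ub[j]),
                "stoichiometry": stoich,
            })
        constraints = []
        for k in range(self.G.shape[0]):
            coefs = {
                self.reaction_ids[j]: self.G[k, j]
                for j in range(self.n_reactions)
                if self.G[k, j] != 0
            }
            constraints.append({"coefficients": coefs, "rhs": self.h[k]})
        return {
            "metabolites": list(self.metabolite_ids),
            "reactions": reactions,
            "constraints": constraints,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MetabolicModel":
        mets = list(doc["metabolites"])
        met_idx = {mid: i for i, mid in enumerate(mets)}
        rxns = doc["reactions"]
        n = len(rxns)
        S = np.zeros((len(mets), n))
        rids, rev, lb, ub = [], [], [], []
        for j, rx in enumerate(rxns):
            rids.append(rx["id"])
            r = bool(rx.get("reversible", False))
            rev.append(r)
            lo = rx.get("lb", None)
            hi = rx.get("ub", None)
            lb.append((-math.inf if r else 0.0) if lo is None else float(lo))
            ub.append(math.inf if hi is None else float(hi))
            for mid, coef in rx.get("stoichiometry", {}).items():
                if mid not in met_idx:
                    raise ValidationError(
                        f"reaction {rx['id']!r} references unknown "
                        f"metabolite {mid!r}"
                    )
                S[met_idx[mid], j] = float(coef)
        cons = doc.get("constraints", []) or []
        G = np.zeros((len(cons), n))
        h = np.zeros(len(cons))
        rid_idx = {rid: j for j, rid in enumerate(rids)}
        for k, row in enumerate(cons):
            for rid, coef in row["coefficients"].items():
                G[k, rid_idx[rid]] = float(coef)
            h[k] = float(row["rhs"])
        return cls(mets, rids, S, rev, lb, ub, G, h)


@dataclass
class Polyhedron:
    """A polyhedron ``{x | A x <= b}`` with designated equality rows.

    ``eq_rows`` indexes rows to tighten to equality (the steady-state block,
    by construction).  ``nonneg`` records which coordinates are
    sign-restricted to be nonnegative; it is redundant with the rows but is
    kept so downstream enumeration need not pattern-match unit rows.
    """

    A: np.ndarray
    b: np.ndarray
    eq_rows: tuple = ()
    nonneg: np.ndarray = None
    names: list = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            self.A = self.A.reshape(-1, self.A.size)
        self.b = np.asarray(self.b, dtype=float).reshape(-1)
        if self.A.shape[0] != self.b.shape[0]:
            raise ValidationError("A and b have mismatched row counts")
        self.eq_rows = tuple(sorted(set(int(i) for i in self.eq_rows)))
        if self.nonneg is None:
            self.nonneg = np.zeros(self.n, dtype=bool)
        self.nonneg = np.asarray(self.nonneg, dtype=bool)

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def is_cone(self) -> bool:
        return bool(np.all(self.b == 0))

    def ineq_eq_split(self):
        """Return (A_ub, b_ub, A_eq, b_eq) for LP backends."""
        mask = np.zeros(self.n_rows, dtype=bool)
        mask[list(self.eq_rows)] = True
        return self.A[~mask], self.b[~mask], self.A[mask], self.b[mask]

    def as_inequalities(self):
        """Literal all-inequality form: equality rows expanded to +/- pairs."""
        A_ub, b_ub, A_eq, b_eq = self.ineq_eq_split()
        A = np.vstack([A_eq, -A_eq, A_ub])
        b = np.concatenate([b_eq, -b_eq, b_ub])
        return A, b

    def with_rows(self, A_new, b_new, equality: bool = False) -> "Polyhedron":
        """A copy with extra rows appended (optionally as equalities)."""
        A_new = np.asarray(A_new, dtype=float).reshape(-1, self.n)
        b_new = np.asarray(b_new, dtype=float).reshape(-1)
        eq = list(self.eq_rows)
        if equality:
            eq += list(range(self.n_rows, self.n_rows + A_new.shape[0]))
        return Polyhedron(
            np.vstack([self.A, A_new]),
            np.concatenate([self.b, b_new]),
            eq_rows=tuple(eq),
            nonneg=self.nonneg.copy(),
            names=self.names,
        )

    def contains(self, x, tol: float = DEFAULT_TOL) -> bool:
        return feasible(self, x, tol)

    def recession_cone(self) -> "Polyhedron":
        """The cone {x | A x <= 0} of unbounded directions."""
        return Polyhedron(self.A.copy(), np.zeros(self.n_rows),
                          eq_rows=self.eq_rows, nonneg=self.nonneg.copy(),
                          names=self.names)


@dataclass
class YieldSpec:
    """A yield objective Y(x) = c.x / d.x.

    The numerator weights products formed, the denominator weights substrates
    consumed; the denominator is required to be positive on the domain of Y.
    """

    c: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float).reshape(-1)
        self.d = np.asarray(self.d, dtype=float).reshape(-1)
        if self.c.shape != self.d.shape:
            raise ValidationError("c and d must have equal length")
        if not np.any(self.d):
            raise ValidationError("denominator d must not be the zero vector")

    @classmethod
    def single_ratio(cls, n: int, num_index: int, den_index: int,
                     num_sign: float = 1.0, den_sign: float = 1.0) -> "YieldSpec":
        c = np.zeros(n)
        d = np.zeros(n)
        c[num_index] = num_sign
        d[den_index] = den_sign
        return cls(c, d)


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def load_model(path, format: str = "json") -> MetabolicModel:
    """Load a model from the native JSON format, SBML, or a TSV pair.

    ``tsv`` expects a metabolite-by-reaction stoichiometry table at ``path``
    and an optional sidecar ``<path>.bounds.tsv`` with columns
    reaction/reversible/lb/ub (empty cell = infinite bound).
    """
    if format == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"cannot parse {path}: {exc}") from exc
        return MetabolicModel.from_dict(doc)
    if format == "sbml":
        return _load_sbml(path)
    if format == "tsv":
        return _load_tsv(path)
    raise ValueError(f"unknown model format {format!r}")


def save_model(model: MetabolicModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_sbml(path) -> MetabolicModel:
    # go through cobra, which handles SBML L3 + fbc bound parameters
    import cobra.io

    cm = cobra.io.read_sbml_model(str(path))
    mets = [m.id for m in cm.metabolites]
    met_idx = {m: i for i, m in enumerate(mets)}
    rids, rev, lb, ub = [], [], [], []
    S = np.zeros((len(mets), len(cm.reactions)))
    for j, rx in enumerate(cm.reactions):
        rids.append(rx.id)
        rev.append(rx.lower_bound < 0)
        lb.append(rx.lower_bound)
        ub.append(rx.upper_bound)
        for met, coef in rx.metabolites.items():
            S[met_idx[met.id], j] = coef
    return MetabolicModel(mets, rids, S, rev, lb, ub)


def _load_tsv(path) -> MetabolicModel:
    import pandas as pd

    table = pd.read_csv(path, sep="\t", index_col=0)
    mets = [str(m) for m in table.index]
    rids = [str(r) for r in table.columns]
    S = table.to_numpy(dtype=float)
    n = len(rids)
    rev = np.zeros(n, dtype=bool)
    lb = np.zeros(n)
    ub = np.full(n, math.inf)
    sidecar = str(path) + ".bounds.tsv"
    try:
        bounds = pd.read_csv(sidecar, sep="\t")
    except FileNotFoundError:
        bounds = None
    if bounds is not None:
        idx = {r: j for j, r in enumerate(rids)}
        for _, row in bounds.iterrows():
            j = idx[str(row["reaction"])]
            rev[j] = bool(row.get("reversible", False))
            if not pd.isna(row.get("lb")):
                lb[j] = float(row["lb"])
            elif rev[j]:
                lb[j] = -math.inf
            if not pd.isna(row.get("ub")):
                ub[j] = float(row["ub"])
        lb[rev & (lb == 0)] = lb[rev & (lb == 0)]  # keep explicit zeros
    return MetabolicModel(mets, rids, S, rev, lb, ub)


# ---------------------------------------------------------------------------
# constraint-system assembly
# ---------------------------------------------------------------------------

def build_polyhedron(model: MetabolicModel, extra_bounds: dict = None,
                     extra_ineqs=None) -> Polyhedron:
    """Assemble the flux polyhedron of a model.

    Row layout: the steady-state block ``S x = 0`` (equality rows), then one
    row per finite upper/lower bound, then the extra-constraint block G.
    Scenario-specific tightenings are passed through ``extra_bounds``
    (reaction id -> (lb, ub), None leaving a side unchanged) and
    ``extra_ineqs`` (iterable of (coefficient map or vector, rhs)) without
    mutating the model.  Infinite bounds produce no row.
    """
    n = model.n_reactions
    lb = model.lb.copy()
    ub = model.ub.copy()
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_index(rid)
            if lo is not None:
                lb[j] = max(lb[j], lo)
            if hi is not None:
                ub[j] = min(ub[j], hi)
            if lb[j] > ub[j]:
                raise ValidationError(
                    f"override makes lb > ub for reaction {rid!r}")

    rows = [model.S]
    rhs = [np.zeros(model.n_metabolites)]
    eq_rows = list(range(model.n_metabolites))
    for j in range(n):
        if math.isfinite(ub[j]):
            e = np.zeros(n)
            e[j] = 1.0
            rows.append(e.reshape(1, -1))
            rhs.append(np.array([ub[j]]))
        if math.isfinite(lb[j]):
            e = np.zeros(n)
            e[j] = -1.0
            rows.append(e.reshape(1, -1))
            rhs.append(np.array([-lb[j]]))
    if model.G.shape[0]:
        rows.append(model.G)
        rhs.append(model.h)
    if extra_ineqs:
        for coefs, val in extra_ineqs:
            a = np.zeros(n)
            if isinstance(coefs, dict):
                for rid, coef in coefs.items():
                    a[model.reaction_index(rid)] = coef
            else:
                a[:] = np.asarray(coefs, dtype=float)
            rows.append(a.reshape(1, -1))
            rhs.append(np.array([float(val)]))

    nonneg = (~model.reversible) & (lb >= 0)
    return Polyhedron(np.vstack(rows), np.concatenate(rhs),
                      eq_rows=tuple(eq_rows), nonneg=nonneg,
                      names=list(model.reaction_ids))


def feasible(poly: Polyhedron, x, tol: float = DEFAULT_TOL) -> bool:
    """True iff ``A x <= b + tol`` with equality rows within ``+/- tol``."""
    x = np.asarray(x, dtype=float).reshape(-1)
    if x.shape[0] != poly.n:
        raise ValidationError(
            f"flux vector has length {x.shape[0]}, polyhedron has {poly.n}")
    r = poly.A @ x - poly.b
    eq = np.zeros(poly.n_rows, dtype=bool)
    eq[list(poly.eq_rows)] = True
    return bool(np.all(r[~eq] <= tol) and np.all(np.abs(r[eq]) <= tol))


def export_polyhedron_tsv(poly: Polyhedron, a_path, b_path) -> None:
    """Two-file TSV export of the (expanded) inequality form."""
    A, b = poly.as_inequalities()
    np.savetxt(a_path, A, delimiter="\t")
    np.savetxt(b_path, b.reshape(-1, 1), delimiter="\t")
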