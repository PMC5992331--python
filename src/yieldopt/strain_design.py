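"""Cut-set strain design from annotated generators.

A design specification partitions the enumerated generators (EFMs/EFVs) of
the wild type into *target* behaviors (to be eliminated), *desired*
behaviors (at least one of which must survive) and *neutral* ones.  A
constrained minimal cut set (MCS) is an inclusion-minimal reaction-knockout
set whose removal blocks every target generator (hits its support) while
leaving at least one desired generator intact.  Cut sets are found by exact
Berge-style minimal-hitting-set enumeration over the target supports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import MetabolicModel, YieldSpec, ValidationError

__all__ = [
    "DesignConstraint",
    "DesignSpec",
    "CutSet",
    "partition_generators",
    "compute_mcs",
    "apply_knockouts",
    "evaluate_design",
]


@dataclass
class DesignConstraint:
    """One linear inequality over a generator's annotated rate or yield.

    quantity: ("rate", coefficient vector) or ("yield", YieldSpec)
    op: one of "<=", ">=", "<", ">"
    """

    quantity: tuple
    op: str
    value: float

    def evaluate(self, x) -> Optional[bool]:
        """Truth of the constraint at flux vector x; None if not applicable
        (yield constraint on a vector with undefined yield)."""
        from .optimize import UNDEFINED, INFINITE, yield_value

        kind, spec = self.quantity
        if kind == "rate":
            v = float(np.asarray(spec) @ np.asarray(x, dtype=float))
        elif kind == "yield":
            v = yield_value(x, spec)
            if v == UNDEFINED:
                return None
            if v == INFINITE:
                v = np.inf
        else:
            raise ValidationError(f"unknown design quantity {kind!r}")
        if self.op == "<=":
            return v <= self.value
        if self.op == ">=":
            return v >= self.value
        if self.op == "<":
            return v < self.value
        if self.op == ">":
            return v > self.value
        raise ValidationError(f"unknown operator {self.op!r}")


@dataclass
class DesignSpec:
    """Target (undesired) and desired regions as inequality conjunctions."""

    target_region: list = field(default_factory=list)
    desired_region: list = field(default_factory=list)
    notes: str = ""

    @classmethod
    def from_json(cls, path, model: MetabolicModel) -> "DesignSpec":
        """Read {constraints: [{quantity, op, value, region}]} where quantity
        is "rate:RID" or "yield:RID/RID"."""
        with open(path) as fh:
            doc = json.load(fh)
        spec = cls(notes=doc.get("notes", ""))
        n = model.n_reactions
        for row in doc["constraints"]:
            q = row["quantity"]
            if q.startswith("rate:"):
                c = np.zeros(n)
                c[model.reaction_index(q[5:])] = 1.0
                quantity = ("rate", c)
            elif q.startswith("yield:"):
                num, den = q[6:].split("/")
                quantity = ("yield", YieldSpec.single_ratio(
                    n, model.reaction_index(num), model.reaction_index(den)))
            else:
                raise ValidationError(f"unknown quantity syntax {q!r}")
            con = DesignConstraint(quantity, row["op"], float(row["value"]))
            region = row["region"]
            if region == "target":
                spec.target_region.append(con)
            elif region == "desired":
                spec.desired_region.append(con)
            else:
                raise ValidationError(f"unknown region {region!r}")
        return spec


@dataclass
class CutSet:
    reactions: frozenset
    minimal: bool = True

    def __len__(self):
        return len(self.reactions)


def _in_region(g, constraints) -> bool:
    """Generator is in a region iff every constraint holds (non-applicable
    constraints -- yields of undefined-yield generators -- fail the region)."""
    if not constraints:
        return False
    for con in constraints:
        ok = con.evaluate(g.x)
        if ok is not True:
            return False
    return True


def partition_generators(gen, design: DesignSpec):
    """Split generators into (targets, desired, neutral) lists."""
    targets, desired, neutral = [], [], []
    for g in gen:
        if _in_region(g, design.target_region):
            targets.append(g)
        elif _in_region(g, design.desired_region):
            desired.append(g)
        else:
            neutral.append(g)
    return targets, desired, neutral


def _minimal_family(sets):
    """Keep only inclusion-minimal members of a family of frozensets."""
    out = []
    for s in sorted(set(sets), key=len):
        if not any(t < s or t == s for t in out):
            out.append(s)
    return out


def compute_mcs(targets, desired, max_size: int, allowed=None):
    """All constrained minimal cut sets up to ``max_size`` knockouts.

    ``targets`` and ``desired`` are generators (objects with .support).
    ``allowed`` optionally restricts knockout candidates to a set of
    reaction indices (e.g. to exclude exchange reactions).  Berge-style
    incremental transversal enumeration, exact at this scale; a reversible
    reaction is hit regardless of its flux direction since a knockout
    removes both.
    """
    if not targets:
        raise ValidationError("target generator list is empty")
    supports = []
    for g in targets:
        sup = frozenset(g.support if allowed is None
                        else (set(g.support) & set(allowed)))
        if not sup:
            # this target cannot be hit at all (e.g. the zero vector)
            return []
        supports.append(sup)
    supports = _minimal_family(supports)

    transversals = [frozenset()]
    for sup in supports:
        nxt = []
        for h in transversals:
            if h & sup:
                nxt.append(h)
            else:
                for r in sorted(sup):
                    grown = h | {r}
                    if len(grown) <= max_size:
                        nxt.append(grown)
        transversals = _minimal_family(nxt)
    # keep cuts that spare at least one desired generator entirely
    cuts = [h for h in transversals
            if any(not (h & set(g.support)) for g in desired)]
    cuts.sort(key=lambda s: (len(s), sorted(s)))
    return [CutSet(frozenset(s)) for s in cuts]


def apply_knockouts(model: MetabolicModel, reactions) -> MetabolicModel:
    """A copy of the model with the listed reactions forced to zero flux."""
    mut = model.copy()
    for rid in reactions:
        j = rid if isinstance(rid, (int, np.integer)) \
            else model.reaction_index(rid)
        mut.lb[j] = 0.0
        mut.ub[j] = 0.0
    mut.validate()
    return mut


@dataclass
class DesignReport:
    passed: bool
    remaining_targets: list
    remaining_desired: list
    n_generators: int


def evaluate_design(model_after: MetabolicModel, design: DesignSpec,
                    extra_bounds: dict = None) -> DesignReport:
    """Re-enumerate the mutant and verify the design outcome.

    Passes iff no generator of the mutant polyhedron falls in the target
    region and at least one falls in the desired region (or the design has
    no desired region at all).
    """
    from .efv import enumerate_efvs
    from .model import build_polyhedron

    poly = build_polyhedron(model_after, extra_bounds=extra_bounds)
    gen = enumerate_efvs(poly)
    targets, desired, _ = partition_generators(gen, design)
    ok = not targets and (bool(desired) or not design.desired_region)
    return DesignReport(passed=ok, remaining_targets=targets,
                        remaining_desired=desired, n_generators=len(gen))
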