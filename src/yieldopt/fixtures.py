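"""Built-in example networks and scenarios.

``example_network`` constructs a small 6-metabolite / 11-reaction toy
network: substrate S is taken up (R1) and converted to B(iomass, excreted
by R4) and the byproducts P (R3) and Q (R2) through the intermediates A and
C; R11 (A <-> B) is the only reversible reaction, and R6 consumes two
molecules of S per C + P formed.  R7/R10/R11 form an internal cycle
(thermodynamically infeasible, kept deliberately to illustrate generators
with undefined yield).

Six scenarios on this network exercise the toolkit:

S1  flux cone (steady state + irreversibility only)
S2  S1 + substrate uptake bound r1 <= 10
S3  S2 + capacity bound r5 <= 5
S4  S2 with R5 knocked out
S5  S2 with R5 and R8 knocked out
S6  S5 + enforced flux r6 >= 3

``random_network`` generates small random sparse networks for
oracle-based property tests.
"""

from __future__ import annotations

import numpy as np

from .model import MetabolicModel, Polyhedron, build_polyhedron
from .strain_design import apply_knockouts

__all__ = ["example_network", "example_network_path", "scenario",
           "random_network", "SCENARIO_IDS"]


def example_network_path():
    """Path to the serialized native-JSON copy of the example network."""
    from importlib.resources import files

    return files("yieldopt").joinpath("data/fig1_example.json")

SCENARIO_IDS = ("S1", "S2", "S3", "S4", "S5", "S6")

_REACTIONS = [
    # id, reversible, {metabolite: coefficient}
    ("R1", False, {"S": 1}),                      # substrate uptake
    ("R2", False, {"Q": -1}),                     # Q excretion
    ("R3", False, {"P": -1}),                     # P excretion
    ("R4", False, {"B": -1}),                     # B(iomass) excretion
    ("R5", False, {"S": -1, "A": 1}),
    ("R6", False, {"S": -2, "C": 1, "P": 1}),
    ("R7", False, {"A": -1, "C": 1}),
    ("R8", False, {"S": -1, "Q": 1}),
    ("R9", False, {"S": -1, "P": 1}),
    ("R10", False, {"C": -1, "B": 1}),
    ("R11", True, {"A": -1, "B": 1}),
]

_METABOLITES = ["S", "A", "B", "C", "P", "Q"]


def example_network() -> MetabolicModel:
    """The 6-metabolite, 11-reaction example network (R11 reversible)."""
    m = len(_METABOLITES)
    n = len(_REACTIONS)
    midx = {mid: i for i, mid in enumerate(_METABOLITES)}
    S = np.zeros((m, n))
    rids, rev = [], []
    for j, (rid, r, stoich) in enumerate(_REACTIONS):
        rids.append(rid)
        rev.append(r)
        for mid, coef in stoich.items():
            S[midx[mid], j] = coef
    rev = np.array(rev)
    lb = np.where(rev, -np.inf, 0.0)
    ub = np.full(n, np.inf)
    return MetabolicModel(_METABOLITES, rids, S, rev, lb, ub)


def scenario(sid: str):
    """Return (model, polyhedron) for one of the scenarios S1..S6."""
    if sid not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario {sid!r}")
    base = example_network()
    if sid == "S1":
        return base, build_polyhedron(base)
    if sid == "S2":
        return base, build_polyhedron(base, extra_bounds={"R1": (None, 10.0)})
    if sid == "S3":
        return base, build_polyhedron(
            base, extra_bounds={"R1": (None, 10.0), "R5": (None, 5.0)})
    if sid == "S4":
        mut = apply_knockouts(base, {"R5"})
        return mut, build_polyhedron(mut, extra_bounds={"R1": (None, 10.0)})
    if sid == "S5":
        mut = apply_knockouts(base, {"R5", "R8"})
        return mut, build_polyhedron(mut, extra_bounds={"R1": (None, 10.0)})
    # S6
    mut = apply_knockouts(base, {"R5", "R8"})
    return mut, build_polyhedron(
        mut, extra_bounds={"R1": (None, 10.0), "R6": (3.0, None)})


def random_network(n_mets: int, n_rxns: int, seed: int) -> MetabolicModel:
    """A random sparse integer network for oracle-based property tests.

    Guarantees at least one uptake (column with a single +1) and one
    excretion reaction (single -1); internal columns have one or two
    substrates and one or two products with coefficients in {1, 2}.
    Roughly one reaction in five is reversible.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    S = np.zeros((n_mets, n_rxns))
    rev = np.zeros(n_rxns, dtype=bool)
    S[0, 0] = 1.0                       # uptake of metabolite 0
    S[n_mets - 1, n_rxns - 1] = -1.0    # excretion of the last metabolite
    for j in range(1, n_rxns - 1):
        k_sub = rng.integers(1, 3)
        k_prod = rng.integers(1, 3)
        mets = rng.permutation(n_mets)
        subs = mets[:k_sub]
        prods = mets[k_sub:k_sub + k_prod]
        for mi in subs:
            S[mi, j] = -float(rng.integers(1, 3))
        for mi in prods:
            S[mi, j] = float(rng.integers(1, 3))
        rev[j] = rng.random() < 0.2
    rids = [f"R{j + 1}" for j in range(n_rxns)]
    mids = [f"M{i + 1}" for i in range(n_mets)]
    lb = np.where(rev, -np.inf, 0.0)
    ub = np.full(n_rxns, np.inf)
    return MetabolicModel(mids, rids, S, rev, lb, ub)
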