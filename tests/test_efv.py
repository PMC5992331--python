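"""Enumeration and optimal-set characterization tests.

The brute-force EFM oracle enumerates candidate supports directly: a
support set S carries an elementary mode iff the stoichiometric columns in
S have a one-dimensional kernel whose vector is nonzero on all of S and
sign-feasible for the irreversible reactions.
"""

import itertools

import numpy as np
import pytest
from fractions import Fraction

import sympy

from yieldopt import (YieldSpec, annotate, classify_optimal, enumerate_efms,
                      enumerate_efvs, feasible, is_yield_optimal,
                      maximize_yield, rate_optimal_set, yield_attained,
                      yield_value, UNDEFINED)
from yieldopt.efv import EnumerationGuardError, decompose, _primitive
from yieldopt.fixtures import example_network, random_network
from yieldopt.model import MetabolicModel, ValidationError, build_polyhedron
from conftest import unit, random_feasible_points


def brute_force_efms(model):
    """All EFMs of the model's flux cone by exhaustive support search."""
    S = sympy.Matrix(model.S.astype(int))
    n = model.n_reactions
    out = []
    for size in range(1, n + 1):
        for sup in itertools.combinations(range(n), size):
            cols = S[:, list(sup)]
            null = cols.nullspace()
            if len(null) != 1:
                continue
            v = null[0]
            if any(v[k] == 0 for k in range(size)):
                continue  # support not exactly sup (handled at smaller size)
            for sign in (1, -1):   # all-reversible supports admit both signs
                w = sign * v
                ok = all(w[k] > 0 or model.reversible[sup[k]]
                         for k in range(size))
                if ok:
                    full = [Fraction(0)] * n
                    for k, j in enumerate(sup):
                        full[j] = Fraction(w[k].p, w[k].q)
                    out.append(_primitive(tuple(full)))
    # drop supersets (kernel dim 1 does not by itself guarantee minimality)
    sups = [frozenset(j for j in range(n) if v[j] != 0) for v in out]
    keep = [k for k, s in enumerate(sups)
            if not any(t < s for t in sups)]
    return [out[k] for k in keep]


class TestEnumeration:
    def test_flux_cone_has_six_efms_including_cycle(self, network):
        gen = enumerate_efms(network)
        assert len(gen) == 6
        assert all(g.kind == "unbounded" for g in gen)
        cycle = [g for g in gen if g.support == frozenset({6, 9, 10})]
        assert len(cycle) == 1
        assert cycle[0].x[10] < 0      # cycle uses R11 backward

    def test_s2_has_seven_efvs_with_zero_and_cycle(self, scenarios):
        gen = enumerate_efvs(scenarios["S2"][1])
        assert len(gen) == 7
        assert sum(g.kind == "bounded" for g in gen) == 6
        assert any(g.is_zero and g.kind == "bounded" for g in gen)
        assert [sorted(g.support) for g in gen.unbounded] == [[6, 9, 10]]
        # bounded pathway generators are scaled to the uptake bound r1 = 10
        for g in gen.bounded:
            if not g.is_zero:
                assert g.x[0] == pytest.approx(10.0)

    def test_single_reaction_chain_has_one_efm(self):
        m = MetabolicModel(["M"], ["Rin", "Rout"], [[1, -1]], [False, False],
                           [0, 0], [np.inf, np.inf])
        gen = enumerate_efms(m)
        assert len(gen) == 1
        assert sorted(gen.generators[0].support) == [0, 1]

    def test_fig1_efm_yield_pairs(self, network, biomass_yield,
                                  product_yield):
        gen = enumerate_efms(network)
        pairs = []
        for g in gen:
            yb = yield_value(g.x, biomass_yield)
            yp = yield_value(g.x, product_yield)
            pairs.append("undefined" if yb == UNDEFINED else (yb, yp))
        expected = [(0.0, 0.0), (0.5, 0.5), (0.0, 1.0), (1.0, 0.0),
                    (1.0, 0.0), "undefined"]
        assert sorted(map(str, pairs)) == sorted(map(str, expected))

    def test_reversed_network_gives_sign_flipped_efms(self):
        m = random_network(4, 6, seed=3)
        m.reversible[:] = False
        m.lb[:] = 0.0
        fwd = enumerate_efms(m)
        flipped = m.copy()
        flipped.S = -m.S
        rev = enumerate_efms(flipped)
        fwd_set = {tuple(g.x_exact) for g in fwd}
        rev_set = {tuple(-v for v in g.x_exact) for g in rev}
        assert fwd_set == rev_set

    @pytest.mark.parametrize("seed", range(8))
    def test_random_networks_match_brute_force_oracle(self, seed):
        model = random_network(5, 8, seed=seed)
        gen = enumerate_efms(model)
        mine = {tuple(g.x_exact) for g in gen}
        oracle = set(brute_force_efms(model))
        assert mine == oracle
        # exact steady state for every EFM
        for g in gen:
            resid = model.S.astype(object) @ np.array(g.x_exact, dtype=object)
            assert all(v == 0 for v in resid)

    def test_size_guard_refuses_large_models(self, network):
        with pytest.raises(EnumerationGuardError):
            enumerate_efvs(build_polyhedron(network), max_reactions=5)


class TestDecomposition:
    @pytest.mark.parametrize("sid", ["S1", "S2", "S3"])
    def test_random_feasible_points_decompose(self, scenarios, sid):
        _, poly = scenarios[sid]
        gen = enumerate_efvs(poly)
        rng = np.random.default_rng(11)
        for x in random_feasible_points(gen, rng, 25):
            assert feasible(poly, x, tol=1e-7)
            assert decompose(gen, x)

    def test_point_outside_does_not_decompose(self, scenarios):
        _, poly = scenarios["S2"]
        gen = enumerate_efvs(poly)
        x = np.zeros(11)
        x[0] = 11.0  # violates r1 <= 10
        assert not decompose(gen, x)


class TestAnnotation:
    def test_table_style_annotations(self, scenarios, biomass_yield):
        gen = enumerate_efvs(scenarios["S2"][1])
        annotate(gen, rate=unit(3), spec=biomass_yield)
        cycle = next(g for g in gen if g.kind == "unbounded")
        assert cycle.yield_status == "undefined"
        zero = next(g for g in gen if g.is_zero)
        assert zero.yield_status == "undefined"
        assert zero.rate == 0.0
        best = [g for g in gen
                if g.yield_status == "defined" and g.yield_value == 1.0]
        assert len(best) == 2
        assert all(g.rate == pytest.approx(10.0) for g in best)


class TestTheorem1Attainment:
    def test_not_attained_with_enforced_excretion(self, scenarios,
                                                  biomass_yield):
        poly = scenarios["S1"][1].with_rows(-unit(1), [-1.0])  # r2 >= 1
        gen = enumerate_efvs(poly)
        attained, supremum = yield_attained(gen, biomass_yield)
        assert not attained
        assert supremum == pytest.approx(1.0)
        # agreement with the LFP attainment test
        res = maximize_yield(poly, biomass_yield)
        assert res.status == "optimal_not_attained"
        assert res.optimal_yield == pytest.approx(supremum)

    def test_s3_attained(self, scenarios, biomass_yield):
        gen = enumerate_efvs(scenarios["S3"][1])
        attained, y_star = yield_attained(gen, biomass_yield)
        assert attained and y_star == pytest.approx(1.0)

    def test_pure_polytope_always_attained(self):
        # bounded chain: ->M-> with both fluxes capped
        m = MetabolicModel(["M"], ["Rin", "Rout"], [[1, -1]], [False, False],
                           [0, 0], [4.0, 4.0])
        gen = enumerate_efvs(build_polyhedron(m))
        assert not gen.unbounded
        attained, y = yield_attained(gen, YieldSpec.single_ratio(2, 1, 0))
        assert attained and y == pytest.approx(1.0)


class TestTheorem2OptimalSets:
    def test_s2_partition(self, scenarios, biomass_yield):
        gen = enumerate_efvs(scenarios["S2"][1])
        part = classify_optimal(gen, biomass_yield)
        stars = [gen.generators[k] for k in part.I_star]
        assert len(stars) == 2
        assert all(g.x[3] == pytest.approx(10.0) for g in stars)
        assert [gen.generators[k].is_zero for k in part.I_u] == [True]
        assert part.J_star == []
        assert [sorted(gen.generators[k].support) for k in part.J_u] == \
            [[6, 9, 10]]

    def test_s1_partition_conical(self, scenarios, biomass_yield):
        gen = enumerate_efvs(scenarios["S1"][1])
        part = classify_optimal(gen, biomass_yield)
        assert len(part.J_star) == 2           # the two yield-1 EFMs
        assert len(part.J_u) == 1              # the cycle
        assert part.I_star == []

    def test_identical_forms_make_all_defined_optimal(self, scenarios):
        gen = enumerate_efvs(scenarios["S2"][1])
        spec = YieldSpec(unit(0), unit(0))     # c = d: yield is 1 on P>
        part = classify_optimal(gen, spec)
        defined = [k for k, g in enumerate(gen.generators)
                   if yield_value(g.x, spec) not in (UNDEFINED,)]
        assert sorted(part.I_star + part.J_star) == sorted(defined)

    def test_membership_lp_positive_and_negative(self, scenarios,
                                                 biomass_yield):
        _, poly = scenarios["S2"]
        gen = enumerate_efvs(poly)
        part = classify_optimal(gen, biomass_yield)
        rng = np.random.default_rng(5)
        stars = [gen.generators[k].x for k in part.I_star]
        cycle = next(g.x for g in gen if g.kind == "unbounded")
        for _ in range(20):
            w = rng.dirichlet(np.ones(len(stars)))
            x = np.array(stars).T @ w + rng.exponential(0.5) * cycle
            assert is_yield_optimal(gen, biomass_yield, x)
            assert yield_value(x, biomass_yield) == pytest.approx(1.0)
        # suboptimal feasible points must fail the membership LP
        for x in random_feasible_points(gen, rng, 40):
            y = yield_value(x, biomass_yield)
            if isinstance(y, str) or y > 1 - 1e-6:
                continue
            assert not is_yield_optimal(gen, biomass_yield, x)

    def test_membership_requires_attainment(self, scenarios, biomass_yield):
        poly = scenarios["S1"][1].with_rows(-unit(1), [-1.0])
        gen = enumerate_efvs(poly)
        with pytest.raises(ValidationError):
            classify_optimal(gen, biomass_yield)


class TestRateOptimalSets:
    def test_s3_rate_optimal_generators(self, scenarios):
        gen = enumerate_efvs(scenarios["S3"][1])
        opt, best, addable = rate_optimal_set(gen, unit(3))
        assert best == pytest.approx(7.5)
        assert len(opt) == 2
        for k in opt:
            assert gen.generators[k].x[3] == pytest.approx(7.5)
        assert [sorted(gen.generators[k].support) for k in addable] == \
            [[6, 9, 10]]

    def test_s2_rate_and_yield_optima_coincide(self, scenarios,
                                               biomass_yield):
        gen = enumerate_efvs(scenarios["S2"][1])
        opt, best, _ = rate_optimal_set(gen, unit(3))
        part = classify_optimal(gen, biomass_yield)
        assert best == pytest.approx(10.0)
        assert sorted(opt) == sorted(part.I_star)

    def test_zero_objective_all_bounded_optimal(self, scenarios):
        gen = enumerate_efvs(scenarios["S2"][1])
        opt, best, _ = rate_optimal_set(gen, np.zeros(11))
        assert best == 0.0
        assert len(opt) == len(gen.bounded)

    def test_unbounded_rate_raises(self, scenarios):
        gen = enumerate_efvs(scenarios["S1"][1])
        with pytest.raises(ValidationError):
            rate_optimal_set(gen, unit(3))


class TestScenarioMonotonicity:
    def test_optima_never_increase_along_s1_s2_s3(self, scenarios,
                                                  biomass_yield):
        y2 = maximize_yield(scenarios["S2"][1], biomass_yield).optimal_yield
        y3 = maximize_yield(scenarios["S3"][1], biomass_yield).optimal_yield
        y1 = maximize_yield(scenarios["S1"][1], biomass_yield).optimal_yield
        assert y1 >= y2 >= y3
        from yieldopt import maximize_rate
        r2 = maximize_rate(scenarios["S2"][1], unit(3)).objective_value
        r3 = maximize_rate(scenarios["S3"][1], unit(3)).objective_value
        assert r2 >= r3
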