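"""Model-free interactions: derivative and Möbius routes, duals, categorical."""

import math
from itertools import combinations, product

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfikit import (
    JointTable,
    background_surprisal,
    boltzmann,
    boolean_derivative,
    categorical_mfi,
    conditioning_set,
    dual_mfi,
    dyadic_distribution,
    enumerate_categorical_interactions,
    gate_distribution,
    j_interaction,
    mfi,
    mfi_moebius,
    surprisal_from_interactions,
    symmetric_j,
    symmetrized_sum,
    triadic_distribution,
)
from mfikit.interactions import CyclicGraphError, InvalidTransitionError

from conftest import random_table

GATES = ("XNOR", "XOR", "AND", "OR", "NAND", "NOR")


class TestBooleanDerivative:
    def test_constant_function_has_zero_derivative(self):
        df = boolean_derivative(lambda a: 3.5, "X")
        assert df({"X": 0, "Y": 1}) == 0.0

    def test_mixed_derivative_of_product_is_one(self):
        f = lambda a: a["X"] * a["Y"]
        d2 = boolean_derivative(boolean_derivative(f, "X"), "Y")
        for x, y in product((0, 1), repeat=2):
            assert d2({"X": x, "Y": y}) == 1.0

    def test_iterated_derivative_is_order_independent(self, rng):
        values = {s: rng.normal() for s in product((0, 1), repeat=3)}
        f = lambda a: values[(a["X"], a["Y"], a["Z"])]
        d_xy = boolean_derivative(boolean_derivative(f, "X"), "Y")
        d_yx = boolean_derivative(boolean_derivative(f, "Y"), "X")
        assert d_xy({"Z": 0}) == pytest.approx(d_yx({"Z": 0}))

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_iterated_derivative_matches_signed_sum(self, rng, n):
        # ∂^n f = Σ_s (−1)^{#zeros(s)} f(s) over the differenced variables
        names = tuple(f"X{i}" for i in range(n))
        values = {s: rng.normal() for s in product((0, 1), repeat=n)}
        f = lambda a: values[tuple(a[v] for v in names)]
        d = f
        for v in names:
            d = boolean_derivative(d, v)
        expected = sum(
            (-1) ** (n - sum(s)) * values[s] for s in product((0, 1), repeat=n)
        )
        assert d({}) == pytest.approx(expected)


class TestMFI:
    def test_independent_bits_have_no_interactions(self, rng):
        margins = [rng.dirichlet((4, 4)) for _ in range(3)]
        probs = np.multiply.outer(np.multiply.outer(margins[0], margins[1]), margins[2])
        t = JointTable(("X", "Y", "Z"), probs)
        for r in (2, 3):
            for tau in combinations(t.variables, r):
                assert mfi(t, tau).value == pytest.approx(0.0, abs=1e-12)

    def test_order_one_is_log_odds(self, table3):
        got = mfi(table3, ("X",)).value
        assert got == pytest.approx(
            math.log(table3.p((1, 0, 0)) / table3.p((0, 0, 0)))
        )

    def test_pair_is_log_cross_ratio(self, table3):
        got = mfi(table3, ("X", "Y")).value
        p = table3.p
        assert got == pytest.approx(
            math.log(p((1, 1, 0)) * p((0, 0, 0)) / (p((1, 0, 0)) * p((0, 1, 0))))
        )

    def test_xnor_gate_value(self):
        t = gate_distribution("XNOR", p=0.2, eps=0.05)
        assert mfi(t, ("A", "B", "C")).value == pytest.approx(
            math.log(0.2**4 / 0.05**4)
        )

    def test_and_gate_value(self):
        t = gate_distribution("AND", p=0.2, eps=0.05)
        assert mfi(t, ("A", "B", "C")).value == pytest.approx(
            2 * math.log(0.2 / 0.05)
        )

    def test_permutation_invariance(self, table3):
        a = mfi(table3, ("X", "Y", "Z")).value
        b = mfi(table3, ("Z", "X", "Y")).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_probability_state_flags_non_finite(self):
        t = JointTable.from_states(
            ("X", "Y"), (2, 2), {(0, 0): 0.5, (0, 1): 0.25, (1, 0): 0.25}
        )
        res = mfi(t, ("X", "Y"))
        assert not res.finite

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 4))
    def test_derivative_and_moebius_routes_agree(self, seed, n):
        rng = np.random.default_rng(seed)
        t = random_table(rng, (2,) * n)
        for r in range(1, n + 1):
            for tau in combinations(t.variables, r):
                assert mfi(t, tau).value == pytest.approx(
                    mfi_moebius(t, tau).value, abs=1e-10
                )

    def test_ising_couplings_recovered_exactly(self, rng):
        for n in (2, 3, 4):
            variables = tuple(f"X{i}" for i in range(n))
            couplings = {
                frozenset(c): float(rng.uniform(-1, 1))
                for r in range(1, n + 1)
                for c in combinations(variables, r)
            }
            t = boltzmann(couplings, variables)
            for subset, j in couplings.items():
                assert mfi(t, tuple(subset)).value == pytest.approx(j, abs=1e-10)

    def test_three_point_decomposes_into_conditioned_pairs(self, table3):
        # I_XYZ = I_XY|Z=1 − I_XY|Z=0, in all three symmetric versions
        triple = mfi(table3, ("X", "Y", "Z")).value
        for fixed, pair in (("Z", ("X", "Y")), ("Y", ("X", "Z")), ("X", ("Y", "Z"))):
            on = mfi(table3.condition({fixed: 1}), pair).value
            off = mfi(table3.condition({fixed: 0}), pair).value
            assert triple == pytest.approx(on - off, abs=1e-10)


class TestDualMFI:
    def test_dual_singleton_is_sum_of_interactions(self, table3):
        assert dual_mfi(table3, ("X",)).value == pytest.approx(
            mfi(table3, ("X", "Y", "Z")).value + mfi(table3, ("Y", "Z")).value
        )

    def test_dual_singleton_log_ratio(self, table3):
        p = table3.p
        assert dual_mfi(table3, ("X",)).value == pytest.approx(
            math.log(p((1, 1, 1)) * p((1, 0, 0)) / (p((1, 0, 1)) * p((1, 1, 0))))
        )

    def test_dual_is_pair_interaction_with_background_one(self, table3):
        # I*(X) equals the YZ interaction computed with X fixed at 1
        cond = table3.condition({"X": 1})
        assert dual_mfi(table3, ("X",)).value == pytest.approx(
            mfi(cond, ("Y", "Z")).value
        )

    def test_independent_product_dual_is_zero(self, rng):
        margins = [rng.dirichlet((4, 4)) for _ in range(3)]
        probs = np.multiply.outer(np.multiply.outer(margins[0], margins[1]), margins[2])
        t = JointTable(("X", "Y", "Z"), probs)
        assert dual_mfi(t, ("X",)).value == pytest.approx(0.0, abs=1e-12)


class TestJInteractions:
    def test_xnor_input_j_is_three_halves(self):
        t = gate_distribution("XNOR", p=0.2, eps=0.05)
        scale = 4 * math.log(0.2 / 0.05)
        assert j_interaction(t, "A") == pytest.approx(1.5 * scale)

    def test_gate_identity_triple_plus_twice_pair(self):
        for name in GATES:
            t = gate_distribution(name, p=0.2, eps=0.05)
            i_abc = mfi(t, ("A", "B", "C")).value
            i_ab = mfi(t, ("A", "B")).value
            assert i_abc + 2 * i_ab == pytest.approx(0.0, abs=1e-10)

    def test_input_j_distinguishes_all_six_gates(self):
        values = [
            round(j_interaction(gate_distribution(name, p=0.2, eps=0.05), "A"), 9)
            for name in GATES
        ]
        assert len(set(values)) == 6

    def test_symmetric_j_is_product_of_three(self):
        t = gate_distribution("AND", p=0.2, eps=0.05)
        expected = 1.0
        for v in ("A", "B", "C"):
            expected *= j_interaction(t, v)
        assert symmetric_j(t) == pytest.approx(expected)

    def test_gate_sign_structure(self):
        # XNOR = −XOR = 2·AND = −2·OR = −2·NAND = 2·NOR at equal (p, ε)
        vals = {
            name: mfi(gate_distribution(name, p=0.2, eps=0.05), ("A", "B", "C")).value
            for name in GATES
        }
        i = vals["XNOR"]
        assert vals["XOR"] == pytest.approx(-i)
        assert vals["AND"] == pytest.approx(i / 2)
        assert vals["OR"] == pytest.approx(-i / 2)
        assert vals["NAND"] == pytest.approx(-i / 2)
        assert vals["NOR"] == pytest.approx(i / 2)


class TestSurprisalDecomposition:
    def test_zeta_sum_reconstructs_background_log_probability(self, table3):
        for r in range(0, 4):
            for tau in combinations(table3.variables, r):
                assert surprisal_from_interactions(table3, tau) == pytest.approx(
                    background_surprisal(table3, tau), abs=1e-10
                )

    def test_empty_set_interaction_is_all_zeros_log_probability(self, table3):
        assert surprisal_from_interactions(table3, ()) == pytest.approx(
            math.log(table3.p((0, 0, 0)))
        )

    def test_uniform_table_reduces_to_constant(self):
        t = JointTable(("X", "Y"), np.full((2, 2), 0.25))
        assert surprisal_from_interactions(t, ("X", "Y")) == pytest.approx(
            math.log(0.25)
        )
        assert mfi(t, ("X", "Y")).value == pytest.approx(0.0, abs=1e-12)


class TestCategorical:
    def test_binary_transition_reduces_to_mfi(self, table3):
        got = categorical_mfi(table3, {"X": (0, 1), "Y": (0, 1)})
        assert got.value == pytest.approx(mfi(table3, ("X", "Y")).value)

    def test_dyadic_diagonal_transition_is_zero(self):
        t = dyadic_distribution(1e-4)
        res = categorical_mfi(t, {"X": (0, 3), "Y": (0, 3), "Z": (0, 3)})
        assert res.value == pytest.approx(0.0, abs=1e-10)

    def test_triadic_diagonal_transition_is_log_eps_over_p(self):
        eps = 1e-4
        t = triadic_distribution(eps)
        p = (1 - 56 * eps) / 8
        res = categorical_mfi(t, {"X": (0, 3), "Y": (0, 3), "Z": (0, 3)})
        assert res.value == pytest.approx(math.log(eps / p), abs=1e-10)

    def test_transitivity_along_the_chain_lattice(self, rng):
        t = random_table(rng, (3, 3), variables=("X", "Y"))
        direct = categorical_mfi(t, {"X": (0, 2), "Y": (0, 1)}).value
        step1 = categorical_mfi(t, {"X": (0, 1), "Y": (0, 1)}).value
        step2 = categorical_mfi(t, {"X": (1, 2), "Y": (0, 1)}).value
        assert direct == pytest.approx(step1 + step2, abs=1e-10)

    def test_non_increasing_transition_rejected(self, table3):
        with pytest.raises(InvalidTransitionError):
            categorical_mfi(table3, {"X": (1, 0)})
        with pytest.raises(InvalidTransitionError):
            categorical_mfi(table3, {"X": (0, 5)})

    def test_enumeration_counts_216_for_arity_four_triple(self):
        t = dyadic_distribution(1e-4)
        results = enumerate_categorical_interactions(t)
        assert len(results) == 216

    def test_enumeration_requires_three_variables(self, table3):
        with pytest.raises(ValueError):
            enumerate_categorical_interactions(table3.marginalize(("X", "Y")))

    def test_symmetrized_sums(self):
        eps = 1e-4
        p = (1 - 56 * eps) / 8
        assert symmetrized_sum(dyadic_distribution(eps)) == pytest.approx(
            0.0, abs=1e-8
        )
        assert symmetrized_sum(triadic_distribution(eps)) == pytest.approx(
            64 * math.log(eps / p), abs=1e-8
        )


class TestConditioningSet:
    def test_chain_interaction_vanishes_given_middle(self, rng):
        # A → B → C: with B held at 0, A and C do not interact
        pa = 0.3
        p_b_given_a = np.array([[0.8, 0.2], [0.3, 0.7]])
        p_c_given_b = np.array([[0.9, 0.1], [0.4, 0.6]])
        probs = np.zeros((2, 2, 2))
        for a, b, c in product((0, 1), repeat=3):
            probs[a, b, c] = (
                (pa if a else 1 - pa) * p_b_given_a[a, b] * p_c_given_b[b, c]
            )
        t = JointTable(("A", "B", "C"), probs)
        assert mfi(t, ("A", "C")).value == pytest.approx(0.0, abs=1e-12)

    def test_blanket_of_chain_and_complete_graph(self):
        chain = nx.DiGraph([("A", "B"), ("B", "C")])
        assert conditioning_set(chain, ("A", "C")) == frozenset({"A", "B", "C"})
        complete = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "C")])
        assert conditioning_set(complete, ("A",)) == frozenset({"A", "B", "C"})

    def test_cyclic_graph_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(CyclicGraphError):
            conditioning_set(g, ("A",))

    def test_independent_variable_can_be_dropped_from_background(self, rng):
        # joint = dependent (X, Y) ⊗ independent W: the blanket omits W and
        # the restricted-background MFI matches full conditioning
        xy = random_table(rng, (2, 2), variables=("X", "Y"))
        w = rng.dirichlet((2, 2))
        probs = np.multiply.outer(xy.probs, w)
        t = JointTable(("X", "Y", "W"), probs)
        graph = nx.DiGraph()
        graph.add_edge("X", "Y")
        graph.add_node("W")
        blanket = conditioning_set(graph, ("X", "Y"))
        assert "W" not in blanket
        assert mfi(t, ("X", "Y"), tuple(blanket)).value == pytest.approx(
            mfi(t, ("X", "Y")).value, abs=1e-12
        )
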