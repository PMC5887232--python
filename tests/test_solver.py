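"""Forcing solutions (prime implicants) and systems of Boolean equations."""

import random

import pytest

import pckernel as pk
from pckernel.model import LogicRule, PartialAssignment, ThresholdRule
from pckernel.solver import forcing_solutions, minimal_elements, system_solutions

from conftest import brute_forcing_solutions, rule_truth_table


def rule(text):
    return pk.parse_logic_model(text).rules[text.split(",")[0].strip()]


class TestForcingSolutions:
    @pytest.mark.parametrize(
        "text, value, expected",
        [
            # the three worked per-equation solution sets
            ("P, C&E", 0, [{"C": 0}, {"E": 0}]),
            ("E, D|F", 0, [{"D": 0, "F": 0}]),
            ("C, (!B)&D&E", 0, [{"B": 1}, {"D": 0}, {"E": 0}]),
            # basics
            ("Y, X", 1, [{"X": 1}]),
            ("P, C&E", 1, [{"C": 1, "E": 1}]),
            ("E, D|F", 1, [{"D": 1}, {"F": 1}]),
            # redundant forms still give semantic implicants
            ("Z, (A&B)|(A&!B)", 1, [{"A": 1}]),
        ],
    )
    def test_worked_equations(self, text, value, expected):
        fss = forcing_solutions(rule(text), value)
        assert [dict(s.items()) for s in fss.solutions] == expected

    def test_unsatisfiable_target_is_flagged(self):
        fss = forcing_solutions(rule("T, A|!A"), 0)
        assert fss.unsatisfiable and fss.solutions == ()

    def test_constant_rule_forced_by_empty_assignment(self):
        fss = forcing_solutions(rule("T, A|!A"), 1)
        assert [dict(s.items()) for s in fss.solutions] == [{}]

    def test_threshold_rule_solutions(self):
        r = ThresholdRule("C", (("A", 1), ("B", -1)))
        # C = 1 requires A = 1 AND B = 0 (sum must exceed zero)
        assert [dict(s.items()) for s in forcing_solutions(r, 1).solutions] == [
            {"A": 1, "B": 0}
        ]
        # C = 0 whenever A = 0 or B = 1 (sum <= 0 maps to 0)
        assert [dict(s.items()) for s in forcing_solutions(r, 0).solutions] == [
            {"A": 0},
            {"B": 1},
        ]

    @pytest.mark.parametrize("seed", range(150))
    def test_matches_brute_force_oracle(self, seed):
        """Prime implicants must equal the naive enumeration of all minimal
        forcing partial assignments, for random rules of 1-5 inputs."""
        rng = random.Random(seed)
        k = rng.randint(1, 5)
        names = [f"x{i}" for i in range(k)]
        table = [rng.randint(0, 1) for _ in range(1 << k)]
        terms = []
        for m, out in enumerate(table):
            if out:
                lits = [("var", names[j]) if (m >> j) & 1 else ("not", ("var", names[j]))
                        for j in range(k)]
                terms.append(lits[0] if k == 1 else ("and", tuple(lits)))
        ast = ("const", 0) if not terms else (terms[0] if len(terms) == 1 else ("or", tuple(terms)))
        r = LogicRule("T", ast)
        for value in (0, 1):
            got = list(forcing_solutions(r, value).solutions)
            assert got == brute_forcing_solutions(r, value)

    @pytest.mark.parametrize("seed", range(20))
    def test_solutions_force_for_all_completions_sympy(self, seed):
        """Independent cross-check with sympy: substituting a solution must
        make the expression identically equal to the target value."""
        import sympy
        from sympy.logic.boolalg import And, Not, Or
        from sympy.logic.inference import satisfiable

        rng = random.Random(1000 + seed)
        from pckernel.fixtures import _nested_ast

        names = [f"x{i}" for i in range(rng.randint(2, 5))]
        ast = _nested_ast(list(names), rng)
        r = LogicRule("T", ast)

        def to_sympy(a):
            tag = a[0]
            if tag == "var":
                return sympy.Symbol(a[1])
            if tag == "const":
                return sympy.true if a[1] else sympy.false
            if tag == "not":
                return Not(to_sympy(a[1]))
            op = And if tag == "and" else Or
            return op(*(to_sympy(s) for s in a[1]))

        expr = to_sympy(ast)
        for value in (0, 1):
            for sol in forcing_solutions(r, value).solutions:
                sub = expr.subs({sympy.Symbol(n): sympy.true if v else sympy.false
                                 for n, v in sol.items()})
                residual = Not(sub) if value else sub
                assert satisfiable(residual) is False


from hypothesis import given, settings
from hypothesis import strategies as st


class TestForcingProperties:
    """Hypothesis property checks over arbitrary small truth tables."""

    @staticmethod
    def _rule_from_table(table):
        k = (len(table) - 1).bit_length()
        names = [f"x{i}" for i in range(k)]
        terms = []
        for m, out in enumerate(table):
            if out:
                lits = [("var", names[j]) if (m >> j) & 1
                        else ("not", ("var", names[j])) for j in range(k)]
                terms.append(lits[0] if k == 1 else ("and", tuple(lits)))
        ast = ("const", 0) if not terms else (
            terms[0] if len(terms) == 1 else ("or", tuple(terms)))
        return LogicRule("T", ast)

    @given(st.integers(min_value=1, max_value=4).flatmap(
        lambda k: st.lists(st.integers(0, 1), min_size=1 << k, max_size=1 << k)))
    @settings(derandomize=True, max_examples=120, deadline=None)
    def test_solutions_are_minimal_forcing_and_complete(self, table):
        r = self._rule_from_table(table)
        for value in (0, 1):
            got = list(forcing_solutions(r, value).solutions)
            assert got == brute_forcing_solutions(r, value)
            # pairwise non-inclusion within the solution set
            for a in got:
                for b in got:
                    assert a == b or not a.issubset(b)


class TestMinimalElements:
    def test_supersets_dropped_and_sorted(self):
        a = PartialAssignment({"A": 0})
        ab = PartialAssignment({"A": 0, "B": 1})
        c = PartialAssignment({"C": 1})
        assert minimal_elements([ab, a, c, a]) == [a, c]

    def test_equal_values_required_for_inclusion(self):
        a0 = PartialAssignment({"A": 0})
        a1b = PartialAssignment({"A": 1, "B": 1})
        assert minimal_elements([a0, a1b]) == [a0, a1b]


class TestSystemSolutions:
    def test_root_system_includes_self_clamp(self, example_net):
        sols = system_solutions(PartialAssignment({"P": 0}), example_net)
        assert [dict(s.items()) for s in sols] == [{"C": 0}, {"E": 0}, {"P": 0}]

    def test_merge_and_minimality_without_self_clamps(self):
        net = pk.parse_logic_model("X, A&B\nY, A|C")
        sols = system_solutions(
            PartialAssignment({"X": 0, "Y": 0}), net, include_self_clamps=False
        )
        assert [dict(s.items()) for s in sols] == [{"A": 0, "C": 0}]

    def test_self_clamps_add_partial_substitutes(self):
        net = pk.parse_logic_model("X, A&B\nY, A|C")
        sols = system_solutions(PartialAssignment({"X": 0, "Y": 0}), net)
        as_dicts = [dict(s.items()) for s in sols]
        assert {"A": 0, "C": 0} in as_dicts  # pure forcing product
        assert {"A": 0, "Y": 0} in as_dicts  # Y clamped, X forced via A
        assert {"X": 0, "Y": 0} in as_dicts  # both clamped (the parent itself)

    def test_conflicting_product_tuples_dropped(self):
        # forcing X=1 requires A=1 while forcing Y=1 requires A=0: the pure
        # product conflicts and is dropped; self-clamp combinations survive
        net = pk.parse_logic_model("X, A\nY, !A")
        sols = system_solutions(PartialAssignment({"X": 1, "Y": 1}), net)
        assert [dict(s.items()) for s in sols] == [
            {"A": 0, "X": 1},
            {"A": 1, "Y": 1},
            {"X": 1, "Y": 1},
        ]

    def test_input_node_parent_is_leaf(self, example_net):
        assert system_solutions(PartialAssignment({"F": 0}), example_net) == []

    def test_clamped_parent_is_leaf(self, example_net):
        net = pk.apply_control(example_net, {"C": 0})
        assert system_solutions(PartialAssignment({"C": 0}), net) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_solutions_force_every_parent_equation(self, seed):
        """Soundness: substituting any returned assignment makes each parent
        node's rule constant at the parent value (or clamps the node)."""
        from conftest import signaling_net

        rng = random.Random(seed)
        net = signaling_net(seed, ("nested", "table")[seed % 2])
        nodes = rng.sample([n for n in net.nodes if n in net.rules], 2)
        parent = PartialAssignment({n: rng.randint(0, 1) for n in nodes})
        for sol in system_solutions(parent, net):
            for node, want in parent.items():
                if dict(sol.items()).get(node) == want:
                    continue  # value held by clamp
                inputs, _ = rule_truth_table(net.rules[node])
                fixed = dict(sol.items())
                for bits in range(1 << len(inputs)):
                    env = {x: (bits >> j) & 1 for j, x in enumerate(inputs)}
                    if any(env[k] != v for k, v in fixed.items() if k in inputs):
                        continue  # completion inconsistent with the solution
                    assert net.rules[node].evaluate(env) == want
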