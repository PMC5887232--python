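"""Converging tree construction, removal rules, and the control kernel."""

import json

import pytest

import pckernel as pk
from pckernel.model import PartialAssignment
from pckernel.tree import is_contradictory, is_included
from pckernel.verify import forces_by_substitution

from conftest import signaling_net


def pa(**kwargs):
    return PartialAssignment(kwargs)


class TestRemovalRules:
    @pytest.mark.parametrize(
        "candidate, others, expected",
        [
            (dict(A=0, B=1), [dict(A=0)], True),   # smaller set achieves as much
            (dict(E=0), [dict(E=0)], True),        # equal sets include each other
            (dict(A=0), [dict(B=0)], False),       # disjoint
            (dict(A=0), [dict(A=1)], False),       # same node, opposite value
            (dict(A=0), [dict(A=0, B=1)], False),  # only smaller-or-equal includes
        ],
    )
    def test_first_rule_inclusion(self, candidate, others, expected):
        flag, witness = is_included(
            PartialAssignment(candidate), [PartialAssignment(o) for o in others]
        )
        assert flag is expected
        assert (witness is not None) is expected

    @pytest.mark.parametrize(
        "candidate, ancestors, expected",
        [
            (dict(C=1, F=0), [dict(B=1), dict(C=0), dict(P=0)], True),
            (dict(B=1), [dict(C=0), dict(P=0)], False),
            (dict(C=0), [dict(C=0)], False),  # same value never contradicts
        ],
    )
    def test_second_rule_contradiction(self, candidate, ancestors, expected):
        flag, witness = is_contradictory(
            PartialAssignment(candidate), [PartialAssignment(a) for a in ancestors]
        )
        assert flag is expected


@pytest.fixture(scope="module")
def example_tree(example_net, pheno_p0):
    return pk.build_converging_tree(example_net, pheno_p0)


@pytest.fixture(scope="module")
def fragment_tree():
    net = pk.simplified_mapk_fragment()
    return pk.build_converging_tree(net, pk.PhenotypeSpec(("Proliferation",), (0,)))


class TestExampleTree:
    """The full worked seven-node example, level by level."""

    @pytest.fixture
    def tree(self, example_tree):
        return example_tree

    def test_complete_status(self, tree):
        assert tree.status == "complete"

    def test_levels(self, tree):
        by_level = {}
        for cs in tree.surviving():
            by_level.setdefault(cs.level, set()).add(cs.assignment)
        assert by_level[1] == {pa(C=0), pa(E=0)}
        assert by_level[2] == {pa(B=1), pa(D=0)}
        assert by_level[3] == {pa(A=0)}
        assert by_level[4] == {pa(F=0)}

    def test_removed_sets_and_reasons(self, tree):
        removed = {
            cs.assignment: (cs.level, cs.removal_reason)
            for cs in tree.sets.values()
            if cs.removed
        }
        assert removed == {
            pa(P=0): (1, "included"),           # redundant with the root
            pa(E=0): (2, "included"),           # already present in level 1
            pa(D=0, F=0): (2, "included"),      # {D=0} is the smaller perturbation
            pa(C=1, F=0): (3, "contradictory"),  # clashes with ancestor {C=0}
        }

    def test_removal_witnesses(self, tree):
        by_assignment = {}
        for cs in tree.sets.values():
            by_assignment.setdefault(cs.assignment, []).append(cs)
        df = next(c for c in by_assignment[pa(D=0, F=0)])
        assert tree.get(df.witness_id).assignment == pa(D=0)
        cf = next(c for c in by_assignment[pa(C=1, F=0)])
        assert tree.get(cf.witness_id).assignment == pa(C=0)

    def test_leaves(self, tree):
        leaves = {cs.assignment for cs in tree.surviving() if cs.leaf}
        # {E=0} has no surviving children; {B=1}'s only child is contradictory;
        # {F=0} clamps an input node
        assert leaves == {pa(E=0), pa(B=1), pa(F=0)}

    def test_pck_is_the_six_sets(self, tree):
        kernel = pk.extract_pck(tree)
        assert [dict(a.items()) for a in kernel.assignments] == [
            {"C": 0}, {"E": 0}, {"B": 1}, {"D": 0}, {"A": 0}, {"F": 0}
        ]
        assert kernel.status == "complete"


class TestMapkFragmentWalkthrough:
    """The documented simplified-MAPK construction, steps 1-4."""

    @pytest.fixture
    def tree(self, fragment_tree):
        return fragment_tree

    def test_levels_match_walkthrough(self, tree):
        by_level = {}
        for cs in tree.surviving():
            by_level.setdefault(cs.level, set()).add(cs.assignment)
        assert by_level[1] == {pa(p70=0), pa(MYC=0)}
        assert by_level[2] == {pa(ERK=0), pa(MSK=0)}
        assert by_level[3] == {pa(MEK1_2=0)}
        assert by_level[4] == {pa(AP1=1)}

    def test_erk_p38_pair_removed_and_msk_is_leaf(self, tree):
        pair = next(c for c in tree.sets.values() if c.assignment == pa(ERK=0, p38=0))
        assert pair.removed and pair.removal_reason == "included"
        assert tree.get(pair.witness_id).assignment == pa(ERK=0)
        msk = next(c for c in tree.surviving() if c.assignment == pa(MSK=0))
        assert msk.leaf


class TestSmallCases:
    def test_single_forcing_input(self):
        net = pk.parse_logic_model("P, A")
        kernel = pk.extract_pck(
            pk.build_converging_tree(net, pk.PhenotypeSpec(("P",), (0,)))
        )
        assert [dict(a.items()) for a in kernel.assignments] == [{"A": 0}]

    def test_input_phenotype_gives_empty_kernel(self):
        net = pk.BooleanNetwork(["P"], [])
        tree = pk.build_converging_tree(net, pk.PhenotypeSpec(("P",), (1,)))
        assert tree.status == "complete"
        assert len(pk.extract_pck(tree)) == 0

    def test_max_level_caps_construction(self, example_net, pheno_p0):
        tree = pk.build_converging_tree(example_net, pheno_p0, max_level=2)
        assert tree.status == "level_capped"
        assert tree.n_levels == 2

    def test_restructuring_discovers_partial_clamps(self):
        """Feedback between the regulators of an XOR-like rule: clamping one
        node propagates to the other, so the singletons are the true minimal
        sets and tree restructuring must surface them."""
        net = pk.parse_logic_model("P, (A&!B)|(!A&B)\nA, B\nB, A")
        pheno = pk.PhenotypeSpec(("P",), (0,))
        tree = pk.build_converging_tree(net, pheno)
        assert tree.status == "complete"
        kernel = pk.extract_pck(tree)
        got = sorted((dict(a.items()) for a in kernel.assignments),
                     key=lambda d: sorted(d.items()))
        assert got == [{"A": 0}, {"A": 1}, {"B": 0}, {"B": 1}]
        assert pk.brute_force_kernel(net, pheno, max_size=2) == sorted(kernel.assignments)


class TestTreeProperties:
    @pytest.mark.parametrize("seed", range(30))
    def test_pck_pairwise_non_inclusion(self, seed):
        net = signaling_net(seed, ("nested", "table", "threshold")[seed % 3])
        tree = pk.build_converging_tree(net, pk.PhenotypeSpec(("P",), (0,)))
        members = pk.extract_pck(tree).assignments
        for a in members:
            for b in members:
                if a != b:
                    assert not a.issubset(b)

    @pytest.mark.parametrize("seed", range(30))
    def test_every_member_forces_by_substitution_and_dynamics(self, seed):
        """Soundness: each surviving control set pins the phenotype both by
        iterated substitution and in the exhaustive state space."""
        net = signaling_net(seed, ("nested", "table", "threshold")[seed % 3])
        pheno = pk.PhenotypeSpec(("P",), (0,))
        tree = pk.build_converging_tree(net, pheno)
        for c in pk.extract_pck(tree).assignments:
            assert forces_by_substitution(net, c, pheno)
            assert pk.verify_control_set(net, c, pheno).holds

    def test_json_deterministic_across_runs(self, example_net, pheno_p0):
        a = pk.build_converging_tree(example_net, pheno_p0).to_json_obj()
        b = pk.build_converging_tree(example_net, pheno_p0).to_json_obj()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_child_levels_increment(self, example_net, pheno_p0):
        tree = pk.build_converging_tree(example_net, pheno_p0)
        for cs in tree.sets.values():
            if cs.parent_id is not None:
                assert cs.level == tree.get(cs.parent_id).level + 1


class TestFindSetsContaining:
    def test_non_layered_node_answers_without_building(self):
        net = pk.parse_logic_model("P, A\nA, B\nX, A")
        hits, tree = pk.find_sets_containing(net, pk.PhenotypeSpec(("P",), (0,)), "X")
        assert hits == [] and tree is None

    def test_layered_node_found_at_its_layer(self, example_net, pheno_p0):
        hits, tree = pk.find_sets_containing(example_net, pheno_p0, "A")
        assert tree is not None
        assert [(c.level, dict(c.assignment.items())) for c in hits] == [(3, {"A": 0})]


class TestKnownScopeLimit:
    def test_dynamic_only_forcing_is_invisible_to_substitution(self):
        """A clamp can control the phenotype through reachability (which
        states actually occur) without ever making the rules constant by
        substitution.  The converging tree characterizes substitution
        forcing, so such sets are outside its scope; this pins the
        documented boundary."""
        net = pk.parse_logic_model(
            "P, !N7\n"
            "N1, !N4&N5&N7\n"
            "N2, (N5|!N6)&N7\n"
            "N3, N5&N6&!N7\n"
            "N4, !N2\n"
            "N5, N3&!N4&!N6\n"
            "N6, !N5\n"
            "N7, N1&!N3&!N5\n"
        )
        pheno = pk.PhenotypeSpec(("P",), (0,))
        clamp = {"N1": 1}
        assert pk.verify_control_set(net, clamp, pheno).holds
        assert not forces_by_substitution(net, clamp, pheno)
        kernel = pk.extract_pck(pk.build_converging_tree(net, pheno))
        assert not any(m.issubset(PartialAssignment(clamp))
                       for m in kernel.assignments)
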