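import random

import pytest

from netsets import SetManager, build_network, select_by_threshold
from netsets.errors import (
    MixedKindError,
    NameCollisionError,
    UnknownElementError,
    UnknownSetError,
    UnsupportedTypeError,
)
from netsets.graph_model import AttributeTable


@pytest.fixture
def mgr(toy_network):
    return SetManager(toy_network)


class TestCreateAndMutate:
    def test_create_dedups_and_keeps_order(self, mgr):
        s = mgr.create_set("A", "node", ["n1", "n2", "n2"])
        assert s.members == ["n1", "n2"]
        assert mgr.creation_order == ["A"]

    def test_duplicate_name_rejected(self, mgr):
        mgr.create_set("A", "node", ["n1"])
        with pytest.raises(NameCollisionError):
            mgr.create_set("A", "node", ["n2"])

    def test_unknown_member_rejected(self, mgr):
        with pytest.raises(UnknownElementError):
            mgr.create_set("A", "node", ["ghost"])

    def test_edge_set_uses_edge_ids(self, mgr):
        s = mgr.create_set("E", "edge", ["n1 (pp) n2"])
        assert s.element_kind == "edge"
        with pytest.raises(UnknownElementError):
            mgr.create_set("E2", "edge", ["n1"])  # node id is not an edge

    def test_add_to_appends_without_duplicates(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        assert mgr.add_to("A", ["n2", "n3"]).members == ["n1", "n2", "n3"]

    def test_add_to_missing_set_errors(self, mgr):
        with pytest.raises(UnknownSetError):
            mgr.add_to("missing", ["n1"])

    def test_remove_from_ignores_absent_members(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        assert mgr.remove_from("A", ["n1", "n5"]).members == ["n2"]

    def test_rename_is_an_involution(self, mgr):
        mgr.create_set("A", "node", ["n1"])
        mgr.create_set("B", "node", ["n2"])
        before = (list(mgr.creation_order), {n: list(mgr.get(n).members) for n in mgr.names()})
        mgr.rename_set("A", "A2")
        assert mgr.creation_order == ["A2", "B"]
        mgr.rename_set("A2", "A")
        after = (list(mgr.creation_order), {n: list(mgr.get(n).members) for n in mgr.names()})
        assert before == after

    def test_rename_to_existing_name_rejected(self, mgr):
        mgr.create_set("A", "node", ["n1"])
        mgr.create_set("B", "node", ["n2"])
        with pytest.raises(NameCollisionError):
            mgr.rename_set("A", "B")

    def test_remove_set_then_query_errors(self, mgr):
        mgr.create_set("A", "node", ["n1"])
        mgr.remove_set("A")
        with pytest.raises(UnknownSetError):
            mgr.get("A")
        assert mgr.creation_order == []


class TestAlgebra:
    @pytest.fixture
    def abc(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        mgr.create_set("B", "node", ["n2", "n3"])
        mgr.create_set("C", "node", ["n2", "n4"])
        return mgr

    def test_union_enumerates_all_members(self, abc):
        assert abc.union_sets("U", ["A", "B"]).members == ["n1", "n2", "n3"]

    def test_intersection_of_three(self, abc):
        assert abc.intersect_sets("I", ["A", "B", "C"]).members == ["n2"]

    def test_intersection_is_idempotent_on_equal_content(self, abc):
        abc.create_set("A2", "node", ["n1", "n2"])
        assert abc.intersect_sets("I", ["A", "A2"]).members == ["n1", "n2"]

    def test_difference_is_order_dependent(self, abc):
        assert abc.difference_sets("D1", ["A", "B"]).members == ["n1"]
        assert abc.difference_sets("D2", ["B", "A"]).members == ["n3"]

    def test_self_difference_is_empty(self, abc):
        abc.create_set("A2", "node", ["n1", "n2"])
        assert abc.difference_sets("D", ["A", "A2"]).members == []

    def test_difference_folds_left_over_three_inputs(self, abc):
        assert abc.difference_sets("D", ["A", "B", "C"]).members == ["n1"]

    def test_kind_mismatch_across_inputs(self, abc):
        abc.create_set("E", "edge", ["n1 (pp) n2"])
        with pytest.raises(MixedKindError):
            abc.union_sets("U", ["A", "E"])

    def test_result_name_collision(self, abc):
        with pytest.raises(NameCollisionError):
            abc.union_sets("C", ["A", "B"])

    def test_operations_leave_other_sets_untouched(self, abc):
        before = {n: list(abc.get(n).members) for n in ("A", "B", "C")}
        abc.union_sets("U", ["A", "B"])
        abc.difference_sets("D", ["A", "C"])
        after = {n: list(abc.get(n).members) for n in ("A", "B", "C")}
        assert before == after


class TestPartition:
    def test_two_overlapping_sets_give_three_atoms(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        mgr.create_set("B", "node", ["n2", "n3"])
        atoms = mgr.partition(["A", "B"], prefix="p ")
        got = {tuple(sorted(sig)): atom.members for sig, atom in atoms.items()}
        assert got == {("A",): ["n1"], ("B",): ["n3"], ("A", "B"): ["n2"]}
        assert atoms[frozenset({"A", "B"})].name == "p A:B"

    def test_disjoint_sets_partition_to_themselves(self, mgr):
        mgr.create_set("A", "node", ["n1"])
        mgr.create_set("B", "node", ["n2", "n3"])
        atoms = mgr.partition(["A", "B"], prefix="p ")
        assert atoms[frozenset({"A"})].members == ["n1"]
        assert atoms[frozenset({"B"})].members == ["n2", "n3"]
        assert len(atoms) == 2

    def test_identical_sets_give_single_atom(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        mgr.create_set("B", "node", ["n1", "n2"])
        atoms = mgr.partition(["A", "B"], prefix="p ")
        assert len(atoms) == 1
        assert atoms[frozenset({"A", "B"})].members == ["n1", "n2"]

    def test_atom_name_collision_rejected_and_atomic(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        mgr.create_set("B", "node", ["n2", "n3"])
        before = list(mgr.creation_order)
        with pytest.raises(NameCollisionError):
            mgr.partition(["A", "B"])  # singleton atom "A" collides with input
        assert mgr.creation_order == before  # nothing registered

    def test_atoms_are_registered_managed_sets(self, mgr):
        mgr.create_set("A", "node", ["n1", "n2"])
        atoms = mgr.partition(["A"], prefix="p ")
        assert mgr.get("p A") is atoms[frozenset({"A"})]


class TestAttributeSets:
    def test_one_set_per_distinct_value(self, toy_network, mgr):
        table = AttributeTable(toy_network, "node")
        table.set_column("grp", "string", {"n1": "a", "n2": "a", "n3": "b"})
        sets = mgr.create_sets_from_attribute("P", "node", table, "grp")
        by_name = {s.name: s.members for s in sets}
        assert by_name == {"Pa": ["n1", "n2"], "Pb": ["n3"]}

    def test_all_null_column_creates_nothing(self, toy_network, mgr):
        table = AttributeTable(toy_network, "node")
        table.set_column("grp", "string", {})
        assert mgr.create_sets_from_attribute("P", "node", table, "grp") == []

    def test_numeric_column_unsupported(self, toy_network, mgr):
        table = AttributeTable(toy_network, "node")
        table.set_column("x", "numeric", {"n1": 1.0})
        with pytest.raises(UnsupportedTypeError):
            mgr.create_sets_from_attribute("P", "node", table, "x")


class TestThresholdSelect:
    @pytest.fixture
    def table(self, toy_network):
        t = AttributeTable(toy_network, "node")
        t.set_column("expr", "numeric", {"n1": -0.8, "n2": -0.2, "n4": 0.7})
        t.set_column("label", "string", {"n1": "x"})
        return t

    def test_lt_excludes_nulls(self, table):
        assert select_by_threshold(table, "expr", "lt", -0.5) == ["n1"]

    def test_gt_below_minimum_selects_all_non_null(self, table):
        assert select_by_threshold(table, "expr", "gt", -10.0) == ["n1", "n2", "n4"]

    def test_boundary_relations(self, table):
        assert select_by_threshold(table, "expr", "le", -0.2) == ["n1", "n2"]
        assert select_by_threshold(table, "expr", "ge", 0.7) == ["n4"]

    def test_string_column_rejected(self, table):
        with pytest.raises(UnsupportedTypeError):
            select_by_threshold(table, "label", "lt", 0)


class TestOracleEquivalence:
    """Set algebra agrees with per-element enumeration on random universes."""

    @staticmethod
    def _random_instance(rng):
        n = rng.randint(5, 20)
        universe = [f"e{i}" for i in range(n)]
        net = build_network("u", [])
        for e in universe:
            net.add_node(e)
        mgr = SetManager(net)
        names = []
        for k in range(rng.randint(3, 5)):
            members = [e for e in universe if rng.random() < 0.4]
            mgr.create_set(f"S{k}", "node", members)
            names.append(f"S{k}")
        return universe, mgr, names, rng

    @pytest.mark.parametrize("seed", range(20))
    def test_algebra_matches_enumeration(self, seed):
        universe, mgr, names, rng = self._random_instance(random.Random(seed))
        member = {n: mgr.get(n).member_set() for n in names}

        union = mgr.union_sets("U", names)
        assert union.member_set() == {e for e in universe if any(e in member[n] for n in names)}

        inter = mgr.intersect_sets("I", names)
        assert inter.member_set() == {e for e in universe if all(e in member[n] for n in names)}

        order = list(names)
        rng.shuffle(order)
        diff = mgr.difference_sets("D", order)
        expected = {
            e
            for e in universe
            if e in member[order[0]] and not any(e in member[n] for n in order[1:])
        }
        assert diff.member_set() == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_matches_signature_enumeration(self, seed):
        universe, mgr, names, _ = self._random_instance(random.Random(1000 + seed))
        member = {n: mgr.get(n).member_set() for n in names}
        atoms = mgr.partition(names, prefix="atom ")

        expected: dict[frozenset, set] = {}
        for e in universe:
            sig = frozenset(n for n in names if e in member[n])
            if sig:
                expected.setdefault(sig, set()).add(e)
        assert {sig: a.member_set() for sig, a in atoms.items()} == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_algebraic_laws(self, seed):
        _, mgr, names, _ = self._random_instance(random.Random(2000 + seed))
        a, b = names[0], names[1]
        assert (
            mgr.union_sets("Uab", [a, b]).member_set()
            == mgr.union_sets("Uba", [b, a]).member_set()
        )
        assert (
            mgr.intersect_sets("Iab", [a, b]).member_set()
            == mgr.intersect_sets("Iba", [b, a]).member_set()
        )
        inter = mgr.intersect_sets("Iall", names).member_set()
        union = mgr.union_sets("Uall", names).member_set()
        for n in names:
            assert inter <= mgr.get(n).member_set() <= union
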