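"""Named sets over a network and the algebra on them.

A :class:`NamedSet` is a uniquely named, homogeneous (node-only or
edge-only) ordered collection of element identifiers bound to one network.
The :class:`SetManager` is the single authority for name uniqueness and
creation order; every operation that produces a set registers its result as
an ordinary managed set so it can participate in later operations and in
persistence.

Semantics worth calling out:

* Union and intersection are well-defined for any number of inputs;
  **difference is order dependent** — a strict left fold
  ``((S1 \\ S2) \\ S3) ...`` in the given input order.
* ``partition`` groups the union of the inputs by membership signature (the
  exact subset of inputs containing each element), yielding pairwise
  disjoint atoms that cover the union — at most ``2**k - 1`` of them for
  ``k`` inputs.
* Member order is deterministic (first-appearance input order) so exports
  and round trips are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import (
    MixedKindError,
    NameCollisionError,
    UnknownElementError,
    UnknownSetError,
    UnsupportedTypeError,
)
from .graph_model import AttributeTable, Network, ELEMENT_KINDS


@dataclass
class NamedSet:
    """A named, ordered, duplicate-free collection of node or edge ids."""

    name: str
    element_kind: str
    members: list[str]
    network: Network

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("set name must be non-empty")
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"element_kind must be 'node' or 'edge', got {self.element_kind!r}")

    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __contains__(self, element_id: str) -> bool:
        return element_id in set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NamedSet):
            return NotImplemented
        return (
            self.name == other.name
            and self.element_kind == other.element_kind
            and self.members == other.members
        )


def _dedup(members: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for m in members:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out


class SetManager:
    """Registry of named sets bound to one network."""

    def __init__(self, network: Network) -> None:
        self.network = network
        self._sets: dict[str, NamedSet] = {}
        self.creation_order: list[str] = []

    # -- queries ------------------------------------------------------------

    @property
    def sets(self) -> dict[str, NamedSet]:
        return dict(self._sets)

    def names(self) -> list[str]:
        return list(self.creation_order)

    def has_set(self, name: str) -> bool:
        return name in self._sets

    def get(self, name: str) -> NamedSet:
        try:
            return self._sets[name]
        except KeyError:
            raise UnknownSetError(f"unknown set: {name!r}") from None

    def _get_all(self, names: Sequence[str]) -> list[NamedSet]:
        sets = [self.get(n) for n in names]
        kinds = {s.element_kind for s in sets}
        if len(kinds) > 1:
            raise MixedKindError(
                f"sets {list(names)} mix node and edge kinds"
            )
        return sets

    # -- creation / mutation --------------------------------------------------

    def _check_members(self, element_kind: str, members: Iterable[str]) -> None:
        for m in members:
            if not self.network.has_element(element_kind, m):
                raise UnknownElementError(
                    f"unknown {element_kind} {m!r} in network {self.network.name!r}"
                )

    def _register(self, s: NamedSet) -> NamedSet:
        if s.name in self._sets:
            raise NameCollisionError(f"a set named {s.name!r} already exists")
        self._sets[s.name] = s
        self.creation_order.append(s.name)
        return s

    def create_set(
        self, name: str, element_kind: str, members: Iterable[str]
    ) -> NamedSet:
        """Register a new set from an identifier list.

        Duplicates are dropped, first appearance wins; every member must
        exist in the network with the requested kind.
        """
        if name in self._sets:
            raise NameCollisionError(f"a set named {name!r} already exists")
        deduped = _dedup(members)
        self._check_members(element_kind, deduped)
        return self._register(NamedSet(name, element_kind, deduped, self.network))

    def add_to(self, name: str, members: Iterable[str]) -> NamedSet:
        """Append new members; existing members are untouched."""
        s = self.get(name)
        new = _dedup(members)
        self._check_members(s.element_kind, new)
        present = set(s.members)
        s.members.extend(m for m in new if m not in present)
        return s

    def remove_from(self, name: str, members: Iterable[str]) -> NamedSet:
        """Delete the listed members; absent members are silently ignored."""
        s = self.get(name)
        self._check_members(s.element_kind, list(members))
        drop = set(members)
        s.members = [m for m in s.members if m not in drop]
        return s

    def rename_set(self, old: str, new: str) -> NamedSet:
        """Rename, keeping members and the creation-order position."""
        s = self.get(old)
        if new in self._sets:
            raise NameCollisionError(f"a set named {new!r} already exists")
        del self._sets[old]
        s.name = new
        self._sets[new] = s
        self.creation_order[self.creation_order.index(old)] = new
        return s

    def remove_set(self, name: str) -> None:
        self.get(name)
        del self._sets[name]
        self.creation_order.remove(name)

    # -- algebra --------------------------------------------------------------

    def union_sets(self, out_name: str, inputs: Sequence[str]) -> NamedSet:
        """All members of any input, ordered by input order then member order."""
        sets = self._require_operands(out_name, inputs)
        members: list[str] = []
        for s in sets:
            members.extend(s.members)
        return self._register(
            NamedSet(out_name, sets[0].element_kind, _dedup(members), self.network)
        )

    def intersect_sets(self, out_name: str, inputs: Sequence[str]) -> NamedSet:
        """Members present in every input, in first-input order."""
        sets = self._require_operands(out_name, inputs)
        common = set(sets[0].members)
        for s in sets[1:]:
            common &= s.member_set()
        members = [m for m in sets[0].members if m in common]
        return self._register(
            NamedSet(out_name, sets[0].element_kind, members, self.network)
        )

    def difference_sets(self, out_name: str, inputs: Sequence[str]) -> NamedSet:
        """Order-dependent left fold ``((S1 \\ S2) \\ S3) ...``."""
        sets = self._require_operands(out_name, inputs)
        members = list(sets[0].members)
        for s in sets[1:]:
            drop = s.member_set()
            members = [m for m in members if m not in drop]
        return self._register(
            NamedSet(out_name, sets[0].element_kind, members, self.network)
        )

    def _require_operands(self, out_name: str, inputs: Sequence[str]) -> list[NamedSet]:
        if len(inputs) < 2:
            raise ValueError("set operations need at least two input sets")
        if out_name in self._sets:
            raise NameCollisionError(f"a set named {out_name!r} already exists")
        return self._get_all(inputs)

    # -- partition ---------------------------------------------------------------

    def partition(
        self,
        inputs: Sequence[str],
        name_sep: str = ":",
        prefix: str = "",
    ) -> dict[frozenset[str], NamedSet]:
        """Split the union of the inputs into membership-signature atoms.

        Each element of the union is assigned the signature ``{S : e in S}``
        over the input sets; one new set is registered per non-empty
        signature, named ``prefix`` + the included set names joined with
        ``name_sep`` in creation order.  Returns signature → atom.  Atoms
        are pairwise disjoint and cover the union of the inputs; there are
        at most ``2**k - 1`` of them.
        """
        if not inputs:
            raise ValueError("partition needs at least one input set")
        sets = self._get_all(inputs)
        kind = sets[0].element_kind
        order = {n: i for i, n in enumerate(self.creation_order)}

        universe: list[str] = _dedup(m for s in sets for m in s.members)
        member_lookup = {s.name: s.member_set() for s in sets}
        by_signature: dict[frozenset[str], list[str]] = {}
        for element in universe:
            sig = frozenset(n for n in inputs if element in member_lookup[n])
            by_signature.setdefault(sig, []).append(element)

        # validate all names before registering anything, so a collision
        # leaves the manager untouched
        named: list[tuple[frozenset[str], str, list[str]]] = []
        for sig, members in by_signature.items():
            atom_name = prefix + name_sep.join(
                sorted(sig, key=lambda n: order[n])
            )
            if atom_name in self._sets:
                raise NameCollisionError(
                    f"partition atom name {atom_name!r} collides with an existing set"
                )
            named.append((sig, atom_name, members))
        if len({name for _, name, _ in named}) != len(named):
            raise NameCollisionError("partition produced duplicate atom names")

        atoms: dict[frozenset[str], NamedSet] = {}
        for sig, atom_name, members in named:
            atoms[sig] = self._register(NamedSet(atom_name, kind, members, self.network))
        return atoms

    # -- attribute-driven creation -------------------------------------------------

    def create_sets_from_attribute(
        self,
        prefix: str,
        element_kind: str,
        table: AttributeTable,
        column: str,
    ) -> list[NamedSet]:
        """One set per distinct non-null value of a string column.

        Sets are named ``prefix + value`` and contain exactly the elements
        carrying that value, in network order.  Only string columns are
        supported.
        """
        if table.element_class != element_kind:
            raise MixedKindError(
                f"table holds {table.element_class} attributes, not {element_kind}"
            )
        col = table.column(column)
        if col.value_type != "string":
            raise UnsupportedTypeError(
                f"attribute-driven set creation supports string columns only; "
                f"{column!r} is {col.value_type}"
            )
        groups: dict[str, list[str]] = {}
        for element in self.network.elements(element_kind):
            value = col.values.get(element)
            if value is not None:
                groups.setdefault(value, []).append(element)
        names = [prefix + v for v in groups]
        for n in names:
            if n in self._sets:
                raise NameCollisionError(f"a set named {n!r} already exists")
        return [
            self._register(NamedSet(prefix + v, element_kind, members, self.network))
            for v, members in groups.items()
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SetManager):
            return NotImplemented
        return (
            self.creation_order == other.creation_order
            and self._sets == other._sets
        )


# ---------------------------------------------------------------------------
# Threshold selection (headless stand-in for an interactive select panel)

_RELATIONS = {
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
}


def select_by_threshold(
    table: AttributeTable,
    column: str,
    relation: str,
    threshold: float,
) -> list[str]:
    """Identifiers whose numeric attribute satisfies the relation.

    Null values never satisfy any relation; results come back in network
    order.  ``relation`` is one of ``lt``, ``le``, ``gt``, ``ge``.
    """
    if relation not in _RELATIONS:
        raise ValueError(f"relation must be one of {sorted(_RELATIONS)}, got {relation!r}")
    col = table.column(column)
    if col.value_type != "numeric":
        raise UnsupportedTypeError(
            f"threshold selection needs a numeric column; {column!r} is {col.value_type}"
        )
    test = _RELATIONS[relation]
    out = []
    for element in table.element_ids():
        value = col.values.get(element)
        if value is not None and test(value, threshold):
            out.append(element)
    return out
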