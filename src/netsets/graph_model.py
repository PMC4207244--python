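"""Minimal network and attribute-table data model.

Everything downstream (named sets, persistence, layouts, commands) operates
on these two containers:

* :class:`Network` — an undirected graph whose nodes and edges are keyed by
  name strings.  Edge identifiers follow the SIF-derived display convention
  ``"source (interaction) target"``; duplicate records are disambiguated
  with a numeric suffix (`` #2``, `` #3``, …) so construction is
  order-stable and reproducible.
* :class:`AttributeTable` — per element class (node or edge), named typed
  columns keyed by element identifier.  Columns carry one of three value
  types (string / numeric / boolean) and live in a ``public`` or ``hidden``
  namespace; the hidden namespace is where set membership is persisted.

Identifier matching is case-sensitive and exact.  Absent attribute values
are explicit ``None``, never sentinel numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional

import pandas as pd

from .errors import (
    TypedColumnError,
    UnknownColumnError,
    UnknownElementError,
)

NODE = "node"
EDGE = "edge"
ELEMENT_KINDS = (NODE, EDGE)

VALUE_TYPES = ("string", "numeric", "boolean")
NAMESPACES = ("public", "hidden")


class Edge(NamedTuple):
    source: str
    target: str
    interaction: str


class Network:
    """An undirected network with named nodes and labelled edges.

    Node order is first-appearance order and is the canonical element order
    used by selections, restored sets and exports.  Edges keep their
    source/target record order for lossless round-tripping even though the
    graph is treated as undirected.
    """

    def __init__(self, name: str = "network") -> None:
        self.name = name
        self._nodes: list[str] = []
        self._node_index: dict[str, int] = {}
        self._edges: dict[str, Edge] = {}

    # -- nodes ------------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    def has_node(self, node_id: str) -> bool:
        return node_id in self._node_index

    def add_node(self, node_id: str) -> str:
        """Add a node; adding an existing node is a no-op."""
        if node_id not in self._node_index:
            self._node_index[node_id] = len(self._nodes)
            self._nodes.append(node_id)
        return node_id

    def node_order(self, node_id: str) -> int:
        try:
            return self._node_index[node_id]
        except KeyError:
            raise UnknownElementError(f"unknown node: {node_id!r}") from None

    # -- edges ------------------------------------------------------------

    @property
    def edges(self) -> dict[str, Edge]:
        return dict(self._edges)

    @property
    def edge_ids(self) -> tuple[str, ...]:
        return tuple(self._edges)

    def has_edge(self, edge_id: str) -> bool:
        return edge_id in self._edges

    def add_edge(self, source: str, interaction: str, target: str) -> str:
        """Add one edge record, creating endpoints as needed.

        Returns the assigned edge identifier.  A record identical to an
        existing one gets the next free numeric suffix.
        """
        self.add_node(source)
        self.add_node(target)
        base = f"{source} ({interaction}) {target}"
        edge_id = base
        n = 2
        while edge_id in self._edges:
            edge_id = f"{base} #{n}"
            n += 1
        self._edges[edge_id] = Edge(source, target, interaction)
        return edge_id

    def elements(self, kind: str) -> tuple[str, ...]:
        if kind == NODE:
            return self.nodes
        if kind == EDGE:
            return self.edge_ids
        raise ValueError(f"element kind must be 'node' or 'edge', got {kind!r}")

    def has_element(self, kind: str, element_id: str) -> bool:
        return self.has_node(element_id) if kind == NODE else self.has_edge(element_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            self.name == other.name
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return (
            f"<Network {self.name!r}: {len(self._nodes)} nodes, "
            f"{len(self._edges)} edges>"
        )


def build_network(
    name: str, edge_records: Iterable[tuple[str, str, str]]
) -> Network:
    """Build a network from ``(source, interaction, target)`` records.

    Nodes appear in first-appearance order of the endpoints; every record
    becomes one edge (duplicates get suffixed identifiers).  Isolated nodes
    can be added afterwards with :meth:`Network.add_node`.
    """
    net = Network(name)
    for source, interaction, target in edge_records:
        net.add_edge(source, interaction, target)
    return net


# ---------------------------------------------------------------------------
# Attribute tables


def _conforms(value: object, value_type: str) -> bool:
    if value is None:
        return True
    if value_type == "string":
        return isinstance(value, str)
    if value_type == "boolean":
        return isinstance(value, bool)
    if value_type == "numeric":
        # bool is an int subclass; reject it so types stay unambiguous
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    raise ValueError(f"unknown value type {value_type!r}")


@dataclass
class Column:
    name: str
    value_type: str
    namespace: str
    values: dict[str, object] = field(default_factory=dict)


class AttributeTable:
    """Typed, namespaced columns over one element class of a network."""

    def __init__(self, network: Network, element_class: str) -> None:
        if element_class not in ELEMENT_KINDS:
            raise ValueError(f"element_class must be 'node' or 'edge', got {element_class!r}")
        self.network = network
        self.element_class = element_class
        self._columns: dict[tuple[str, str], Column] = {}

    def element_ids(self) -> tuple[str, ...]:
        return self.network.elements(self.element_class)

    # -- column API --------------------------------------------------------

    def set_column(
        self,
        name: str,
        value_type: str,
        values: Mapping[str, object],
        namespace: str = "public",
    ) -> Column:
        """Create or fully replace a column.

        Every key must be an element of the bound network; every value must
        conform to ``value_type``.  Elements without a key read back as
        ``None``.
        """
        if value_type not in VALUE_TYPES:
            raise ValueError(f"value_type must be one of {VALUE_TYPES}, got {value_type!r}")
        if namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {NAMESPACES}, got {namespace!r}")
        for key, value in values.items():
            if not self.network.has_element(self.element_class, key):
                raise UnknownElementError(
                    f"unknown {self.element_class} {key!r} in column {name!r}"
                )
            if not _conforms(value, value_type):
                raise TypedColumnError(
                    f"column {name!r} is {value_type}; value {value!r} for "
                    f"{key!r} does not conform"
                )
        col = Column(name, value_type, namespace, dict(values))
        self._columns[(namespace, name)] = col
        return col

    def has_column(self, name: str, namespace: str = "public") -> bool:
        return (namespace, name) in self._columns

    def column(self, name: str, namespace: str = "public") -> Column:
        try:
            return self._columns[(namespace, name)]
        except KeyError:
            raise UnknownColumnError(
                f"no {namespace} {self.element_class} column {name!r}"
            ) from None

    def drop_column(self, name: str, namespace: str = "public") -> None:
        self._columns.pop((namespace, name), None)

    def columns(self, namespace: Optional[str] = None) -> Iterator[Column]:
        for (ns, _), col in self._columns.items():
            if namespace is None or ns == namespace:
                yield col

    def value(self, column: str, element_id: str, namespace: str = "public") -> object:
        return self.column(column, namespace).values.get(element_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AttributeTable):
            return NotImplemented
        return (
            self.element_class == other.element_class
            and self._columns == other._columns
        )


def set_column(
    table: AttributeTable,
    column: str,
    value_type: str,
    namespace: str,
    values: Mapping[str, object],
) -> AttributeTable:
    """Functional wrapper over :meth:`AttributeTable.set_column`."""
    table.set_column(column, value_type, values, namespace=namespace)
    return table


@dataclass
class Tables:
    """The pair of attribute tables bound to one network, plus network-level
    metadata (used by persistence to keep set creation order)."""

    node: AttributeTable
    edge: AttributeTable
    meta: dict[str, object] = field(default_factory=dict)

    @classmethod
    def for_network(cls, network: Network) -> "Tables":
        return cls(AttributeTable(network, NODE), AttributeTable(network, EDGE))

    def for_kind(self, kind: str) -> AttributeTable:
        if kind == NODE:
            return self.node
        if kind == EDGE:
            return self.edge
        raise ValueError(f"element kind must be 'node' or 'edge', got {kind!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Tables):
            return NotImplemented
        return (
            self.node == other.node
            and self.edge == other.edge
            and self.meta == other.meta
        )


# ---------------------------------------------------------------------------
# Readers: SIF networks and TSV attribute tables


def read_sif(path, name: Optional[str] = None) -> Network:
    """Read a Simple Interaction Format file.

    Lines are ``source interaction target [target ...]``; a line containing
    a tab is split on tabs (the SIF convention for names with spaces),
    otherwise on whitespace.  Multi-target lines expand to one edge per
    target.  A single-token line declares an isolated node.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    net = Network(name if name is not None else str(path))
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split("\t")] if "\t" in raw else line.split()
        fields = [f for f in fields if f]
        if len(fields) == 1:
            net.add_node(fields[0])
        elif len(fields) >= 3:
            source, interaction = fields[0], fields[1]
            for target in fields[2:]:
                net.add_edge(source, interaction, target)
        else:
            raise ValueError(f"malformed SIF line: {raw!r}")
    return net


def write_sif(network: Network, path) -> None:
    """Write edges as three-column tab-separated SIF plus isolated nodes."""
    touched: set[str] = set()
    lines = []
    for edge in network.edges.values():
        lines.append(f"{edge.source}\t{edge.interaction}\t{edge.target}")
        touched.add(edge.source)
        touched.add(edge.target)
    for node in network.nodes:
        if node not in touched:
            lines.append(node)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in lines:
            fh.write(line + "\n")


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_attributes_tsv(
    network: Network, element_class: str, path, namespace: str = "public"
) -> AttributeTable:
    """Read a TSV attribute table keyed on its first column.

    The header row names the columns.  A column whose non-null values all
    parse as numbers is loaded as numeric, one whose values are all
    ``true``/``false`` as boolean, anything else as string.  Empty cells are
    nulls.  Every identifier must exist in the network.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = AttributeTable(network, element_class)
    if df.shape[1] < 1:
        return table
    ids = df.iloc[:, 0].tolist()
    for col_name in df.columns[1:]:
        raw = df[col_name].tolist()
        cells = [(i, c) for i, c in zip(ids, raw) if c != ""]
        non_null = [c for _, c in cells]
        if non_null and all(_NUMERIC_RE.match(c) for c in non_null):
            values = {i: float(c) for i, c in cells}
            vtype = "numeric"
        elif non_null and all(c in ("true", "false") for c in non_null):
            values = {i: c == "true" for i, c in cells}
            vtype = "boolean"
        else:
            values = {i: c for i, c in cells}
            vtype = "string"
        table.set_column(col_name, vtype, values, namespace=namespace)
    return table
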