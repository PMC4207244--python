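"""Seeded synthetic data emulating a yeast galactose-pathway workflow.

Generates a small connected protein-interaction-style network whose node
table carries numeric fold-change columns for several deletion conditions
(default ``gal1RGexp``, ``gal4RGexp``, ``gal80Rexp``) plus companion
significance columns (``gal1RGsig``, …).  A planted subset of nodes is
co-under-expressed across all conditions and another co-over-expressed:

* planted under-expressed nodes draw from Uniform(−2.0, −0.6),
* planted over-expressed nodes from Uniform(0.6, 2.0),
* background nodes from Uniform(−0.45, 0.45).

The deliberate gap around ±0.5 makes threshold selection at the
fold-change cutoff of ±0.5 sharp: selecting ``< −0.5`` per condition and
intersecting recovers the planted under-expressed list exactly (and
likewise ``> 0.5`` for the over-expressed list), for every seed.  By
default one node is planted down and five up, matching the intersection
sizes the exploratory workflow is meant to surface.

Topology is a random spanning tree plus extra random edges, so the network
is always connected (which the layout tests rely on).  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError
from .graph_model import Network, Tables, build_network
from .sets_core import SetManager, select_by_threshold

DEFAULT_CONDITIONS = ("gal1RGexp", "gal4RGexp", "gal80Rexp")

BACKGROUND_RANGE = (-0.45, 0.45)
DOWN_RANGE = (-2.0, -0.6)
UP_RANGE = (0.6, 2.0)

_COMPARTMENTS = ("nucleus", "cytoplasm", "membrane", "mitochondrion")


def node_ids(n_nodes: int) -> list[str]:
    """Deterministic ORF-style node names for a generated network."""
    return [f"YSN{i:03d}W" for i in range(n_nodes)]


def sig_column_name(condition: str) -> str:
    """Companion significance column: trailing 'exp' becomes 'sig'."""
    if condition.endswith("exp"):
        return condition[:-3] + "sig"
    return condition + "_sig"


def condition_label(condition: str) -> str:
    """Short condition tag: leading letters+digits run, upper-cased.

    ``gal1RGexp`` → ``GAL1``, ``gal80Rexp`` → ``GAL80``.
    """
    m = re.match(r"^([A-Za-z]+\d+)", condition)
    return (m.group(1) if m else condition).upper()


def generate_gal_like(
    n_nodes: int = 60,
    n_edges: int = 90,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    planted_down: Optional[Sequence[str]] = None,
    planted_up: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> tuple[Network, Tables]:
    """Generate the synthetic network and its attribute tables.

    ``planted_down`` / ``planted_up`` are node-id lists (subsets of
    :func:`node_ids`); ``None`` plants 1 under- and 5 over-expressed nodes
    chosen by the seed.  The lists must be disjoint.
    """
    if n_nodes < 20:
        raise ParameterError(f"n_nodes must be >= 20, got {n_nodes}")
    ids = node_ids(n_nodes)
    rng = np.random.default_rng(seed)

    if planted_down is None or planted_up is None:
        picks = rng.choice(n_nodes, size=6, replace=False)
        if planted_down is None:
            planted_down = [ids[int(picks[0])]]
        if planted_up is None:
            planted_up = [ids[int(i)] for i in picks[1:6]]
    planted_down = list(planted_down)
    planted_up = list(planted_up)
    if set(planted_down) & set(planted_up):
        raise ParameterError("planted_down and planted_up must be disjoint")
    for node in planted_down + planted_up:
        if node not in set(ids):
            raise ParameterError(f"planted node {node!r} is not a generated node id")

    # random spanning tree: attach node i to a uniformly chosen earlier node
    records: list[tuple[str, str, str]] = []
    present: set[tuple[str, str]] = set()
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        records.append((ids[j], "pp", ids[i]))
        present.add((ids[j], ids[i]))
        present.add((ids[i], ids[j]))
    extra = max(0, n_edges - (n_nodes - 1))
    attempts = 0
    while extra > 0 and attempts < 50 * n_edges:
        a, b = (int(x) for x in rng.integers(0, n_nodes, size=2))
        attempts += 1
        if a == b or (ids[a], ids[b]) in present:
            continue
        records.append((ids[a], "pp", ids[b]))
        present.add((ids[a], ids[b]))
        present.add((ids[b], ids[a]))
        extra -= 1

    network = build_network("gal-like", records)
    tables = Tables.for_network(network)

    down, up = set(planted_down), set(planted_up)
    for condition in conditions:
        values: dict[str, float] = {}
        sig: dict[str, float] = {}
        for node in ids:
            if node in down:
                values[node] = float(rng.uniform(*DOWN_RANGE))
                sig[node] = float(rng.uniform(1e-6, 1e-3))
            elif node in up:
                values[node] = float(rng.uniform(*UP_RANGE))
                sig[node] = float(rng.uniform(1e-6, 1e-3))
            else:
                values[node] = float(rng.uniform(*BACKGROUND_RANGE))
                sig[node] = float(rng.uniform(0.05, 1.0))
        tables.node.set_column(condition, "numeric", values)
        tables.node.set_column(sig_column_name(condition), "numeric", sig)

    compartments = {
        node: _COMPARTMENTS[int(rng.integers(0, len(_COMPARTMENTS)))] for node in ids
    }
    tables.node.set_column("compartment", "string", compartments)
    return network, tables


def write_fixture(network: Network, tables: Tables, directory) -> tuple[str, str]:
    """Write the SIF network and the node attribute TSV into a directory."""
    import os

    from .graph_model import write_sif

    os.makedirs(directory, exist_ok=True)
    sif_path = os.path.join(directory, "network.sif")
    tsv_path = os.path.join(directory, "node_attrs.tsv")
    write_sif(network, sif_path)

    cols = list(tables.node.columns(namespace="public"))
    with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["name"] + [c.name for c in cols]) + "\n")
        for node in network.nodes:
            cells = [node]
            for c in cols:
                v = c.values.get(node)
                cells.append("" if v is None else (repr(v) if c.value_type == "numeric" else str(v)))
            fh.write("\t".join(cells) + "\n")
    return sif_path, tsv_path


def run_expression_workflow(
    network: Network,
    tables: Tables,
    mgr: Optional[SetManager] = None,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    threshold: float = 0.5,
    up_suffix: str = "+",
    down_suffix: str = "-",
) -> tuple[SetManager, "NamedSetPair"]:
    """The exploratory set workflow on expression columns.

    For every condition, select nodes under the negative threshold and
    above the positive one, save each selection as a named set
    (``<LABEL>-`` / ``<LABEL>+``), then intersect all under-expressed sets
    into ``<common>-`` and all over-expressed sets into ``<common>+``.
    Returns the manager and the pair of intersection sets.
    """
    mgr = mgr or SetManager(network)
    minus_names, plus_names = [], []
    for condition in conditions:
        label = condition_label(condition)
        under = select_by_threshold(tables.node, condition, "lt", -threshold)
        over = select_by_threshold(tables.node, condition, "gt", threshold)
        mgr.create_set(label + down_suffix, "node", under)
        mgr.create_set(label + up_suffix, "node", over)
        minus_names.append(label + down_suffix)
        plus_names.append(label + up_suffix)

    common = _common_prefix([condition_label(c) for c in conditions]) or "ALL"
    down_set = mgr.intersect_sets(common + down_suffix, minus_names)
    up_set = mgr.intersect_sets(common + up_suffix, plus_names)
    return mgr, NamedSetPair(down_set, up_set)


class NamedSetPair(tuple):
    """(under-expressed intersection, over-expressed intersection)."""

    def __new__(cls, down, up):
        return super().__new__(cls, (down, up))

    @property
    def down(self):
        return self[0]

    @property
    def up(self):
        return self[1]


def _common_prefix(labels: Sequence[str]) -> str:
    if not labels:
        return ""
    prefix = labels[0]
    for label in labels[1:]:
        while not label.startswith(prefix):
            prefix = prefix[:-1]
            if not prefix:
                return ""
    return prefix.rstrip("0123456789")
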