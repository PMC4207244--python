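"""Set persistence: hidden boolean columns and session bundles.

Membership is serialized the way a network-analysis session table would
carry it: each set becomes a boolean column in the *hidden* attribute table
of its element class, true for members and explicit false for non-members
(so empty sets restore unambiguously).  Set columns live under the
dedicated namespace prefix ``setsApp::`` so a restore never resurrects
unrelated boolean columns, and creation order is kept as network-level
metadata so difference folds and partition atom names stay deterministic
across a reload.

A session is a single-file zip bundle: ``network.sif``, public and hidden
attribute TSVs, and a JSON manifest (format version, network name, node
order, sets with member order, selection).  String cells in the TSVs are
JSON-quoted so nulls, empty strings and embedded tabs round-trip exactly.
"""

from __future__ import annotations

import io
import json
import zipfile
from typing import Optional

from .errors import ColumnCollisionError, SessionFormatError
from .graph_model import (
    AttributeTable,
    Network,
    Tables,
    NODE,
    EDGE,
)
from .sets_core import SetManager

SET_COLUMN_PREFIX = "setsApp::"
CREATION_ORDER_KEY = "setsApp::creation_order"
FORMAT_VERSION = 1


def _column_name(set_name: str) -> str:
    return SET_COLUMN_PREFIX + set_name


def sync_to_table(mgr: SetManager, tables: Tables) -> Tables:
    """Write every set as a hidden boolean column; drop stale set columns.

    Idempotent: syncing twice leaves the tables identical.  A hidden column
    in the set namespace that is not boolean (so not ours) triggers a
    collision error rather than being overwritten.
    """
    wanted: dict[str, set[str]] = {NODE: set(), EDGE: set()}
    for name in mgr.creation_order:
        s = mgr.get(name)
        col_name = _column_name(name)
        table = tables.for_kind(s.element_kind)
        if table.has_column(col_name, namespace="hidden"):
            existing = table.column(col_name, namespace="hidden")
            if existing.value_type != "boolean":
                raise ColumnCollisionError(
                    f"hidden column {col_name!r} exists with type "
                    f"{existing.value_type!r} and cannot hold set membership"
                )
        members = s.member_set()
        values = {e: (e in members) for e in table.element_ids()}
        table.set_column(col_name, "boolean", values, namespace="hidden")
        wanted[s.element_kind].add(col_name)

    for kind in (NODE, EDGE):
        table = tables.for_kind(kind)
        stale = [
            col.name
            for col in table.columns(namespace="hidden")
            if col.name.startswith(SET_COLUMN_PREFIX) and col.name not in wanted[kind]
        ]
        for name in stale:
            table.drop_column(name, namespace="hidden")

    tables.meta[CREATION_ORDER_KEY] = list(mgr.creation_order)
    return tables


def restore_from_table(network: Network, tables: Tables) -> SetManager:
    """Rebuild a manager from hidden set columns.

    One set per hidden boolean column in the set namespace; members are the
    elements whose value is true, in network order.  Creation order comes
    from the persisted metadata when present, otherwise column order.
    Tables without set columns yield an empty manager.
    """
    mgr = SetManager(network)
    found: dict[str, tuple[str, list[str]]] = {}
    for kind in (NODE, EDGE):
        table = tables.for_kind(kind)
        for col in table.columns(namespace="hidden"):
            if not col.name.startswith(SET_COLUMN_PREFIX) or col.value_type != "boolean":
                continue
            set_name = col.name[len(SET_COLUMN_PREFIX):]
            members = [e for e in table.element_ids() if col.values.get(e) is True]
            found[set_name] = (kind, members)

    persisted_order = tables.meta.get(CREATION_ORDER_KEY, [])
    order = [n for n in persisted_order if n in found]
    order += [n for n in found if n not in set(order)]
    for name in order:
        kind, members = found[name]
        mgr.create_set(name, kind, members)
    return mgr


# ---------------------------------------------------------------------------
# Session bundles


def _encode_cell(value: object, value_type: str) -> str:
    if value is None:
        return ""
    if value_type == "boolean":
        return "true" if value else "false"
    if value_type == "numeric":
        return repr(float(value))
    return json.dumps(value)  # string: JSON-quoted, lossless


def _decode_cell(cell: str, value_type: str) -> object:
    if cell == "":
        return None
    if value_type == "boolean":
        return cell == "true"
    if value_type == "numeric":
        return float(cell)
    return json.loads(cell)


def _table_to_tsv(table: AttributeTable, namespace: str) -> tuple[str, list[dict]]:
    cols = list(table.columns(namespace=namespace))
    meta = [{"name": c.name, "value_type": c.value_type} for c in cols]
    buf = io.StringIO()
    buf.write("\t".join(["id"] + [c.name for c in cols]) + "\n")
    for element in table.element_ids():
        row = [json.dumps(element)]
        for c in cols:
            row.append(_encode_cell(c.values.get(element), c.value_type))
        buf.write("\t".join(row) + "\n")
    return buf.getvalue(), meta


def _table_from_tsv(
    table: AttributeTable, namespace: str, text: str, meta: list[dict]
) -> None:
    lines = text.splitlines()
    if not lines:
        return
    col_meta = {m["name"]: m["value_type"] for m in meta}
    header = lines[0].split("\t")[1:]
    values: dict[str, dict[str, object]] = {name: {} for name in header}
    for line in lines[1:]:
        cells = line.split("\t")
        element = json.loads(cells[0])
        for name, cell in zip(header, cells[1:]):
            decoded = _decode_cell(cell, col_meta[name])
            if decoded is not None:
                values[name][element] = decoded
    for name in header:
        table.set_column(name, col_meta[name], values[name], namespace=namespace)


_MEMBERS = {
    ("node", "public"): "node_attrs.tsv",
    ("node", "hidden"): "hidden_node_attrs.tsv",
    ("edge", "public"): "edge_attrs.tsv",
    ("edge", "hidden"): "hidden_edge_attrs.tsv",
}


def save_session(
    network: Network,
    tables: Tables,
    mgr: SetManager,
    path,
    selection: Optional[dict] = None,
) -> None:
    """Write the network, attribute tables and sets as one zip bundle.

    Membership columns are synced to the hidden tables first, so the bundle
    is self-describing even for readers that only look at the tables.
    """
    sync_to_table(mgr, tables)
    manifest = {
        "format_version": FORMAT_VERSION,
        "network_name": network.name,
        "node_order": list(network.nodes),
        "edges": [
            [eid, e.source, e.interaction, e.target]
            for eid, e in network.edges.items()
        ],
        "creation_order": list(mgr.creation_order),
        "sets": [
            {
                "name": s.name,
                "element_kind": s.element_kind,
                "members": list(s.members),
            }
            for s in (mgr.get(n) for n in mgr.creation_order)
        ],
        "selection": selection or {"nodes": [], "edges": []},
        "columns": {},
    }

    sif_buf = io.StringIO()
    touched: set[str] = set()
    for e in network.edges.values():
        sif_buf.write(f"{e.source}\t{e.interaction}\t{e.target}\n")
        touched.update((e.source, e.target))
    for n in network.nodes:
        if n not in touched:
            sif_buf.write(n + "\n")

    tsv_payload: dict[str, str] = {}
    for (kind, namespace), member in _MEMBERS.items():
        text, meta = _table_to_tsv(tables.for_kind(kind), namespace)
        tsv_payload[member] = text
        manifest["columns"][member] = meta

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("network.sif", sif_buf.getvalue())
        for member, text in tsv_payload.items():
            zf.writestr(member, text)
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))


def load_session(path) -> tuple[Network, Tables, SetManager, dict]:
    """Load a session bundle; exact inverse of :func:`save_session`.

    Returns ``(network, tables, manager, selection)``.  A truncated or
    malformed file raises :class:`SessionFormatError`.
    """
    try:
        with zipfile.ZipFile(path, "r") as zf:
            manifest = json.loads(zf.read("manifest.json").decode("utf-8"))
            if manifest.get("format_version") != FORMAT_VERSION:
                raise SessionFormatError(
                    f"unsupported session format version: {manifest.get('format_version')!r}"
                )
            network = Network(manifest["network_name"])
            for node in manifest["node_order"]:
                network.add_node(node)
            for eid, source, interaction, target in manifest["edges"]:
                assigned = network.add_edge(source, interaction, target)
                if assigned != eid:
                    raise SessionFormatError(
                        f"edge identifier mismatch: expected {eid!r}, got {assigned!r}"
                    )
            tables = Tables.for_network(network)
            for (kind, namespace), member in _MEMBERS.items():
                _table_from_tsv(
                    tables.for_kind(kind),
                    namespace,
                    zf.read(member).decode("utf-8"),
                    manifest["columns"][member],
                )
            tables.meta[CREATION_ORDER_KEY] = list(manifest["creation_order"])
            mgr = SetManager(network)
            for rec in manifest["sets"]:
                mgr.create_set(rec["name"], rec["element_kind"], rec["members"])
            selection = manifest.get("selection", {"nodes": [], "edges": []})
            return network, tables, mgr, selection
    except SessionFormatError:
        raise
    except (zipfile.BadZipFile, KeyError, ValueError, json.JSONDecodeError, OSError) as exc:
        raise SessionFormatError(f"unreadable session bundle {path!r}: {exc}") from exc
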