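"""Command-style scripting interface.

A name-for-name dispatcher for the ten set commands — ``addTo``,
``createSet``, ``difference``, ``export``, ``import``, ``intersect``,
``remove``, ``removeFrom``, ``rename``, ``union`` — with their published
argument names accepted verbatim (``nodeList``, ``edgeList``, ``network``,
``name``, ``set1``, ``set2``, ``newName``, ``oldName``, ``setFile``,
``Column``, ``Type``).  Two keywords are honoured: ``selected`` as a
node/edge list resolves to the session's current selection, and
``current`` as a network resolves to the active network.

The :class:`Session` is the headless stand-in for an interactive
workspace: it holds the loaded networks, their attribute tables and set
managers, and the selection state that ``selected`` refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import set_io
from .errors import (
    DomainError,
    MissingArgumentError,
    MixedKindError,
    UnknownCommandError,
)
from .graph_model import Network, Tables
from .sets_core import SetManager, select_by_threshold


@dataclass
class NetworkBundle:
    network: Network
    tables: Tables
    mgr: SetManager

    @classmethod
    def for_network(cls, network: Network) -> "NetworkBundle":
        return cls(network, Tables.for_network(network), SetManager(network))


@dataclass
class Session:
    """Loaded networks plus the selection state backing ``selected``."""

    networks: dict[str, NetworkBundle] = field(default_factory=dict)
    current: Optional[str] = None
    selected_nodes: list[str] = field(default_factory=list)
    selected_edges: list[str] = field(default_factory=list)

    def add_network(self, bundle: NetworkBundle, make_current: bool = True) -> None:
        self.networks[bundle.network.name] = bundle
        if make_current or self.current is None:
            self.current = bundle.network.name

    def resolve_network(self, name: Optional[str]) -> NetworkBundle:
        if name in (None, "", "current"):
            if self.current is not None:
                return self.networks[self.current]
            if len(self.networks) == 1:
                return next(iter(self.networks.values()))
            raise DomainError(
                "no current network: load one or name it with network="
            )
        try:
            return self.networks[name]
        except KeyError:
            raise DomainError(f"unknown network: {name!r}") from None

    def select_nodes(self, node_ids: list[str]) -> None:
        self.selected_nodes = list(node_ids)

    def select_edges(self, edge_ids: list[str]) -> None:
        self.selected_edges = list(edge_ids)


@dataclass
class CommandResult:
    """Outcome record plus a human-readable message."""

    data: dict
    message: str


def _require(args: dict[str, str], *names: str) -> list[str]:
    values = []
    for name in names:
        if name not in args or args[name] == "":
            raise MissingArgumentError(f"missing required argument: {name}")
        values.append(args[name])
    return values


def _parse_list(value: str, session: Session, kind: str) -> list[str]:
    if value == "selected":
        return list(session.selected_nodes if kind == "node" else session.selected_edges)
    return [item.strip() for item in value.split(",") if item.strip()]


def _member_args(session: Session, args: dict[str, str]) -> tuple[str, list[str]]:
    """Resolve the mutually exclusive nodeList/edgeList pair."""
    has_nodes = "nodeList" in args
    has_edges = "edgeList" in args
    if has_nodes and has_edges:
        raise MixedKindError("both nodeList and edgeList provided")
    if not has_nodes and not has_edges:
        raise MissingArgumentError("missing required argument: nodeList or edgeList")
    if has_nodes:
        return "node", _parse_list(args["nodeList"], session, "node")
    return "edge", _parse_list(args["edgeList"], session, "edge")


def _cmd_create_set(session: Session, args: dict[str, str]) -> CommandResult:
    (name,) = _require(args, "name")
    kind, members = _member_args(session, args)
    bundle = session.resolve_network(args.get("network"))
    s = bundle.mgr.create_set(name, kind, members)
    return CommandResult(
        {"set": s.name, "count": len(s)},
        f"created {kind} set {s.name!r} with {len(s)} members",
    )


def _cmd_add_to(session: Session, args: dict[str, str]) -> CommandResult:
    (name,) = _require(args, "name")
    kind, members = _member_args(session, args)
    bundle = session.resolve_network(args.get("network"))
    s = bundle.mgr.get(name)
    if s.element_kind != kind:
        raise MixedKindError(
            f"set {name!r} holds {s.element_kind}s but a {kind} list was given"
        )
    s = bundle.mgr.add_to(name, members)
    return CommandResult(
        {"set": s.name, "count": len(s)},
        f"set {s.name!r} now has {len(s)} members",
    )


def _cmd_remove_from(session: Session, args: dict[str, str]) -> CommandResult:
    (name,) = _require(args, "name")
    kind, members = _member_args(session, args)
    bundle = session.resolve_network(args.get("network"))
    s = bundle.mgr.get(name)
    if s.element_kind != kind:
        raise MixedKindError(
            f"set {name!r} holds {s.element_kind}s but a {kind} list was given"
        )
    s = bundle.mgr.remove_from(name, members)
    return CommandResult(
        {"set": s.name, "count": len(s)},
        f"set {s.name!r} now has {len(s)} members",
    )


def _binary_op(op_name: str):
    def run(session: Session, args: dict[str, str]) -> CommandResult:
        name, set1, set2 = _require(args, "name", "set1", "set2")
        bundle = session.resolve_network(args.get("network"))
        op = getattr(bundle.mgr, op_name)
        s = op(name, [set1, set2])
        return CommandResult(
            {"set": s.name, "count": len(s)},
            f"created set {s.name!r} with {len(s)} members",
        )

    return run


def _cmd_rename(session: Session, args: dict[str, str]) -> CommandResult:
    old, new = _require(args, "oldName", "newName")
    bundle = session.resolve_network(args.get("network"))
    s = bundle.mgr.rename_set(old, new)
    return CommandResult({"set": s.name}, f"renamed {old!r} to {new!r}")


def _cmd_remove(session: Session, args: dict[str, str]) -> CommandResult:
    (name,) = _require(args, "name")
    bundle = session.resolve_network(args.get("network"))
    bundle.mgr.remove_set(name)
    return CommandResult({"set": name}, f"removed set {name!r}")


def _cmd_export(session: Session, args: dict[str, str]) -> CommandResult:
    name, set_file = _require(args, "name", "setFile")
    bundle = session.resolve_network(args.get("network"))
    column = args.get("Column")
    set_io.export_set(bundle.mgr, bundle.tables, name, set_file, id_column=column)
    count = len(bundle.mgr.get(name))
    return CommandResult(
        {"set": name, "file": set_file, "count": count},
        f"exported {count} members of {name!r} to {set_file}",
    )


def _cmd_import(session: Session, args: dict[str, str]) -> CommandResult:
    name, set_file, kind_arg = _require(args, "name", "setFile", "Type")
    if kind_arg not in ("Node", "Edge"):
        raise MissingArgumentError(f"Type must be Node or Edge, got {kind_arg!r}")
    bundle = session.resolve_network(args.get("network"))
    column = args.get("Column")
    s, report = set_io.import_set(
        bundle.mgr, bundle.tables, name, kind_arg.lower(), set_file, id_column=column
    )
    return CommandResult(
        {
            "set": s.name,
            "count": len(s),
            "unmatched": list(report.unmatched),
            "ambiguous": list(report.ambiguous),
        },
        f"imported set {s.name!r} ({report.summary()})",
    )


_HANDLERS = {
    "addTo": _cmd_add_to,
    "createSet": _cmd_create_set,
    "difference": _binary_op("difference_sets"),
    "export": _cmd_export,
    "import": _cmd_import,
    "intersect": _binary_op("intersect_sets"),
    "remove": _cmd_remove,
    "removeFrom": _cmd_remove_from,
    "rename": _cmd_rename,
    "union": _binary_op("union_sets"),
}

COMMANDS = tuple(sorted(_HANDLERS))


def dispatch(session: Session, command: str, args: dict[str, str]) -> CommandResult:
    """Run one named command against the session.

    Raises :class:`UnknownCommandError` / :class:`MissingArgumentError` for
    malformed invocations; domain errors from the underlying operations
    propagate with their messages.
    """
    try:
        handler = _HANDLERS[command]
    except KeyError:
        raise UnknownCommandError(
            f"unknown command {command!r}; expected one of {', '.join(COMMANDS)}"
        ) from None
    return handler(session, args)


def select_threshold(
    session: Session,
    column: str,
    relation: str,
    threshold: float,
    element_kind: str = "node",
    network: Optional[str] = None,
) -> list[str]:
    """Threshold selection populating the session's ``selected`` state."""
    bundle = session.resolve_network(network)
    table = bundle.tables.for_kind(element_kind)
    hits = select_by_threshold(table, column, relation, threshold)
    if element_kind == "node":
        session.select_nodes(hits)
    else:
        session.select_edges(hits)
    return hits
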