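"""Plain-text set import and export.

The file dialect is one identifier per line: lines starting with ``#`` are
comments, surrounding whitespace is stripped, blank lines are skipped, CRLF
and LF are both accepted, and output uses LF with a trailing newline.

Identifiers are matched against a chosen *id column* of the attribute
table; by default the element identifier itself is the key.  Import is
auditable: the returned report lists lines that matched nothing and lines
that matched more than one element (all matches are included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import EmptyImportError, ExportError
from .graph_model import Tables
from .sets_core import NamedSet, SetManager


@dataclass
class ImportReport:
    """What happened to each line of an imported set file."""

    n_lines: int = 0
    n_matched: int = 0
    unmatched: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.n_matched}/{self.n_lines} lines matched; "
            f"{len(self.unmatched)} unmatched, {len(self.ambiguous)} ambiguous"
        )


def _id_values(tables: Tables, element_kind: str, id_column: Optional[str]):
    """Yield (element, key value) pairs for the chosen id column."""
    table = tables.for_kind(element_kind)
    if id_column is None or id_column == "name":
        for element in table.element_ids():
            yield element, element
    else:
        col = table.column(id_column)
        for element in table.element_ids():
            yield element, col.values.get(element)


def export_set(
    mgr: SetManager,
    tables: Tables,
    name: str,
    path,
    id_column: Optional[str] = None,
) -> None:
    """Write one line per member, in member order.

    ``id_column`` selects which attribute identifies each member; the
    default (or ``"name"``) is the element identifier itself.  A member
    whose id value is null aborts the export with an error naming it.
    """
    s = mgr.get(name)
    keys = dict(_id_values(tables, s.element_kind, id_column))
    lines = []
    for member in s.members:
        value = keys.get(member)
        if value is None:
            raise ExportError(
                f"member {member!r} of set {name!r} has no value in id column "
                f"{id_column or 'name'!r}"
            )
        lines.append(str(value))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in lines:
            fh.write(line + "\n")


def import_set(
    mgr: SetManager,
    tables: Tables,
    name: str,
    element_kind: str,
    path,
    id_column: Optional[str] = None,
) -> tuple[NamedSet, ImportReport]:
    """Create a set from an identifier file.

    Each payload line is matched exactly against the id-column values; the
    matched elements form the new set in file order (all matches of an
    ambiguous line are kept).  If no line matches anything, no set is
    created and an :class:`EmptyImportError` is raised.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw_lines = fh.read().splitlines()

    # match on the string form, the same rendering export writes
    lookup: dict[str, list[str]] = {}
    for element, value in _id_values(tables, element_kind, id_column):
        if value is not None:
            lookup.setdefault(str(value), []).append(element)

    report = ImportReport()
    members: list[str] = []
    for raw in raw_lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        report.n_lines += 1
        matches = lookup.get(line, [])
        if not matches:
            report.unmatched.append(line)
            continue
        if len(matches) > 1:
            report.ambiguous.append(line)
        report.n_matched += 1
        members.extend(matches)

    if report.n_matched == 0:
        raise EmptyImportError(
            f"no line of {path!r} matched any {element_kind} via column "
            f"{id_column or 'name'!r}"
        )
    return mgr.create_set(name, element_kind, members), report
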