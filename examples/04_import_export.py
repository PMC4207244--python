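"""Export a set to a plain-text file and import it back.

The file dialect is one identifier per line ("#" comments, blank lines
skipped).  Import matches lines against a chosen id column and reports
unmatched and ambiguous lines instead of failing silently.
"""

import tempfile
from pathlib import Path

from netsets import SetManager, Tables, build_network, export_set, import_set

net = build_network("toy", [(f"n{i}", "pp", f"n{i+1}") for i in range(5)])
tables = Tables.for_network(net)
tables.node.set_column(
    "symbol", "string", {"n0": "GAL1", "n1": "GAL4", "n2": "GAL80", "n3": "GAL3"}
)

mgr = SetManager(net)
mgr.create_set("galactose", "node", ["n0", "n1", "n2"])

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "galactose.txt"
    export_set(mgr, tables, "galactose", path, id_column="symbol")
    print("exported file contents:")
    print(path.read_text(), end="")

    # add a line that matches nothing, then re-import
    path.write_text(path.read_text() + "NOT_A_GENE\n")
    imported, report = import_set(
        mgr, tables, "galactose2", "node", path, id_column="symbol"
    )
    print("imported members:", imported.members)
    print("report:", report.summary())

# The round trip preserves membership; the bogus line shows up in the
# report as unmatched rather than corrupting the set.
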