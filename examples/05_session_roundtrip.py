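"""Persist sets as hidden boolean columns and round-trip a session bundle.

Each set becomes a boolean column (true = member) in the hidden attribute
table of its element class, so membership survives alongside the network;
a session bundle zips the network, tables and manifest into one file that
loads back exactly.
"""

import tempfile
from pathlib import Path

from netsets import (
    SetManager,
    Tables,
    build_network,
    load_session,
    restore_from_table,
    save_session,
    sync_to_table,
)

net = build_network("toy", [("A", "pp", "B"), ("B", "pp", "C")])
tables = Tables.for_network(net)
mgr = SetManager(net)
mgr.create_set("S", "node", ["A", "C"])
mgr.create_set("interactions", "edge", ["A (pp) B"])

sync_to_table(mgr, tables)
col = tables.node.column("setsApp::S", namespace="hidden")
print("hidden column setsApp::S =", col.values)

restored = restore_from_table(net, tables)
print("restored sets:", restored.creation_order)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "session.zip"
    save_session(net, tables, mgr, path)
    net2, tables2, mgr2, _ = load_session(path)
    print("session round trip exact:", (net2, tables2, mgr2) == (net, tables, mgr))

# The boolean column records membership for every node (false for
# non-members, so empty sets restore too); the bundle reload reproduces
# the network, tables and manager bit for bit.
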