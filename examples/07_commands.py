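"""Drive the library through the command dispatcher.

The same operations are exposed as named commands with string arguments —
the scripting surface.  "selected" resolves to the session's selection
state and "current" to the active network.
"""

from netsets import SetManager
from netsets.commands import NetworkBundle, Session, dispatch, select_threshold
from netsets.fixtures import generate_gal_like

network, tables = generate_gal_like(seed=7)
session = Session()
bundle = NetworkBundle(network, tables, SetManager(network))
session.add_network(bundle)

# threshold-select, then save the selection as a set — all via commands
select_threshold(session, "gal1RGexp", "lt", -0.5)
result = dispatch(
    session, "createSet", {"name": "GAL1-", "nodeList": "selected", "network": "current"}
)
print(result.message)

select_threshold(session, "gal4RGexp", "lt", -0.5)
dispatch(session, "createSet", {"name": "GAL4-", "nodeList": "selected"})

result = dispatch(
    session, "intersect", {"name": "both", "set1": "GAL1-", "set2": "GAL4-"}
)
print(result.message)
print("members:", bundle.mgr.get("both").members)

# The intersection holds the genes under-expressed in both conditions —
# identical to calling mgr.intersect_sets directly.
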