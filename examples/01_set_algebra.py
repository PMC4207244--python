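"""Named-set algebra on a small network.

Builds a five-node network, defines two overlapping node sets, and
combines them with union, intersection and the order-dependent difference.
"""

from netsets import SetManager, build_network

net = build_network(
    "toy",
    [("A", "pp", "B"), ("B", "pp", "C"), ("C", "pp", "D"), ("D", "pp", "E")],
)
mgr = SetManager(net)
mgr.create_set("left", "node", ["A", "B", "C"])
mgr.create_set("right", "node", ["C", "D", "E"])

print("union:       ", mgr.union_sets("both", ["left", "right"]).members)
print("intersection:", mgr.intersect_sets("shared", ["left", "right"]).members)
print("left - right:", mgr.difference_sets("only_left", ["left", "right"]).members)
print("right - left:", mgr.difference_sets("only_right", ["right", "left"]).members)

# The two differences disagree because difference folds left over the given
# order: what survives depends on which set you start from.
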