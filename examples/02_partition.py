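"""Partition overlapping sets into membership-signature atoms.

Every element of the union is grouped by exactly which input sets contain
it; the resulting atoms are disjoint, cover the union, and are registered
as ordinary sets (here under the prefix "part ").
"""

from netsets import SetManager, build_network

net = build_network("toy", [])
for n in "abcdefg":
    net.add_node(n)

mgr = SetManager(net)
mgr.create_set("X", "node", ["a", "b", "c", "d"])
mgr.create_set("Y", "node", ["c", "d", "e"])
mgr.create_set("Z", "node", ["d", "e", "f"])

atoms = mgr.partition(["X", "Y", "Z"], name_sep=":", prefix="part ")
for signature, atom in sorted(atoms.items(), key=lambda kv: kv[1].name):
    print(f"{atom.name:<14} members={atom.members}")

# Each line is one atom: e.g. "part X:Y" holds the elements in X and Y but
# not Z.  With 3 inputs there can be at most 2**3 - 1 = 7 atoms; empty
# signatures are never created.
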