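"""The threshold-and-intersect workflow on synthetic expression data.

Generates a connected 60-node network whose node table carries three
fold-change columns (gal1RGexp, gal4RGexp, gal80Rexp).  One node is
planted as co-under-expressed and five as co-over-expressed across all
conditions.  Selecting < -0.5 and > 0.5 per condition gives six sets
(GAL1-, GAL1+, ...); intersecting the three "-" sets and the three "+"
sets recovers the planted genes exactly.
"""

from netsets.fixtures import generate_gal_like, run_expression_workflow

network, tables = generate_gal_like(seed=7)
mgr, pair = run_expression_workflow(network, tables)

for name in mgr.creation_order:
    print(f"{name:<7} {len(mgr.get(name)):>2} members")

print()
print("co-under-expressed genes:", pair.down.members)
print("co-over-expressed genes: ", pair.up.members)

# GAL- holds the single gene repressed under every condition and GAL+ the
# five genes induced under every condition — the planted subsets, recovered
# purely by thresholding and set intersection.
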