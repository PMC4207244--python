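"""Set-aware layouts: grid of grids, and force-directed with set springs.

Two five-node sets joined by one bridge edge.  The grid layout separates
the sets into disjoint blocks; the force layout pulls co-set nodes
together, and raising set_weight tightens each cluster (lower intra/inter
distance ratio).
"""

from netsets import (
    ForceParams,
    SetManager,
    build_network,
    cohesion_ratio,
    force_layout,
    grid_layout,
)
from netsets.layouts import block_bounding_boxes

left = [f"L{i}" for i in range(5)]
right = [f"R{i}" for i in range(5)]
records = [(left[i], "pp", left[i + 1]) for i in range(4)]
records += [(right[i], "pp", right[i + 1]) for i in range(4)]
records.append((left[-1], "pp", right[0]))  # the bridge

net = build_network("bridge", records)
mgr = SetManager(net)
mgr.create_set("left", "node", left)
mgr.create_set("right", "node", right)

coords = grid_layout(net, mgr, spacing=1.0)
for label, box in block_bounding_boxes(net, mgr, coords).items():
    print(f"grid block {label!r}: bounding box {box}")

for weight in (0.0, 1.0, 5.0):
    ratios = [
        cohesion_ratio(
            force_layout(net, mgr, ForceParams(set_weight=weight, iterations=100, seed=s)),
            [left, right],
        )
        for s in range(20)
    ]
    print(f"set_weight={weight}: mean intra/inter distance ratio "
          f"{sum(ratios) / len(ratios):.3f} (20 seeds)")

# The block boxes never overlap.  The ratio falls as set_weight grows:
# stronger virtual springs pull each set's members closer together
# relative to the other set.
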