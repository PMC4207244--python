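"""Set-aware node layouts.

Two placement algorithms that use set membership, not just connectivity:

* :func:`grid_layout` — a *grid of grids*: each set gets its own
  near-square block of nodes at a fixed pitch, blocks are arranged on an
  outer grid, and nodes in no set form a final "unassigned" block.  Block
  bounding boxes never overlap (margin of at least one pitch), which makes
  this ideal for quickly separating sets for manual rearrangement.
* :func:`force_layout` — a seeded Fruchterman–Reingold-style spring
  embedder (pairwise repulsion, edge springs, linear cooling) augmented
  with *virtual springs between every pair of co-set nodes*.  The
  ``set_weight`` knob scales the virtual springs relative to edge springs;
  at ``set_weight = 0`` the result is bit-identical to the plain embedder,
  and larger weights pull each set's members closer together.

Coordinates are abstract Cartesian units with y increasing downward, and
force layouts are centred so the node centroid sits at the origin —
translation carries no information.  Same inputs and seed give the same
coordinates, bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError
from .graph_model import Network
from .sets_core import SetManager

LayoutResult = dict[str, tuple[float, float]]

UNASSIGNED = "(unassigned)"


# ---------------------------------------------------------------------------
# Grid of grids


def _owning_blocks(network: Network, mgr: Optional[SetManager]) -> list[tuple[str, list[str]]]:
    """Assign each node to exactly one block.

    A node in several sets is owned by the earliest set in creation order
    that contains it; nodes in no node-set fall into the unassigned block.
    """
    assigned: set[str] = set()
    blocks: list[tuple[str, list[str]]] = []
    if mgr is not None:
        for name in mgr.creation_order:
            s = mgr.get(name)
            if s.element_kind != "node":
                continue
            mine = [n for n in s.members if n not in assigned]
            if mine:
                assigned.update(mine)
                blocks.append((name, mine))
    free = [n for n in network.nodes if n not in assigned]
    if free:
        blocks.append((UNASSIGNED, free))
    return blocks


def grid_layout(
    network: Network, mgr: Optional[SetManager] = None, spacing: float = 1.0
) -> LayoutResult:
    """Place each set in its own grid and arrange the grids on a grid.

    Within a block, nodes fill rows of a near-square grid
    (``columns = ceil(sqrt(m))``) at pitch ``spacing``; outer cells are
    padded so distinct block bounding boxes stay at least ``spacing``
    apart.  With no sets defined, all nodes form a single grid.
    """
    if spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    blocks = _owning_blocks(network, mgr)
    coords: LayoutResult = {}
    if not blocks:
        return coords

    widths, heights = [], []
    for _, members in blocks:
        cols = math.ceil(math.sqrt(len(members)))
        rows = math.ceil(len(members) / cols)
        widths.append((cols - 1) * spacing)
        heights.append((rows - 1) * spacing)
    cell_w = max(widths) + 2 * spacing
    cell_h = max(heights) + 2 * spacing

    outer_cols = math.ceil(math.sqrt(len(blocks)))
    for b, (_, members) in enumerate(blocks):
        ox = (b % outer_cols) * cell_w
        oy = (b // outer_cols) * cell_h
        cols = math.ceil(math.sqrt(len(members)))
        for k, node in enumerate(members):
            coords[node] = (ox + (k % cols) * spacing, oy + (k // cols) * spacing)
    return coords


def block_bounding_boxes(
    network: Network, mgr: Optional[SetManager], coords: LayoutResult
) -> dict[str, tuple[float, float, float, float]]:
    """Axis-aligned (xmin, ymin, xmax, ymax) of each block's nodes."""
    boxes = {}
    for label, members in _owning_blocks(network, mgr):
        xs = [coords[n][0] for n in members]
        ys = [coords[n][1] for n in members]
        boxes[label] = (min(xs), min(ys), max(xs), max(ys))
    return boxes


# ---------------------------------------------------------------------------
# Force-directed with intra-set attraction


@dataclass
class ForceParams:
    """Spring-embedder parameters.

    set_weight: strength of same-set attraction relative to edge
        attraction (0 disables it and reduces to the plain embedder).
    iterations: annealing steps.
    seed: initial-placement (and pair-subsampling) seed.
    repulsion / edge_attraction: global force scales; both positive.
    """

    set_weight: float = 1.0
    iterations: int = 100
    seed: int = 0
    repulsion: float = 1.0
    edge_attraction: float = 1.0

    def validate(self) -> None:
        values = (self.set_weight, self.repulsion, self.edge_attraction)
        if not all(math.isfinite(v) for v in values):
            raise ParameterError(f"non-finite force parameter in {self}")
        if self.set_weight < 0:
            raise ParameterError("set_weight must be >= 0")
        if self.repulsion <= 0 or self.edge_attraction <= 0:
            raise ParameterError("repulsion and edge_attraction must be > 0")
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")


MAX_EXACT_SET = 50  # above this, pairwise set springs are subsampled


def _set_springs(
    mgr: SetManager, index: dict[str, int], rng: np.random.Generator
) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    for name in mgr.creation_order:
        s = mgr.get(name)
        if s.element_kind != "node":
            continue
        idx = [index[m] for m in s.members if m in index]
        m = len(idx)
        if m < 2:
            continue
        if m <= MAX_EXACT_SET:
            pairs.extend((idx[i], idx[j]) for i in range(m) for j in range(i + 1, m))
        else:
            # cap cost at 50*m seeded random pairs
            draws = rng.integers(0, m, size=(MAX_EXACT_SET * m, 2))
            for a, b in draws:
                if a != b:
                    pairs.append((idx[int(a)], idx[int(b)]))
    return pairs


def force_layout(
    network: Network,
    mgr: Optional[SetManager] = None,
    params: Optional[ForceParams] = None,
) -> LayoutResult:
    """Seeded spring embedder with optional same-set attraction.

    Repulsion acts between all node pairs, attraction along edges, and —
    when ``params.set_weight > 0`` and a manager is given — along virtual
    springs joining every pair of nodes that share a set, with strength
    ``set_weight * edge_attraction``.  Deterministic given the seed.
    """
    params = params or ForceParams()
    params.validate()

    nodes = list(network.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    if n == 1:
        return {nodes[0]: (0.0, 0.0)}

    index = {node: i for i, node in enumerate(nodes)}
    rng = np.random.default_rng(params.seed)
    side = math.sqrt(n)
    pos = rng.uniform(-side / 2, side / 2, size=(n, 2))

    springs: list[tuple[int, int, float]] = []
    for e in network.edges.values():
        springs.append((index[e.source], index[e.target], params.edge_attraction))
    if mgr is not None and params.set_weight > 0:
        for i, j in _set_springs(mgr, index, rng):
            springs.append((i, j, params.set_weight * params.edge_attraction))

    k = side / math.sqrt(n)  # ideal pairwise distance (= 1 for unit density)
    eps = 1e-9
    if springs:
        spring_i = np.array([s[0] for s in springs])
        spring_j = np.array([s[1] for s in springs])
        spring_w = np.array([s[2] for s in springs])

    t0 = 0.1 * side
    for step in range(params.iterations):
        delta = pos[:, None, :] - pos[None, :, :]  # (n, n, 2)
        dist = np.sqrt((delta**2).sum(axis=2)) + eps
        # repulsion: k^2 / d along +delta
        rep = params.repulsion * (k * k) / dist
        np.fill_diagonal(rep, 0.0)
        disp = (delta / dist[:, :, None] * rep[:, :, None]).sum(axis=1)

        if springs:
            dvec = pos[spring_i] - pos[spring_j]
            d = np.sqrt((dvec**2).sum(axis=1)) + eps
            # attraction: w * d^2 / k along -delta
            force = (spring_w * d / k)[:, None] * dvec
            np.add.at(disp, spring_i, -force)
            np.add.at(disp, spring_j, force)

        temp = t0 * (1.0 - step / params.iterations)
        norm = np.sqrt((disp**2).sum(axis=1)) + eps
        scale = np.minimum(norm, temp) / norm
        pos = pos + disp * scale[:, None]

    pos = pos - pos.mean(axis=0)
    return {node: (float(pos[i, 0]), float(pos[i, 1])) for node, i in index.items()}


def write_layout_tsv(coords: LayoutResult, path) -> None:
    """Write node coordinates as a three-column TSV (node, x, y)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tx\ty\n")
        for node, (x, y) in coords.items():
            fh.write(f"{node}\t{x!r}\t{y!r}\n")


def cohesion_ratio(
    coords: LayoutResult, groups: list[list[str]]
) -> float:
    """Mean intra-group pairwise distance over mean inter-group distance.

    A value below 1 means group members sit closer to each other than to
    members of other groups; lowering it is what the set springs are for.
    """
    intra: list[float] = []
    inter: list[float] = []
    membership = {n: gi for gi, g in enumerate(groups) for n in g}
    nodes = [n for g in groups for n in g]
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            na, nb = nodes[a], nodes[b]
            d = math.dist(coords[na], coords[nb])
            (intra if membership[na] == membership[nb] else inter).append(d)
    if not intra or not inter:
        raise ValueError("cohesion ratio needs both intra- and inter-group pairs")
    return (sum(intra) / len(intra)) / (sum(inter) / len(inter))
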