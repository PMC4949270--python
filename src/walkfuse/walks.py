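"""Spanning-tree walks: sequential MAP updates in Prim insertion order.

Each patch's low-confidence voxels form an undirected 6-adjacency graph
with edge weights equal to the squared intensity gradient,

    w(x_i, x_j) = (f_i - f_j)^2   for 6-adjacent pairs (non-adjacent pairs
                                   are non-edges),

which Prim's algorithm, started at the seed, turns into a rooted minimum
spanning tree. The walk then visits the voxels exactly once in Prim
insertion order — label information flows from the seed (the most
high-confidence-surrounded voxel) outward along low-gradient routes — and
replaces each voxel's label by the argmin of its conditional energy given
the current, partially updated configuration. This is deliberately a
single non-iterative pass, in contrast with ICM/EM-style sweeps: each
update is immediately visible to later voxels, which is the mechanism by
which confidence propagates.

Low-confidence voxels in the patch but not 6-connected to the seed's
component are unreachable by the tree; they keep their baseline label
(same fallback as voxels outside every patch).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .mrf import GaussianParams, PatchGraph, conditional_energy
from .patching import Patch
from .volumes import as_array

__all__ = ["SpanningTree", "build_mst", "walk_update"]

_OFFSETS6 = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


@dataclass
class SpanningTree:
    """A rooted MST over the seed's connected LOW component.

    ``order`` is the Prim insertion sequence (root first; every voxel after
    its parent); ``parent`` maps each non-root voxel to its tree parent.
    """

    root: tuple
    order: list
    parent: dict

    def total_weight(self, image) -> float:
        img = as_array(image)
        return float(
            sum((img[c] - img[p]) ** 2 for c, p in self.parent.items())
        )


def build_mst(patch: Patch, image) -> SpanningTree:
    """Prim's algorithm from the seed over the patch's LOW voxels.

    Edge-weight ties are broken by lexicographic (parent, child) voxel
    index, making the tree and its insertion order fully deterministic.
    Only the seed's 6-connected component is spanned; membership of the
    tree is how callers detect disconnected voxels.
    """
    low = {tuple(v) for v in np.asarray(patch.members_low, dtype=int)}
    seed = tuple(int(c) for c in patch.seed)
    if seed not in low:
        raise ValueError(f"seed {seed} is not among the patch's LOW voxels")
    img = as_array(image)

    def push_edges(heap, n):
        fn = float(img[n])
        for d in _OFFSETS6:
            m = (n[0] + d[0], n[1] + d[1], n[2] + d[2])
            if m in low and m not in visited:
                heapq.heappush(heap, ((fn - float(img[m])) ** 2, n, m))

    visited = {seed}
    order = [seed]
    parent: dict = {}
    heap: list = []
    push_edges(heap, seed)
    while heap:
        w, p, c = heapq.heappop(heap)
        if c in visited:
            continue
        visited.add(c)
        parent[c] = p
        order.append(c)
        push_edges(heap, c)
    return SpanningTree(seed, order, parent)


def walk_update(
    tree: SpanningTree,
    graph: PatchGraph,
    init: dict,
    g: GaussianParams,
    lam: float,
) -> dict:
    """One sequential pass over the tree: per-voxel conditional-energy argmin.

    Each voxel in ``tree.order`` is visited exactly once; its label becomes
    the energy-minimizing one given the labels its neighbors hold at that
    moment (already-walked voxels contribute their updated labels,
    high-confidence neighbors their fixed labels). Ties keep the current
    label. High-confidence nodes are never touched. Since every update is
    a conditional argmin, the total patch energy cannot increase.
    """
    graph._check_cfg(init)
    cfg = dict(init)
    node_set = set(graph.nodes)
    for v in tree.order:
        if v not in node_set:
            raise ValueError(f"tree voxel {v} is not a node of the patch graph")
        e0 = conditional_energy(v, 0, cfg, graph, g, lam)
        e1 = conditional_energy(v, 1, cfg, graph, g, lam)
        if e1 < e0:
            cfg[v] = 1
        elif e0 < e1:
            cfg[v] = 0
        # exact tie: keep current label
    return cfg
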