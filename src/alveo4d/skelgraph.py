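"""Voxel-skeleton graph utilities shared by ring and vessel analysis.

A binary mask is thinned to a unit-width skeleton; skeleton voxels become
graph nodes connected to their 26-neighbours, with edge weights equal to the
physical step length so arc lengths honour anisotropic voxels.  Redundant
diagonal edges (a diagonal step whose two endpoints share an orthogonal
common neighbour) are dropped so that a one-voxel-wide curve yields a simple
path rather than a mesh of triangles.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize

__all__ = ["skeleton_graph", "prune_spurs"]

_OFFSETS = [
    np.array(o)
    for o in itertools.product((-1, 0, 1), repeat=3)
    if any(o)
]


def skeleton_graph(mask: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> nx.Graph:
    """Skeletonize a 3-D binary mask and return its voxel graph.

    Nodes are skeleton voxel index tuples (z, y, x) with a ``pos`` attribute
    in μm; edges carry ``length`` in μm.
    """
    mask = np.asarray(mask).astype(bool)
    g = nx.Graph()
    if not mask.any():
        return g
    skel = skeletonize(mask)
    vox = np.asarray(voxel_size, dtype=float)
    coords = np.argwhere(skel)
    present = {tuple(c) for c in map(tuple, coords)}
    for c in present:
        g.add_node(c, pos=np.asarray(c) * vox)
    for c in present:
        ca = np.asarray(c)
        for off in _OFFSETS:
            nb = tuple(ca + off)
            if nb <= c or nb not in present:
                continue
            g.add_edge(c, nb, length=float(np.linalg.norm(off * vox)))
    _drop_redundant_diagonals(g)
    return g


def _drop_redundant_diagonals(g: nx.Graph) -> None:
    # remove diagonal edges shortcut by a shared closer neighbour, longest first
    edges = sorted(
        g.edges(data="length"), key=lambda e: -e[2]
    )
    for u, v, length in edges:
        step = sum(abs(a - b) for a, b in zip(u, v))
        if step < 2 or not g.has_edge(u, v):
            continue
        common = set(g[u]) & set(g[v])
        for w in common:
            if g[u][w]["length"] < length and g[v][w]["length"] < length:
                g.remove_edge(u, v)
                break


def prune_spurs(g: nx.Graph, min_length: float = 3.0) -> nx.Graph:
    """Iteratively remove short terminal branches (thinning artifacts).

    A spur is a chain ending in a degree-1 node whose arc length from its
    nearest junction is below ``min_length`` μm.
    """
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for tip in [n for n in g.nodes if g.degree(n) == 1]:
            if tip not in g:
                continue
            chain = [tip]
            length = 0.0
            node = tip
            prev = None
            while g.degree(node) <= 2:
                nbrs = [n for n in g[node] if n != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g[node][nxt]["length"]
                prev, node = node, nxt
                if g.degree(node) != 2:
                    break
                chain.append(node)
            if length < min_length and g.degree(node) >= 3:
                g.remove_nodes_from(chain)
                changed = True
    return g
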