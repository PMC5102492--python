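"""Sprout identification and tip-cell occupancy.

A sprout is the connection between an end point E and a branch point B of the
network skeleton.  For each end point, all *other* node pixels are removed
from the skeleton; the connected piece still containing E is the branch, and
the node adjacent to that piece (once the nodes are superimposed again) is B.
The cells at the sprout tip are then found on the cell-adjacency graph: with
shortest-path distances to the cell under B (Dijkstra with unit edge
weights), a search growing from the cell under E — stopped at the branch-point
cell — returns the visited cell(s) with the longest shortest path.  A sprout
whose skeleton has no branch point (an isolated filament), or whose nodes
cannot be mapped onto a cell, is flagged and excluded from occupancy
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .lattice import CellLattice
from .morphometrics import (SkeletonGraph, SkeletonNode, UndefinedValueError,
                            largest_connected_component, skeletonize)
from .params import TIP
from .tip_selection import _interface_pairs


@dataclass
class Sprout:
    """One sprout: its skeleton nodes, tip cells and occupancy."""

    end_point: tuple[float, float]
    branch_point: tuple[float, float] | None
    tip_cells: set[int] = field(default_factory=set)
    tip_occupied: bool = False
    flagged: bool = False


def find_branch_point(skel: SkeletonGraph, end: SkeletonNode
                      ) -> SkeletonNode | None:
    """Branch point connected to ``end``, or None for an isolated filament.

    Removes every node pixel except those of ``end`` from the skeleton, takes
    the connected component containing ``end``, and returns the node whose
    pixels touch that component when the nodes are superimposed again.
    """
    img = skel.skeleton.copy()
    for node in skel.nodes:
        if node is end:
            continue
        for y, x in node.pixels:
            img[y, x] = False
    labels, n = ndimage.label(img, structure=np.ones((3, 3), dtype=bool))
    end_labels = {labels[y, x] for y, x in end.pixels if labels[y, x] > 0}
    if not end_labels:
        return None
    branch_mask = np.isin(labels, list(end_labels))
    grown = ndimage.binary_dilation(branch_mask,
                                    structure=np.ones((3, 3), dtype=bool))
    candidates = []
    for node in skel.nodes:
        if node is end or node.kind != "branch":
            continue
        if any(grown[y, x] for y, x in node.pixels):
            candidates.append(node)
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0]
    # pathological tie: nearest node to the end point along straight distance
    ep = np.array(end.position)
    return min(candidates,
               key=lambda nd: float(((np.array(nd.position) - ep) ** 2).sum()))


def build_cell_graph(lattice: CellLattice) -> nx.Graph:
    """Cell-adjacency graph: an edge joins cells with interface length ≥ 1."""
    graph = nx.Graph()
    graph.add_nodes_from(int(i) for i in lattice.cell_ids())
    sa, sb = _interface_pairs(lattice, connectivity=4)
    cellcell = (sa > 0) & (sb > 0)
    edges = np.unique(np.sort(np.stack([sa[cellcell], sb[cellcell]], axis=1),
                              axis=1), axis=0)
    graph.add_edges_from((int(a), int(b)) for a, b in edges)
    return graph


def cell_at_node(lattice: CellLattice, position: tuple[float, float],
                 search_radius: float = 3.0) -> int | None:
    """Cell whose territory contains the node pixel.

    Merged node positions are means and may round onto the ECM; in that case
    the nearest cell site within ``search_radius`` is used, else None
    (the sprout is flagged).
    """
    y = int(round(position[0]))
    x = int(round(position[1]))
    h, w = lattice.shape
    y = min(max(y, 0), h - 1)
    x = min(max(x, 0), w - 1)
    if lattice.sigma[y, x] > 0:
        return int(lattice.sigma[y, x])
    r = int(np.ceil(search_radius))
    best, best_d2 = None, search_radius**2 + 1e-9
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            ny, nx_ = y + dy, x + dx
            if (d2 <= best_d2 and 0 <= ny < h and 0 <= nx_ < w
                    and lattice.sigma[ny, nx_] > 0):
                if d2 < best_d2 or (best is not None
                                    and lattice.sigma[ny, nx_] < best):
                    best, best_d2 = int(lattice.sigma[ny, nx_]), d2
    return best


def sprout_tip_cells(graph: nx.Graph, v_b: int, v_e: int) -> set[int]:
    """Cells at the sprout tip: the longest shortest path from the branch.

    Distances to ``v_b`` come from Dijkstra with unit weights; the search
    grows outward from ``v_e`` and never expands through ``v_b``, confining it
    to the sprout.  Returns the visited cell(s) at maximal distance (ties all
    returned).  Raises :class:`UndefinedValueError` when ``v_e`` cannot reach
    ``v_b``.
    """
    if v_b == v_e:
        return {v_e}
    dist = nx.single_source_dijkstra_path_length(graph, v_b, weight=None)
    if v_e not in dist:
        raise UndefinedValueError("end-point cell unreachable from branch point")
    visited = {v_e}
    frontier = [v_e]
    while frontier:
        nxt = []
        for node in frontier:
            if node == v_b:
                continue  # stop the search at the branch point
            for nb in graph.neighbors(node):
                if nb not in visited:
                    visited.add(nb)
                    nxt.append(nb)
        frontier = nxt
    candidates = visited - {v_b}
    dmax = max(dist[v] for v in candidates)
    return {v for v in candidates if dist[v] == dmax}


def analyze_sprouts(lattice: CellLattice,
                    skel: SkeletonGraph | None = None) -> list[Sprout]:
    """Build the sprout record for every skeleton end point."""
    if skel is None:
        skel = skeletonize(lattice.binary_mask())
    graph = build_cell_graph(lattice)
    sprouts = []
    for end in skel.end_nodes():
        sprout = Sprout(end_point=end.position, branch_point=None)
        branch = find_branch_point(skel, end)
        if branch is None:
            sprout.flagged = True  # isolated filament spans the component
            sprouts.append(sprout)
            continue
        sprout.branch_point = branch.position
        v_e = cell_at_node(lattice, end.position)
        v_b = cell_at_node(lattice, branch.position)
        if v_e is None or v_b is None:
            sprout.flagged = True
            sprouts.append(sprout)
            continue
        try:
            sprout.tip_cells = sprout_tip_cells(graph, v_b, v_e)
        except UndefinedValueError:
            sprout.flagged = True
            sprouts.append(sprout)
            continue
        sprout.tip_occupied = any(
            lattice.cell_types[c] == TIP for c in sprout.tip_cells)
        sprouts.append(sprout)
    return sprouts


def percent_sprout_tips_occupied(lattice: CellLattice,
                                 skel: SkeletonGraph | None = None) -> float:
    """Percentage of (valid) sprouts with ≥ 1 tip cell at the sprout tip."""
    valid = [s for s in analyze_sprouts(lattice, skel) if not s.flagged]
    if not valid:
        raise UndefinedValueError("no valid sprouts in this morphology")
    return 100.0 * sum(s.tip_occupied for s in valid) / len(valid)


def sprout_table(lattice: CellLattice, skel: SkeletonGraph | None = None,
                 replicate: int | None = None, mcs: int | None = None):
    """Per-sprout table: node positions, tip-cell count and occupancy."""
    import pandas as pd

    rows = []
    for s in analyze_sprouts(lattice, skel):
        rows.append({
            "replicate": replicate,
            "mcs": mcs,
            "end_y": s.end_point[0],
            "end_x": s.end_point[1],
            "branch_y": None if s.branch_point is None else s.branch_point[0],
            "branch_x": None if s.branch_point is None else s.branch_point[1],
            "n_tip_cells_at_tip": len(s.tip_cells),
            "tip_occupied": s.tip_occupied,
            "flagged": s.flagged,
        })
    return pd.DataFrame(rows, columns=[
        "replicate", "mcs", "end_y", "end_x", "branch_y", "branch_x",
        "n_tip_cells_at_tip", "tip_occupied", "flagged"])


def count_sprouts(mask: np.ndarray) -> int:
    """Number of sprouts: merged skeleton end points of the largest
    connected component (the automated stand-in for manual counting)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    comp, _ = largest_connected_component(mask)
    return skeletonize(comp).n_end_points
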