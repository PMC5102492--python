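"""Morphometrics of simulated vascular networks.

Quantifies a binary morphology (1 where a cell is present) by:

* **compactness** C = A_cell / A_hull — area of the largest 8-connected
  cluster of cell sites over the area of its convex hull (C → 1 for a disk,
  C → 0 for a sparse network);
* **lacunae** — enclosed ECM regions (4-connected background components not
  touching the lattice border) and the dispersion of their areas;
* **skeleton topology** — branch points and end points of the single-pixel
  morphological skeleton (closing with a disk of radius 3, then homotopic
  hit-and-miss thinning to convergence), with nearby nodes merged.

The largest-component search uses a union-find with path compression and the
hull a Graham scan over the unit-square corners of the sites, so a solid
convex shape gives exactly C = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import closing as _closing, disk as _disk, thin as _thin

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class UndefinedValueError(ValueError):
    """A morphometric that is undefined for this input (e.g. empty mask)."""


# ---------------------------------------------------------------------------
# connected components (union-find with path compression)

class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def label_components(mask: np.ndarray) -> np.ndarray:
    """8-connected labeling of True sites (0 = background).

    Labels are assigned in raster order of each component's first site.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    uf = _UnionFind(int(mask.sum()))
    ys, xs = np.nonzero(mask)
    for y, x in zip(ys, xs):
        # union with the already-scanned half of the 8-neighborhood
        for dy, dx in ((0, -1), (-1, -1), (-1, 0), (-1, 1)):
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and mask[ny, nx]:
                uf.union(idx[y, x], idx[ny, nx])
    labels = np.zeros(mask.shape, dtype=np.int64)
    root_label: dict[int, int] = {}
    nxt = 1
    for y, x in zip(ys, xs):
        r = uf.find(idx[y, x])
        if r not in root_label:
            root_label[r] = nxt
            nxt += 1
        labels[y, x] = root_label[r]
    return labels


def largest_connected_component(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Largest 8-connected component of 1-sites (ties → smallest label).

    Returns ``(component_mask, area)``; an empty mask yields an all-False
    mask and area 0.
    """
    labels = label_components(mask)
    n = labels.max()
    if n == 0:
        return np.zeros_like(np.asarray(mask, dtype=bool)), 0
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1  # first max = smallest label
    return labels == best, int(sizes[best - 1])


# ---------------------------------------------------------------------------
# convex hull (Graham scan, monotone-chain variant) and compactness

def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def convex_hull(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex hull polygon (CCW vertices) and its shoelace area.

    ``points`` are (x, y) rows.  Degenerate inputs (single point, collinear
    sets) return the reduced polygon with area 0.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) == 1:
        return pts, 0.0
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.array(lower[:-1] + upper[:-1])
    x, y = hull[:, 0], hull[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return hull, float(area)


def site_corner_points(mask: np.ndarray) -> np.ndarray:
    """Unit-square corner points (x, y) of every True site."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    corners = np.concatenate([
        np.stack([xs, ys], axis=1),
        np.stack([xs + 1, ys], axis=1),
        np.stack([xs, ys + 1], axis=1),
        np.stack([xs + 1, ys + 1], axis=1),
    ])
    return np.unique(corners, axis=0).astype(float)


def compactness(mask: np.ndarray) -> float:
    """C = (area of largest component) / (area of its convex hull) ∈ (0, 1]."""
    comp, area = largest_connected_component(mask)
    if area == 0:
        raise UndefinedValueError("compactness is undefined for an empty mask")
    _, hull_area = convex_hull(site_corner_points(comp))
    return area / hull_area


# ---------------------------------------------------------------------------
# lacunae

def label_lacunae(mask: np.ndarray) -> list[int]:
    """Areas of the lacunae: 4-connected ECM components fully enclosed by
    cell sites (components touching the lattice border are not lacunae)."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(~mask, structure=_STRUCT4)
    if n == 0:
        return []
    border = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    return [int(sizes[i]) for i in range(1, n + 1) if i not in border]


def lacuna_area_sd(areas) -> float:
    """Population standard deviation of lacuna areas.

    Accepts a list of areas or a :class:`MorphometricsReport`.  Raises
    :class:`UndefinedValueError` when there are no lacunae (reported as
    missing, never as 0).
    """
    if isinstance(areas, MorphometricsReport):
        areas = areas.lacuna_areas
    if len(areas) == 0:
        raise UndefinedValueError("no lacunae: area dispersion undefined")
    return float(np.std(np.asarray(areas, dtype=float)))


# ---------------------------------------------------------------------------
# skeleton and nodes

@dataclass
class SkeletonNode:
    """A (possibly merged) skeleton node: mean position and kind."""

    position: tuple[float, float]  # (y, x)
    kind: str  # "branch" or "end"
    pixels: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class SkeletonGraph:
    """Single-pixel skeleton with its merged branch/end nodes."""

    skeleton: np.ndarray
    nodes: list[SkeletonNode]
    merged: bool = True

    def end_nodes(self) -> list[SkeletonNode]:
        return [n for n in self.nodes if n.kind == "end"]

    def branch_nodes(self) -> list[SkeletonNode]:
        return [n for n in self.nodes if n.kind == "branch"]

    @property
    def n_end_points(self) -> int:
        return len(self.end_nodes())

    @property
    def n_branch_points(self) -> int:
        return len(self.branch_nodes())


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant")


def detect_nodes(skel: np.ndarray) -> list[tuple[int, int, str]]:
    """Raw node pixels: (y, x, kind); >2 skeleton neighbors → branch,
    exactly 1 → end."""
    counts = _neighbor_counts(skel)
    out = []
    for y, x in zip(*np.nonzero(skel & (counts == 1))):
        out.append((int(y), int(x), "end"))
    for y, x in zip(*np.nonzero(skel & (counts > 2))):
        out.append((int(y), int(x), "branch"))
    return out


def merge_nodes(raw_nodes, radius: float = 10.0) -> list[SkeletonNode]:
    """Single-linkage clustering of node pixels at the merge radius.

    Every cluster of same-kind nodes with chained pairwise distance < radius
    is replaced by one node at the mean position.  End points and branch
    points are merged separately: the sprout-detection step needs each sprout
    tip to keep a distinct end node even when it lies close to a junction.
    Deterministic regardless of input order.
    """
    merged = []
    for kind in ("end", "branch"):
        nodes = [n for n in raw_nodes if n[2] == kind]
        if not nodes:
            continue
        pos = np.array([(y, x) for y, x, _ in nodes], dtype=float)
        n = len(pos)
        uf = _UnionFind(n)
        d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        for i in range(n):
            for j in range(i + 1, n):
                if d2[i, j] < radius**2:
                    uf.union(i, j)
        clusters: dict[int, list[int]] = {}
        for i in range(n):
            clusters.setdefault(uf.find(i), []).append(i)
        for members in clusters.values():
            mp = pos[members].mean(axis=0)
            merged.append(SkeletonNode(
                position=(float(mp[0]), float(mp[1])), kind=kind,
                pixels=[(nodes[i][0], nodes[i][1]) for i in members]))
    merged.sort(key=lambda nd: nd.position)
    return merged


def detect_and_merge_nodes(skel: np.ndarray,
                           radius: float = 10.0) -> list[SkeletonNode]:
    return merge_nodes(detect_nodes(skel), radius)


def skeletonize(mask: np.ndarray, closing_radius: int = 3,
                merge_radius: float = 10.0,
                max_cycles: int | None = None) -> SkeletonGraph:
    """Morphological skeleton of a binary morphology, with merged nodes.

    Rough edges are removed by a morphological closing with a disk of radius
    ``closing_radius``; the closed image is then thinned homotopically (the
    rotated hit-and-miss operators applied cyclically) until no pixel changes,
    or for at most ``max_cycles`` cycles.  Thinning preserves connectivity and
    holes, so the skeleton has the topology of the (closed) morphology.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return SkeletonGraph(np.zeros_like(mask), [])
    closed = _closing(mask, _disk(closing_radius)) if closing_radius else mask
    skel = _thin(closed, max_num_iter=max_cycles)
    return SkeletonGraph(skel, detect_and_merge_nodes(skel, merge_radius))


# ---------------------------------------------------------------------------
# report

@dataclass
class MorphometricsReport:
    """Morphometrics of one binary morphology."""

    compactness: float
    n_lacunae: int
    lacuna_areas: list[int]
    n_branch_points: int
    n_end_points: int
    largest_component_area: int

    @property
    def lacuna_area_sd(self) -> float | None:
        return lacuna_area_sd(self.lacuna_areas) if self.lacuna_areas else None


def analyze(mask: np.ndarray, merge_radius: float = 10.0,
            closing_radius: int = 3) -> MorphometricsReport:
    """Compute the full morphometrics report for a binary morphology."""
    comp, area = largest_connected_component(mask)
    if area == 0:
        raise UndefinedValueError("empty morphology")
    _, hull_area = convex_hull(site_corner_points(comp))
    lacunae = label_lacunae(mask)
    graph = skeletonize(mask, closing_radius=closing_radius,
                        merge_radius=merge_radius)
    return MorphometricsReport(
        compactness=area / hull_area,
        n_lacunae=len(lacunae),
        lacuna_areas=lacunae,
        n_branch_points=graph.n_branch_points,
        n_end_points=graph.n_end_points,
        largest_component_area=area,
    )
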