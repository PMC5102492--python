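"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately use different algorithms (or different
libraries) than the implementation they check: flood fill via scipy labeling
for the union-find components, an O(n^3) half-plane test for the convex hull,
a Floyd-Warshall triple loop for graph distances, and full-Hamiltonian
differences for the incremental energy kernel.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy import ndimage

from angiosprout import CellLattice, CPMParameters
from angiosprout.params import ECM, STALK, TIP

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

STRUCT8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# oracles

def flood_fill_components(mask: np.ndarray) -> np.ndarray:
    """Independent 8-connected labeling (scipy's flood-fill style labeler)."""
    labels, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=STRUCT8)
    return labels


def brute_force_hull_vertices(points: np.ndarray) -> set[tuple[float, float]]:
    """Hull vertices by the half-plane test over all directed point pairs.

    A point pair (i, j) spans a hull edge iff every other point lies on one
    side of the line through it; hull vertices are the edge endpoints.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n <= 2:
        return {tuple(p) for p in pts}
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            side = np.sign(np.round(
                d[0] * (pts[:, 1] - pts[i, 1])
                - d[1] * (pts[:, 0] - pts[i, 0]), 12))
            if (side >= 0).all() or (side <= 0).all():
                # supporting line found; of the collinear points only the two
                # extremes along the line are vertices
                on_line = pts[side == 0]
                proj = on_line @ d
                verts.add(tuple(on_line[np.argmin(proj)]))
                verts.add(tuple(on_line[np.argmax(proj)]))
    return verts


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of an ordered polygon."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def floyd_warshall(n_nodes: int, edges) -> np.ndarray:
    """All-pairs unit-weight shortest paths by the O(n^3) recurrence."""
    dist = np.full((n_nodes, n_nodes), np.inf)
    np.fill_diagonal(dist, 0.0)
    for a, b in edges:
        dist[a, b] = dist[b, a] = 1.0
    for k in range(n_nodes):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    return dist


# ---------------------------------------------------------------------------
# lattice builders

def lattice_from_sigma(sigma: np.ndarray, types: dict[int, int] | None = None
                       ) -> CellLattice:
    """CellLattice from an integer grid; per-cell types default to stalk."""
    sigma = np.asarray(sigma, dtype=np.int32)
    n = int(sigma.max())
    cell_types = np.full(n + 1, STALK, dtype=np.int8)
    cell_types[0] = ECM
    for cid, t in (types or {}).items():
        cell_types[cid] = t
    return CellLattice(sigma, cell_types)


def two_block_lattice(type_a: int = STALK, type_b: int = STALK,
                      size: int = 10) -> CellLattice:
    """Two size×size cells side by side (interface length = size)."""
    sigma = np.zeros((size + 8, 2 * size + 8), dtype=np.int32)
    sigma[4:4 + size, 4:4 + size] = 1
    sigma[4:4 + size, 4 + size:4 + 2 * size] = 2
    return lattice_from_sigma(sigma, {1: type_a, 2: type_b})


def random_small_state(rng: np.random.Generator, size: int = 8
                       ) -> tuple[CellLattice, CPMParameters]:
    """Random 8×8 multi-cell state and random (valid) CPM parameters."""
    sigma = rng.integers(0, 4, size=(size, size)).astype(np.int32)
    types = {1: STALK, 2: TIP, 3: STALK}
    lattice = lattice_from_sigma(sigma, types)
    j_cc = float(rng.uniform(0, 50))
    params = CPMParameters(
        j_tip_tip=float(rng.uniform(0, 50)),
        j_tip_stalk=j_cc,
        j_stalk_stalk=float(rng.uniform(0, 50)),
        j_tip_ecm=float(rng.uniform(0, 50)),
        j_stalk_ecm=float(rng.uniform(0, 50)),
        lambda_tip=float(rng.uniform(0, 30)),
        lambda_stalk=float(rng.uniform(0, 30)),
        a_tip=float(rng.integers(1, 20)),
        a_stalk=float(rng.integers(1, 20)),
    )
    return lattice, params


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
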