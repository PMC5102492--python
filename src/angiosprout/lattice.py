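"""Cell lattice state and blob initialization.

The lattice is a 2D grid of cell identifiers σ (0 = extracellular matrix,
ECM); all sites sharing a positive σ form one cell.  Per-cell bookkeeping
(type and area) is kept in flat arrays indexed by σ so the Monte Carlo kernel
can address it in O(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import (ECM, STALK, TIP, LATTICE_SPACING_UM, CPMParameters,
                     ConfigurationError)

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class CellRecord:
    """One cell: identifier, current type and current area (site count)."""

    id: int
    cell_type: int
    area: int

    @property
    def type_name(self) -> str:
        return {STALK: "stalk", TIP: "tip"}[self.cell_type]


class CellLattice:
    """2D grid of cell identifiers plus per-cell records.

    Parameters
    ----------
    sigma
        Integer grid of cell ids, row-major, origin top-left; 0 is ECM.
    cell_types
        Array indexed by cell id; entry 0 is the ECM code.
    """

    lattice_spacing_um = LATTICE_SPACING_UM

    def __init__(self, sigma: np.ndarray, cell_types: np.ndarray):
        self.sigma = np.ascontiguousarray(sigma, dtype=np.int32)
        self.cell_types = np.ascontiguousarray(cell_types, dtype=np.int8)
        self.areas = np.bincount(
            self.sigma.ravel(), minlength=len(self.cell_types)
        ).astype(np.int64)
        self.areas[0] = 0  # ECM is not a cell

    @property
    def height(self) -> int:
        return self.sigma.shape[0]

    @property
    def width(self) -> int:
        return self.sigma.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.sigma.shape

    def cell_ids(self) -> np.ndarray:
        """Ids of cells currently present (area > 0), ascending."""
        return np.flatnonzero(self.areas > 0)

    def records(self) -> list[CellRecord]:
        return [CellRecord(int(i), int(self.cell_types[i]), int(self.areas[i]))
                for i in self.cell_ids()]

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.areas > 0))

    def binary_mask(self) -> np.ndarray:
        """Boolean grid, True where a cell is present (σ > 0)."""
        return self.sigma > 0

    def type_grid(self) -> np.ndarray:
        """Per-site cell-type codes (ECM/stalk/tip)."""
        return self.cell_types[self.sigma]

    def realized_tip_fraction(self) -> float:
        ids = self.cell_ids()
        if len(ids) == 0:
            return float("nan")
        return float(np.mean(self.cell_types[ids] == TIP))

    def centroids(self) -> dict[int, tuple[float, float]]:
        """Cell centroids in site units as {id: (x, y)} (x = column)."""
        ids = self.cell_ids()
        ys, xs = np.nonzero(self.sigma)
        sig = self.sigma[ys, xs]
        n = len(self.cell_types)
        sx = np.bincount(sig, weights=xs, minlength=n)
        sy = np.bincount(sig, weights=ys, minlength=n)
        return {int(i): (sx[i] / self.areas[i], sy[i] / self.areas[i])
                for i in ids}

    def recount_areas(self) -> np.ndarray:
        """Recompute areas from the grid (bookkeeping oracle)."""
        counts = np.bincount(self.sigma.ravel(), minlength=len(self.cell_types))
        counts[0] = 0
        return counts.astype(np.int64)

    def check_consistency(self) -> None:
        if not np.array_equal(self.recount_areas(), self.areas):
            raise AssertionError("recorded cell areas disagree with the grid")

    def copy(self) -> "CellLattice":
        new = CellLattice.__new__(CellLattice)
        new.sigma = self.sigma.copy()
        new.cell_types = self.cell_types.copy()
        new.areas = self.areas.copy()
        return new


def initialize_blob(n_cells: int, lattice_dims: tuple[int, int],
                    params: CPMParameters, seed: int,
                    margin: int = 10) -> CellLattice:
    """Tessellate a centered disk of area ``n_cells * A(stalk)`` into cells.

    Cell centers are sampled uniformly over the disk sites and every disk site
    is assigned to its nearest center (a Voronoi tessellation of the disk),
    after which stray fragments are reassigned to adjacent cells so every cell
    is 4-connected.  All cells start as stalk cells.

    Raises
    ------
    ConfigurationError
        If the disk plus the ECM margin does not fit in the lattice; the
        message names the minimum lattice size required.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    width, height = int(lattice_dims[0]), int(lattice_dims[1])
    radius = float(np.sqrt(n_cells * params.a_stalk / np.pi))
    need = int(np.ceil(2 * (radius + margin)))
    if need > min(width, height):
        raise ConfigurationError(
            f"blob of {n_cells} cells (radius {radius:.1f} sites) with a "
            f"{margin}-site ECM margin needs a lattice of at least "
            f"{need}x{need} sites; got {width}x{height}")

    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ys, xs = np.mgrid[0:height, 0:width]
    disk = (ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2
    dy, dx = np.nonzero(disk)
    rng = np.random.default_rng(seed)
    centers = rng.choice(len(dy), size=n_cells, replace=False)
    cyx = np.stack([dy[centers], dx[centers]], axis=1).astype(float)

    # nearest-center assignment; ties resolved to the lowest center index
    d2 = ((dy[:, None] - cyx[None, :, 0]) ** 2
          + (dx[:, None] - cyx[None, :, 1]) ** 2)
    assign = np.argmin(d2, axis=1) + 1

    sigma = np.zeros((height, width), dtype=np.int32)
    sigma[dy, dx] = assign
    _repair_connectivity(sigma, n_cells)

    cell_types = np.full(n_cells + 1, STALK, dtype=np.int8)
    cell_types[0] = ECM
    return CellLattice(sigma, cell_types)


def _repair_connectivity(sigma: np.ndarray, n_cells: int) -> None:
    """Reassign fragments so each cell is one 4-connected patch (in place)."""
    stray = np.zeros(sigma.shape, dtype=bool)
    for cid in range(1, n_cells + 1):
        mask = sigma == cid
        labels, n = ndimage.label(mask, structure=_STRUCT4)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        stray |= mask & (labels != keep)
    # peel stray sites onto 4-adjacent accepted cells until none remain
    while stray.any():
        progressed = False
        for y, x in zip(*np.nonzero(stray)):
            for ny, nx in ((y - 1, x), (y + 1, x), (y, x - 1), (y, x + 1)):
                if (0 <= ny < sigma.shape[0] and 0 <= nx < sigma.shape[1]
                        and not stray[ny, nx] and sigma[ny, nx] > 0
                        and sigma[ny, nx] != sigma[y, x]):
                    sigma[y, x] = sigma[ny, nx]
                    stray[y, x] = False
                    progressed = True
                    break
        if not progressed:  # isolated stray pocket: hand it to the ECM
            sigma[stray] = 0
            break
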