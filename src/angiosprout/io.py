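"""Snapshot, track and field export.

Snapshots are written both as 8-bit grayscale PNGs (ECM black, stalk cells
mid-gray, tip cells white; a blinded variant renders all cells white) and as
lossless integer grid dumps (one row per line, space-separated) for exact
restart and testing.  Centroid tracks and morphometric samples go to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .lattice import CellLattice
from .params import ECM, STALK, TIP

_GRAY = {ECM: 0, STALK: 128, TIP: 255}


def snapshot_image(lattice: CellLattice, blinded: bool = False) -> np.ndarray:
    """8-bit grayscale rendering of the lattice state."""
    tg = lattice.type_grid()
    img = np.zeros(lattice.shape, dtype=np.uint8)
    if blinded:
        img[tg != ECM] = 255
    else:
        for code, gray in _GRAY.items():
            img[tg == code] = gray
    return img


def save_snapshot_png(lattice: CellLattice, path: str | Path,
                      blinded: bool = False) -> None:
    try:
        Image.fromarray(snapshot_image(lattice, blinded)).save(str(path))
    except OSError as exc:
        raise OSError(f"could not write snapshot to {path}: {exc}") from exc


def load_mask_image(path: str | Path) -> np.ndarray:
    """Binary mask from any PNG/TIFF image (nonzero pixels are foreground),
    so externally segmented micrograph masks can be analyzed too."""
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return arr > 0


def save_field_png(c: np.ndarray, path: str | Path) -> None:
    """False-color (viridis) rendering of a concentration field."""
    from matplotlib import cm

    cmax = float(c.max())
    norm = c / cmax if cmax > 0 else np.zeros_like(c)
    rgba = (cm.viridis(norm) * 255).astype(np.uint8)
    Image.fromarray(rgba).save(str(path))


def save_grid_dump(array: np.ndarray, path: str | Path) -> None:
    """Lossless integer grid dump: one row per line, space-separated."""
    np.savetxt(str(path), np.asarray(array), fmt="%d")


def load_grid_dump(path: str | Path) -> np.ndarray:
    return np.loadtxt(str(path), dtype=np.int64, ndmin=2)


def save_field_csv(c: np.ndarray, path: str | Path) -> None:
    np.savetxt(str(path), c, delimiter=",")


def save_tracks_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    """Centroid tracks: columns mcs, cell_id, cell_type, x, y (site units)."""
    tracks.to_csv(str(path), index=False)


def save_run_metadata(path: str | Path, config_dict: dict, seed: int,
                      extra: dict | None = None) -> None:
    meta = {"seed": seed, "config": config_dict}
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str))
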