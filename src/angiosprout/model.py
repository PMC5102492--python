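"""Model and results objects: configure, run, summarize.

:class:`AngiogenesisModel` wraps a validated :class:`SimulationConfig`;
``run(seed)`` executes the Monte Carlo loop and returns a
:class:`SimulationResult` holding the final state, lattice snapshots,
centroid tracks and per-snapshot morphometric samples, with ``summary()``
rendering the headline read-outs as a table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as _io
from . import morphometrics as mm
from . import sprout_analysis as sa
from .chemo import ChemoattractantField
from .core import _KernelArgs, run_mcs, seed_rng
from .lattice import CellLattice, initialize_blob
from .params import TYPE_NAMES, SimulationConfig
from .tip_selection import assign_static_types


@dataclass
class Snapshot:
    mcs: int
    sigma: np.ndarray
    cell_types: np.ndarray

    def as_lattice(self) -> CellLattice:
        return CellLattice(self.sigma.copy(), self.cell_types.copy())


class SimulationResult:
    """State, trajectories and morphometrics of one finished run."""

    def __init__(self, config: SimulationConfig, seed: int,
                 lattice: CellLattice, field: ChemoattractantField,
                 snapshots: list[Snapshot], tracks: pd.DataFrame,
                 samples: pd.DataFrame):
        self.config = config
        self.seed = seed
        self.lattice = lattice
        self.field = field
        self.snapshots = snapshots
        self.tracks = tracks
        self.samples = samples
        self._report: mm.MorphometricsReport | None = None

    # -- derived quantities -------------------------------------------------
    def morphometrics(self) -> mm.MorphometricsReport:
        """Morphometrics of the final state (computed once, cached)."""
        if self._report is None:
            self._report = mm.analyze(self.lattice.binary_mask())
        return self._report

    def percent_sprout_tips_occupied(self) -> float:
        return sa.percent_sprout_tips_occupied(self.lattice)

    def sprout_count(self) -> int:
        return sa.count_sprouts(self.lattice.binary_mask())

    def realized_tip_fraction(self) -> float:
        return self.lattice.realized_tip_fraction()

    def centroid_track(self, cell_id: int) -> np.ndarray:
        """(x, y) positions of one cell over time, in site units."""
        t = self.tracks[self.tracks.cell_id == cell_id]
        return t[["x", "y"]].to_numpy()

    def pair_centroid_track(self) -> np.ndarray:
        """Mean position of all cells per sampled MCS (for pair migration)."""
        g = self.tracks.groupby("mcs")[["x", "y"]].mean()
        return g.to_numpy()

    # -- presentation -------------------------------------------------------
    def summary(self) -> str:
        rep = self.morphometrics()
        sd = rep.lacuna_area_sd
        try:
            occ = f"{self.percent_sprout_tips_occupied():.1f} %"
        except mm.UndefinedValueError:
            occ = "undefined (no valid sprouts)"
        rows = [
            ("mode", self.config.mode),
            ("seed", self.seed),
            ("MCS run", self.config.n_mcs),
            ("cells (final)", self.lattice.n_cells),
            ("realized tip fraction", f"{self.realized_tip_fraction():.3f}"),
            ("compactness C", f"{rep.compactness:.4f}"),
            ("lacunae", rep.n_lacunae),
            ("lacuna area SD [sites]",
             "undefined" if sd is None else f"{sd:.1f}"),
            ("branch points", rep.n_branch_points),
            ("end points", rep.n_end_points),
            ("sprout count", self.sprout_count()),
            ("sprout tips occupied", occ),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Angiogenesis simulation summary",
                 "=" * (width + 24)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)

    def plot(self, ax=None, show_field: bool = False):
        """Render the final lattice (and optionally the field) to an axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if show_field:
            ax.imshow(self.field.c, cmap="viridis")
        ax.imshow(_io.snapshot_image(self.lattice), cmap="gray",
                  vmin=0, vmax=255, alpha=0.9 if show_field else 1.0)
        ax.set_axis_off()
        return ax

    def save(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.save_snapshot_png(self.lattice, out / "final.png")
        _io.save_snapshot_png(self.lattice, out / "final_blinded.png",
                              blinded=True)
        _io.save_grid_dump(self.lattice.sigma, out / "final_sigma.txt")
        _io.save_field_csv(self.field.c, out / "final_field.csv")
        _io.save_field_png(self.field.c, out / "final_field.png")
        _io.save_tracks_csv(self.tracks, out / "tracks.csv")
        self.samples.to_csv(out / "samples.csv", index=False)
        from .tip_selection import cell_state_table

        cell_state_table(self.lattice, self.config.notch).to_csv(
            out / "final_cells.csv", index=False)
        sa.sprout_table(self.lattice, mcs=self.config.n_mcs).to_csv(
            out / "final_sprouts.csv", index=False)
        _io.save_run_metadata(out / "metadata.json",
                              self.config.to_flat_dict(), self.seed)


class AngiogenesisModel:
    """Cell-based model of angiogenic sprouting.

    Endothelial cells on a Potts lattice secrete an autocrine chemoattractant
    and chemotact up its gradient at cell–ECM interfaces only; tip and stalk
    cells may differ in sensitivity, secretion, adhesion or motility, with
    identities fixed (static mode) or selected by Dll4–Notch lateral
    inhibition (dynamic mode).
    """

    def __init__(self, config: SimulationConfig | None = None, **overrides):
        config = config or SimulationConfig()
        if overrides:
            config = config.replace(**overrides)
        config.validate()
        self.config = config

    @classmethod
    def from_file(cls, path) -> "AngiogenesisModel":
        return cls(SimulationConfig.from_file(path))

    @classmethod
    def from_dict(cls, data: dict) -> "AngiogenesisModel":
        return cls(SimulationConfig.from_dict(data))

    def initialize(self, seed: int) -> tuple[CellLattice, ChemoattractantField]:
        """Blob initialization plus type assignment (kernel RNG not seeded)."""
        cfg = self.config
        ss = np.random.SeedSequence(seed)
        blob_seed, type_seed, _ = ss.spawn(3)
        lattice = initialize_blob(cfg.n_cells, cfg.lattice_dims, cfg.cpm,
                                  seed=blob_seed, margin=cfg.blob_margin)
        if cfg.mode == "static":
            assign_static_types(lattice, cfg.f_tip,
                                np.random.default_rng(type_seed))
        # dynamic mode starts all-stalk; the NICD rule takes over per MCS
        return lattice, ChemoattractantField.for_lattice(lattice)

    def run(self, seed: int | None = None) -> SimulationResult:
        """Run ``n_mcs`` Monte Carlo steps and collect the trajectory."""
        cfg = self.config
        if seed is None:
            seed = cfg.seed if cfg.seed is not None else 0
        lattice, field = self.initialize(seed)
        kernel_seed = int(
            np.random.SeedSequence(seed).spawn(3)[2].generate_state(1)[0]
            % (2**31))
        seed_rng(kernel_seed)
        ka = _KernelArgs(cfg)

        snapshots: list[Snapshot] = []
        track_rows: list[tuple] = []
        sample_rows: list[dict] = []

        def record(mcs: int) -> None:
            if cfg.snapshot_interval > 0 and mcs % cfg.snapshot_interval == 0:
                snapshots.append(Snapshot(mcs, lattice.sigma.copy(),
                                          lattice.cell_types.copy()))
                mask = lattice.binary_mask()
                try:
                    comp = mm.compactness(mask)
                except mm.UndefinedValueError:
                    comp = float("nan")
                sample_rows.append({
                    "mcs": mcs,
                    "compactness": comp,
                    "n_lacunae": len(mm.label_lacunae(mask)),
                    "realized_tip_fraction": lattice.realized_tip_fraction(),
                })
            if cfg.track_interval > 0 and mcs % cfg.track_interval == 0:
                for cid, (x, y) in lattice.centroids().items():
                    track_rows.append(
                        (mcs, cid, TYPE_NAMES[int(lattice.cell_types[cid])],
                         x, y))

        record(0)
        for mcs in range(1, cfg.n_mcs + 1):
            run_mcs(lattice, field, cfg, kernel_args=ka)
            record(mcs)

        tracks = pd.DataFrame(
            track_rows, columns=["mcs", "cell_id", "cell_type", "x", "y"])
        samples = pd.DataFrame(
            sample_rows, columns=["mcs", "compactness", "n_lacunae",
                                  "realized_tip_fraction"])
        return SimulationResult(cfg, seed, lattice, field, snapshots,
                                tracks, samples)


def run_simulation(config: SimulationConfig, seed: int | None = None
                   ) -> SimulationResult:
    """Functional entry point: run one simulation from a config."""
    return AngiogenesisModel(config).run(seed)
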