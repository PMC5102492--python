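"""Model parameters and run configuration.

The simulator couples a two-dimensional cellular Potts model (CPM) of
endothelial cells to an autocrine chemoattractant field and a Notch-based
tip/stalk selection rule.  Every symbol of the Hamiltonian, the
reaction--diffusion equation and the lateral-inhibition rule lives here, with
the published nominal values as defaults: one lattice site is a 2 μm × 2 μm
patch, the cell target area is 100 sites (400 μm²), and one Monte Carlo step
(MCS) corresponds to 30 s of simulated time (15 forward-Euler steps of 2 s).

Configs are plain TOML or JSON files whose keys mirror the parameter symbols
(``j_tip_stalk``, ``chi_tip``, ``alpha_stalk``, ``theta_nicd``, ``f_tip``,
...), plus run settings (``lattice_dims``, ``n_cells``, ``n_mcs``,
``snapshot_interval``, ``seed``, ``mode``).
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Cell-type codes used throughout the lattice arrays.
ECM, STALK, TIP = 0, 1, 2
TYPE_NAMES = {ECM: "ecm", STALK: "stalk", TIP: "tip"}

#: Physical side length of one lattice site, in micrometres.
LATTICE_SPACING_UM = 2.0


class ParameterError(ValueError):
    """An invalid or inconsistent parameter value."""


class ConfigurationError(ValueError):
    """A run configuration that cannot be realized (e.g. blob does not fit)."""


class StabilityError(ParameterError):
    """The explicit diffusion scheme would be unstable for these parameters."""


@dataclass
class CPMParameters:
    """Contact energies, area constraint and motilities of the Potts model.

    ``J(τ, τ′)`` is symmetric; ``A(τ)`` is the target area in lattice sites;
    ``λ(τ)`` the area elasticity; ``μ(τ)`` the cellular-temperature-like
    motility entering the acceptance function.  ``μ(ECM) = 0`` so that for a
    cell–ECM copy the "max" branch of the acceptance temperature resolves to
    the participating cell's motility.
    """

    j_tip_tip: float = 40.0
    j_tip_stalk: float = 40.0
    j_stalk_stalk: float = 40.0
    j_tip_ecm: float = 20.0
    j_stalk_ecm: float = 20.0
    lambda_tip: float = 25.0
    lambda_stalk: float = 25.0
    a_tip: float = 100.0
    a_stalk: float = 100.0
    mu_tip: float = 50.0
    mu_stalk: float = 50.0
    mu_ecm: float = 0.0
    #: count each unordered adjacent site pair once (default) or twice in Eq. (1)
    count_pairs_once: bool = True

    def validate(self) -> None:
        if self.a_tip < 0 or self.a_stalk < 0:
            raise ParameterError("target areas must be >= 0")
        if self.lambda_tip < 0 or self.lambda_stalk < 0:
            raise ParameterError("elasticity parameters must be >= 0")
        if self.mu_tip <= 0 or self.mu_stalk <= 0:
            raise ParameterError("cell motilities must be > 0")
        if self.mu_ecm < 0:
            raise ParameterError("mu_ecm must be >= 0")

    def contact_energy_table(self) -> np.ndarray:
        """Symmetric 3x3 array J[τ, τ′] over type codes (ECM, stalk, tip)."""
        j = np.zeros((3, 3))
        j[STALK, STALK] = self.j_stalk_stalk
        j[TIP, TIP] = self.j_tip_tip
        j[TIP, STALK] = j[STALK, TIP] = self.j_tip_stalk
        j[STALK, ECM] = j[ECM, STALK] = self.j_stalk_ecm
        j[TIP, ECM] = j[ECM, TIP] = self.j_tip_ecm
        return j

    def elasticity_array(self) -> np.ndarray:
        return np.array([0.0, self.lambda_stalk, self.lambda_tip])

    def target_area_array(self) -> np.ndarray:
        return np.array([0.0, self.a_stalk, self.a_tip])

    def motility_array(self) -> np.ndarray:
        return np.array([self.mu_ecm, self.mu_stalk, self.mu_tip])


@dataclass
class ChemoParameters:
    """Chemoattractant dynamics and the chemotaxis energy term.

    The field obeys ∂c/∂t = D ∇²c + α(τ) inside cells − ε c in the ECM, solved
    with a forward Euler scheme (`steps_per_mcs` steps of `dt` seconds per
    MCS) on the CPM lattice with absorbing boundaries.  ``χ(τ)`` is the
    chemoattractant sensitivity used in the contact-inhibited chemotaxis term,
    which acts only at cell–ECM interfaces; ``saturation`` is the receptor
    saturation ``s`` (0 for the nominal runs).
    """

    diffusion: float = 1e-13  # m^2/s
    alpha_tip: float = 1e-3  # s^-1 (field units per second below a cell)
    alpha_stalk: float = 1e-3
    epsilon_ecm: float = 1e-3  # s^-1, decay in ECM only
    dx: float = LATTICE_SPACING_UM * 1e-6  # m
    dt: float = 2.0  # s
    steps_per_mcs: int = 15
    chi_tip: float = 500.0
    chi_stalk: float = 500.0
    saturation: float = 0.0

    def validate(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ParameterError("dx and dt must be > 0")
        if min(self.diffusion, self.alpha_tip, self.alpha_stalk,
               self.epsilon_ecm, self.saturation) < 0:
            raise ParameterError("rates must be >= 0")
        if self.steps_per_mcs < 1:
            raise ParameterError("steps_per_mcs must be >= 1")
        n = self.diffusion_number()
        if n > 0.25:
            raise StabilityError(
                f"diffusion number D*dt/dx^2 = {n:.4g} exceeds 0.25; "
                "reduce dt or increase dx")

    def diffusion_number(self) -> float:
        """Stability number D·dt/dx² of the explicit scheme."""
        return self.diffusion * self.dt / self.dx**2

    @property
    def seconds_per_mcs(self) -> float:
        return self.steps_per_mcs * self.dt

    def alpha_array(self) -> np.ndarray:
        return np.array([0.0, self.alpha_stalk, self.alpha_tip])

    def chi_array(self) -> np.ndarray:
        return np.array([0.0, self.chi_stalk, self.chi_tip])


@dataclass
class NotchParameters:
    """Dll4–Notch lateral-inhibition parameters of the tip-selection rule.

    Tip cells carry more membrane Dll4 than stalk cells (D(tip)=4, D(stalk)=1)
    while expressing less Notch (N(tip)=0.3 < N(stalk)=0.5); the Notch
    asymmetry gives the type-switching rule a hysteresis band.  A cell becomes
    (or stays) tip when its NICD level I(σ) ≤ Θ_NICD, else stalk.
    """

    notch_tip: float = 0.3
    notch_stalk: float = 0.5
    delta_tip: float = 4.0
    delta_stalk: float = 1.0
    theta_nicd: float = 0.2
    #: adjacency used for interface lengths (4 = edge-sharing site pairs)
    interface_connectivity: int = 4

    def validate(self) -> None:
        if min(self.notch_tip, self.notch_stalk,
               self.delta_tip, self.delta_stalk) < 0:
            raise ParameterError("Notch/Delta levels must be >= 0")
        if not self.notch_tip < self.notch_stalk:
            raise ParameterError("hysteresis requires N(tip) < N(stalk)")
        if not self.delta_tip > self.delta_stalk:
            raise ParameterError("tip cells must express more Delta: D(tip) > D(stalk)")
        if self.interface_connectivity not in (4, 8):
            raise ParameterError("interface_connectivity must be 4 or 8")

    def notch_array(self) -> np.ndarray:
        return np.array([0.0, self.notch_stalk, self.notch_tip])

    def delta_array(self) -> np.ndarray:
        return np.array([0.0, self.delta_stalk, self.delta_tip])


@dataclass
class SimulationConfig:
    """Complete run configuration: parameters plus lattice and schedule."""

    lattice_width: int = 200
    lattice_height: int = 200
    n_cells: int = 50
    n_mcs: int = 10_000
    snapshot_interval: int = 100
    track_interval: int = 10
    mode: str = "static"  # "static" (fixed F_tip) or "dynamic" (NICD selection)
    f_tip: float = 0.2
    seed: int | None = None
    blob_margin: int = 10
    cpm: CPMParameters = field(default_factory=CPMParameters)
    chemo: ChemoParameters = field(default_factory=ChemoParameters)
    notch: NotchParameters = field(default_factory=NotchParameters)

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")
        if self.mode not in ("static", "dynamic"):
            raise ConfigurationError("mode must be 'static' or 'dynamic'")
        if not 0.0 <= self.f_tip <= 1.0:
            raise ConfigurationError("f_tip must lie in [0, 1]")
        if self.n_mcs < 0:
            raise ConfigurationError("n_mcs must be >= 0")
        self.cpm.validate()
        self.chemo.validate()
        self.notch.validate()

    @property
    def lattice_dims(self) -> tuple[int, int]:
        return (self.lattice_width, self.lattice_height)

    def replace(self, **kwargs) -> "SimulationConfig":
        """Copy with flat parameter overrides (keys as in the config file)."""
        d = self.to_flat_dict()
        d.update(kwargs)
        return SimulationConfig.from_dict(d)

    def to_flat_dict(self) -> dict:
        d = {}
        for obj in (self, self.cpm, self.chemo, self.notch):
            for f in dataclasses.fields(obj):
                if f.name in ("cpm", "chemo", "notch"):
                    continue
                d[f.name] = getattr(obj, f.name)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "lattice_dims" in data:
            w, h = data.pop("lattice_dims")
            data["lattice_width"], data["lattice_height"] = int(w), int(h)
        groups = {"cpm": {}, "chemo": {}, "notch": {}, "top": {}}
        names = {
            "cpm": {f.name for f in dataclasses.fields(CPMParameters)},
            "chemo": {f.name for f in dataclasses.fields(ChemoParameters)},
            "notch": {f.name for f in dataclasses.fields(NotchParameters)},
            "top": {f.name for f in dataclasses.fields(cls)} - {"cpm", "chemo", "notch"},
        }
        for key, value in data.items():
            for group, members in names.items():
                if key in members:
                    groups[group][key] = value
                    break
            else:
                raise ConfigurationError(f"unrecognized config key: {key!r}")
        cfg = cls(
            cpm=CPMParameters(**groups["cpm"]),
            chemo=ChemoParameters(**groups["chemo"]),
            notch=NotchParameters(**groups["notch"]),
            **groups["top"],
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        if path.suffix.lower() == ".json":
            data = json.loads(path.read_text())
        else:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        return cls.from_dict(data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_flat_dict(), indent=2))
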