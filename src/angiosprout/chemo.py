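"""Autocrine chemoattractant dynamics and contact-inhibited chemotaxis.

Endothelial cells secrete a diffusive chemoattractant (Apelin in the
biological reading) at rate α(τ); the field decays at rate ε in the ECM only
and is absorbed at the lattice boundary (c = 0 on the boundary ring).  The
concentration obeys

    ∂c/∂t = D ∇²c + α(τ(σ(x)))·1[σ(x) > 0] − ε·1[σ(x) = 0]·c

and is advanced by an explicit forward-Euler scheme with a 5-point Laplacian,
``steps_per_mcs`` steps of ``dt`` seconds after every Monte Carlo step.

Chemotaxis enters the Potts dynamics as an energy bias at cell–ECM interfaces
only (contact inhibition): a copy attempt from site x into x′ contributes

    ΔH_chemotaxis = −χ · (c(x′)/(1 + s·c(x′)) − c(x)/(1 + s·c(x)))

with χ the sensitivity of the participating cell and s the receptor
saturation.
"""

from __future__ import annotations

import numpy as np

from .lattice import CellLattice
from .params import ChemoParameters


class ChemoattractantField:
    """Non-negative concentration grid co-registered with the cell lattice."""

    def __init__(self, shape: tuple[int, int], c: np.ndarray | None = None):
        if c is None:
            c = np.zeros(shape)
        self.c = np.ascontiguousarray(c, dtype=np.float64)
        if self.c.shape != tuple(shape):
            raise ValueError("field shape mismatch")

    @classmethod
    def for_lattice(cls, lattice: CellLattice) -> "ChemoattractantField":
        return cls(lattice.shape)

    def total_mass(self) -> float:
        return float(self.c.sum())

    def copy(self) -> "ChemoattractantField":
        return ChemoattractantField(self.c.shape, self.c.copy())


def diffusion_number(p: ChemoParameters) -> float:
    """Return the stability number D·dt/dx² (must be ≤ 0.25).

    Raises :class:`~angiosprout.params.StabilityError` via ``p.validate()``
    when the bound is exceeded.
    """
    p.validate()
    return p.diffusion_number()


def evolve_chemoattractant(field: ChemoattractantField, lattice: CellLattice,
                           p: ChemoParameters,
                           n_steps: int | None = None) -> ChemoattractantField:
    """Advance the field by one MCS worth of Euler steps, in place.

    Under the stability bound the scheme preserves non-negativity, so no
    clamping is applied.  Boundary sites are reset to 0 after every step
    (absorbing boundaries).
    """
    from . import _kernels

    if field.c.shape != lattice.shape:
        raise ValueError("field and lattice dimensions differ")
    if n_steps is None:
        n_steps = p.steps_per_mcs
    k = p.diffusion_number()
    source = p.dt * p.alpha_array()[lattice.type_grid()]
    ecm_decay = p.dt * p.epsilon_ecm * (lattice.sigma == 0).astype(np.float64)
    _kernels.euler_steps(field.c, source, ecm_decay, k, n_steps)
    return field


def chemotaxis_delta_h(c_target: float, c_source: float, chi: float,
                       s: float = 0.0) -> float:
    """Energy change of a copy attempt due to chemotaxis (Eq. above).

    Only called when exactly one of the copy participants is ECM; ``chi`` is
    the sensitivity of the cell taking part.  Negative for extensions up the
    gradient, making them more likely to be accepted.
    """
    return -chi * (c_target / (1.0 + s * c_target)
                   - c_source / (1.0 + s * c_source))
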