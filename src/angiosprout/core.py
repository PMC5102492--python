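"""Cellular Potts engine: Hamiltonian, copy dynamics and the MCS loop.

The model Hamiltonian is

    H = Σ_(x,x′) J(τ, τ′) (1 − δ(σ, σ′))  +  Σ_σ λ(τ) (a(σ) − A(τ))²

with the first sum over unordered pairs of 8-adjacent lattice sites (both
inside the box) and the second over all cells.  A copy attempt that changes
the energy by ΔH is accepted with probability 1 if ΔH ≤ 0 and
exp(−ΔH / f) otherwise, where f is the motility min(μ(τ), μ(τ′)) for a
cell–cell copy and max(μ(τ), μ(τ′)) otherwise (so a cell–ECM copy uses the
cell's motility, since μ(ECM) = 0).  One Monte Carlo step (MCS) consists of
as many random copy attempts as there are lattice sites, followed by one
chemoattractant update and — in dynamic mode — one tip/stalk selection pass.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .chemo import ChemoattractantField, evolve_chemoattractant
from .lattice import CellLattice
from .params import ParameterError, SimulationConfig


def hamiltonian(lattice: CellLattice, params, count_pairs_once: bool | None = None
                ) -> float:
    """Full evaluation of the Hamiltonian (adhesion + area constraint).

    Used as the reference for the incremental ΔH of the copy kernel; the
    chemotaxis bias is a ΔH-only term and is not part of H.
    """
    J = params.contact_energy_table()
    if count_pairs_once is None:
        count_pairs_once = params.count_pairs_once
    sig = lattice.sigma
    tg = lattice.type_grid()
    adhesion = 0.0
    # four shift directions cover each unordered 8-neighbor pair exactly once
    pairs = (
        (sig[:, :-1], tg[:, :-1], sig[:, 1:], tg[:, 1:]),
        (sig[:-1, :], tg[:-1, :], sig[1:, :], tg[1:, :]),
        (sig[:-1, :-1], tg[:-1, :-1], sig[1:, 1:], tg[1:, 1:]),
        (sig[:-1, 1:], tg[:-1, 1:], sig[1:, :-1], tg[1:, :-1]),
    )
    for s1, t1, s2, t2 in pairs:
        mism = s1 != s2
        adhesion += float(J[t1[mism], t2[mism]].sum())
    if not count_pairs_once:
        adhesion *= 2.0

    lam = params.elasticity_array()
    At = params.target_area_array()
    ids = lattice.cell_ids()
    ct = lattice.cell_types[ids]
    area_term = float(np.sum(lam[ct] * (lattice.areas[ids] - At[ct]) ** 2))
    return adhesion + area_term


def copy_attempt_delta_h(lattice: CellLattice, field: ChemoattractantField,
                         params, source: tuple[int, int],
                         target: tuple[int, int],
                         chemo_params=None) -> float:
    """Incremental ΔH of copying σ(source) into target (8-neighbor sites).

    ``source`` and ``target`` are (y, x) site coordinates with
    σ(source) ≠ σ(target).  The chemotaxis term is included when exactly one
    participant is ECM; pass ``chemo_params`` for the sensitivities (χ ≡ 0
    when omitted).
    """
    ys, xs = source
    yt, xt = target
    if max(abs(ys - yt), abs(xs - xt)) != 1:
        raise ValueError("source and target must be 8-neighbors")
    if lattice.sigma[ys, xs] == lattice.sigma[yt, xt]:
        raise ValueError("same-cell copy attempts are rejected upstream")
    if chemo_params is not None:
        chi = chemo_params.chi_array()
        sat = chemo_params.saturation
    else:
        chi = np.zeros(3)
        sat = 0.0
    pair_factor = 1.0 if params.count_pairs_once else 2.0
    return float(_kernels.delta_h_site(
        lattice.sigma, lattice.cell_types, lattice.areas, field.c,
        params.contact_energy_table(), params.elasticity_array(),
        params.target_area_array(), chi, sat,
        ys, xs, yt, xt, pair_factor))


def accept_probability(delta_h: float, f: float) -> float:
    """Metropolis-style acceptance: 1 if ΔH ≤ 0, else exp(−ΔH / f)."""
    if f <= 0:
        raise ParameterError("acceptance temperature f must be > 0")
    if delta_h <= 0:
        return 1.0
    return float(np.exp(-delta_h / f))


class _KernelArgs:
    """Parameter arrays packed once per run for the numba kernel."""

    def __init__(self, config: SimulationConfig):
        self.J = config.cpm.contact_energy_table()
        self.lam = config.cpm.elasticity_array()
        self.At = config.cpm.target_area_array()
        self.mu = config.cpm.motility_array()
        self.chi = config.chemo.chi_array()
        self.sat = config.chemo.saturation
        self.pair_factor = 1.0 if config.cpm.count_pairs_once else 2.0


def run_mcs(lattice: CellLattice, field: ChemoattractantField,
            config: SimulationConfig, kernel_args: _KernelArgs | None = None,
            update_types: bool = True) -> None:
    """Advance the coupled system by one Monte Carlo step, in place.

    Performs |Λ| copy attempts, then one chemoattractant update, then (in
    dynamic mode, unless ``update_types`` is False) one synchronous tip/stalk
    selection pass.  The caller is responsible for seeding the kernel RNG
    (see :func:`seed_rng`).
    """
    from .tip_selection import update_cell_types

    ka = kernel_args or _KernelArgs(config)
    _kernels.run_mcs_kernel(lattice.sigma, lattice.cell_types, lattice.areas,
                            field.c, ka.J, ka.lam, ka.At, ka.mu, ka.chi,
                            ka.sat, ka.pair_factor)
    evolve_chemoattractant(field, lattice, config.chemo)
    if config.mode == "dynamic" and update_types:
        update_cell_types(lattice, config.notch)


def seed_rng(seed: int) -> None:
    """Seed the copy-attempt kernel's RNG (numba's per-thread stream)."""
    _kernels.seed_kernel_rng(int(seed) % (2**31))
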