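"""Tip/stalk cell identity: static fractions and NICD lateral inhibition.

In static mode a fraction F_tip of the cells is predefined as tip cells and
never changes.  In dynamic mode each cell's NICD level is recomputed every
MCS from the Dll4 (Delta) presented by its contact neighbors,

    I(σ) = N(τ(σ)) / a(σ) · Σ_n D(τ(n)) · L_{σ∩n},

and the cell becomes tip if I(σ) ≤ Θ_NICD, stalk otherwise.  Because
N(tip) = 0.3 < N(stalk) = 0.5 the effective switching threshold differs by
current type, which gives the rule hysteresis and prevents rapid flipping.
"""

from __future__ import annotations

import numpy as np

from .lattice import CellLattice
from .params import ECM, STALK, TIP, NotchParameters


def assign_static_types(lattice: CellLattice, f_tip: float,
                        seed: int | np.random.Generator) -> int:
    """Set round(f_tip · n) uniformly chosen cells to tip, the rest to stalk.

    Rounding is round-half-up.  Returns the number of tip cells assigned.
    """
    if not 0.0 <= f_tip <= 1.0:
        raise ValueError("f_tip must lie in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = lattice.cell_ids()
    n_tip = int(np.floor(f_tip * len(ids) + 0.5))
    lattice.cell_types[ids] = STALK
    if n_tip > 0:
        chosen = rng.choice(ids, size=n_tip, replace=False)
        lattice.cell_types[chosen] = TIP
    return n_tip


def _interface_pairs(lattice: CellLattice, connectivity: int = 4):
    """Arrays (sa, sb) of σ values of adjacent site pairs with σa ≠ σb."""
    sig = lattice.sigma
    shifts = [(sig[:, :-1], sig[:, 1:]), (sig[:-1, :], sig[1:, :])]
    if connectivity == 8:
        shifts += [(sig[:-1, :-1], sig[1:, 1:]), (sig[:-1, 1:], sig[1:, :-1])]
    sa, sb = [], []
    for s1, s2 in shifts:
        m = s1 != s2
        sa.append(s1[m])
        sb.append(s2[m])
    return np.concatenate(sa), np.concatenate(sb)


def interface_length(lattice: CellLattice, cell_a: int, cell_b: int,
                     connectivity: int = 4) -> int:
    """Number of adjacent site pairs with one site in each cell (symmetric)."""
    sa, sb = _interface_pairs(lattice, connectivity)
    return int(np.count_nonzero((sa == cell_a) & (sb == cell_b))
               + np.count_nonzero((sa == cell_b) & (sb == cell_a)))


def _delta_contact_sums(lattice: CellLattice, notch: NotchParameters
                        ) -> np.ndarray:
    """Σ_n D(τ(n))·L_{σ∩n} for every cell id (ECM neighbors contribute 0)."""
    delta = notch.delta_array()
    sa, sb = _interface_pairs(lattice, notch.interface_connectivity)
    cellcell = (sa > 0) & (sb > 0)
    sa, sb = sa[cellcell], sb[cellcell]
    n = len(lattice.cell_types)
    sums = np.zeros(n)
    np.add.at(sums, sa, delta[lattice.cell_types[sb]])
    np.add.at(sums, sb, delta[lattice.cell_types[sa]])
    return sums


def compute_nicd(lattice: CellLattice, cell: int,
                 notch: NotchParameters) -> float:
    """NICD level I(σ) of one cell, using its current type's Notch level."""
    area = int(lattice.areas[cell])
    if area <= 0:
        raise ValueError(f"cell {cell} has no sites")
    sums = _delta_contact_sums(lattice, notch)
    n_level = notch.notch_array()[lattice.cell_types[cell]]
    return float(n_level / area * sums[cell])


def nicd_levels(lattice: CellLattice, notch: NotchParameters) -> np.ndarray:
    """I(σ) for all cell ids at once (entry 0 and absent ids are 0)."""
    sums = _delta_contact_sums(lattice, notch)
    levels = np.zeros(len(lattice.cell_types))
    ids = lattice.cell_ids()
    n_arr = notch.notch_array()
    levels[ids] = (n_arr[lattice.cell_types[ids]] / lattice.areas[ids]
                   * sums[ids])
    return levels


def cell_state_table(lattice: CellLattice, notch: NotchParameters):
    """Per-cell snapshot table: cell_id, type, area and NICD level."""
    import pandas as pd

    from .params import TYPE_NAMES

    levels = nicd_levels(lattice, notch)
    ids = lattice.cell_ids()
    return pd.DataFrame({
        "cell_id": ids,
        "type": [TYPE_NAMES[int(t)] for t in lattice.cell_types[ids]],
        "area": lattice.areas[ids],
        "nicd": levels[ids],
    })


def update_cell_types(lattice: CellLattice, notch: NotchParameters) -> int:
    """One synchronous tip/stalk selection pass; returns the change count.

    All NICD levels are computed against the pre-pass type map (each cell
    using its *current* type's Notch level — the hysteresis), then every cell
    is set to tip if I(σ) ≤ Θ_NICD and to stalk otherwise.
    """
    ids = lattice.cell_ids()
    if len(ids) == 0:
        return 0
    levels = nicd_levels(lattice, notch)
    new_types = np.where(levels[ids] <= notch.theta_nicd, TIP, STALK)
    changed = int(np.count_nonzero(new_types != lattice.cell_types[ids]))
    lattice.cell_types[ids] = new_types
    return changed
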