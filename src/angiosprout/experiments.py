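"""Computational experiments: screening, controls, pair migration, Apelin.

Reproduces the paper-style in-silico experiments at a configurable scale:

* one-at-a-time parameter screening of tip-cell behavior, read out as the
  percentage of sprout tips occupied by tip cells and as network morphology
  (compactness, lacuna count), each condition compared with the
  identical-cells control by Welch's t-test;
* the averaged-parameter control model (one cell type with
  P = (1 − F_tip)·P(stalk) + F_tip·P(tip));
* migration of a tip–stalk cell pair quantified by the McCutcheon index
  (net displacement over path length);
* the NICD-threshold × χ(tip) morphospace of the dynamic selection model;
* the in-silico Apelin (chemoattractant) inhibition assay: sprout counts at
  750 MCS with and without 90% secretion knockdown, for a tip/stalk mix
  (Θ_NICD = 0.2) and a stalk-only population (Θ_NICD = 0).

Desk-scale defaults (small lattice, 2000 MCS, 10 replicates) keep every
experiment workstation-sized; ``scale="full"`` restores the cluster-scale
settings (10 000 MCS, 50–100 replicates).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import AngiogenesisModel
from .morphometrics import UndefinedValueError
from .params import SimulationConfig

#: Parameters that may be swept one at a time (tip behavior screen).
SWEEPABLE = ("mu_tip", "j_tip_ecm", "j_tip_stalk", "chi_tip", "alpha_tip",
             "j_stalk_ecm", "theta_nicd")


# ---------------------------------------------------------------------------
# statistics helpers

def averaged_parameters(p_tip: float, p_stalk: float, f_tip: float) -> float:
    """Single-cell-type control value: (1 − F_tip)·P(stalk) + F_tip·P(tip)."""
    if not 0.0 <= f_tip <= 1.0:
        raise ValueError("f_tip must lie in [0, 1]")
    return (1.0 - f_tip) * p_stalk + f_tip * p_tip


def welch_t_test(a, b, sided: str = "two") -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, p).

    ``sided="one"`` tests H1: mean(a) > mean(b).  With zero variance in both
    samples and equal means the test is uninformative: t = 0, one-sided
    p = 0.5 (two-sided p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per sample")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 0.5 if sided == "one" else 1.0
        t = np.inf if a.mean() > b.mean() else -np.inf
        if sided == "one":
            return float(t), df, 0.0 if t > 0 else 1.0
        return float(t), df, 0.0
    alternative = "greater" if sided == "one" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mccutcheon_index(track: np.ndarray) -> float:
    """Net displacement over total path length of a centroid track ∈ [0, 1].

    1 for straight-line motion, 0 for a closed loop; undefined (raises) for
    fewer than two samples or zero path length.
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or len(track) < 2:
        raise UndefinedValueError("need at least two track samples")
    steps = np.linalg.norm(np.diff(track, axis=0), axis=1)
    total = float(steps.sum())
    if total == 0.0:
        raise UndefinedValueError("zero path length: index undefined")
    net = float(np.linalg.norm(track[-1] - track[0]))
    return net / total


def _seeds(base_seed: int, n: int, tag: str) -> list[int]:
    """Deterministic per-replicate seeds (< 2^31) for one experiment arm."""
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(tag.encode())])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# replicate harness

@dataclass
class ReplicateSummary:
    """Read-outs of one finished replicate (reproducible from config+seed)."""

    seed: int
    compactness: float
    n_lacunae: int
    lacuna_area_sd: float  # nan when no lacunae
    n_branch_points: int
    n_end_points: int
    sprout_count: int
    percent_occupied: float  # nan when no valid sprouts
    realized_tip_fraction: float


def run_replicate(config: SimulationConfig, seed: int) -> ReplicateSummary:
    """Run one simulation and compute all standard read-outs."""
    result = AngiogenesisModel(config).run(seed)
    rep = result.morphometrics()
    try:
        occupied = result.percent_sprout_tips_occupied()
    except UndefinedValueError:
        occupied = float("nan")
    sd = rep.lacuna_area_sd
    return ReplicateSummary(
        seed=seed,
        compactness=rep.compactness,
        n_lacunae=rep.n_lacunae,
        lacuna_area_sd=float("nan") if sd is None else sd,
        n_branch_points=rep.n_branch_points,
        n_end_points=rep.n_end_points,
        sprout_count=result.sprout_count(),
        percent_occupied=occupied,
        realized_tip_fraction=result.realized_tip_fraction(),
    )


def _summaries_frame(summaries: list[ReplicateSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def desk_config(**overrides) -> SimulationConfig:
    """Desk-scale base configuration: 150×150 lattice, 50 cells, 2000 MCS."""
    base = dict(lattice_width=150, lattice_height=150, n_cells=50,
                n_mcs=2000, snapshot_interval=500, track_interval=100)
    base.update(overrides)
    return SimulationConfig.from_dict(base)


def full_config(**overrides) -> SimulationConfig:
    """Full-scale configuration: 200×200 lattice, 50 cells, 10 000 MCS."""
    base = dict(lattice_width=200, lattice_height=200, n_cells=50,
                n_mcs=10_000, snapshot_interval=500, track_interval=100)
    base.update(overrides)
    return SimulationConfig.from_dict(base)


# ---------------------------------------------------------------------------
# parameter screen

@dataclass
class SweepSpec:
    """One-at-a-time sweep of a tip-cell parameter.

    ``parameter`` must be one of the sweepable config keys; each value is run
    for every tip fraction with ``replicates`` replicates and compared with
    the identical-cells control (and, optionally, with the averaged-parameter
    control model).
    """

    parameter: str
    values: list[float]
    tip_fractions: list[float] = field(default_factory=lambda: [0.2])
    replicates: int = 10
    averaged_control: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"parameter must be one of {SWEEPABLE}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for any test")


def _stalk_counterpart(name: str) -> str:
    return name.replace("tip", "stalk")


def run_screen(spec: SweepSpec, base_config: SimulationConfig | None = None
               ) -> pd.DataFrame:
    """Run the tip-cell behavior screen against the identical-cells control.

    For every (parameter value × tip fraction) condition the returned table
    holds mean ± SD of the percentage of occupied sprout tips, compactness and
    lacuna count, with Welch p-values against the control run at the same tip
    fraction: one-sided (greater) for occupancy, two-sided for the morphology
    measures.  With ``spec.averaged_control`` the single-cell-type
    averaged-parameter model is run and compared as well (two-sided).
    """
    spec.validate()
    base = base_config or desk_config()
    rows = []
    controls: dict[float, pd.DataFrame] = {}
    for f_tip in spec.tip_fractions:
        cfg = base.replace(f_tip=f_tip)
        summaries = [run_replicate(cfg, s)
                     for s in _seeds(spec.seed, spec.replicates,
                                     f"control-{f_tip}")]
        controls[f_tip] = _summaries_frame(summaries)

    for value in spec.values:
        for f_tip in spec.tip_fractions:
            cfg = base.replace(f_tip=f_tip, **{spec.parameter: value})
            frame = _summaries_frame(
                [run_replicate(cfg, s)
                 for s in _seeds(spec.seed, spec.replicates,
                                 f"{spec.parameter}-{value}-{f_tip}")])
            ctrl = controls[f_tip]
            row = {
                "parameter": spec.parameter,
                "value": value,
                "f_tip": f_tip,
                "n": spec.replicates,
            }
            occ = frame.percent_occupied.dropna()
            occ_ctrl = ctrl.percent_occupied.dropna()
            row["occupied_mean"] = occ.mean()
            row["occupied_sd"] = occ.std(ddof=1)
            row["occupied_control_mean"] = occ_ctrl.mean()
            if len(occ) >= 2 and len(occ_ctrl) >= 2:
                _, _, row["occupied_p_one_sided"] = welch_t_test(
                    occ, occ_ctrl, sided="one")
            else:
                row["occupied_p_one_sided"] = float("nan")
            for col in ("compactness", "n_lacunae"):
                row[f"{col}_mean"] = frame[col].mean()
                row[f"{col}_sd"] = frame[col].std(ddof=1)
                _, _, row[f"{col}_p"] = welch_t_test(
                    frame[col], ctrl[col], sided="two")
            if spec.averaged_control and spec.parameter != "theta_nicd":
                stalk_name = _stalk_counterpart(spec.parameter)
                p_stalk = getattr_flat(base, stalk_name)
                avg = averaged_parameters(value, p_stalk, f_tip)
                avg_cfg = base.replace(
                    f_tip=0.0, **{spec.parameter: avg, stalk_name: avg})
                avg_frame = _summaries_frame(
                    [run_replicate(avg_cfg, s)
                     for s in _seeds(spec.seed, spec.replicates,
                                     f"avg-{spec.parameter}-{value}-{f_tip}")])
                for col in ("compactness", "n_lacunae"):
                    row[f"{col}_avg_mean"] = avg_frame[col].mean()
                    _, _, row[f"{col}_p_vs_averaged"] = welch_t_test(
                        frame[col], avg_frame[col], sided="two")
            rows.append(row)
    return pd.DataFrame(rows)


def getattr_flat(config: SimulationConfig, key: str):
    return config.to_flat_dict()[key]


# ---------------------------------------------------------------------------
# cell-pair migration

def pair_config(**overrides) -> SimulationConfig:
    """Two cells (one tip, one stalk) on a roomy lattice, dense tracking."""
    base = dict(lattice_width=200, lattice_height=200, n_cells=2,
                n_mcs=2000, f_tip=0.5, mode="static",
                snapshot_interval=1000, track_interval=10)
    base.update(overrides)
    return SimulationConfig.from_dict(base)


def pair_migration_experiment(chi_tip_values=(0.0, 250.0, 500.0),
                              config: SimulationConfig | None = None,
                              n_replicates: int = 10,
                              seed: int = 0) -> pd.DataFrame:
    """Migration of a tip–stalk pair for a range of tip sensitivities.

    χ(stalk) stays at 500; each replicate tracks both centroids and the
    McCutcheon index is computed on the pair centroid (per-cell indices are
    reported alongside).  Returns one row per (χ(tip), replicate).
    """
    base = config or pair_config()
    rows = []
    for chi in chi_tip_values:
        cfg = base.replace(chi_tip=chi)
        for rep, s in enumerate(_seeds(seed, n_replicates, f"pair-{chi}")):
            result = AngiogenesisModel(cfg).run(s)
            row = {"chi_tip": chi, "replicate": rep, "seed": s}
            try:
                row["mccutcheon_pair"] = mccutcheon_index(
                    result.pair_centroid_track())
            except UndefinedValueError:
                row["mccutcheon_pair"] = float("nan")
            for cid in result.lattice.cell_ids():
                track = result.centroid_track(int(cid))
                name = result.tracks[result.tracks.cell_id == cid
                                     ].cell_type.iloc[0]
                try:
                    row[f"mccutcheon_{name}"] = mccutcheon_index(track)
                except UndefinedValueError:
                    row[f"mccutcheon_{name}"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def pair_migration_trend(table: pd.DataFrame) -> tuple[float, float]:
    """Spearman rank correlation of the pair McCutcheon index vs χ(tip)."""
    clean = table.dropna(subset=["mccutcheon_pair"])
    rho, p = stats.spearmanr(clean.chi_tip, clean.mccutcheon_pair)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# in-silico Apelin inhibition

def apelin_config(**overrides) -> SimulationConfig:
    """Dynamic-selection model with differential Apelin secretion.

    Tip cells secrete the chemoattractant ten times faster than stalk cells
    (α(tip) = 1e-2, α(stalk) = 1e-3 s⁻¹) and are five times less sensitive
    (χ(tip) = 100 vs χ(stalk) = 500); sprouting is assessed at 750 MCS.
    """
    base = dict(lattice_width=150, lattice_height=150, n_cells=50,
                n_mcs=750, mode="dynamic", theta_nicd=0.2,
                chi_tip=100.0, chi_stalk=500.0,
                alpha_tip=1e-2, alpha_stalk=1e-3,
                snapshot_interval=250, track_interval=250)
    base.update(overrides)
    return SimulationConfig.from_dict(base)


#: 90% knockdown of chemoattractant secretion (the siAPLN mimic).
APELIN_INHIBITED = {"alpha_tip": 1e-3, "alpha_stalk": 1e-4}


def apelin_inhibition_experiment(config: SimulationConfig | None = None,
                                 n_replicates: int = 20, seed: int = 0
                                 ) -> tuple[pd.DataFrame, dict]:
    """Four-arm in-silico siRNA assay: sprout counts at 750 MCS.

    Arms: Θ_NICD ∈ {0.2 (tip/stalk mix), 0 (all-stalk)} × {uninhibited,
    inhibited (α(tip) = 1e-3, α(stalk) = 1e-4 s⁻¹)}.  The same replicate
    seeds are used across arms.  Returns the per-replicate table and the
    one-sided Welch p-value (control > inhibited) per Θ_NICD.
    """
    base = config or apelin_config()
    seeds = _seeds(seed, n_replicates, "apelin")
    rows = []
    for theta in (0.2, 0.0):
        for inhibited in (False, True):
            cfg = base.replace(theta_nicd=theta,
                               **(APELIN_INHIBITED if inhibited else {}))
            for rep, s in enumerate(seeds):
                summary = run_replicate(cfg, s)
                rows.append({
                    "theta_nicd": theta,
                    "inhibited": inhibited,
                    "replicate": rep,
                    "seed": s,
                    "sprout_count": summary.sprout_count,
                    "realized_tip_fraction": summary.realized_tip_fraction,
                    "compactness": summary.compactness,
                })
    table = pd.DataFrame(rows)
    pvalues = {}
    for theta in (0.2, 0.0):
        ctrl = table.query("theta_nicd == @theta and not inhibited"
                           ).sprout_count
        inhib = table.query("theta_nicd == @theta and inhibited").sprout_count
        _, _, pvalues[theta] = welch_t_test(ctrl, inhib, sided="one")
    return table, pvalues


# ---------------------------------------------------------------------------
# NICD-threshold morphospace

def morphospace(theta_values, chi_tip_values,
                config: SimulationConfig | None = None,
                n_replicates: int = 3, seed: int = 0) -> pd.DataFrame:
    """Θ_NICD × χ(tip) grid of the dynamic-selection model's morphologies."""
    base = config or desk_config(mode="dynamic")
    rows = []
    for theta in theta_values:
        for chi in chi_tip_values:
            cfg = base.replace(theta_nicd=theta, chi_tip=chi)
            for rep, s in enumerate(
                    _seeds(seed, n_replicates, f"morpho-{theta}-{chi}")):
                summary = run_replicate(cfg, s)
                rows.append({
                    "theta_nicd": theta, "chi_tip": chi, "replicate": rep,
                    "seed": s, "compactness": summary.compactness,
                    "n_lacunae": summary.n_lacunae,
                    "n_branch_points": summary.n_branch_points,
                    "lacuna_area_sd": summary.lacuna_area_sd,
                    "realized_tip_fraction": summary.realized_tip_fraction,
                })
    return pd.DataFrame(rows)
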