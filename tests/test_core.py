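"""Potts engine: Hamiltonian, incremental ΔH, acceptance rule, MCS loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import angiosprout as ag
from angiosprout import (ChemoattractantField, accept_probability,
                         copy_attempt_delta_h, hamiltonian)
from angiosprout.core import _KernelArgs, run_mcs
from angiosprout.params import CPMParameters, ParameterError, SimulationConfig
from conftest import lattice_from_sigma, random_small_state


class TestHamiltonian:
    def test_all_ecm_is_zero(self):
        lat = lattice_from_sigma(np.zeros((8, 8), dtype=int))
        assert hamiltonian(lat, CPMParameters()) == 0.0

    def test_single_site_cell_hand_value(self):
        # 8 stalk-ECM contacts at J=20 plus area penalty 25*(1-100)^2
        sigma = np.zeros((9, 9), dtype=int)
        sigma[4, 4] = 1
        lat = lattice_from_sigma(sigma)
        p = CPMParameters(j_stalk_ecm=20, lambda_stalk=25, a_stalk=100)
        assert hamiltonian(lat, p) == 8 * 20 + 25 * 99**2 == 245185

    def test_homogeneous_lattice_at_target_area_is_zero(self):
        sigma = np.ones((10, 10), dtype=int)
        lat = lattice_from_sigma(sigma)
        p = CPMParameters(a_stalk=100, lambda_stalk=25)
        assert hamiltonian(lat, p) == 0.0

    def test_pair_counting_flag_doubles_adhesion(self):
        sigma = np.zeros((8, 8), dtype=int)
        sigma[3:5, 3:5] = 1
        lat = lattice_from_sigma(sigma)
        p = CPMParameters(lambda_stalk=0.0)
        once = hamiltonian(lat, p, count_pairs_once=True)
        twice = hamiltonian(lat, p, count_pairs_once=False)
        assert twice == 2 * once > 0


class TestCopyAttemptDeltaH:
    def test_matches_full_hamiltonian_on_random_states(self, rng):
        """Incremental ΔH equals H(after) - H(before), 50 random 8x8 states."""
        field = ChemoattractantField((8, 8))
        checked = 0
        while checked < 50:
            lattice, params = random_small_state(rng)
            ys, xs = rng.integers(1, 7, size=2)
            dy, dx = rng.choice([-1, 0, 1], size=2)
            if dy == 0 and dx == 0:
                continue
            yt, xt = ys + dy, xs + dx
            if lattice.sigma[ys, xs] == lattice.sigma[yt, xt]:
                continue
            dh = copy_attempt_delta_h(lattice, field, params,
                                      (ys, xs), (yt, xt))
            before = hamiltonian(lattice, params)
            after_lat = lattice.copy()
            after_lat.sigma[yt, xt] = lattice.sigma[ys, xs]
            after_lat.areas = after_lat.recount_areas()
            after = hamiltonian(after_lat, params)
            assert dh == pytest.approx(after - before, abs=1e-9)
            checked += 1

    def test_area_term_only(self):
        # J=0: growing a cell from a=A to A+1 costs lambda*(1)^2
        sigma = np.zeros((14, 14), dtype=int)
        sigma[2:12, 2:12] = 1  # 100 sites
        lat = lattice_from_sigma(sigma)
        p = CPMParameters(j_stalk_ecm=0, j_stalk_stalk=0,
                          lambda_stalk=25, a_stalk=100)
        dh = copy_attempt_delta_h(lat, ChemoattractantField((14, 14)), p,
                                  (2, 2), (1, 2))
        assert dh == pytest.approx(25.0)

    def test_flat_field_contributes_no_chemotaxis(self):
        sigma = np.zeros((10, 10), dtype=int)
        sigma[4:6, 4:6] = 1
        lat = lattice_from_sigma(sigma)
        p = CPMParameters()
        cfg = SimulationConfig()
        flat = ChemoattractantField((10, 10), np.full((10, 10), 2.5))
        zero = ChemoattractantField((10, 10))
        dh_flat = copy_attempt_delta_h(lat, flat, p, (4, 4), (3, 4),
                                       chemo_params=cfg.chemo)
        dh_zero = copy_attempt_delta_h(lat, zero, p, (4, 4), (3, 4),
                                       chemo_params=cfg.chemo)
        assert dh_flat == pytest.approx(dh_zero)

    def test_same_cell_attempt_rejected_upstream(self):
        sigma = np.zeros((6, 6), dtype=int)
        sigma[2:4, 2:4] = 1
        lat = lattice_from_sigma(sigma)
        with pytest.raises(ValueError, match="upstream"):
            copy_attempt_delta_h(lat, ChemoattractantField((6, 6)),
                                 CPMParameters(), (2, 2), (3, 3))


class TestAcceptProbability:
    @pytest.mark.parametrize("dh, f, expected", [
        (-10.0, 50.0, 1.0),
        (0.0, 50.0, 1.0),
        (50.0, 50.0, np.exp(-1.0)),
    ])
    def test_known_values(self, dh, f, expected):
        assert accept_probability(dh, f) == pytest.approx(expected)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ParameterError):
            accept_probability(1.0, 0.0)

    @given(dh=st.floats(0.01, 1e3), f=st.floats(0.01, 1e3))
    def test_uphill_probability_below_one(self, dh, f):
        # strictly below 1; may underflow to 0 for dh >> f
        assert 0.0 <= accept_probability(dh, f) < 1.0

    @given(f=st.floats(0.1, 1e3), dh=st.floats(0.0, 100.0),
           extra=st.floats(0.1, 100.0))
    def test_monotone_decreasing_in_dh(self, f, dh, extra):
        assert accept_probability(dh + extra, f) <= accept_probability(dh, f)


class TestRunMcs:
    def _tiny_config(self, **kw):
        base = dict(lattice_width=50, lattice_height=50, n_cells=6,
                    n_mcs=0, snapshot_interval=0, track_interval=0)
        base.update(kw)
        return SimulationConfig.from_dict(base)

    def test_frozen_dynamics_with_vanishing_motility(self):
        # all moves are uphill (lambda > 0, J = 0) and mu -> 0+: p -> 0
        sigma = np.zeros((14, 14), dtype=int)
        sigma[2:12, 2:12] = 1
        lat = lattice_from_sigma(sigma)
        cfg = self._tiny_config(mu_tip=1e-6, mu_stalk=1e-6, j_stalk_ecm=0.0,
                                j_stalk_stalk=0.0, j_tip_ecm=0.0,
                                j_tip_stalk=0.0, j_tip_tip=0.0,
                                chi_tip=0.0, chi_stalk=0.0, alpha_tip=0.0,
                                alpha_stalk=0.0)
        field = ChemoattractantField((14, 14))
        before = lat.sigma.copy()
        ag.seed_rng(5)
        for _ in range(10):
            run_mcs(lat, field, cfg)
        assert np.array_equal(lat.sigma, before)

    def test_area_bookkeeping_after_100_mcs(self):
        cfg = self._tiny_config()
        model = ag.AngiogenesisModel(cfg)
        lat, field = model.initialize(seed=2)
        ag.seed_rng(2)
        ka = _KernelArgs(cfg)
        for _ in range(100):
            run_mcs(lat, field, cfg, kernel_args=ka)
        lat.check_consistency()
        assert lat.areas.sum() == np.count_nonzero(lat.sigma)

    def test_same_seed_same_state(self):
        cfg = self._tiny_config(n_mcs=50)
        a = ag.AngiogenesisModel(cfg).run(9)
        b = ag.AngiogenesisModel(cfg).run(9)
        assert np.array_equal(a.lattice.sigma, b.lattice.sigma)
        assert np.allclose(a.field.c, b.field.c)

    def test_cohesive_cells_aggregate_without_chemotaxis(self):
        """J favoring cell-cell contact pulls a dispersed population together
        (largest-component growth), even with chi = 0."""
        from angiosprout.morphometrics import largest_connected_component

        sigma = np.zeros((46, 46), dtype=int)
        cid = 1
        for by in range(3):  # 3x3 grid of 5x5 cells, 2-site gaps
            for bx in range(3):
                y0, x0 = 12 + by * 7, 12 + bx * 7
                sigma[y0:y0 + 5, x0:x0 + 5] = cid
                cid += 1
        cfg = self._tiny_config(j_stalk_stalk=5.0, j_stalk_ecm=20.0,
                                chi_tip=0.0, chi_stalk=0.0,
                                a_stalk=25.0, a_tip=25.0)
        growth = []
        for seed in (1, 2, 3):
            lat = lattice_from_sigma(sigma.copy())
            field = ChemoattractantField(lat.shape)
            ag.seed_rng(seed)
            ka = _KernelArgs(cfg)
            for _ in range(300):
                run_mcs(lat, field, cfg, kernel_args=ka)
            _, area = largest_connected_component(lat.binary_mask())
            growth.append(area)
        assert np.mean(growth) > 25  # initial largest component is one cell
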