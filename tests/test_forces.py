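"""Pair-force law, weight functions, fluctuation-dissipation, bonded forces."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hgdpd import _kernels
from hgdpd.core import (ForceField, State, bonded_forces, fdt_sigma,
                        pair_forces, weight_conservative, weight_dissipative,
                        weight_random)
from hgdpd.topology import SystemTopology


class TestWeightFunctions:
    @pytest.mark.parametrize("r, expected", [(1.0, 0.0), (0.5, 0.5), (1.7, 0.0),
                                             (0.0, 1.0)])
    def test_conservative_weight_is_linear_inside_cutoff(self, r, expected):
        assert weight_conservative(r) == pytest.approx(expected)

    @pytest.mark.parametrize("r, s, wd, wr", [
        (0.5, 2.0, 0.25, 0.5),
        (0.5, 0.5, math.sqrt(0.5), 0.5**0.25),   # the calibrated exponent
        (1.2, 2.0, 0.0, 0.0),
        (1.2, 0.5, 0.0, 0.0),
    ])
    def test_dissipative_and_random_weights(self, r, s, wd, wr):
        assert weight_dissipative(r, s) == pytest.approx(wd)
        assert weight_random(r, s) == pytest.approx(wr)

    @pytest.mark.parametrize("s", [0.0, -1.0])
    def test_non_positive_exponent_rejected(self, s):
        with pytest.raises(ValueError):
            weight_dissipative(0.5, s)

    @given(r=st.floats(0, 2), s=st.floats(0.1, 4))
    def test_detailed_balance_identity_wd_equals_wr_squared(self, r, s):
        # holds exactly for all r and s, as required for canonical sampling
        assert weight_dissipative(r, s) == weight_random(r, s) ** 2


class TestFluctuationDissipation:
    @pytest.mark.parametrize("gamma, expected, tol", [
        (23.53, 6.86, 5e-3),   # the calibrated pair
        (4.5, 3.0, 1e-12),     # the standard literature pair
        (0.0, 0.0, 0.0),
    ])
    def test_sigma_from_gamma(self, gamma, expected, tol):
        assert fdt_sigma(gamma, 1.0) == pytest.approx(expected, abs=tol)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            fdt_sigma(-1.0)

    def test_default_forcefield_is_thermostat_consistent(self):
        assert ForceField.default().thermostat_consistent()
        assert ForceField.water().thermostat_consistent()
        incon = ForceField.water(sigma=3.1)
        assert not incon.thermostat_consistent()


def _two_bead_state(r, v_i=(0, 0, 0), v_j=(0, 0, 0)):
    pos = np.array([[1.0 + r, 1.0, 1.0], [1.0, 1.0, 1.0]])
    vel = np.array([v_i, v_j], dtype=float)
    return State(pos, vel, np.ones(2), np.zeros(2, np.int64), ("X",))


class TestPairForces:
    def test_conservative_magnitude_at_half_cutoff(self):
        # a=50 at r=0.5: |F^C| = 50 * (1 - 0.5) = 25 along r_hat
        ff = ForceField(("X",), np.array([[50.0]]), 0.0, 0.0, 2.0)
        state = _two_bead_state(0.5)
        f, _ = pair_forces(state, np.full(3, 10.0), ff, ([0], [1]), 0.001,
                           np.zeros(1))
        assert f[0] == pytest.approx([25.0, 0.0, 0.0])
        assert f[1] == pytest.approx([-25.0, 0.0, 0.0])

    def test_dissipative_force_opposes_approach(self):
        # gamma=4.5, s=2, r=0.5, head-on approach with v_ij . r_hat = -1:
        # F^D = -4.5 * 0.25 * (-1) = +1.125 along r_hat (decelerates)
        ff = ForceField(("X",), np.array([[0.0]]), 0.0, 4.5, 2.0)
        state = _two_bead_state(0.5, v_i=(-1.0, 0.0, 0.0))
        f, _ = pair_forces(state, np.full(3, 10.0), ff, ([0], [1]), 0.001,
                           np.zeros(1))
        assert f[0] == pytest.approx([1.125, 0.0, 0.0])

    def test_random_force_scales_with_inverse_sqrt_dt(self):
        # sigma=3, s=2, r=0.5, xi=1, dt=0.001: |F^R| = 3*0.5/sqrt(0.001)
        ff = ForceField(("X",), np.array([[0.0]]), 3.0, 0.0, 2.0)
        state = _two_bead_state(0.5)
        f, _ = pair_forces(state, np.full(3, 10.0), ff, ([0], [1]), 0.001,
                           np.ones(1))
        assert np.linalg.norm(f[0]) == pytest.approx(47.434, abs=1e-3)

    def test_exact_overlap_contributes_zero_and_is_counted(self):
        ff = ForceField(("X",), np.array([[50.0]]), 3.0, 4.5, 2.0)
        state = _two_bead_state(0.0)
        f, n_overlap = pair_forces(state, np.full(3, 10.0), ff, ([0], [1]),
                                   0.001, np.ones(1))
        assert n_overlap == 1
        assert np.all(f == 0.0)

    def test_pairs_beyond_cutoff_contribute_nothing(self):
        ff = ForceField(("X",), np.array([[50.0]]), 3.0, 4.5, 2.0)
        state = _two_bead_state(1.5)
        f, _ = pair_forces(state, np.full(3, 10.0), ff, ([0], [1]), 0.001,
                           np.ones(1))
        assert np.all(f == 0.0)

    def test_forces_vanish_exactly_at_cutoff_boundary(self):
        ff = ForceField(("X",), np.array([[50.0]]), 3.0, 4.5, 2.0)
        state = _two_bead_state(1.0)
        f, _ = pair_forces(state, np.full(3, 10.0), ff, ([0], [1]), 0.001,
                           np.ones(1))
        assert np.all(f == 0.0)

    def test_every_pair_contribution_is_antisymmetric(self):
        rng = np.random.RandomState(3)
        n = 40
        pos = rng.uniform(0, 5, (n, 3))
        vel = rng.standard_normal((n, 3))
        state = State(pos, vel, np.ones(n), np.zeros(n, np.int64), ("X",))
        ff = ForceField(("X",), np.array([[25.0]]), 3.0, 4.5, 2.0)
        pi, pj = np.triu_indices(n, 1)
        f, _ = pair_forces(state, np.full(3, 5.0), ff, (pi, pj), 0.001,
                           rng.standard_normal(pi.size))
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_minimum_image_convention_across_boundary(self):
        ff = ForceField(("X",), np.array([[50.0]]), 0.0, 0.0, 2.0)
        pos = np.array([[0.1, 1.0, 1.0], [4.9, 1.0, 1.0]])  # 0.2 apart via wrap
        state = State(pos, np.zeros((2, 3)), np.ones(2), np.zeros(2, np.int64), ("X",))
        f, _ = pair_forces(state, np.full(3, 5.0), ff, ([0], [1]), 0.001,
                           np.zeros(1))
        # bead 0 is pushed in +x (away from the image of bead 1 at -0.1)
        assert f[0, 0] == pytest.approx(50.0 * 0.8)


def _numeric_gradient(pos, box, topo, h=1e-6):
    """Central-difference gradient of the bonded energy (the force oracle)."""
    def energy(p):
        e = 0.0
        if topo.n_bonds:
            e += _kernels.bond_energy_kernel(p, box, topo.bond_i, topo.bond_j,
                                             topo.bond_ks, topo.bond_l0)
        if topo.n_angles:
            e += _kernels.angle_energy_kernel(p, box, topo.angle_i, topo.angle_j,
                                              topo.angle_k, topo.angle_ka,
                                              topo.angle_theta0)
        return e

    g = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            p = pos.copy()
            p[i, d] += h
            ep = energy(p)
            p[i, d] -= 2 * h
            em = energy(p)
            g[i, d] = (ep - em) / (2 * h)
    return g


class TestBondedForces:
    def test_bond_at_rest_length_gives_zero_force(self):
        topo = SystemTopology(types=np.zeros(2, np.int64), type_names=("GalA",),
                              bond_i=[0], bond_j=[1], bond_ks=[3375.0],
                              bond_l0=[0.62])
        pos = np.array([[1.0, 1.0, 1.0], [1.62, 1.0, 1.0]])
        f, _ = bonded_forces(pos, np.full(3, 10.0), topo)
        assert np.abs(f).max() < 1e-10

    def test_angle_at_rest_gives_zero_force(self):
        th0 = 2.83
        topo = SystemTopology(types=np.zeros(3, np.int64), type_names=("GalA",),
                              angle_i=[0], angle_j=[1], angle_k=[2],
                              angle_ka=[29.0], angle_theta0=[th0])
        c, s = np.cos(th0), np.sin(th0)
        pos = np.array([[1.62, 1.0, 1.0], [1.0, 1.0, 1.0],
                        [1.0 + 0.62 * c, 1.0 + 0.62 * s, 1.0]])
        f, _ = bonded_forces(pos, np.full(3, 10.0), topo)
        assert np.abs(f).max() < 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_forces_match_numeric_energy_gradient(self, seed):
        rng = np.random.RandomState(seed)
        pos = 2.0 + rng.uniform(-0.5, 0.5, (3, 3))
        box = np.full(3, 10.0)
        topo = SystemTopology(types=np.zeros(3, np.int64), type_names=("GalA",),
                              bond_i=[0, 1], bond_j=[1, 2],
                              bond_ks=[3375.0, 2700.0], bond_l0=[0.62, 0.63],
                              angle_i=[0], angle_j=[1], angle_k=[2],
                              angle_ka=[29.0], angle_theta0=[2.83])
        f, _ = bonded_forces(pos, box, topo)
        assert np.allclose(f, -_numeric_gradient(pos, box, topo), atol=1e-6)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_angle_forces_have_zero_net_force_and_torque(self, seed):
        rng = np.random.RandomState(seed)
        pos = 2.0 + rng.uniform(-0.5, 0.5, (3, 3))
        topo = SystemTopology(types=np.zeros(3, np.int64), type_names=("GalA",),
                              angle_i=[0], angle_j=[1], angle_k=[2],
                              angle_ka=[29.0], angle_theta0=[2.83])
        f, _ = bonded_forces(pos, np.full(3, 10.0), topo)
        assert np.abs(f.sum(axis=0)).max() < 1e-12
        torque = np.cross(pos - pos.mean(axis=0), f).sum(axis=0)
        assert np.abs(torque).max() < 1e-10

    def test_collinear_angle_is_clamped_not_nan(self):
        topo = SystemTopology(types=np.zeros(3, np.int64), type_names=("GalA",),
                              angle_i=[0], angle_j=[1], angle_k=[2],
                              angle_ka=[29.0], angle_theta0=[2.83])
        pos = np.array([[1.0, 1.0, 1.0], [2.0, 1.0, 1.0], [3.0, 1.0, 1.0]])
        f, n_clamped = bonded_forces(pos, np.full(3, 10.0), topo)
        assert n_clamped == 1
        assert np.all(np.isfinite(f))
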