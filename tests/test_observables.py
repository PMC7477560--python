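"""RDF, MSD/diffusion, velocity statistics and bonded distributions."""

import numpy as np
import pytest

from hgdpd.observables import (bonded_distributions, diffusion_coefficient,
                               kinetic_temperature, rdf, velocity_stats)
from hgdpd.synthetic import generate_lattice
from hgdpd.topology import build_chain
from hgdpd.trajectory import Trajectory


class TestRDF:
    def test_ideal_gas_is_structureless(self):
        rng = np.random.RandomState(0)
        pos = rng.uniform(0, 20, (20, 2000, 3))
        traj = Trajectory(positions=pos, box=np.full(3, 20.0), units="real")
        curve = rdf(traj, bin_width=0.5, r_max=9.0)
        assert np.abs(curve.g[1:] - 1.0).max() < 0.03
        assert 0.9 < curve.tail_mean() < 1.1

    def test_simple_cubic_lattice_first_peak_counts_six_neighbours(self):
        lat = generate_lattice(1.0, 4)
        curve = rdf(lat, bin_width=0.1, r_max=1.3)
        # the peak bin contains the lattice spacing
        peak = curve.r[np.argmax(curve.g)]
        assert abs(peak - 1.0) <= 0.05 + 1e-12
        # integrate 4 pi r^2 rho g(r) dr across the peak: 6 nearest neighbours
        rho = lat.n_particles / float(np.prod(lat.box))
        shell = 4 * np.pi * curve.r**2 * rho * curve.g * curve.bin_width
        near = (curve.r > 0.8) & (curve.r < 1.2)
        assert shell[near].sum() == pytest.approx(6.0, rel=0.05)

    def test_no_pairs_below_lattice_spacing(self):
        lat = generate_lattice(1.0, 4)
        curve = rdf(lat, bin_width=0.1, r_max=1.3)
        assert np.all(curve.g[curve.r < 0.9] == 0.0)

    def test_r_max_beyond_half_box_rejected(self):
        lat = generate_lattice(1.0, 3)
        with pytest.raises(ValueError, match="half the box"):
            rdf(lat, bin_width=0.1, r_max=2.0)

    def test_empty_type_selection_rejected(self):
        lat = generate_lattice(1.0, 3)
        with pytest.raises((ValueError, KeyError)):
            rdf(lat, type_pair=("GalA", "GalA"), bin_width=0.1, r_max=1.2)

    def test_cross_type_rdf_of_interleaved_lattices(self):
        # two interpenetrating sc lattices: nearest A-B distance = d/2 * sqrt(3)
        lat = generate_lattice(1.0, 4)
        n = lat.n_particles
        pos_b = (lat.positions[0] + 0.5) % 4.0
        pos = np.concatenate([lat.positions[0], pos_b])[None]
        types = np.array([0] * n + [1] * n)
        traj = Trajectory(positions=pos, box=lat.box, units="real",
                          types=types, type_names=("A", "B"))
        curve = rdf(traj, type_pair=("A", "B"), bin_width=0.05, r_max=1.5)
        first = curve.r[curve.g > 0][0]
        assert first == pytest.approx(np.sqrt(3) / 2, abs=0.05)


class TestDiffusion:
    def test_recovers_brownian_ground_truth(self, brownian_fine):
        series = diffusion_coefficient(brownian_fine)
        truth = brownian_fine.metadata["ground_truth_D"]
        assert series.D == pytest.approx(truth, rel=0.05)
        assert not series.ballistic

    def test_static_particles_have_zero_diffusivity(self):
        pos = np.ones((30, 50, 3)) * 2.5
        traj = Trajectory(positions=pos, box=np.full(3, 10.0),
                          frame_interval=1.0, units="real")
        assert diffusion_coefficient(traj).D == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_motion_is_flagged(self):
        t = np.arange(40)[:, None, None]
        v = np.array([[[0.11, 0.0, 0.0]]])
        pos = (np.zeros((40, 5, 3)) + t * v)
        traj = Trajectory(positions=pos % 50.0, box=np.full(3, 50.0),
                          unwrapped=pos, frame_interval=1.0, units="real")
        series = diffusion_coefficient(traj)
        assert series.ballistic
        assert series.exponent == pytest.approx(2.0, abs=0.05)

    def test_too_few_lags_in_window_rejected(self):
        pos = np.random.RandomState(0).uniform(0, 5, (4, 10, 3))
        traj = Trajectory(positions=pos, box=np.full(3, 5.0), units="real")
        with pytest.raises(ValueError, match="lags"):
            diffusion_coefficient(traj)

    def test_insensitive_to_halving_the_save_interval(self, brownian_fine):
        full = diffusion_coefficient(brownian_fine)
        half = Trajectory(positions=brownian_fine.positions[::2],
                          box=brownian_fine.box,
                          unwrapped=brownian_fine.unwrapped[::2],
                          frame_interval=2 * brownian_fine.frame_interval,
                          units="real")
        assert diffusion_coefficient(half).D == pytest.approx(full.D, rel=0.02)

    def test_unwrap_chaining_matches_exact_unwrapped(self, brownian_fine):
        chained = Trajectory(positions=brownian_fine.positions,
                             box=brownian_fine.box,
                             frame_interval=brownian_fine.frame_interval,
                             units="real")
        d_exact = diffusion_coefficient(brownian_fine).D
        d_chained = diffusion_coefficient(chained).D
        assert d_chained == pytest.approx(d_exact, rel=0.05)


class TestVelocityStats:
    def test_maxwell_boltzmann_closed_forms(self):
        rng = np.random.RandomState(1)
        v = rng.standard_normal((40, 3000, 3))
        traj = Trajectory(positions=np.zeros_like(v), box=np.full(3, 10.0),
                          velocities=v, units="reduced")
        stats = velocity_stats(traj)
        assert stats.mean_speed == pytest.approx(np.sqrt(8 / np.pi), rel=0.01)
        assert stats.rms_speed == pytest.approx(np.sqrt(3.0), rel=0.01)
        assert kinetic_temperature(traj) == pytest.approx(1.0, rel=0.01)
        assert stats.rms_speed >= stats.mean_speed > 0

    def test_zero_velocities_give_zero_stats(self):
        traj = Trajectory(positions=np.zeros((3, 10, 3)),
                          velocities=np.zeros((3, 10, 3)),
                          box=np.full(3, 5.0), units="reduced")
        stats = velocity_stats(traj)
        assert stats.mean_speed == 0.0 and stats.rms_speed == 0.0
        assert kinetic_temperature(traj) == 0.0

    def test_missing_velocities_rejected(self):
        traj = Trajectory(positions=np.zeros((3, 10, 3)), box=np.full(3, 5.0),
                          units="reduced")
        with pytest.raises(ValueError, match="velocities"):
            velocity_stats(traj)
        with pytest.raises(ValueError, match="velocities"):
            kinetic_temperature(traj)

    def test_mass_weighting_enters_the_temperature(self):
        v = np.ones((2, 4, 3))
        traj = Trajectory(positions=np.zeros_like(v), box=np.full(3, 5.0),
                          velocities=v, units="reduced",
                          masses=np.array([1.0, 1.0, 2.0, 2.0]))
        assert kinetic_temperature(traj) == pytest.approx(4.5 / 3.0)


class TestBondedDistributions:
    def test_frozen_chain_has_zero_variance_at_exact_geometry(self):
        topo = build_chain(5, "all-protonated")
        # straight chain at exactly the rest length
        pos = np.zeros((1, 5, 3))
        pos[0, :, 0] = np.arange(5) * 0.62 + 1.0
        traj = Trajectory(positions=np.repeat(pos, 3, axis=0),
                          box=np.full(3, 10.0), units="reduced")
        dists = bonded_distributions(traj, topo)
        bond = next(d for d in dists.values() if d.kind == "bond")
        angle = next(d for d in dists.values() if d.kind == "angle")
        assert bond.mean == pytest.approx(0.62)
        assert bond.variance == pytest.approx(0.0, abs=1e-20)
        assert angle.mean == pytest.approx(np.pi)
        assert angle.variance == pytest.approx(0.0, abs=1e-20)

    def test_terms_group_by_type_sequence(self):
        topo = build_chain(6, "alternating")
        pos = np.zeros((1, 6, 3))
        pos[0, :, 0] = np.arange(6) * 0.63
        traj = Trajectory(positions=pos, box=np.full(3, 10.0), units="reduced")
        dists = bonded_distributions(traj, topo)
        kinds = {k: d.kind for k, d in dists.items()}
        assert sum(1 for v in kinds.values() if v == "bond") == 1   # (-)-GalA only
        assert sum(1 for v in kinds.values() if v == "angle") == 2  # two triplet types
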