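"""Shared fixtures: cached small simulations and synthetic references.

Simulation-backed tests share seeded runs through session-scoped caches so
that the same trajectory can serve several independent checks without being
recomputed.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hgdpd.core import (ForceField, IntegratorConfig, Simulation, State,
                        fdt_sigma, initialize_water_state,
                        maxwell_boltzmann_velocities)
from hgdpd.synthetic import GeneratorSpec, generate_brownian_water
from hgdpd.topology import SystemTopology

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def water_run():
    """Cached seeded water-box runs: water_run(a=..., gamma=..., s=...)."""

    @functools.lru_cache(maxsize=None)
    def _run(a=25.0, gamma=4.5, s=2.0, n=375, edge=5.0, seed=1,
             warmup=2000, production=4000, save=50, skin=0.0, check=False):
        ff = ForceField(("(H2O)4",), np.array([[a]]), fdt_sigma(gamma), gamma, s)
        st = initialize_water_state(n, edge, seed)
        cfg = IntegratorConfig(seed=seed, warmup_steps=warmup,
                               production_steps=production, save_every=save,
                               neighbor_skin=skin, check_missed_pairs=check)
        return Simulation(st, ff, None, cfg, np.full(3, edge)).run()

    return _run


@pytest.fixture(scope="session")
def brownian_fine():
    """One seeded Brownian water-like reference trajectory (real units)."""
    return generate_brownian_water(GeneratorSpec(n_frames=200, seed=7))


def _bath_bonded(kind: str, k: float, rest: float, seed: int, steps: int):
    """Dimer/trimer immersed in an ideal-gas DPD bath (canonical sampling)."""
    edge = 3.0
    n = int(3 * edge**3)
    rng = np.random.RandomState(seed)
    pos = rng.uniform(0.0, edge, (n, 3))
    types = np.zeros(n, dtype=np.int64)
    if kind == "bond":
        topo = SystemTopology(types=types, type_names=("GalA",),
                              bond_i=[0], bond_j=[1], bond_ks=[k], bond_l0=[rest])
        pos[:2] = [[1.5, 1.5, 1.5], [1.5 + rest, 1.5, 1.5]]
    else:
        bk, bl = 3375.0, 0.62
        topo = SystemTopology(types=types, type_names=("GalA",),
                              bond_i=[0, 1], bond_j=[1, 2],
                              bond_ks=[bk, bk], bond_l0=[bl, bl],
                              angle_i=[0], angle_j=[1], angle_k=[2],
                              angle_ka=[k], angle_theta0=[rest])
        c, s = np.cos(rest), np.sin(rest)
        pos[:3] = [[1.5 + bl, 1.5, 1.5], [1.5, 1.5, 1.5],
                   [1.5 + bl * c, 1.5 + bl * s, 1.5]]
    ff = ForceField(("GalA",), np.array([[0.0]]), fdt_sigma(23.53), 23.53, 0.5)
    state = State(pos, maxwell_boltzmann_velocities(np.ones(n), 1.0, rng),
                  np.ones(n), types, ("GalA",))
    cfg = IntegratorConfig(seed=seed, warmup_steps=3000, production_steps=steps,
                           save_every=50)
    traj = Simulation(state, ff, topo, cfg, np.full(3, edge)).run()
    return traj, topo


@pytest.fixture(scope="session")
def bath_trimer():
    """Trimer with the softest-relevant angle (k_A=29, theta0=2.83) in a bath."""
    return _bath_bonded("angle", 29.0, 2.83, seed=13, steps=120000)


@pytest.fixture(scope="session")
def isolated_dimer():
    """Isolated harmonic dimer (k_S=3375, l0=0.62) under the thermostat."""
    topo = SystemTopology(types=np.zeros(2, np.int64), type_names=("GalA",),
                          bond_i=[0], bond_j=[1], bond_ks=[3375.0],
                          bond_l0=[0.62])
    rng = np.random.RandomState(11)
    pos = np.array([[2.0, 2.0, 2.0], [2.62, 2.0, 2.0]])
    ff = ForceField(("GalA",), np.array([[0.0]]), fdt_sigma(23.53), 23.53, 0.5)
    state = State(pos, maxwell_boltzmann_velocities(np.ones(2), 1.0, rng),
                  np.ones(2), np.zeros(2, np.int64), ("GalA",))
    cfg = IntegratorConfig(seed=11, warmup_steps=2000, production_steps=80000,
                           save_every=25)
    traj = Simulation(state, ff, topo, cfg, np.full(3, 4.0)).run()
    return traj, topo
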