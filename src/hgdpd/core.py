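"""The DPD engine.

Beads interact through three pairwise, centre-to-centre forces inside a
cut-off radius ``r_C`` (the reduced length unit):

* conservative soft repulsion ``F^C = a_ij (1 - r/r_C) r_hat``,
* dissipative friction ``F^D = -gamma w^D(r) (v_ij . r_hat) r_hat`` with
  ``w^D(r) = (1 - r/r_C)^s``,
* random kicks ``F^R = sigma w^R(r) xi_ij dt^(-1/2) r_hat`` with
  ``w^R = sqrt(w^D)`` and symmetric unit-variance noise ``xi_ij``.

The pairing ``w^D = (w^R)^2`` together with the fluctuation-dissipation
relation ``sigma^2 = 2 gamma k_B T`` makes the dissipative/random pair a
momentum-conserving thermostat whose stationary state is canonical at
``k_B T``.  Chains add harmonic distance bonds ``U = k_S (r - l0)^2 / 2``
and harmonic angles ``U = k_A (theta - theta0)^2 / 2``.

Equations of motion are integrated with the modified velocity-Verlet scheme
(velocity prediction factor ``lambda``), neighbour pairs come from a cell
list refreshed on a fixed schedule, and all randomness flows from a single
seeded Mersenne-Twister generator so that runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _kernels, parameters
from .trajectory import Trajectory, wrap_positions

__all__ = [
    "ForceField",
    "SimulationBox",
    "State",
    "IntegratorConfig",
    "Simulation",
    "fdt_sigma",
    "weight_conservative",
    "weight_dissipative",
    "weight_random",
    "pair_forces",
    "bonded_forces",
    "build_cell_list",
    "integrate_step",
    "run_simulation",
    "initialize_water_state",
    "maxwell_boltzmann_velocities",
]


# ---------------------------------------------------------------------------
# weight functions and the fluctuation-dissipation relation
# ---------------------------------------------------------------------------

def weight_conservative(r, cutoff: float = 1.0):
    """Linear conservative weight, (1 - r/r_C) inside the cut-off, else 0."""
    r = np.asarray(r, dtype=float)
    out = np.where(r < cutoff, 1.0 - r / cutoff, 0.0)
    return out if out.ndim else float(out)


def weight_random(r, s: float, cutoff: float = 1.0):
    """Random-force weight, w^R = (1 - r/r_C)^(s/2) inside the cut-off."""
    if s <= 0:
        raise ValueError(f"weight exponent s must be > 0, got {s}")
    r = np.asarray(r, dtype=float)
    base = np.where(r < cutoff, 1.0 - r / cutoff, 0.0)
    out = base ** (0.5 * s)
    return out if out.ndim else float(out)


def weight_dissipative(r, s: float, cutoff: float = 1.0):
    """Dissipative weight, w^D = (w^R)^2 = (1 - r/r_C)^s inside the cut-off."""
    wr = np.asarray(weight_random(r, s, cutoff))
    out = wr * wr
    return out if out.ndim else float(out)


def fdt_sigma(gamma: float, kbt: float = 1.0) -> float:
    """Noise amplitude from friction, sigma = sqrt(2 gamma k_B T)."""
    if gamma < 0:
        raise ValueError(f"friction gamma must be >= 0, got {gamma}")
    if kbt <= 0:
        raise ValueError(f"k_B T must be > 0, got {kbt}")
    return math.sqrt(2.0 * gamma * kbt)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ForceField:
    """Non-bonded DPD force field: repulsion matrix plus thermostat.

    ``repulsion`` is indexed by integer type codes in the order of
    ``type_names``; entries are in k_BT/r_C.  ``cutoff`` is the reduced
    cut-off radius and equals 1 by construction of the unit system.
    """

    type_names: tuple[str, ...]
    repulsion: np.ndarray
    sigma: float
    gamma: float
    s: float
    cutoff: float = 1.0

    def __post_init__(self) -> None:
        self.repulsion = np.asarray(self.repulsion, dtype=float)
        n = len(self.type_names)
        if self.repulsion.shape != (n, n):
            raise ValueError(
                f"repulsion matrix shape {self.repulsion.shape} does not match "
                f"{n} bead types"
            )
        if not np.allclose(self.repulsion, self.repulsion.T):
            raise ValueError("repulsion matrix must be symmetric")
        if np.any(self.repulsion < 0):
            raise ValueError("repulsion entries must be >= 0")
        if self.s <= 0:
            raise ValueError(f"weight exponent s must be > 0, got {self.s}")
        if self.sigma < 0 or self.gamma < 0:
            raise ValueError("sigma and gamma must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")

    def thermostat_consistent(self, kbt: float = 1.0, rtol: float = 1e-10) -> bool:
        """Whether sigma^2 = 2 gamma k_B T holds to relative tolerance."""
        lhs = self.sigma**2
        rhs = 2.0 * self.gamma * kbt
        if rhs == 0.0:
            return lhs == 0.0
        return abs(lhs - rhs) <= rtol * rhs

    def repulsion_between(self, name_a: str, name_b: str) -> float:
        ia = self.type_names.index(name_a)
        ib = self.type_names.index(name_b)
        return float(self.repulsion[ia, ib])

    @classmethod
    def water(cls, a: float = 25.0, sigma: float = 3.0, gamma: float = 4.5,
              s: float = 2.0) -> "ForceField":
        """Single-bead-type water field (defaults: the standard literature set)."""
        return cls(("(H2O)4",), np.array([[a]]), sigma, gamma, s)

    @classmethod
    def default(cls) -> "ForceField":
        """The packaged homogalacturonan/water field with its calibrated thermostat."""
        t = parameters.load_tables()
        names = parameters.BEAD_TYPES
        mat = np.zeros((len(names), len(names)))
        for row in t["repulsion"]:
            ia = names.index(row["pair"][0])
            ib = names.index(row["pair"][1])
            mat[ia, ib] = mat[ib, ia] = row["a"]
        th = t["thermostat"]
        # sigma is derived from gamma so sigma^2 = 2 gamma k_BT holds exactly
        # (the tabulated 6.86 is that same number printed to 2 decimals)
        return cls(tuple(names), mat, fdt_sigma(th["gamma"]), th["gamma"], th["s"])


@dataclass
class SimulationBox:
    """Cubic periodic box; edge lengths in r_C."""

    edge: np.ndarray

    def __post_init__(self) -> None:
        self.edge = np.broadcast_to(np.asarray(self.edge, dtype=float), (3,)).copy()
        if np.any(self.edge <= 0):
            raise ValueError("box edges must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edge))

    def validate_cutoff(self, cutoff: float) -> None:
        if np.any(self.edge < 2.0 * cutoff):
            raise ValueError(
                f"box edge {self.edge} violates the minimum-image requirement "
                f"edge >= 2*cutoff = {2 * cutoff}"
            )


@dataclass
class State:
    """Instantaneous mechanical state of the bead system (reduced units)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    types: np.ndarray
    type_names: tuple[str, ...]
    step_count: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.types = np.asarray(self.types, dtype=np.int64)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise ValueError("positions and velocities must have shape (n, 3)")
        if self.masses.shape != (n,) or self.types.shape != (n,):
            raise ValueError("masses and types must have shape (n,)")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.velocities))):
            raise ValueError("state contains non-finite entries")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "State":
        return State(self.positions.copy(), self.velocities.copy(),
                     self.masses.copy(), self.types.copy(),
                     self.type_names, self.step_count)


@dataclass
class IntegratorConfig:
    """Time stepping, neighbour-list and output schedule.

    ``dt`` is in tau; the default 0.001 is deliberately small so that the
    conservative force is integrated accurately and thermostat artefacts on
    the kinetic temperature stay negligible.  ``neighbor_skin`` widens the
    pair list beyond the cut-off; 0 reproduces the plain
    refresh-every-``cell_refresh``-steps protocol, a positive value
    guarantees no pair can enter the cut-off undetected between refreshes.
    """

    seed: int
    dt: float = 0.001
    lam: float = 0.5
    cell_refresh: int = 8
    warmup_steps: int = 2000
    production_steps: int = 20000
    save_every: int = 200
    neighbor_skin: float = 0.0
    check_missed_pairs: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.cell_refresh < 1 or self.save_every < 1:
            raise ValueError("cell_refresh and save_every must be >= 1")
        if self.warmup_steps < 0 or self.production_steps < 0:
            raise ValueError("step counts must be >= 0")
        if self.neighbor_skin < 0:
            raise ValueError("neighbor_skin must be >= 0")


# ---------------------------------------------------------------------------
# functional operations (thin wrappers over the kernels)
# ---------------------------------------------------------------------------

def build_cell_list(positions, box, cutoff: float):
    """Ordered, duplicate-free pair list of all minimum-image pairs r < cutoff."""
    positions = np.ascontiguousarray(positions, dtype=float)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    if np.any(box < 2.0 * cutoff):
        raise ValueError(
            f"box {box} too small for cutoff {cutoff}: minimum-image search "
            "requires edge >= 2*cutoff"
        )
    return _kernels.pairs_cells(positions, box, cutoff)


def pair_forces(state: State, box, forcefield: ForceField, pairs, dt: float,
                noise: np.ndarray):
    """Accumulated non-bonded forces for a given pair list and noise draws.

    ``noise`` has one entry per listed pair; symmetry (xi_ij = xi_ji) holds
    by construction because each unordered pair appears once.  Returns the
    per-bead force array and the number of exactly-overlapping pairs (which
    contribute zero force).
    """
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    pi, pj = pairs
    f = np.zeros_like(state.positions)
    n_overlap = _kernels.pair_forces_kernel(
        state.positions, state.velocities, box,
        np.asarray(pi, dtype=np.int64), np.asarray(pj, dtype=np.int64),
        state.types, forcefield.repulsion,
        forcefield.gamma, forcefield.sigma, forcefield.s,
        1.0 / math.sqrt(dt), np.asarray(noise, dtype=float),
        forcefield.cutoff, f,
    )
    return f, n_overlap


def bonded_forces(positions, box, topology):
    """Harmonic bond and angle forces; returns (forces, n_clamped_angles)."""
    positions = np.ascontiguousarray(positions, dtype=float)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    f = np.zeros_like(positions)
    n_clamped = 0
    if topology is not None and topology.n_bonds:
        _kernels.bond_forces_kernel(positions, box, topology.bond_i,
                                    topology.bond_j, topology.bond_ks,
                                    topology.bond_l0, f)
    if topology is not None and topology.n_angles:
        n_clamped = _kernels.angle_forces_kernel(
            positions, box, topology.angle_i, topology.angle_j,
            topology.angle_k, topology.angle_ka, topology.angle_theta0, f)
    return f, int(n_clamped)


def potential_energy(state: State, box, forcefield: ForceField, topology=None) -> float:
    """Conservative + bonded potential energy (thermostat forces have none)."""
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    pi, pj = build_cell_list(state.positions, box, forcefield.cutoff)
    e = _kernels.pair_energy_kernel(state.positions, box, pi, pj, state.types,
                                    forcefield.repulsion, forcefield.cutoff)
    if topology is not None and topology.n_bonds:
        e += _kernels.bond_energy_kernel(state.positions, box, topology.bond_i,
                                         topology.bond_j, topology.bond_ks,
                                         topology.bond_l0)
    if topology is not None and topology.n_angles:
        e += _kernels.angle_energy_kernel(state.positions, box, topology.angle_i,
                                          topology.angle_j, topology.angle_k,
                                          topology.angle_ka, topology.angle_theta0)
    return float(e)


def kinetic_energy(state: State) -> float:
    return float(0.5 * np.sum(state.masses[:, None] * state.velocities**2))


def maxwell_boltzmann_velocities(masses, kbt: float, rng: np.random.RandomState,
                                 remove_com: bool = True) -> np.ndarray:
    """Maxwell-Boltzmann draw at k_B T, optionally with zero total momentum."""
    masses = np.asarray(masses, dtype=float)
    v = rng.standard_normal((masses.size, 3)) * np.sqrt(kbt / masses)[:, None]
    if remove_com:
        p = (masses[:, None] * v).sum(axis=0)
        v -= p / masses.sum()
    return v


def initialize_water_state(n_beads: int, box_edge: float, seed: int,
                           kbt: float = 1.0) -> State:
    """Uniform random water box with thermal velocities (reduced units)."""
    rng = np.random.RandomState(seed)
    pos = rng.uniform(0.0, box_edge, size=(n_beads, 3))
    masses = np.ones(n_beads)
    vel = maxwell_boltzmann_velocities(masses, kbt, rng)
    return State(pos, vel, masses, np.zeros(n_beads, dtype=np.int64), ("(H2O)4",))


# ---------------------------------------------------------------------------
# the simulation driver
# ---------------------------------------------------------------------------

class Simulation:
    """Owns the mutable state, neighbour list, RNG stream and diagnostics.

    All stochastic draws come from one ``numpy.random.RandomState`` (a
    Mersenne-Twister generator) seeded with ``config.seed``: identical seeds
    give bit-identical trajectories.
    """

    def __init__(self, state: State, forcefield: ForceField, topology=None,
                 config: IntegratorConfig | None = None, box=None):
        if config is None:
            raise ValueError("an IntegratorConfig (with a seed) is required")
        self.state = state
        self.forcefield = forcefield
        self.topology = topology
        self.config = config
        self.box = SimulationBox(np.asarray(box, dtype=float)) if not isinstance(box, SimulationBox) else box
        self.box.validate_cutoff(forcefield.cutoff)
        self.rng = np.random.RandomState(config.seed)
        self.unwrapped = state.positions.copy()
        state.positions[...] = wrap_positions(state.positions, self.box.edge)
        self.diagnostics: dict[str, int] = {
            "overlap_events": 0,
            "missed_pair_events": 0,
            "clamped_angle_events": 0,
            "pair_list_rebuilds": 0,
        }
        self._steps_since_refresh = 0
        self._pairs = None
        self._refresh_pairs()
        self._forces = self._compute_forces(self.state.velocities)

    # -- internals -------------------------------------------------------

    def _refresh_pairs(self) -> None:
        rlist = self.forcefield.cutoff + self.config.neighbor_skin
        new_pairs = build_cell_list(self.state.positions, self.box.edge, rlist)
        if self.config.check_missed_pairs and self._pairs is not None:
            self.diagnostics["missed_pair_events"] += int(
                _kernels.count_missing_pairs(self.state.positions, self.box.edge,
                                             self.forcefield.cutoff,
                                             self._pairs[0], self._pairs[1]))
        self._pairs = new_pairs
        self._steps_since_refresh = 0
        self.diagnostics["pair_list_rebuilds"] += 1

    def _compute_forces(self, velocities: np.ndarray) -> np.ndarray:
        pi, pj = self._pairs
        ff = self.forcefield
        f = np.zeros_like(self.state.positions)
        noise = (self.rng.standard_normal(pi.size)
                 if (ff.sigma != 0.0 or ff.gamma != 0.0)
                 else np.zeros(pi.size))
        n_overlap = _kernels.pair_forces_kernel(
            self.state.positions, velocities, self.box.edge, pi, pj,
            self.state.types, ff.repulsion, ff.gamma, ff.sigma, ff.s,
            1.0 / math.sqrt(self.config.dt), noise, ff.cutoff, f)
        self.diagnostics["overlap_events"] += n_overlap
        topo = self.topology
        if topo is not None and topo.n_bonds:
            _kernels.bond_forces_kernel(self.state.positions, self.box.edge,
                                        topo.bond_i, topo.bond_j,
                                        topo.bond_ks, topo.bond_l0, f)
        if topo is not None and topo.n_angles:
            self.diagnostics["clamped_angle_events"] += int(
                _kernels.angle_forces_kernel(
                    self.state.positions, self.box.edge, topo.angle_i,
                    topo.angle_j, topo.angle_k, topo.angle_ka,
                    topo.angle_theta0, f))
        return f

    # -- public API ------------------------------------------------------

    def step(self) -> None:
        """One modified velocity-Verlet step.

        Position update with the current force, velocity prediction with
        factor lambda, force recomputation at the new positions/predicted
        velocities, then the velocity correction.
        """
        st = self.state
        cfg = self.config
        dt = cfg.dt
        inv_m = 1.0 / st.masses[:, None]
        f = self._forces
        disp = dt * st.velocities + 0.5 * dt * dt * f * inv_m
        self.unwrapped += disp
        st.positions += disp
        st.positions[...] = wrap_positions(st.positions, self.box.edge)
        v_pred = st.velocities + cfg.lam * dt * f * inv_m

        self._steps_since_refresh += 1
        if self._steps_since_refresh >= cfg.cell_refresh:
            self._refresh_pairs()

        f_new = self._compute_forces(v_pred)
        st.velocities += 0.5 * dt * (f + f_new) * inv_m
        self._forces = f_new
        st.step_count += 1

        if not np.all(np.isfinite(f_new)) or not np.all(np.isfinite(st.positions)):
            bad = np.flatnonzero(~np.isfinite(f_new).all(axis=1))[:10]
            raise RuntimeError(
                f"non-finite force/position at step {st.step_count}; "
                f"first affected beads: {bad.tolist()}; "
                f"dt={dt}, ff=(sigma={self.forcefield.sigma}, "
                f"gamma={self.forcefield.gamma}, s={self.forcefield.s})"
            )

    def run(self) -> Trajectory:
        """Warm up, then run production, saving frames on the configured schedule.

        Warm-up frames are discarded; a frame (positions, velocities and
        exactly-tracked unwrapped positions) is saved after every
        ``save_every`` production steps.
        """
        cfg = self.config
        for _ in range(cfg.warmup_steps):
            self.step()
        n_frames = cfg.production_steps // cfg.save_every
        n = self.state.n_beads
        pos = np.empty((n_frames, n, 3))
        vel = np.empty((n_frames, n, 3))
        unw = np.empty((n_frames, n, 3))
        frame = 0
        for k in range(1, cfg.production_steps + 1):
            self.step()
            if k % cfg.save_every == 0:
                pos[frame] = self.state.positions
                vel[frame] = self.state.velocities
                unw[frame] = self.unwrapped
                frame += 1
        return Trajectory(
            positions=pos[:frame], box=self.box.edge, velocities=vel[:frame],
            unwrapped=unw[:frame], frame_interval=cfg.save_every * cfg.dt,
            units="reduced", types=self.state.types.copy(),
            type_names=self.state.type_names,
            masses=self.state.masses.copy(),
            metadata=self.provenance(),
        )

    def provenance(self) -> dict[str, Any]:
        """Everything needed to reproduce this run."""
        ff = self.forcefield
        cfg = self.config
        return {
            "seed": cfg.seed,
            "n_beads": self.state.n_beads,
            "box": self.box.edge.tolist(),
            "forcefield": {
                "type_names": list(ff.type_names),
                "repulsion": ff.repulsion.tolist(),
                "sigma": ff.sigma, "gamma": ff.gamma, "s": ff.s,
                "cutoff": ff.cutoff,
            },
            "integrator": {
                "dt": cfg.dt, "lambda": cfg.lam,
                "cell_refresh": cfg.cell_refresh,
                "warmup_steps": cfg.warmup_steps,
                "production_steps": cfg.production_steps,
                "save_every": cfg.save_every,
                "neighbor_skin": cfg.neighbor_skin,
            },
            "units": "reduced (r_C, bead mass, k_BT, tau)",
            "diagnostics": dict(self.diagnostics),
        }


def integrate_step(state: State, forcefield: ForceField, topology, config:
                   IntegratorConfig, box) -> State:
    """Single modified velocity-Verlet step on ``state`` (mutated in place).

    Convenience wrapper for tests and single-shot use: builds a fresh
    neighbour list and RNG stream (seeded from ``config.seed`` and the
    current step count) each call.  Loops should use :class:`Simulation`.
    """
    cfg_seed = (config.seed + state.step_count) % (2**31)
    one = IntegratorConfig(**{**config.__dict__, "seed": cfg_seed})
    sim = Simulation(state, forcefield, topology, one, box)
    sim.step()
    return state


def run_simulation(initial_state: State, forcefield: ForceField, topology,
                   config: IntegratorConfig, box) -> Trajectory:
    """Run warm-up + production and return the saved trajectory."""
    return Simulation(initial_state, forcefield, topology, config, box).run()
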