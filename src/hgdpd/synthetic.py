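"""Synthetic fine-grained trajectory generators.

The coarse-graining and calibration stages consume per-frame molecule
positions and velocities.  These generators provide seeded stand-ins with
known ground truth: periodic Brownian point clouds with a prescribed
diffusivity and Maxwell-Boltzmann velocities (a *fixture*, not a water
model — there is no inter-molecular structure), harmonic bond/angle sample
draws, and simple-cubic lattices for pair-search and RDF oracles.  Ground
truth is embedded in the trajectory metadata so recovery tests can read it
back.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .trajectory import Trajectory, wrap_positions

__all__ = [
    "GeneratorSpec",
    "generate_brownian_water",
    "generate_bonded_samples",
    "generate_lattice",
    "BOLTZMANN_J_PER_K",
    "SPC_WATER_MASS_KG",
]

BOLTZMANN_J_PER_K = 1.380649e-23
#: one water molecule (18.0153 g/mol)
SPC_WATER_MASS_KG = 2.9915e-26


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the Brownian water fixture (real units: Angstrom, ps, K).

    Defaults emulate the reference fine-grained system: 967 molecules in a
    31.036 Angstrom periodic cube at 298 K, frames every 2 ps.  The default
    molecular diffusivity of 0.6 A^2/ps is chosen so that clouds of four
    molecules diffuse near the 0.15 A^2/ps coarse-grained regime (the mean
    of four independent Brownian walkers diffuses four times slower).
    """

    n_molecules: int = 967
    box: float = 31.036
    target_diffusivity: float = 0.6
    temperature: float = 298.0
    mass: float = SPC_WATER_MASS_KG
    frame_interval: float = 2.0
    n_frames: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_molecules <= 0 or self.box <= 0 or self.temperature <= 0
                or self.mass <= 0 or self.frame_interval <= 0
                or self.n_frames <= 0):
            raise ValueError("all GeneratorSpec fields must be positive")
        if self.target_diffusivity < 0:
            raise ValueError("target_diffusivity must be >= 0")


def generate_brownian_water(spec: GeneratorSpec) -> Trajectory:
    """Independent periodic Brownian motion with Maxwell-Boltzmann velocities.

    Per-frame displacements are Gaussian with variance ``2 D dt`` per axis;
    velocities are redrawn from the Maxwell-Boltzmann distribution at the
    spec temperature every frame (positions and velocities are therefore
    uncorrelated, which is all the downstream statistics need).
    """
    rng = np.random.RandomState(spec.seed)
    box = np.full(3, spec.box)
    shape = (spec.n_frames, spec.n_molecules, 3)
    unwrapped = np.empty(shape)
    unwrapped[0] = rng.uniform(0.0, spec.box, (spec.n_molecules, 3))
    if spec.n_frames > 1:
        step_sd = np.sqrt(2.0 * spec.target_diffusivity * spec.frame_interval)
        steps = rng.standard_normal((spec.n_frames - 1, spec.n_molecules, 3)) * step_sd
        unwrapped[1:] = unwrapped[0] + np.cumsum(steps, axis=0)
    # velocity scale in Angstrom/ps: sqrt(kB T / m) [m/s] * 1e-2
    v_sd = np.sqrt(BOLTZMANN_J_PER_K * spec.temperature / spec.mass) * 1e-2
    velocities = rng.standard_normal(shape) * v_sd
    return Trajectory(
        positions=wrap_positions(unwrapped, box), box=box,
        velocities=velocities, unwrapped=unwrapped,
        frame_interval=spec.frame_interval, units="real",
        metadata={"generator": "brownian_water", "ground_truth_D": spec.target_diffusivity,
                  **asdict(spec)},
    )


def generate_bonded_samples(k: float, rest: float, kbt: float = 1.0,
                            n: int = 1000, seed: int = 0) -> np.ndarray:
    """Gaussian bond-length or angle samples: mean ``rest``, variance ``kbt/k``."""
    if k <= 0:
        raise ValueError(f"stiffness k must be > 0, got {k}")
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    rng = np.random.RandomState(seed)
    return rest + np.sqrt(kbt / k) * rng.standard_normal(n)


def generate_lattice(spacing: float, n_per_axis: int) -> Trajectory:
    """Simple-cubic lattice in a periodic box of edge ``spacing * n_per_axis``."""
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if n_per_axis < 1:
        raise ValueError("n_per_axis must be >= 1")
    g = np.arange(n_per_axis) * spacing
    pos = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    box = np.full(3, spacing * n_per_axis)
    return Trajectory(positions=pos[None], box=box, units="real",
                      metadata={"generator": "lattice", "spacing": spacing,
                                "n_per_axis": n_per_axis})
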