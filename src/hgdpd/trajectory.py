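"""Time-ordered frames of positions (and optionally velocities) in a periodic box.

One container serves both sides of the workflow: reduced-unit DPD
trajectories produced by the engine and real-unit (Angstrom / ps)
fine-grained or coarse-grained trajectories consumed and produced by the
mapping module.  ``units`` records which convention applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["Trajectory", "wrap_positions", "minimum_image"]


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into ``[0, L)`` per axis."""
    return np.mod(positions, box)


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention applied to a displacement array."""
    return displacement - box * np.rint(displacement / box)


@dataclass
class Trajectory:
    """Frames of a periodic simulation.

    Attributes
    ----------
    positions:
        ``(n_frames, n_particles, 3)`` wrapped coordinates.
    box:
        ``(3,)`` box edge lengths (cubic in practice; stored per axis).
    velocities:
        Optional ``(n_frames, n_particles, 3)``.
    unwrapped:
        Optional unwrapped coordinates of identical shape, used for MSD
        analysis.  The engine tracks these exactly; file readers leave them
        unset and the observables module reconstructs them by minimum-image
        chaining.
    frame_interval:
        Time between saved frames (tau for reduced, ps for real units).
    units:
        ``"reduced"`` or ``"real"``.
    types:
        Optional integer type code per particle, indexing ``type_names``.
    masses:
        Optional per-particle masses (reduced or kg, matching ``units``).
    metadata:
        Free-form provenance (seed, parameters, generator ground truth, ...).
    """

    positions: np.ndarray
    box: np.ndarray
    velocities: np.ndarray | None = None
    unwrapped: np.ndarray | None = None
    frame_interval: float = 1.0
    units: str = "reduced"
    types: np.ndarray | None = None
    type_names: tuple[str, ...] | None = None
    masses: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 3:
            raise ValueError(
                f"positions must have shape (n_frames, n, 3), got {self.positions.shape}"
            )
        for name in ("velocities", "unwrapped"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.positions.shape:
                    raise ValueError(f"{name} shape {arr.shape} != positions shape")
                setattr(self, name, arr)
        if self.units not in ("reduced", "real"):
            raise ValueError(f"units must be 'reduced' or 'real', got {self.units!r}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def type_indices(self, name: str) -> np.ndarray:
        """Particle indices of the bead type called ``name``."""
        if self.types is None or self.type_names is None:
            raise ValueError("trajectory carries no type information")
        try:
            code = self.type_names.index(name)
        except ValueError:
            raise KeyError(f"unknown bead type {name!r}; known: {self.type_names}") from None
        return np.flatnonzero(self.types == code)

    def unwrap(self) -> np.ndarray:
        """Unwrapped coordinates, reconstructing by minimum-image chaining if needed.

        Chaining assumes no particle moves further than half a box edge
        between saved frames; save more often if that is violated.
        """
        if self.unwrapped is not None:
            return self.unwrapped
        out = np.empty_like(self.positions)
        out[0] = self.positions[0]
        steps = minimum_image(np.diff(self.positions, axis=0), self.box)
        out[1:] = out[0] + np.cumsum(steps, axis=0)
        return out
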