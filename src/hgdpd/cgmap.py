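"""Mapping fine-grained molecule trajectories onto equal-occupancy beads.

Solvent molecules move independently, so the molecules belonging to one
coarse-grained bead must be re-identified dynamically in every frame.  The
algorithm here is a step-wise iterative unique-nearest-neighbour search that
*forces* every bead to own exactly ``cg_ratio`` molecules:

1. Bead positions start from randomly chosen molecule coordinates of the
   first frame (later frames start from the previous frame's updated
   positions).
2. The assignment runs ``cg_ratio`` sequential rounds.  In each round every
   bead acquires exactly one new molecule: each bead claims its nearest
   still-unassigned molecule (minimum-image distance); a molecule claimed by
   several beads goes to the closest claimant, and the losing beads search
   again among the remaining molecules until every bead has gained one.
3. Only after all rounds finish is each bead position updated to the
   (minimum-image aware) centre of mass of its molecular cloud.

Equal occupancy and the partition property (no molecule in two beads) hold
by construction; a few molecules should be left unassigned as a stability
margin.  Distance ties are broken deterministically: lower bead index first,
then lower molecule id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory, minimum_image, wrap_positions

__all__ = [
    "CGAssignment",
    "initialize_beads",
    "assign_frame",
    "update_bead_positions",
    "map_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass
class CGAssignment:
    """Partition of molecules into equal-size clouds, one per bead.

    ``members[b]`` lists the molecule ids of bead ``b`` in the order they
    were acquired (one per round).
    """

    members: np.ndarray          # (n_beads, cg_ratio) molecule ids
    bead_positions: np.ndarray   # (n_beads, 3) positions used for the search

    @property
    def n_beads(self) -> int:
        return self.members.shape[0]

    @property
    def cg_ratio(self) -> int:
        return self.members.shape[1]

    def validate(self, n_molecules: int) -> None:
        flat = self.members.ravel()
        if flat.min() < 0 or flat.max() >= n_molecules:
            raise AssertionError("assignment references molecules out of range")
        if np.unique(flat).size != flat.size:
            raise AssertionError("a molecule belongs to more than one bead")


def _check_margin(n_molecules: int, n_beads: int, cg_ratio: int) -> None:
    needed = n_beads * cg_ratio
    if needed > n_molecules:
        raise ValueError(
            f"{n_beads} beads x ratio {cg_ratio} = {needed} molecules needed "
            f"but only {n_molecules} available; choose n_beads so that a few "
            "free molecules remain as a stability margin"
        )
    if needed == n_molecules:
        logger.warning(
            "n_beads * cg_ratio equals the molecule count exactly; the "
            "assignment is still valid but leaves no stability margin"
        )


def initialize_beads(first_frame: np.ndarray, n_beads: int, cg_ratio: int,
                     seed: int) -> np.ndarray:
    """Seed bead positions: distinct molecule coordinates from the first frame."""
    first_frame = np.asarray(first_frame, dtype=float)
    _check_margin(first_frame.shape[0], n_beads, cg_ratio)
    rng = np.random.RandomState(seed)
    picks = rng.choice(first_frame.shape[0], size=n_beads, replace=False)
    return first_frame[picks].copy()


def assign_frame(bead_positions: np.ndarray, frame_positions: np.ndarray,
                 box: np.ndarray, cg_ratio: int) -> CGAssignment:
    """One frame of the step-wise iterative unique-nearest-neighbour search.

    Bead positions are *not* moved during assignment; call
    :func:`update_bead_positions` afterwards.
    """
    bead_positions = np.asarray(bead_positions, dtype=float)
    frame_positions = np.asarray(frame_positions, dtype=float)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,))
    n_beads = bead_positions.shape[0]
    n_mol = frame_positions.shape[0]
    _check_margin(n_mol, n_beads, cg_ratio)

    # distances are fixed for the whole frame: beads do not move while assigning
    delta = minimum_image(bead_positions[:, None, :] - frame_positions[None, :, :], box)
    d2 = np.einsum("bmx,bmx->bm", delta, delta)

    available = np.ones(n_mol, dtype=bool)
    members = np.full((n_beads, cg_ratio), -1, dtype=np.int64)
    for rnd in range(cg_ratio):
        pending = np.arange(n_beads)
        iterations = 0
        while pending.size:
            iterations += 1
            if iterations > n_beads + 1:
                raise AssertionError(
                    f"assignment round {rnd} failed to terminate after "
                    f"{iterations} iterations; pending beads: {pending.tolist()}"
                )
            masked = d2[pending][:, available]
            if masked.shape[1] < pending.size:
                raise AssertionError(
                    f"round {rnd}: {pending.size} beads compete for "
                    f"{int(available.sum())} remaining molecules"
                )
            avail_ids = np.flatnonzero(available)
            # nearest available molecule per pending bead; argmin takes the
            # lowest molecule id on ties
            local = np.argmin(masked, axis=1)
            claimed = avail_ids[local]
            dist = masked[np.arange(pending.size), local]
            # conflict resolution: each molecule goes to the closest claimant,
            # ties to the lower bead index (stable ordering of pending)
            order = np.lexsort((pending, dist))
            seen: set[int] = set()
            winners = []
            for idx in order:
                mol = claimed[idx]
                if mol in seen:
                    continue
                seen.add(mol)
                winners.append(idx)
                members[pending[idx], rnd] = mol
            won_mols = claimed[np.array(winners, dtype=int)]
            available[won_mols] = False
            lost = np.ones(pending.size, dtype=bool)
            lost[np.array(winners, dtype=int)] = False
            pending = pending[lost]
    return CGAssignment(members=members, bead_positions=bead_positions.copy())


def update_bead_positions(assignment: CGAssignment, frame_positions: np.ndarray,
                          box: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Centre of mass of each cloud, minimum-image aware.

    Members are unwrapped relative to their bead before averaging so that a
    cloud straddling the periodic boundary lands on the short arc; the
    result is re-wrapped into the box.
    """
    frame_positions = np.asarray(frame_positions, dtype=float)
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,))
    ref = assignment.bead_positions
    mem = frame_positions[assignment.members]              # (B, R, 3)
    rel = minimum_image(mem - ref[:, None, :], box)
    if masses is None:
        com = rel.mean(axis=1)
    else:
        w = np.asarray(masses, dtype=float)[assignment.members]
        com = (rel * w[..., None]).sum(axis=1) / w.sum(axis=1)[:, None]
    return wrap_positions(ref + com, box)


def map_trajectory(fine: Trajectory, cg_ratio: int, n_beads: int, seed: int,
                   velocity_mode: str = "member-mean",
                   molecule_mass: float | None = None,
                   cloud_radius_warn: float | None = None) -> Trajectory:
    """Map a fine-grained trajectory onto a coarse-grained bead trajectory.

    Frame 0 seeds the bead positions from random molecule coordinates; each
    subsequent frame starts the assignment from the previous frame's updated
    bead positions (frame chaining).  Per-frame bead velocities are either
    the mean of the member molecule velocities (``"member-mean"``, requires
    fine velocities) or the bead displacement divided by the frame interval
    (``"displacement"``, forward difference, last frame repeats the
    previous value).

    A warning is logged whenever a bead's cloud radius exceeds
    ``cloud_radius_warn`` (same length unit as the trajectory).
    """
    if fine.n_frames < 1:
        raise ValueError("need at least one frame")
    if velocity_mode not in ("member-mean", "displacement"):
        raise ValueError(f"unknown velocity_mode {velocity_mode!r}")
    if velocity_mode == "member-mean" and fine.velocities is None:
        raise ValueError("member-mean velocities need fine-grained velocities; "
                         "use velocity_mode='displacement'")
    box = fine.box
    bead_pos = initialize_beads(fine.positions[0], n_beads, cg_ratio, seed)
    positions = np.empty((fine.n_frames, n_beads, 3))
    unwrapped = np.empty_like(positions)
    velocities = np.empty_like(positions)
    members = np.empty((fine.n_frames, n_beads, cg_ratio), dtype=np.int64)
    prev_unwrapped = None
    for t in range(fine.n_frames):
        frame = fine.positions[t]
        if frame.shape[0] != fine.positions[0].shape[0]:
            raise ValueError(f"frame {t}: molecule count changed")
        assignment = assign_frame(bead_pos, frame, box, cg_ratio)
        assignment.validate(frame.shape[0])
        new_pos = update_bead_positions(assignment, frame, box)
        members[t] = assignment.members
        if cloud_radius_warn is not None:
            rel = minimum_image(frame[assignment.members] - new_pos[:, None, :], box)
            radius = np.sqrt((rel**2).sum(axis=2)).max(axis=1)
            for b in np.flatnonzero(radius > cloud_radius_warn):
                logger.warning("frame %d: bead %d cloud radius %.3f exceeds %.3f",
                               t, b, radius[b], cloud_radius_warn)
        positions[t] = new_pos
        if t == 0:
            unwrapped[0] = new_pos
        else:
            unwrapped[t] = prev_unwrapped + minimum_image(
                new_pos - positions[t - 1], box)
        prev_unwrapped = unwrapped[t]
        if velocity_mode == "member-mean":
            velocities[t] = fine.velocities[t][assignment.members].mean(axis=1)
        bead_pos = new_pos
    if velocity_mode == "displacement":
        if fine.n_frames > 1:
            velocities[:-1] = np.diff(unwrapped, axis=0) / fine.frame_interval
            velocities[-1] = velocities[-2]
        else:
            velocities[:] = 0.0
    bead_mass = None
    if molecule_mass is not None:
        bead_mass = np.full(n_beads, cg_ratio * molecule_mass)
    return Trajectory(
        positions=positions, box=box, velocities=velocities,
        unwrapped=unwrapped, frame_interval=fine.frame_interval,
        units=fine.units, masses=bead_mass,
        metadata={**fine.metadata, "cg_ratio": cg_ratio, "n_beads": n_beads,
                  "cg_seed": seed, "velocity_mode": velocity_mode,
                  "members": members},
    )
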