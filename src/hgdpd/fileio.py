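"""Trajectory file formats: extended XYZ (canonical) and GRO.

Extended XYZ carries positions *and* velocities plus per-frame metadata
(step, time, box, units) on the comment line, and is therefore the
package's canonical format.  GRO is supported for interoperability with
standard MD tooling; per that format's convention lengths are nm and
velocities nm/ps on file, converted to/from the package's internal
Angstrom / ps on the fly (reduced-unit trajectories are written
unit-for-unit with a flag in the title line).  Multi-frame GRO files are
concatenated frames, as produced by common trajectory tools.

Parse errors name the offending line.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .trajectory import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_xyz", "read_xyz",
           "write_gro", "read_gro"]

#: GRO atom names are <= 5 chars and cannot hold "(H2O)4"
_GRO_NAMES = {"(H2O)4": "W", "GalA": "GA", "GalA(-)": "GAD"}
_GRO_NAMES_INV = {v: k for k, v in _GRO_NAMES.items()}


def _type_labels(traj: Trajectory) -> list[str]:
    if traj.types is not None and traj.type_names is not None:
        return [traj.type_names[t] for t in traj.types]
    return ["X"] * traj.n_particles


def _codes_from_labels(labels: list[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    names = tuple(dict.fromkeys(labels))
    codes = np.array([names.index(l) for l in labels], dtype=np.int64)
    return codes, names


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    """Write all frames as extended XYZ (velocities included when present)."""
    labels = _type_labels(traj)
    with_vel = traj.velocities is not None
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            bx, by, bz = traj.box
            fh.write(
                f'frame={t} time={t * traj.frame_interval:.10g} '
                f'box="{bx:.10g} {by:.10g} {bz:.10g}" units={traj.units} '
                f'velocities={int(with_vel)}\n'
            )
            for i in range(traj.n_particles):
                x, y, z = traj.positions[t, i]
                line = f"{labels[i]} {x:.8f} {y:.8f} {z:.8f}"
                if with_vel:
                    vx, vy, vz = traj.velocities[t, i]
                    line += f" {vx:.8f} {vy:.8f} {vz:.8f}"
                fh.write(line + "\n")


def read_xyz(path) -> Trajectory:
    """Read an extended XYZ trajectory written by :func:`write_xyz`."""
    frames, vels, labels = [], [], None
    box = units = None
    times = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_total = len(lines)
    while ln < n_total:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ValueError(f"{path}:{ln + 1}: expected an atom count, got "
                             f"{lines[ln]!r}") from None
        if ln + 1 + n >= n_total + 1:
            raise ValueError(
                f"{path}:{ln + 1}: truncated frame {len(frames)}: header "
                f"promises {n} atoms but the file ends early")
        comment = lines[ln + 1]
        m = re.search(r'box="([^"]+)"', comment)
        if not m:
            raise ValueError(f"{path}:{ln + 2}: comment line lacks box=\"...\"")
        box = np.array([float(v) for v in m.group(1).split()])
        mu = re.search(r"units=(\S+)", comment)
        units = mu.group(1) if mu else "real"
        mt = re.search(r"time=(\S+)", comment)
        times.append(float(mt.group(1)) if mt else float(len(frames)))
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        has_vel = True
        frame_labels = []
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            if len(parts) not in (4, 7):
                raise ValueError(
                    f"{path}:{ln + 3 + i}: expected 'type x y z [vx vy vz]', "
                    f"got {lines[ln + 2 + i]!r}")
            frame_labels.append(parts[0])
            pos[i] = [float(v) for v in parts[1:4]]
            if len(parts) == 7:
                vel[i] = [float(v) for v in parts[4:7]]
            else:
                has_vel = False
        if labels is None:
            labels = frame_labels
        frames.append(pos)
        vels.append(vel if has_vel else None)
        ln += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    positions = np.stack(frames)
    velocities = np.stack(vels) if all(v is not None for v in vels) else None
    codes, names = _codes_from_labels(labels)
    interval = times[1] - times[0] if len(times) > 1 else 1.0
    return Trajectory(positions=positions, box=box, velocities=velocities,
                      frame_interval=interval, units=units, types=codes,
                      type_names=names, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def write_gro(traj: Trajectory, path) -> None:
    """Write concatenated GRO frames (nm / nm-per-ps for real-unit input)."""
    scale = 0.1 if traj.units == "real" else 1.0  # Angstrom -> nm
    labels = _type_labels(traj)
    short = [_GRO_NAMES.get(l, l[:5]) for l in labels]
    with_vel = traj.velocities is not None
    with open(path, "w") as fh:
        for t in range(traj.n_frames):
            fh.write(f"hgdpd frame {t}, t= {t * traj.frame_interval:.5f}, "
                     f"units={traj.units}\n")
            fh.write(f"{traj.n_particles}\n")
            for i in range(traj.n_particles):
                x, y, z = traj.positions[t, i] * scale
                line = (f"{(i % 99999) + 1:>5d}{'MOL':<5s}{short[i]:>5s}"
                        f"{(i % 99999) + 1:>5d}{x:8.3f}{y:8.3f}{z:8.3f}")
                if with_vel:
                    vx, vy, vz = traj.velocities[t, i] * scale
                    line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
                fh.write(line + "\n")
            bx, by, bz = traj.box * scale
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


def read_gro(path, frame_interval: float = 1.0) -> Trajectory:
    """Read a (possibly multi-frame) GRO file into Angstrom / ps.

    Reduced-unit files written by :func:`write_gro` (flagged in the title
    line) are read back without rescaling.
    """
    with open(path) as fh:
        lines = fh.readlines()
    frames, vels, labels = [], [], None
    box = None
    units = "real"
    ln = 0
    n_total = len(lines)
    while ln < n_total:
        if not lines[ln].strip():
            ln += 1
            continue
        title = lines[ln]
        if "units=reduced" in title:
            units = "reduced"
        try:
            n = int(lines[ln + 1].strip())
        except (IndexError, ValueError):
            raise ValueError(f"{path}:{ln + 2}: expected an atom count") from None
        if ln + 2 + n + 1 > n_total:
            raise ValueError(f"{path}:{ln + 1}: truncated frame {len(frames)}: "
                             f"{n} atoms plus a box line do not fit")
        pos = np.empty((n, 3))
        vel = np.zeros((n, 3))
        has_vel = False
        frame_labels = []
        for i in range(n):
            line = lines[ln + 2 + i].rstrip("\n")
            try:
                frame_labels.append(line[10:15].strip())
                pos[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
                if len(line) >= 68:
                    vel[i] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                    has_vel = True
            except (ValueError, IndexError):
                raise ValueError(f"{path}:{ln + 3 + i}: malformed atom line "
                                 f"{line!r}") from None
        box_parts = lines[ln + 2 + n].split()
        if len(box_parts) < 3:
            raise ValueError(f"{path}:{ln + 3 + n}: malformed box line")
        box = np.array([float(v) for v in box_parts[:3]])
        if labels is None:
            labels = frame_labels
        frames.append(pos)
        vels.append(vel if has_vel else None)
        ln += 3 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    scale = 10.0 if units == "real" else 1.0  # nm -> Angstrom
    positions = np.stack(frames) * scale
    velocities = (np.stack(vels) * scale
                  if all(v is not None for v in vels) else None)
    full = [_GRO_NAMES_INV.get(l, l) for l in labels]
    codes, names = _codes_from_labels(full)
    return Trajectory(positions=positions, box=box * scale,
                      velocities=velocities, frame_interval=frame_interval,
                      units=units, types=codes, type_names=names,
                      metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# format dispatch
# ---------------------------------------------------------------------------

def _format_of(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("xyz", "gro"):
        return suffix
    raise ValueError(f"cannot infer format from {path!r}; pass fmt='xyz'|'gro'")


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    {"xyz": write_xyz, "gro": write_gro}[_format_of(path, fmt)](traj, path)


def read_trajectory(path, fmt: str | None = None, **kw) -> Trajectory:
    return {"xyz": read_xyz, "gro": read_gro}[_format_of(path, fmt)](path, **kw)
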