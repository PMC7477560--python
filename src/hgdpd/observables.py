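"""Trajectory statistics used as calibration targets.

Radial distribution functions, mean-squared-displacement diffusion
coefficients, velocity statistics and kinetic temperature, and
bond-length/angle distributions.  All functions accept the package's
:class:`~hgdpd.trajectory.Trajectory` container in either reduced or real
units; outputs carry the same unit convention as their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .trajectory import Trajectory, minimum_image

__all__ = [
    "RDFCurve",
    "MSDSeries",
    "VelocityStats",
    "rdf",
    "diffusion_coefficient",
    "velocity_stats",
    "kinetic_temperature",
    "bonded_distributions",
    "BondedDistribution",
]


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------

@dataclass
class RDFCurve:
    """g(r) on a uniform grid; pair counts are normalised by the ideal-gas
    shell expectation at the system's partial densities."""

    r: np.ndarray
    g: np.ndarray
    bin_width: float
    r_max: float
    pair: tuple[str, str] | None = None

    def tail_mean(self, fraction: float = 0.2) -> float:
        """Average of g over the outermost ``fraction`` of bins."""
        k = max(1, int(round(self.g.size * fraction)))
        return float(self.g[-k:].mean())

    def squared_distance(self, other: "RDFCurve") -> float:
        """Unweighted least-squares distance to another curve (same binning)."""
        if self.g.size != other.g.size or abs(self.bin_width - other.bin_width) > 1e-12:
            raise ValueError("RDF curves must share binning to be compared")
        return float(np.sum((self.g - other.g) ** 2))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"r": self.r, "g": self.g})


def rdf(traj: Trajectory, type_pair: tuple[str, str] | None = None,
        bin_width: float = 0.05, r_max: float | None = None) -> RDFCurve:
    """Radial distribution function averaged over frames.

    ``type_pair`` selects the two bead types to correlate (both may be
    equal); ``None`` uses all particles.  ``r_max`` must not exceed half the
    smallest box edge (minimum-image validity) and defaults to it.
    """
    box = traj.box
    half = float(box.min()) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-12:
        raise ValueError(f"r_max={r_max} exceeds half the box edge ({half})")
    if bin_width <= 0 or r_max <= bin_width:
        raise ValueError("need 0 < bin_width < r_max")

    if type_pair is None:
        sel_a = sel_b = np.arange(traj.n_particles)
        same = True
    else:
        sel_a = traj.type_indices(type_pair[0])
        sel_b = traj.type_indices(type_pair[1])
        same = type_pair[0] == type_pair[1]
        if sel_a.size == 0 or sel_b.size == 0:
            raise ValueError(f"empty type selection {type_pair}")

    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    for t in range(traj.n_frames):
        pos = np.ascontiguousarray(traj.positions[t])
        if same:
            d = _kernels.self_distances(pos[sel_a], box, r_max)
        else:
            d = _kernels.cross_distances(pos[sel_a], pos[sel_b], box, r_max)
        hist += np.histogram(d, bins=edges)[0]
    hist /= traj.n_frames

    volume = float(np.prod(box))
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n = sel_a.size
        ideal_pairs = 0.5 * n * (n - 1) * shell / volume
    else:
        ideal_pairs = sel_a.size * sel_b.size * shell / volume
    g = np.divide(hist, ideal_pairs, out=np.zeros_like(hist), where=ideal_pairs > 0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return RDFCurve(r=centres, g=g, bin_width=bin_width, r_max=r_max,
                    pair=type_pair)


# ---------------------------------------------------------------------------
# diffusion from the mean-squared displacement
# ---------------------------------------------------------------------------

@dataclass
class MSDSeries:
    """MSD(lag) with its linear fit and the resulting diffusion coefficient.

    ``D = slope / 6`` in 3-D.  ``exponent`` is the best-fit power of
    MSD ~ t^exponent over the fit window; values near 2 indicate a
    ballistic (non-diffusive) regime and set the ``ballistic`` flag.
    """

    lags: np.ndarray
    msd: np.ndarray
    fit_window: tuple[float, float]
    D: float
    slope: float
    intercept: float
    r_squared: float
    exponent: float
    ballistic: bool = field(default=False)


def diffusion_coefficient(traj: Trajectory, fit_window: tuple[float, float] = (0.2, 0.8),
                          type_name: str | None = None) -> MSDSeries:
    """Self-diffusion coefficient from the MSD slope.

    Uses unwrapped coordinates (exact if the trajectory carries them,
    otherwise reconstructed by minimum-image chaining, which assumes no
    particle moves more than half a box edge between frames), all particles
    of the selected type and every frame as a time origin.
    """
    coords = traj.unwrap()
    if type_name is not None:
        coords = coords[:, traj.type_indices(type_name), :]
    n_frames = coords.shape[0]
    if n_frames < 3:
        raise ValueError("need at least 3 frames for an MSD")
    max_lag = n_frames - 1
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    for k, lag in enumerate(lags):
        d = coords[lag:] - coords[:-lag]
        msd[k] = np.mean(np.sum(d * d, axis=-1))
    times = lags * traj.frame_interval

    lo, hi = fit_window
    sel = (lags >= lo * max_lag) & (lags <= hi * max_lag)
    if sel.sum() < 5:
        raise ValueError(
            f"fit window {fit_window} leaves {int(sel.sum())} lags; need >= 5 "
            "(save more frames or widen the window)"
        )
    slope, intercept = np.polyfit(times[sel], msd[sel], 1)
    resid = msd[sel] - (slope * times[sel] + intercept)
    ss_tot = np.sum((msd[sel] - msd[sel].mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if np.all(msd[sel] > 0):
        exponent = float(np.polyfit(np.log(times[sel]), np.log(msd[sel]), 1)[0])
    else:
        exponent = 0.0
    full_msd = np.concatenate([[0.0], msd])
    full_lags = np.concatenate([[0.0], times])
    return MSDSeries(lags=full_lags, msd=full_msd, fit_window=fit_window,
                     D=float(slope) / 6.0, slope=float(slope),
                     intercept=float(intercept), r_squared=r2,
                     exponent=exponent, ballistic=exponent > 1.5)


# ---------------------------------------------------------------------------
# velocities and temperature
# ---------------------------------------------------------------------------

@dataclass
class VelocityStats:
    mean_speed: float
    rms_speed: float
    component_variance: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges)


def velocity_stats(traj: Trajectory, type_name: str | None = None,
                   n_bins: int = 50) -> VelocityStats:
    """Mean/RMS speed, per-component variance and a speed histogram."""
    if traj.velocities is None:
        raise ValueError("trajectory carries no velocities")
    v = traj.velocities
    if type_name is not None:
        v = v[:, traj.type_indices(type_name), :]
    speeds = np.sqrt(np.sum(v * v, axis=-1)).ravel()
    counts, edges = np.histogram(speeds, bins=n_bins)
    return VelocityStats(
        mean_speed=float(speeds.mean()),
        rms_speed=float(np.sqrt(np.mean(speeds**2))),
        component_variance=v.reshape(-1, 3).var(axis=0),
        histogram=(counts, edges),
    )


def kinetic_temperature(traj: Trajectory) -> float:
    """Equipartition temperature T = <sum m v^2> / (3 N k_B), frame-averaged.

    In reduced units the result is directly in k_BT; masses default to 1
    when the trajectory does not carry them.
    """
    if traj.velocities is None:
        raise ValueError("trajectory carries no velocities")
    m = traj.masses if traj.masses is not None else np.ones(traj.n_particles)
    v2 = np.sum(traj.velocities**2, axis=-1)          # (F, N)
    return float(np.mean(np.sum(m * v2, axis=1) / (3.0 * traj.n_particles)))


# ---------------------------------------------------------------------------
# bonded geometry distributions
# ---------------------------------------------------------------------------

@dataclass
class BondedDistribution:
    """Samples and moments of one bonded-term type.

    For angles, ``corrected_mean``/``corrected_variance`` are moments of the
    sin(theta)-deweighted distribution (each sample weighted by 1/sin(theta)),
    i.e. of the distribution with the 3-D phase-space factor removed.  The
    raw moments of soft angles near pi are biased away from the harmonic
    k_BT/k_A expectation by that factor; see the methods documentation.
    """

    label: str
    kind: str                     # "bond" | "angle"
    samples: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]
    mean: float
    variance: float
    corrected_mean: float | None = None
    corrected_variance: float | None = None


def _term_label(type_names, types, idx) -> str:
    return "-".join(type_names[types[i]] for i in idx)


def _safe_hist(x: np.ndarray, n_bins: int):
    """Histogram that tolerates (near-)constant samples, e.g. frozen geometry."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-9 * max(1.0, abs(hi)):
        centre = 0.5 * (lo + hi)
        return np.histogram(x, bins=n_bins, range=(centre - 0.5, centre + 0.5))
    return np.histogram(x, bins=n_bins)


def bonded_distributions(traj: Trajectory, topology, n_bins: int = 60
                         ) -> dict[str, BondedDistribution]:
    """Per-bond-type length and per-angle-type angle distributions.

    Terms are grouped by the type sequence of their beads (reversal
    normalised), pooled over frames.
    """
    box = traj.box
    names = topology.type_names
    out: dict[str, BondedDistribution] = {}

    groups: dict[str, list[int]] = {}
    for b in range(topology.n_bonds):
        i, j = topology.bond_i[b], topology.bond_j[b]
        key = min(_term_label(names, topology.types, (i, j)),
                  _term_label(names, topology.types, (j, i)))
        groups.setdefault(key, []).append(b)
    for label, idxs in groups.items():
        bi = topology.bond_i[idxs]
        bj = topology.bond_j[idxs]
        d = minimum_image(traj.positions[:, bi] - traj.positions[:, bj], box)
        lengths = np.sqrt(np.sum(d * d, axis=-1)).ravel()
        out[label] = BondedDistribution(
            label=label, kind="bond", samples=lengths,
            histogram=_safe_hist(lengths, n_bins),
            mean=float(lengths.mean()), variance=float(lengths.var()),
        )

    agroups: dict[str, list[int]] = {}
    for a in range(topology.n_angles):
        i, j, k = topology.angle_i[a], topology.angle_j[a], topology.angle_k[a]
        key = min(_term_label(names, topology.types, (i, j, k)),
                  _term_label(names, topology.types, (k, j, i)))
        agroups.setdefault(key, []).append(a)
    for label, idxs in agroups.items():
        ai = topology.angle_i[idxs]
        aj = topology.angle_j[idxs]
        ak = topology.angle_k[idxs]
        u = minimum_image(traj.positions[:, ai] - traj.positions[:, aj], box)
        w = minimum_image(traj.positions[:, ak] - traj.positions[:, aj], box)
        cosang = np.sum(u * w, axis=-1) / (
            np.linalg.norm(u, axis=-1) * np.linalg.norm(w, axis=-1))
        theta = np.arccos(np.clip(cosang, -1.0, 1.0)).ravel()
        wts = 1.0 / np.maximum(np.sin(theta), 1e-8)
        wmean = float(np.average(theta, weights=wts))
        wvar = float(np.average((theta - wmean) ** 2, weights=wts))
        out[label] = BondedDistribution(
            label=label, kind="angle", samples=theta,
            histogram=_safe_hist(theta, n_bins),
            mean=float(theta.mean()), variance=float(theta.var()),
            corrected_mean=wmean, corrected_variance=wvar,
        )
    return out
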