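"""Bead types, bonded-parameter tables and system builders.

The model has three bead types: ``(H2O)4`` (four water molecules, the
reduced mass unit), ``GalA`` (a protonated galacturonic-acid unit) and
``GalA(-)`` (a deprotonated unit).  Homogalacturonan chains are linear
sequences of GalA/GalA(-) beads joined by harmonic distance bonds, with a
harmonic angle on every interior triplet.  Bond and angle parameters depend
on the protonation states of the participating units and come from the
packaged tables; lookups are symmetric under reversal of the type sequence
and only the listed combinations exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import parameters
from .core import State, maxwell_boltzmann_velocities
from .trajectory import wrap_positions

__all__ = [
    "BEAD_TYPES",
    "bead_mass",
    "lookup_pair_repulsion",
    "lookup_bond",
    "lookup_angle",
    "BondTerm",
    "AngleTerm",
    "SystemTopology",
    "build_chain",
    "build_system",
    "CHAIN_PATTERNS",
]

BEAD_TYPES = parameters.BEAD_TYPES

CHAIN_PATTERNS = ("all-protonated", "all-deprotonated", "alternating",
                  "alternating-pairs")


def bead_mass(name: str) -> float:
    """Reduced mass of a bead type ((H2O)4 = 1 by definition)."""
    masses = parameters.load_tables()["bead_masses"]
    try:
        return float(masses[name])
    except KeyError:
        raise KeyError(f"unknown bead type {name!r}; known: {tuple(masses)}") from None


def _check_types(*names: str) -> None:
    for n in names:
        if n not in BEAD_TYPES:
            raise KeyError(f"unknown bead type {n!r}; known: {BEAD_TYPES}")


def lookup_pair_repulsion(type_a: str, type_b: str) -> float:
    """Conservative repulsion a_ij (k_BT/r_C) from the packaged table."""
    _check_types(type_a, type_b)
    for row in parameters.load_tables()["repulsion"]:
        p = row["pair"]
        if (p[0], p[1]) in ((type_a, type_b), (type_b, type_a)):
            return float(row["a"])
    raise KeyError(f"no repulsion entry for pair ({type_a}, {type_b})")


def lookup_bond(type_a: str, type_b: str) -> tuple[float, float]:
    """Distance-bond parameters (k_S in k_BT/r_C^2, l0 in r_C)."""
    _check_types(type_a, type_b)
    for row in parameters.load_tables()["bonds"]:
        t = row["types"]
        if (t[0], t[1]) in ((type_a, type_b), (type_b, type_a)):
            return float(row["k_s"]), float(row["l0"])
    raise KeyError(f"no bond entry for pair ({type_a}, {type_b})")


def lookup_angle(type_a: str, type_b: str, type_c: str) -> tuple[float, float]:
    """Angle parameters (k_A in k_BT/rad^2, theta0 in rad); b is the middle bead."""
    _check_types(type_a, type_b, type_c)
    for row in parameters.load_tables()["angles"]:
        t = tuple(row["types"])
        if t in ((type_a, type_b, type_c), (type_c, type_b, type_a)):
            return float(row["k_a"]), float(row["theta0"])
    raise KeyError(
        f"no angle entry for triplet ({type_a}, {type_b}, {type_c}); only the "
        "six tabulated combinations exist"
    )


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_s: float
    l0: float


@dataclass(frozen=True)
class AngleTerm:
    """Angle term with ``j`` as the central bead."""

    i: int
    j: int
    k: int
    k_a: float
    theta0: float


@dataclass
class SystemTopology:
    """Per-bead types plus bond/angle term arrays and chain membership.

    ``chain_id`` is -1 for solvent beads.  Term parameters are stored as
    flat arrays (``bond_i``, ``bond_ks``, ...) for the engine kernels;
    :meth:`bond_terms` / :meth:`angle_terms` give the object views.
    """

    types: np.ndarray
    type_names: tuple[str, ...] = BEAD_TYPES
    bond_i: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    bond_j: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    bond_ks: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    bond_l0: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    angle_i: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    angle_j: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    angle_k: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    angle_ka: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    angle_theta0: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    chain_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.types = np.asarray(self.types, dtype=np.int64)
        n = self.types.size
        for name in ("bond_i", "bond_j", "angle_i", "angle_j", "angle_k"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            setattr(self, name, arr)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} references beads outside [0, {n})")
        for name in ("bond_ks", "bond_l0", "angle_ka", "angle_theta0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.bond_i.size != self.bond_j.size or self.bond_i.size != self.bond_ks.size:
            raise ValueError("inconsistent bond array lengths")
        if np.any(self.bond_i == self.bond_j):
            raise ValueError("bonds must reference distinct beads")
        if self.angle_i.size:
            a = np.stack([self.angle_i, self.angle_j, self.angle_k])
            if np.any((a[0] == a[1]) | (a[1] == a[2]) | (a[0] == a[2])):
                raise ValueError("angles must reference three distinct beads")
        if self.chain_id is None:
            self.chain_id = np.full(n, -1, dtype=np.int64)
        else:
            self.chain_id = np.asarray(self.chain_id, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return self.types.size

    @property
    def n_bonds(self) -> int:
        return self.bond_i.size

    @property
    def n_angles(self) -> int:
        return self.angle_i.size

    def bond_terms(self) -> list[BondTerm]:
        return [BondTerm(int(i), int(j), float(k), float(l)) for i, j, k, l in
                zip(self.bond_i, self.bond_j, self.bond_ks, self.bond_l0)]

    def angle_terms(self) -> list[AngleTerm]:
        return [AngleTerm(int(i), int(j), int(k), float(ka), float(t0))
                for i, j, k, ka, t0 in zip(self.angle_i, self.angle_j,
                                           self.angle_k, self.angle_ka,
                                           self.angle_theta0)]

    def masses(self) -> np.ndarray:
        per_type = np.array([bead_mass(n) for n in self.type_names])
        return per_type[self.types]

    @classmethod
    def water(cls, n_beads: int) -> "SystemTopology":
        """Pure-solvent topology: n water beads, no bonded terms."""
        return cls(types=np.zeros(n_beads, dtype=np.int64))

    # -- plain-text serialization ---------------------------------------

    def to_text(self) -> str:
        """Documented plain-text table format (beads / bonds / angles sections)."""
        lines = ["[beads]", "# id type chain"]
        for i, (t, c) in enumerate(zip(self.types, self.chain_id)):
            lines.append(f"{i} {self.type_names[t]} {c}")
        lines.append("[bonds]")
        lines.append("# i j k_s l0")
        for b in self.bond_terms():
            lines.append(f"{b.i} {b.j} {b.k_s:g} {b.l0:g}")
        lines.append("[angles]")
        lines.append("# i j k k_a theta0")
        for a in self.angle_terms():
            lines.append(f"{a.i} {a.j} {a.k} {a.k_a:g} {a.theta0:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SystemTopology":
        section = None
        beads: list[tuple[int, str, int]] = []
        bonds: list[tuple[int, int, float, float]] = []
        angles: list[tuple[int, int, int, float, float]] = []
        for ln, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                if section not in ("beads", "bonds", "angles"):
                    raise ValueError(f"line {ln}: unknown section {section!r}")
                continue
            parts = line.split()
            try:
                if section == "beads":
                    beads.append((int(parts[0]), parts[1], int(parts[2])))
                elif section == "bonds":
                    bonds.append((int(parts[0]), int(parts[1]),
                                  float(parts[2]), float(parts[3])))
                elif section == "angles":
                    angles.append((int(parts[0]), int(parts[1]), int(parts[2]),
                                   float(parts[3]), float(parts[4])))
                else:
                    raise ValueError("data before any section header")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"line {ln}: cannot parse {raw!r}: {exc}") from None
        beads.sort()
        names = BEAD_TYPES
        types = np.array([names.index(t) for _, t, _ in beads], dtype=np.int64)
        chain = np.array([c for _, _, c in beads], dtype=np.int64)
        b = np.array(bonds, dtype=float).reshape(-1, 4)
        a = np.array(angles, dtype=float).reshape(-1, 5)
        return cls(types=types, type_names=names, chain_id=chain,
                   bond_i=b[:, 0], bond_j=b[:, 1], bond_ks=b[:, 2], bond_l0=b[:, 3],
                   angle_i=a[:, 0], angle_j=a[:, 1], angle_k=a[:, 2],
                   angle_ka=a[:, 3], angle_theta0=a[:, 4])


def _pattern_types(n_units: int, pattern: str) -> list[str]:
    if pattern == "all-protonated":
        return ["GalA"] * n_units
    if pattern == "all-deprotonated":
        return ["GalA(-)"] * n_units
    if pattern == "alternating":
        return ["GalA(-)" if i % 2 == 0 else "GalA" for i in range(n_units)]
    if pattern == "alternating-pairs":
        return ["GalA(-)" if (i // 2) % 2 == 0 else "GalA" for i in range(n_units)]
    raise ValueError(f"unknown chain pattern {pattern!r}; known: {CHAIN_PATTERNS}")


def build_chain(n_units: int, pattern: str = "all-protonated") -> SystemTopology:
    """Linear homogalacturonan chain topology with table-driven parameters.

    ``n_units`` beads, ``n_units - 1`` distance bonds and ``n_units - 2``
    angle terms, each parameterized by the protonation-state-dependent
    lookups.
    """
    if n_units < 2:
        raise ValueError(f"a chain needs at least 2 units, got {n_units}")
    names = _pattern_types(n_units, pattern)
    types = np.array([BEAD_TYPES.index(n) for n in names], dtype=np.int64)
    bi, bj, bks, bl0 = [], [], [], []
    for i in range(n_units - 1):
        ks, l0 = lookup_bond(names[i], names[i + 1])
        bi.append(i)
        bj.append(i + 1)
        bks.append(ks)
        bl0.append(l0)
    ai, aj, ak, aka, ath = [], [], [], [], []
    for i in range(n_units - 2):
        ka, th0 = lookup_angle(names[i], names[i + 1], names[i + 2])
        ai.append(i)
        aj.append(i + 1)
        ak.append(i + 2)
        aka.append(ka)
        ath.append(th0)
    return SystemTopology(types=types, chain_id=np.zeros(n_units, dtype=np.int64),
                          bond_i=bi, bond_j=bj, bond_ks=bks, bond_l0=bl0,
                          angle_i=ai, angle_j=aj, angle_k=ak, angle_ka=aka,
                          angle_theta0=ath)


def _chain_walk(n_units: int, l0s: np.ndarray, theta0s: np.ndarray,
                box: np.ndarray, rng: np.random.RandomState) -> np.ndarray:
    """Random walk with fixed step lengths and bond angles near theta0.

    Each new bond direction makes the tabulated rest angle with the previous
    one, at a uniformly random azimuth; periodic wrapping is allowed and
    initial overlaps with other chains are acceptable (the soft potentials
    resolve them during warm-up).
    """
    pos = np.empty((n_units, 3))
    pos[0] = rng.uniform(0.0, 1.0, 3) * box
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    pos[1] = pos[0] + l0s[0] * d
    for i in range(2, n_units):
        # rotate previous direction by (pi - theta0) about a random azimuth
        bend = np.pi - theta0s[i - 2]
        a = rng.standard_normal(3)
        a -= d * (a @ d)
        a /= np.linalg.norm(a)
        new_d = np.cos(bend) * d + np.sin(bend) * a
        pos[i] = pos[i - 1] + l0s[i - 1] * new_d
        d = new_d
    return pos


def build_system(n_chains: int, chain_length: int, pattern: str,
                 box_edge: float, density_number: float = 3.0,
                 seed: int = 0, kbt: float = 1.0) -> tuple[State, SystemTopology]:
    """Chains-in-water system: random-walk chains plus uniform solvent.

    The total bead count is ``density_number * box_volume`` (rounded);
    whatever the chains do not use is filled with (H2O)4 beads.  Velocities
    are Maxwell-Boltzmann at ``kbt`` with the centre-of-mass momentum
    removed.  Fully seeded and reproducible.
    """
    box = np.full(3, float(box_edge))
    n_total = int(round(density_number * np.prod(box)))
    n_chain_beads = n_chains * chain_length
    if n_chain_beads > n_total:
        raise ValueError(
            f"{n_chains} chains x {chain_length} units = {n_chain_beads} beads "
            f"exceed the bead budget {n_total} (rho={density_number}, "
            f"box={box_edge}^3)"
        )
    rng = np.random.RandomState(seed)
    chain_topo = build_chain(chain_length, pattern)
    types = np.zeros(n_total, dtype=np.int64)
    chain_id = np.full(n_total, -1, dtype=np.int64)
    pos = np.empty((n_total, 3))
    bi, bj, bks, bl0 = [], [], [], []
    ai, aj, ak, aka, ath = [], [], [], [], []
    for c in range(n_chains):
        off = c * chain_length
        sl = slice(off, off + chain_length)
        types[sl] = chain_topo.types
        chain_id[sl] = c
        pos[sl] = _chain_walk(chain_length, chain_topo.bond_l0,
                              chain_topo.angle_theta0, box, rng)
        bi.extend(chain_topo.bond_i + off)
        bj.extend(chain_topo.bond_j + off)
        bks.extend(chain_topo.bond_ks)
        bl0.extend(chain_topo.bond_l0)
        ai.extend(chain_topo.angle_i + off)
        aj.extend(chain_topo.angle_j + off)
        ak.extend(chain_topo.angle_k + off)
        aka.extend(chain_topo.angle_ka)
        ath.extend(chain_topo.angle_theta0)
    pos[n_chain_beads:] = rng.uniform(0.0, 1.0, (n_total - n_chain_beads, 3)) * box
    pos = wrap_positions(pos, box)
    topo = SystemTopology(types=types, chain_id=chain_id,
                          bond_i=bi, bond_j=bj, bond_ks=bks, bond_l0=bl0,
                          angle_i=ai, angle_j=aj, angle_k=ak, angle_ka=aka,
                          angle_theta0=ath)
    masses = topo.masses()
    vel = maxwell_boltzmann_velocities(masses, kbt, rng)
    state = State(pos, vel, masses, types, BEAD_TYPES)
    return state, topo
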