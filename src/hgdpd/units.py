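"""Reduced-unit system and reduced/real conversions.

DPD simulations run in dimensionless units built from four base quantities:

* length — the pair-force cut-off radius ``r_C``,
* mass — the mass of one bead (here the (H2O)4 water bead),
* energy — the thermal energy ``k_B T``,
* time — ``tau``, which has *no* a-priori value and is fixed a posteriori by
  matching a dynamical observable (bead velocity or diffusivity) of the
  coarse-grained reference system.

The cut-off itself follows from the reference system through
``r_C = (rho * V / N)**(1/3)`` where ``rho`` is the bead number density,
``V`` the box volume and ``N`` the bead count.  Derived dimensions
(velocity = length/time, diffusivity = length^2/time) are never stored
independently.  Conversions that involve time before ``tau`` has been
calibrated raise :class:`UncalibratedTimeScaleError` instead of guessing.

Internal real-unit conventions: Angstrom, picosecond, kilogram, Joule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import parameters

__all__ = [
    "ReducedUnitSystem",
    "UncalibratedTimeScaleError",
    "derive_cutoff_radius",
    "convert",
    "DIMENSIONS",
]


class UncalibratedTimeScaleError(ValueError):
    """A time-dependent conversion was requested before tau was calibrated."""


#: supported dimensions as exponents of (length, mass, energy, time)
DIMENSIONS: dict[str, tuple[int, int, int, int]] = {
    "length": (1, 0, 0, 0),
    "mass": (0, 1, 0, 0),
    "energy": (0, 0, 1, 0),
    "time": (0, 0, 0, 1),
    "velocity": (1, 0, 0, -1),
    "diffusivity": (2, 0, 0, -1),
}


def derive_cutoff_radius(density_number: float, box_volume: float, n_beads: float) -> float:
    """Cut-off radius ``r_C = (rho V / N)**(1/3)`` of the reference system.

    Parameters
    ----------
    density_number:
        Bead number density rho in beads per ``r_C^3``.
    box_volume:
        Reference box volume in Angstrom^3.
    n_beads:
        Number of coarse-grained beads the reference box maps onto.

    Returns
    -------
    float
        ``r_C`` in Angstrom.
    """
    if density_number <= 0 or box_volume <= 0 or n_beads <= 0:
        raise ValueError(
            "derive_cutoff_radius requires strictly positive arguments, got "
            f"rho={density_number}, V={box_volume}, N={n_beads}"
        )
    return float(density_number * box_volume / n_beads) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ReducedUnitSystem:
    """The four DPD base units and the conversion contracts built on them.

    Attributes
    ----------
    length:
        Angstrom per ``r_C``.
    mass:
        kg per bead mass.
    energy:
        Joule per ``k_B T``.
    time:
        ps per ``tau``; ``None`` until fixed by calibration.
    """

    length: float
    mass: float
    energy: float
    time: float | None = None

    def __post_init__(self) -> None:
        for name in ("length", "mass", "energy"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"unit '{name}' must be strictly positive, got {v}")
        if self.time is not None and not self.time > 0:
            raise ValueError(f"unit 'time' must be strictly positive, got {self.time}")

    @classmethod
    def defaults(cls, time: float | None = None) -> "ReducedUnitSystem":
        """Unit system of the packaged homogalacturonan/water model.

        ``tau`` is left unset unless given: it is a calibration output, not a
        model constant.
        """
        return cls(
            length=parameters.CUTOFF_ANGSTROM,
            mass=parameters.WATER_BEAD_MASS_KG,
            energy=parameters.KBT_JOULE,
            time=time,
        )

    def with_time(self, tau_ps: float) -> "ReducedUnitSystem":
        """Return a copy with the time unit fixed to ``tau_ps`` (ps)."""
        return replace(self, time=tau_ps)

    # -- conversions -----------------------------------------------------

    def factor(self, dimension: str) -> float:
        """Real units per one reduced unit for ``dimension``."""
        try:
            el, em, ee, et = DIMENSIONS[dimension]
        except KeyError:
            raise ValueError(
                f"unknown dimension {dimension!r}; expected one of {sorted(DIMENSIONS)}"
            ) from None
        if et != 0 and self.time is None:
            raise UncalibratedTimeScaleError(
                f"conversion of dimension {dimension!r} needs the time unit tau, "
                "which has not been calibrated yet (see hgdpd.calibration)"
            )
        f = self.length**el * self.mass**em * self.energy**ee
        if et != 0:
            f *= self.time**et
        return f

    def to_real(self, value, dimension: str):
        """Convert ``value`` from reduced to real units."""
        return value * self.factor(dimension)

    def to_reduced(self, value, dimension: str):
        """Convert ``value`` from real to reduced units."""
        return value / self.factor(dimension)


def convert(value, dimension: str, direction: str, units: ReducedUnitSystem):
    """Functional conversion front-end.

    ``direction`` is ``"reduced->real"`` or ``"real->reduced"``.
    """
    if direction == "reduced->real":
        return units.to_real(value, dimension)
    if direction == "real->reduced":
        return units.to_reduced(value, dimension)
    raise ValueError(f"direction must be 'reduced->real' or 'real->reduced', got {direction!r}")
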