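"""Packaged force-field constants and their loader.

The default parameter set (bead masses, conservative repulsion matrix,
harmonic bond/angle tables, thermostat coefficients and the fine-grained
reference targets) ships with the package as a YAML file.  Everything is
overridable at the API level; this module only centralises the defaults.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import yaml

__all__ = [
    "load_tables",
    "BEAD_TYPES",
    "CUTOFF_ANGSTROM",
    "WATER_BEAD_MASS_KG",
    "KBT_JOULE",
    "V_MD_ANGSTROM_PER_PS",
    "D_MD_ANGSTROM2_PER_PS",
]

#: canonical bead-type order used for integer type codes throughout
BEAD_TYPES = ("(H2O)4", "GalA", "GalA(-)")


@lru_cache(maxsize=1)
def load_tables() -> dict[str, Any]:
    """Load the packaged parameter tables as a plain dictionary."""
    ref = resources.files("hgdpd.data").joinpath("forcefield.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_T = load_tables()

CUTOFF_ANGSTROM: float = _T["base_units"]["length_angstrom"]
WATER_BEAD_MASS_KG: float = _T["base_units"]["mass_kg"]
KBT_JOULE: float = _T["base_units"]["energy_joule"]
V_MD_ANGSTROM_PER_PS: float = _T["reference_targets"]["v_md_angstrom_per_ps"]
D_MD_ANGSTROM2_PER_PS: float = _T["reference_targets"]["d_md_angstrom2_per_ps"]
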