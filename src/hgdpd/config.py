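"""Schema-validated YAML run configuration.

Unknown keys are rejected (typos must not silently change a simulation) and
the seed is mandatory: every artifact must be reproducible from its config.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import ForceField, IntegratorConfig, initialize_water_state
from .topology import CHAIN_PATTERNS, SystemTopology, build_system

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemSection(_Strict):
    kind: str = "water"                   # "water" | "chains"
    box_edge: float = Field(gt=0)
    n_beads: int | None = Field(default=None, gt=0)
    density_number: float = Field(default=3.0, gt=0)
    n_chains: int = Field(default=0, ge=0)
    chain_length: int = Field(default=0, ge=0)
    pattern: str = "all-protonated"

    @model_validator(mode="after")
    def _check(self):
        if self.kind not in ("water", "chains"):
            raise ValueError(f"system.kind must be 'water' or 'chains', got {self.kind!r}")
        if self.kind == "chains" and (self.n_chains < 1 or self.chain_length < 2):
            raise ValueError("chains systems need n_chains >= 1 and chain_length >= 2")
        if self.pattern not in CHAIN_PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; known: {CHAIN_PATTERNS}")
        return self


class ForceFieldSection(_Strict):
    preset: str = "water"                 # "water" | "default"
    a: float = Field(default=25.0, ge=0)
    sigma: float = Field(default=3.0, ge=0)
    gamma: float = Field(default=4.5, ge=0)
    s: float = Field(default=2.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.preset not in ("water", "default"):
            raise ValueError(f"forcefield.preset must be 'water' or 'default', got {self.preset!r}")
        return self

    def build(self) -> ForceField:
        if self.preset == "default":
            return ForceField.default()
        return ForceField.water(a=self.a, sigma=self.sigma, gamma=self.gamma, s=self.s)


class IntegratorSection(_Strict):
    dt: float = Field(default=0.001, gt=0)
    lam: float = 0.5
    cell_refresh: int = Field(default=8, ge=1)
    warmup_steps: int = Field(default=2000, ge=0)
    production_steps: int = Field(default=20000, ge=0)
    save_every: int = Field(default=200, ge=1)
    neighbor_skin: float = Field(default=0.0, ge=0)


class OutputSection(_Strict):
    trajectory: str = "trajectory.xyz"
    format: str = "xyz"
    log: str | None = None


class RunConfig(_Strict):
    """Full simulation run: system + force field + integrator + outputs."""

    seed: int
    system: SystemSection
    forcefield: ForceFieldSection = ForceFieldSection()
    integrator: IntegratorSection = IntegratorSection()
    output: OutputSection = OutputSection()

    def build(self):
        """Instantiate (state, topology, forcefield, config, box)."""
        ff = self.forcefield.build()
        integ = IntegratorConfig(seed=self.seed, **self.integrator.model_dump(exclude={"lam"}),
                                 lam=self.integrator.lam)
        box = np.full(3, self.system.box_edge)
        if self.system.kind == "water":
            n = self.system.n_beads
            if n is None:
                n = int(round(self.system.density_number * self.system.box_edge**3))
            state = initialize_water_state(n, self.system.box_edge, self.seed)
            topo = None
            if ff.repulsion.shape[0] > 1:
                topo = SystemTopology.water(n)
                state.types = topo.types
        else:
            state, topo = build_system(self.system.n_chains, self.system.chain_length,
                                       self.system.pattern, self.system.box_edge,
                                       self.system.density_number, self.seed)
            if self.forcefield.preset != "default":
                raise ValueError("chain systems need forcefield.preset: default "
                                 "(the water preset has no GalA types)")
        return state, topo, ff, integ, box


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig(**data)
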