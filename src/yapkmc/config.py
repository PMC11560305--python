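"""Run configuration: all model parameters, geometry and run controls.

Defaults are the baseline parameter set: D = 0.8 μm²/s, Rb = 50 s⁻¹,
Rp = 200 s⁻¹, Ru_YAP = Ru_pYAP = 0.1 s⁻¹, Rdeph = 0.035 s⁻¹, 250 YAP
molecules in a 40×40×20 box with l = 0.2 μm, nine 3×3 adhesions, no
confinement, no turnover.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .lattice import LatticeGeometry


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every offending key."""


@dataclass
class SimulationConfig:
    # geometry
    nx: int = 40
    ny: int = 40
    nz: int = 20
    l: float = 0.2
    # rates
    D: float = 0.8            # μm²/s, cytosolic diffusion coefficient
    Rb: float = 50.0          # s⁻¹, YAP binding from z=2 onto a free site
    Rp: float = 200.0         # s⁻¹, phosphorylation of bound YAP
    Ru_YAP: float = 0.1       # s⁻¹, release of bound YAP without phosphorylation
    Ru_pYAP: float = 0.1      # s⁻¹, release of bound pYAP
    Rdeph: float = 0.035      # s⁻¹, cytosolic dephosphorylation of pYAP
    # composition / adhesions
    n_yap: int = 250
    n_adhesions: int = 9
    adhesion_width: int = 3
    adhesion_height: int = 3
    r: float = 1.0            # confinement fraction (1 = whole membrane)
    clump_policy: str = "spaced"
    lifetime: Optional[float] = None   # s; None = no adhesion turnover
    # run controls
    steps: int = 1_000_000
    record_every: int = 1000
    seed: int = 0
    replicates: int = 3
    burn_in_fraction: float = 0.5

    @property
    def geometry(self) -> LatticeGeometry:
        return LatticeGeometry(self.nx, self.ny, self.nz, self.l)

    def validate(self) -> "SimulationConfig":
        errors = []
        for key in ("D", "Rb", "Rp", "Ru_YAP", "Ru_pYAP", "Rdeph"):
            if getattr(self, key) < 0:
                errors.append(f"{key} must be >= 0 (got {getattr(self, key)})")
        for key in ("nx", "ny", "nz"):
            if getattr(self, key) < 2:
                errors.append(f"{key} must be >= 2 (got {getattr(self, key)})")
        if self.l <= 0:
            errors.append(f"l must be > 0 (got {self.l})")
        if self.n_yap < 1:
            errors.append(f"n_yap must be >= 1 (got {self.n_yap})")
        elif self.n_yap > self.nx * self.ny * (self.nz - 1):
            errors.append("n_yap exceeds the number of cytosolic sites")
        if not 0 < self.r <= 1:
            errors.append(f"r must be in (0, 1] (got {self.r})")
        if self.clump_policy not in ("spaced", "clumping_allowed"):
            errors.append(f"clump_policy must be 'spaced' or 'clumping_allowed' "
                          f"(got {self.clump_policy!r})")
        if self.lifetime is not None and self.lifetime <= 0:
            errors.append(f"lifetime must be > 0 or none (got {self.lifetime})")
        if self.n_adhesions < 0:
            errors.append(f"n_adhesions must be >= 0 (got {self.n_adhesions})")
        if self.adhesion_width < 1 or self.adhesion_height < 1:
            errors.append("adhesion footprint dimensions must be >= 1")
        if self.steps < 1:
            errors.append(f"steps must be >= 1 (got {self.steps})")
        if self.record_every < 1:
            errors.append(f"record_every must be >= 1 (got {self.record_every})")
        if self.replicates < 1:
            errors.append(f"replicates must be >= 1 (got {self.replicates})")
        if not 0 <= self.burn_in_fraction < 1:
            errors.append(f"burn_in_fraction must be in [0, 1) "
                          f"(got {self.burn_in_fraction})")
        if errors:
            raise ConfigError("; ".join(errors))
        if (self.lifetime is not None
                and self.adhesion_width * self.adhesion_height > 9):
            warnings.warn(
                "turnover lifetimes are meant for small (nascent) adhesions; "
                "large footprints normally outlive the simulated window",
                stacklevel=2)
        return self

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def config_from_dict(data: dict) -> SimulationConfig:
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
    if isinstance(data.get("lifetime"), str):
        if data["lifetime"].lower() == "none":
            data = {**data, "lifetime": None}
        else:
            raise ConfigError(f"lifetime must be a number or 'none' "
                              f"(got {data['lifetime']!r})")
    return SimulationConfig(**data).validate()


def load_config(path) -> SimulationConfig:
    """Load a YAML or JSON run configuration; missing keys take defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of configuration keys")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
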