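"""Run configuration: schema-validated structured text (YAML) in, provenance out.

Units in config files: lengths mm, moduli Pa, compliance 1/Pa, density kg/m^3.
Every run emits a provenance record containing the fully resolved
configuration (defaults included), package versions and the seed, from which
the run is reproducible.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .materials import MaterialParams, neo_hookean

__all__ = [
    "GeometryConfig", "MaterialConfig", "NeedleConfig", "SolverConfig",
    "OutputConfig", "RunConfig", "ConfigError", "load_config", "provenance_record",
]


class ConfigError(ValueError):
    pass


class GeometryConfig(BaseModel):
    kind: Literal["cylinder", "layered_cylinder", "file"] = "cylinder"
    radius: Optional[float] = None          # mm
    height: Optional[float] = None          # mm (cylinder)
    layer_heights: Optional[list[float]] = None  # mm, base up (layered)
    target_nodes: int = 3000
    path: Optional[str] = None              # geometry file (kind = "file")

    @model_validator(mode="after")
    def _check(self):
        if self.kind == "cylinder" and (self.radius is None or self.height is None):
            raise ValueError("cylinder geometry needs radius and height")
        if self.kind == "layered_cylinder" and (
                self.radius is None or not self.layer_heights):
            raise ValueError("layered_cylinder geometry needs radius and layer_heights")
        if self.kind == "file" and not self.path:
            raise ValueError("file geometry needs a path")
        return self


class MaterialConfig(BaseModel):
    """One material block, assigned to material_id values in listing order."""

    name: str = ""
    model: Literal["ogden", "neo_hookean"] = "ogden"
    a: float = -1.3
    mu: float                                # Pa
    D: Optional[float] = None                # 1/Pa
    poisson: Optional[float] = None          # used if D absent (neo_hookean)

    def build(self) -> MaterialParams:
        if self.model == "neo_hookean":
            if self.D is not None:
                return MaterialParams(a=2.0, mu=self.mu, D=self.D, name=self.name)
            return neo_hookean(self.mu, self.poisson if self.poisson is not None
                               else 0.49, name=self.name)
        if self.D is None:
            raise ConfigError(f"Ogden material {self.name!r} needs D")
        return MaterialParams(a=self.a, mu=self.mu, D=self.D, name=self.name)


class NeedleConfig(BaseModel):
    entry_point: Optional[list[float]] = None  # mm; default: top surface centre
    axis: list[float] = Field(default_factory=lambda: [0.0, 0.0, -1.0])
    diameter: float = 1.6                      # mm
    depth: float = 15.0                        # mm
    eps_p: float = 1e-5
    cd: float = 0.4
    capture_radius: Optional[float] = None     # mm
    monitor_radius: Optional[float] = None     # mm
    fade_steps: int = 400                      # solver steps to blend a capture


class SolverConfig(BaseModel):
    safety: float = 0.5
    density: float = 1000.0                    # kg/m^3
    damping_factor: float = 1.0
    ramp_steps: int = 1500
    settle_tol: float = 1e-9
    max_steps_per_stage: int = 60000
    snapshot_depths: Optional[list[float]] = None  # mm; default: [depth]


class OutputConfig(BaseModel):
    directory: str = "mtled_out"
    vtk: bool = False
    csv: bool = True


class RunConfig(BaseModel):
    geometry: GeometryConfig
    materials: list[MaterialConfig]
    needle: NeedleConfig
    solver: SolverConfig = Field(default_factory=SolverConfig)
    outputs: OutputConfig = Field(default_factory=OutputConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.materials:
            raise ValueError("at least one material block is required")
        return self


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                         for e in exc.errors())
        raise ConfigError(f"invalid run configuration: {msgs}") from exc


def provenance_record(config: RunConfig) -> dict:
    import mtled
    import numba
    import scipy
    return {
        "resolved_config": json.loads(config.model_dump_json()),
        "versions": {"mtled": mtled.__version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "numba": numba.__version__,
                     "python": platform.python_version()},
        "seed": config.seed,
    }
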