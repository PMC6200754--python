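"""Run configuration: validated schema, YAML/JSON loading, scenario presets.

All physical quantities carry explicit units in their key names
(``b0_tesla``, ``lambda_h_hz``, ``horizon_s`` ...).  Unknown keys are
rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .hamiltonians import SystemSpec

__all__ = ["SystemConfig", "SolverConfig", "OutputConfig", "RunConfig",
           "PRESETS", "preset_config", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemConfig(_Strict):
    """Physical parameters; defaults are the geomagnetic-field scenario."""

    mode: Literal["collective", "noncollective"] = "collective"
    b0_tesla: float = Field(default=47e-6, gt=0)
    field_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    temperature_k: float = Field(default=300.0, gt=0)
    alpha: float = Field(default=1.0, ge=0)
    dipole_moment_cm: Optional[float] = None
    n1: int = Field(default=1, ge=0)
    n2: int = Field(default=1, ge=0)
    lambda_h_hz: float = Field(default=1e7, ge=0)
    a1: tuple[float, float, float] = (2.0, 2.0, 1.0)
    a2: tuple[float, float, float] = (1.0, 1.0, 1.0)
    couplings_hz: tuple[tuple[float, float, float], ...] = ()

    def to_spec(self) -> SystemSpec:
        return SystemSpec(
            mode=self.mode,
            b0_tesla=self.b0_tesla,
            field_axis=self.field_axis,
            temperature_k=self.temperature_k,
            alpha=self.alpha,
            dipole_moment_cm=self.dipole_moment_cm,
            n1=self.n1,
            n2=self.n2,
            lambda_h_hz=self.lambda_h_hz,
            a1=self.a1,
            a2=self.a2,
            couplings_hz=self.couplings_hz,
        )


class SolverConfig(_Strict):
    grid_points: int = Field(default=2000, ge=2)
    horizon_s: float = Field(default=5.0, gt=0)
    #: geometric time grid resolves second-scale tails and ms-scale decay alike
    geometric_grid: bool = False
    grouping_tol: float = Field(default=1e-9, gt=0)
    decoherence_factor: float = Field(default=10.0, ge=10.0)
    schrodinger: bool = False


class OutputConfig(_Strict):
    directory: str = "rpsim_out"
    formats: tuple[Literal["csv", "hdf5"], ...] = ("csv",)


class RunConfig(_Strict):
    preset: Optional[str] = None
    system: SystemConfig = SystemConfig()
    solver: SolverConfig = SolverConfig()
    outputs: OutputConfig = OutputConfig()

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v):
        if v is not None and v not in PRESETS:
            raise ValueError(f"unknown preset {v!r}; available: {sorted(PRESETS)}")
        return v


def _xonly(w: float) -> tuple[float, float, float]:
    # transverse single-axis hyperfine coupling: drives singlet-triplet
    # interconversion and reproduces the equal-vs-mixed coupling contrast
    return (w, 0.0, 0.0)


def _collective_preset(n: int) -> dict:
    return {
        "system": {"mode": "collective", "n1": n, "n2": n, "lambda_h_hz": 1e7},
        "solver": {"horizon_s": 400.0, "grid_points": 600, "geometric_grid": True},
    }


#: scenario presets: the nuclei-count sweep (fig2_n*), the long-lived
#: (j1, j2) = (0, 0) sector demonstration (fig3), and the three two-nucleus
#: hyperfine configurations (fig4a/b/c: equal-strong, equal-weak, mixed).
PRESETS: dict[str, dict] = {
    **{f"fig2_n{n}": _collective_preset(n) for n in range(1, 11)},
    "fig3": {
        "system": {"mode": "collective", "n1": 2, "n2": 2, "lambda_h_hz": 1e7},
        "solver": {"horizon_s": 400.0, "grid_points": 600, "geometric_grid": True},
    },
    "fig4a": {
        "system": {"mode": "noncollective",
                   "couplings_hz": (_xonly(1e7), _xonly(1e7))},
        "solver": {"horizon_s": 200.0, "grid_points": 800, "geometric_grid": True},
    },
    "fig4b": {
        "system": {"mode": "noncollective",
                   "couplings_hz": (_xonly(1e4), _xonly(1e4))},
        "solver": {"horizon_s": 200.0, "grid_points": 800, "geometric_grid": True},
    },
    "fig4c": {
        "system": {"mode": "noncollective",
                   "couplings_hz": (_xonly(1e7), _xonly(1e4))},
        "solver": {"horizon_s": 200.0, "grid_points": 800, "geometric_grid": True},
    },
}


def preset_config(name: str) -> RunConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return RunConfig(preset=name, **PRESETS[name])


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML or JSON run configuration.

    A ``preset`` key loads the preset first and applies the file's other
    sections on top of it.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    preset = raw.get("preset")
    if preset is not None:
        base = {k: dict(v) for k, v in PRESETS.get(preset, {}).items()}
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        for section, values in raw.items():
            if section == "preset":
                continue
            base.setdefault(section, {})
            base[section].update(values)
        raw = {"preset": preset, **base}
    return RunConfig(**raw)
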