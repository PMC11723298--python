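"""Run configuration: validated, unit-normalized input for the CLI.

Config files are TOML or JSON.  Units at the config boundary are the
human-friendly ones of device datasheets — micrometres, volts, hertz —
normalized to SI internally.  Example (TOML)::

    [geometry]
    preset = "type_a"          # or explicit width_um / spacing_um / height_um

    [drive]
    vpp = 10.0                 # or vrms; exactly one
    frequency_hz = 8.5e6

    [medium]
    epsilon_l = 6.9e-10        # F/m (or epsilon_l_rel)
    sigma_l = 1.0e-3           # S/m

    [cell]
    re_beta = 0.98             # or the full single-shell parameter set
    diameter_um = 15.0

    [solver]
    n_terms = 10000
    gap_constant = 0.75480

    [sampling]
    nx = 201
    ny = 201

Three device presets ship with the package: ``type_a`` (width 50 um,
spacing 50 um), ``type_b`` (50, 75) and ``type_c`` (75, 50), all with a
500-um channel.
"""

from __future__ import annotations

import json
import math
import tomllib
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cm import (VACUUM_PERMITTIVITY, CellDielectricModel, MediumProperties,
                 cm_single_shell, dep_prefactor)
from .device import (DEFAULT_GAP_CONSTANT, DeviceGeometry, DriveSettings,
                     GapApproximation)

__all__ = ["PRESETS", "RunConfig", "load_config"]

_UM = 1e-6

PRESETS = {
    "type_a": {"width_um": 50.0, "spacing_um": 50.0, "height_um": 500.0},
    "type_b": {"width_um": 50.0, "spacing_um": 75.0, "height_um": 500.0},
    "type_c": {"width_um": 75.0, "spacing_um": 50.0, "height_um": 500.0},
}


class GeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Optional[str] = None
    width_um: Optional[float] = Field(None, gt=0, description="finger width 2w")
    spacing_um: Optional[float] = Field(None, gt=0, description="spacing d")
    pitch_um: Optional[float] = Field(None, gt=0, description="pitch L")
    height_um: Optional[float] = Field(None, gt=0)

    @model_validator(mode="after")
    def _resolve(self):
        if self.preset is not None:
            if self.preset not in PRESETS:
                raise ValueError(
                    f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
            p = PRESETS[self.preset]
            self.width_um = self.width_um or p["width_um"]
            self.spacing_um = self.spacing_um or p["spacing_um"]
            self.height_um = self.height_um or p["height_um"]
        if self.width_um is None or self.height_um is None:
            raise ValueError("geometry needs width_um and height_um "
                             "(directly or via preset)")
        have_spacing = self.spacing_um is not None
        have_pitch = self.pitch_um is not None
        if have_spacing and have_pitch:
            if not math.isclose(self.pitch_um,
                                self.width_um + self.spacing_um,
                                rel_tol=1e-9):
                raise ValueError(
                    f"contradictory geometry: pitch_um={self.pitch_um} but "
                    f"width_um + spacing_um = {self.width_um + self.spacing_um}")
        elif have_pitch:
            self.spacing_um = self.pitch_um - self.width_um
            if self.spacing_um <= 0:
                raise ValueError("pitch_um must exceed width_um")
        elif not have_spacing:
            raise ValueError("geometry needs spacing_um or pitch_um")
        return self

    def to_geometry(self) -> DeviceGeometry:
        return DeviceGeometry.from_width_spacing(
            self.width_um * _UM, self.spacing_um * _UM, self.height_um * _UM)


class DriveConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vrms: Optional[float] = Field(None, gt=0)
    vpp: Optional[float] = Field(None, gt=0)
    frequency_hz: float = Field(8.5e6, gt=0)

    @model_validator(mode="after")
    def _one_voltage(self):
        if (self.vrms is None) == (self.vpp is None):
            raise ValueError("specify exactly one of vrms, vpp")
        return self

    def to_drive(self) -> DriveSettings:
        if self.vpp is not None:
            return DriveSettings.from_vpp(self.vpp, f=self.frequency_hz)
        return DriveSettings(V_rms=self.vrms, f=self.frequency_hz)


class MediumConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epsilon_l: Optional[float] = Field(None, gt=0, description="F/m")
    epsilon_l_rel: Optional[float] = Field(None, gt=0)
    sigma_l: float = Field(..., ge=0, description="S/m")

    @model_validator(mode="after")
    def _one_eps(self):
        if (self.epsilon_l is None) == (self.epsilon_l_rel is None):
            raise ValueError("specify exactly one of epsilon_l, epsilon_l_rel")
        return self

    def to_medium(self) -> MediumProperties:
        eps = (self.epsilon_l if self.epsilon_l is not None
               else self.epsilon_l_rel * VACUUM_PERMITTIVITY)
        return MediumProperties(epsilon_l=eps, sigma_l=self.sigma_l)


class CellConfig(BaseModel):
    """Either a directly supplied Re(beta) or full single-shell parameters."""
    model_config = ConfigDict(extra="forbid")
    diameter_um: float = Field(15.0, gt=0)
    re_beta: Optional[float] = Field(None, ge=-0.5, le=1.0)
    membrane_capacitance: Optional[float] = Field(None, gt=0, description="F/m^2")
    epsilon_c: Optional[float] = Field(None, gt=0, description="F/m")
    epsilon_c_rel: Optional[float] = Field(None, gt=0)
    sigma_c: Optional[float] = Field(None, gt=0, description="S/m")

    @model_validator(mode="after")
    def _check(self):
        any_shell = (self.membrane_capacitance is not None
                     or self.sigma_c is not None
                     or self.epsilon_c is not None
                     or self.epsilon_c_rel is not None)
        full = (self.membrane_capacitance is not None
                and self.sigma_c is not None
                and (self.epsilon_c is not None or self.epsilon_c_rel is not None))
        if any_shell and not full:
            raise ValueError("incomplete single-shell cell block: need "
                             "membrane_capacitance, sigma_c and epsilon_c[_rel]")
        return self

    def to_cell(self) -> Optional[CellDielectricModel]:
        if self.membrane_capacitance is None:
            return None
        eps = (self.epsilon_c if self.epsilon_c is not None
               else self.epsilon_c_rel * VACUUM_PERMITTIVITY)
        return CellDielectricModel(
            d_c=self.diameter_um * _UM, c_m=self.membrane_capacitance,
            epsilon_c_eff=eps, sigma_c_eff=self.sigma_c)

    def resolve_re_beta(self, medium: MediumProperties, f: float) -> float:
        if self.re_beta is not None:
            return self.re_beta
        return float(cm_single_shell(self.to_cell(), medium, f).real)


class SolverConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_terms: int = Field(10_000, ge=1)
    gap_constant: float = Field(DEFAULT_GAP_CONSTANT, gt=0, lt=math.pi / 2)
    edge_continuous: bool = False
    fd_target_nodes: int = Field(1_000_000, ge=100)

    def to_gap(self) -> GapApproximation:
        return GapApproximation(C=self.gap_constant,
                                edge_continuous=self.edge_continuous)


class SamplingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nx: int = Field(201, ge=2)
    ny: int = Field(201, ge=2)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    geometry: GeometryConfig
    drive: DriveConfig
    medium: Optional[MediumConfig] = None
    cell: CellConfig = CellConfig()
    solver: SolverConfig = SolverConfig()
    sampling: SamplingConfig = SamplingConfig()

    def to_geometry(self) -> DeviceGeometry:
        return self.geometry.to_geometry()

    def to_drive(self) -> DriveSettings:
        return self.drive.to_drive()

    def to_prefactor(self) -> float:
        """DEP prefactor from the medium/cell blocks (F*m).

        Falls back to the standard assay conditions (epsilon_l = 6.9e-10
        F/m, Re(beta) = 0.98, 15-um cell) when no medium block is given.
        """
        medium = (self.medium.to_medium() if self.medium is not None
                  else MediumProperties(epsilon_l=6.9e-10, sigma_l=1.0e-3))
        re_beta = (self.cell.resolve_re_beta(medium, self.to_drive().f)
                   if (self.cell.re_beta is not None
                       or self.cell.membrane_capacitance is not None)
                   else 0.98)
        return dep_prefactor(medium, self.cell.diameter_um * _UM, re_beta)

    def content_hash(self) -> str:
        import hashlib
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read and validate a TOML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return RunConfig.model_validate(data)
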