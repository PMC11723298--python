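"""Shared fixtures: the canonical Type-A device and standard assay conditions."""

import math

import numpy as np
import pytest

from depfield import (
    CellDielectricModel,
    DeviceGeometry,
    DriveSettings,
    GapApproximation,
    MediumProperties,
    VACUUM_PERMITTIVITY,
    build_solution,
)


@pytest.fixture(scope="session")
def type_a() -> DeviceGeometry:
    """Type-A interdigitated layout: 50-um fingers, 50-um gaps, 500-um channel."""
    return DeviceGeometry.from_width_spacing(50e-6, 50e-6, 500e-6)


@pytest.fixture(scope="session")
def drive() -> DriveSettings:
    """10-V peak-to-peak sinusoidal drive at 8.5 MHz."""
    return DriveSettings(V_rms=5.0 / math.sqrt(2.0), f=8.5e6)


@pytest.fixture(scope="session")
def gap() -> GapApproximation:
    """Published (discontinuous) cubic gap profile, canonical C."""
    return GapApproximation()


@pytest.fixture(scope="session")
def gap_continuous() -> GapApproximation:
    """Edge-continuous cubic gap profile, canonical C."""
    return GapApproximation(edge_continuous=True)


@pytest.fixture(scope="session")
def medium() -> MediumProperties:
    """Low-conductivity mannitol-type assay medium."""
    return MediumProperties(epsilon_l=6.9e-10, sigma_l=1.0e-3)


@pytest.fixture(scope="session")
def cell() -> CellDielectricModel:
    """Synthetic mammalian-cell parameter set (15-um cell, 10 mF/m^2 membrane)."""
    return CellDielectricModel(d_c=15e-6, c_m=0.01,
                               epsilon_c_eff=50 * VACUUM_PERMITTIVITY,
                               sigma_c_eff=0.5)


@pytest.fixture(scope="session")
def small_solution(type_a, drive, gap):
    """Closed-form Type-A series with a modest 400-term truncation."""
    return build_solution(type_a, drive, gap=gap, n_terms=400)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240185)
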