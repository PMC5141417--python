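"""Shared fixtures: the two published colloid parameter sets and media."""

import numpy as np
import pytest

from spasim.core import FieldProtocol, MediumSpec, ParticleSpec


@pytest.fixture(scope="session")
def pei_particle() -> ParticleSpec:
    """PEI-coated magnetite: d = 25 ± 5 nm, Ms = 51 Am²/kg, H_A = 34.5 kA/m."""
    return ParticleSpec(
        d_mean=25e-9, d_sd=5e-9, Ms_mass=51.0, H_A=34.5e3, tau0=1e-9
    )


@pytest.fixture(scope="session")
def paa_particle() -> ParticleSpec:
    """PAA-coated magnetite: d = 32 ± 6 nm, Ms = 54 Am²/kg, simulation
    anisotropy field 55 kA/m."""
    return ParticleSpec(
        d_mean=32e-9, d_sd=6e-9, Ms_mass=54.0, H_A=55e3, tau0=1e-9
    )


@pytest.fixture(scope="session")
def pei_mono() -> ParticleSpec:
    """Monodisperse 25 nm variant of the PEI set."""
    return ParticleSpec(
        d_mean=25e-9, d_sd=0.0, Ms_mass=51.0, H_A=34.5e3, tau0=1e-9
    )


@pytest.fixture(scope="session")
def room_medium() -> MediumSpec:
    """Water-like carrier at body-experiment temperature, rotation blocked
    (no hydrodynamic diameter -> Néel-only)."""
    return MediumSpec(viscosity=1.0e-3, temperature=300.0)


@pytest.fixture(scope="session")
def field_560() -> FieldProtocol:
    """The experimental working point: 24 kA/m at 560 kHz."""
    return FieldProtocol(H0=24e3, f=560e3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160738)
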