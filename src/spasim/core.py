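"""Physical constants, field-unit conversions and the parameter containers
shared by every other module.

Everything internal is strict SI (A/m, Pa·s, J, m, K).  kA/m, Oe and mT are
accepted only at I/O boundaries through :func:`convert_field`.  This avoids
the unit confusion endemic to the hyperthermia literature, where field
amplitudes are quoted interchangeably in kA/m, Oe and mT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import k as K_B  # Boltzmann constant, J/K
from scipy.constants import mu_0 as MU0  # vacuum permeability, T·m/A

__all__ = [
    "MU0",
    "K_B",
    "MAGNETITE_DENSITY",
    "convert_field",
    "anisotropy_constant",
    "anisotropy_field",
    "sphere_volume",
    "ParticleSpec",
    "MediumSpec",
    "FieldProtocol",
]

#: Bulk magnetite density, kg/m³ (config-overridable default).
MAGNETITE_DENSITY = 5180.0

# Multiplicative factors to A/m.  mT is interpreted as μ₀H, i.e. the field
# magnitude quoted as an induction in vacuum.
_TO_A_PER_M = {
    "A/m": 1.0,
    "kA/m": 1.0e3,
    "Oe": 1.0e3 / (4.0 * math.pi),
    "mT": 1.0e-3 / MU0,
}


def convert_field(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a magnetic field magnitude between A/m, kA/m, Oe and mT (μ₀H).

    Round trips are identity to 1e-12 relative; conversions compose
    associatively because each unit is a fixed multiple of A/m.

    Raises
    ------
    ValueError
        If either unit token is unknown.
    """
    for unit in (from_unit, to_unit):
        if unit not in _TO_A_PER_M:
            raise ValueError(
                f"unknown field unit {unit!r}; expected one of "
                f"{sorted(_TO_A_PER_M)}"
            )
    return value * _TO_A_PER_M[from_unit] / _TO_A_PER_M[to_unit]


def sphere_volume(d: float) -> float:
    """Volume πd³/6 of a sphere with diameter ``d`` (m)."""
    if d <= 0:
        raise ValueError(f"diameter must be positive, got {d}")
    return math.pi * d**3 / 6.0


def anisotropy_constant(Ms_mass: float, density: float, H_A: float) -> float:
    """Effective uniaxial anisotropy K_eff (J/m³) from the anisotropy field.

    Uses the uniaxial single-domain (Stoner–Wohlfarth) identity
    K_eff = μ₀·M_S·H_A/2 with M_S the volume magnetization Ms_mass·density.

    ``H_A = 0`` is allowed (isotropic particle → K_eff = 0).
    """
    if Ms_mass <= 0 or density <= 0:
        raise ValueError("Ms_mass and density must be positive")
    if H_A < 0:
        raise ValueError(f"anisotropy field must be non-negative, got {H_A}")
    return 0.5 * MU0 * (Ms_mass * density) * H_A


def anisotropy_field(K_eff: float, Ms_vol: float) -> float:
    """Anisotropy field H_A = 2·K_eff/(μ₀·M_S) (A/m), inverse of
    :func:`anisotropy_constant`."""
    if Ms_vol <= 0:
        raise ValueError("volume magnetization must be positive")
    if K_eff < 0:
        raise ValueError("K_eff must be non-negative")
    return 2.0 * K_eff / (MU0 * Ms_vol)


def _positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass(frozen=True)
class ParticleSpec:
    """Intrinsic physics of one single-domain nanoparticle population.

    Parameters
    ----------
    d_mean, d_sd : float
        Mean and standard deviation of the TEM magnetic-core diameter (m).
        ``d_sd = 0`` denotes a monodisperse ensemble.
    Ms_mass : float
        Mass saturation magnetization (A·m²/kg).
    density : float
        Particle mass density (kg/m³); defaults to bulk magnetite.
    H_A : float, optional
        Uniaxial anisotropy field (A/m).
    K_eff : float, optional
        Effective uniaxial anisotropy constant (J/m³).  At least one of
        ``H_A``/``K_eff`` must be given; if both are given they must satisfy
        K_eff = μ₀·Ms_vol·H_A/2 to 1e-9 relative.
    tau0 : float
        Néel attempt time (s), typically 1e-10–1e-9 s for magnetite.
    """

    d_mean: float
    d_sd: float
    Ms_mass: float
    density: float = MAGNETITE_DENSITY
    H_A: float | None = None
    K_eff: float | None = None
    tau0: float = 1.0e-9

    def __post_init__(self) -> None:
        _positive("d_mean", self.d_mean)
        if self.d_sd < 0:
            raise ValueError(f"d_sd must be non-negative, got {self.d_sd}")
        if self.d_sd >= self.d_mean:
            raise ValueError("d_sd must be smaller than d_mean")
        _positive("Ms_mass", self.Ms_mass)
        _positive("density", self.density)
        _positive("tau0", self.tau0)
        if self.H_A is None and self.K_eff is None:
            raise ValueError("one of H_A or K_eff must be specified")
        if self.H_A is not None and self.H_A < 0:
            raise ValueError("H_A must be non-negative")
        if self.K_eff is not None and self.K_eff < 0:
            raise ValueError("K_eff must be non-negative")
        if self.H_A is None:
            object.__setattr__(
                self, "H_A", anisotropy_field(self.K_eff, self.Ms_vol)
            )
        elif self.K_eff is None:
            object.__setattr__(
                self,
                "K_eff",
                anisotropy_constant(self.Ms_mass, self.density, self.H_A),
            )
        else:
            expected = anisotropy_constant(self.Ms_mass, self.density, self.H_A)
            scale = max(abs(expected), abs(self.K_eff), 1e-300)
            if abs(self.K_eff - expected) > 1e-9 * scale:
                raise ValueError(
                    f"K_eff = {self.K_eff} inconsistent with "
                    f"μ₀·Ms·H_A/2 = {expected}"
                )

    @property
    def Ms_vol(self) -> float:
        """Volume saturation magnetization (A/m)."""
        return self.Ms_mass * self.density

    @property
    def volume_mean(self) -> float:
        """Volume of the mean-diameter sphere (m³)."""
        return sphere_volume(self.d_mean)


@dataclass(frozen=True)
class MediumSpec:
    """Carrier-medium properties relevant to Brownian rotation.

    ``hydrodynamic_diameter`` may be None when only Néel dynamics are of
    interest (e.g. the intracellular, rotation-blocked regime).
    """

    viscosity: float  # Pa·s
    temperature: float  # K
    hydrodynamic_diameter: float | None = None  # m

    def __post_init__(self) -> None:
        _positive("viscosity", self.viscosity)
        _positive("temperature", self.temperature)
        if self.hydrodynamic_diameter is not None:
            _positive("hydrodynamic_diameter", self.hydrodynamic_diameter)

    def check_against_particle(self, particle: ParticleSpec) -> None:
        """Enforce d_H ≥ core diameter when both are known."""
        if (
            self.hydrodynamic_diameter is not None
            and self.hydrodynamic_diameter < particle.d_mean
        ):
            raise ValueError(
                "hydrodynamic diameter smaller than the magnetic core"
            )


@dataclass(frozen=True)
class FieldProtocol:
    """Sinusoidal AC field H(t) = H0·sin(2πft) and its discretization.

    ``n_cycles`` includes the first cycle, which is discarded as a transient
    before loop areas are measured.
    """

    H0: float  # A/m
    f: float  # Hz
    steps_per_cycle: int = 2000
    n_cycles: int = 3
    waveform: str = "sinusoidal"

    def __post_init__(self) -> None:
        if self.H0 < 0:
            raise ValueError("H0 must be non-negative")
        _positive("f", self.f)
        if self.steps_per_cycle < 100:
            raise ValueError("steps_per_cycle must be at least 100")
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be at least 2 (first is transient)")
        if self.waveform != "sinusoidal":
            raise ValueError("only the sinusoidal waveform is supported")

    @property
    def period(self) -> float:
        return 1.0 / self.f

    @property
    def dt(self) -> float:
        return self.period / self.steps_per_cycle
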