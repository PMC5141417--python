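"""Linear-response-theory (LRT) specific power absorption.

For a dilute ensemble of monodisperse, non-interacting superparamagnetic
particles driven well below the anisotropy field, the absorbed power per
unit mass of magnetic material is (Rosensweig form)

    SPA = μ₀·π·χ₀·H₀²·f · 2πfτ/(1 + (2πfτ)²) / ρ

with χ₀ the Langevin initial (zero-field equilibrium, volume-basis)
susceptibility μ₀M_S²V/(3k_BT) and τ the effective Néel/Brown relaxation
time.  SPA is exactly quadratic in H₀ (exponent λ = 2) — this is the
baseline the nonlinear dynamic-hysteresis simulator is contrasted against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import K_B, MU0, FieldProtocol, MediumSpec, ParticleSpec
from . import relaxation

__all__ = [
    "LrtResult",
    "equilibrium_susceptibility",
    "dissipation_factor",
    "lrt_spa",
    "spa_frequency_curve",
    "LRT_FIELD_RATIO_WARN",
]

#: Above H0/H_A = 0.2 the quadratic small-field expansion is unreliable and a
#: warning is emitted; above 1 LRT is simply invalid.
LRT_FIELD_RATIO_WARN = 0.2


@dataclass(frozen=True)
class LrtResult:
    chi0: float  # dimensionless, volume basis
    dissipation_factor: float  # 2πfτ/(1+(2πfτ)²) ∈ [0, 0.5]
    spa: float  # W per kg of magnetic material


def equilibrium_susceptibility(
    particle: ParticleSpec, temperature: float
) -> float:
    """Langevin initial susceptibility χ₀ = μ₀·M_S²·V/(3·k_B·T)
    (volume basis, dimensionless)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return (
        MU0
        * particle.Ms_vol**2
        * particle.volume_mean
        / (3.0 * K_B * temperature)
    )


def dissipation_factor(f: float, tau: float) -> float:
    """Out-of-phase factor x/(1+x²) with x = 2πfτ; maximal (0.5) at x = 1."""
    x = 2.0 * np.pi * f * tau
    return x / (1.0 + x * x)


def _effective_tau(particle: ParticleSpec, medium: MediumSpec) -> float:
    tau_n = relaxation.neel_time(particle, medium.temperature)
    if medium.hydrodynamic_diameter is None:
        return tau_n  # rotation blocked / not modelled
    tau_b = relaxation.brown_time(
        medium.hydrodynamic_diameter, medium.viscosity, medium.temperature
    )
    return relaxation.effective_time(tau_n, tau_b)


def lrt_spa(
    particle: ParticleSpec,
    medium: MediumSpec,
    field: FieldProtocol,
    *,
    tau_override: float | None = None,
) -> LrtResult:
    """LRT power absorption for one (particle, medium, field) combination.

    Raises
    ------
    ValueError
        If H0 exceeds the anisotropy field — the linear regime does not
        exist there; use the dynamic-hysteresis simulator instead.

    Warns when H0/H_A > 0.2, where fields at the experimental scale already
    invalidate the quadratic approximation.
    """
    ratio = field.H0 / particle.H_A if particle.H_A > 0 else 0.0
    if ratio > 1.0:
        raise ValueError(
            f"H0/H_A = {ratio:.2f} > 1: LRT is invalid at this amplitude; "
            "use spasim.hysteresis.ensemble_spa"
        )
    if ratio > LRT_FIELD_RATIO_WARN:
        warnings.warn(
            f"H0/H_A = {ratio:.2f} exceeds {LRT_FIELD_RATIO_WARN}: LRT "
            "results are only indicative here",
            stacklevel=2,
        )
    chi0 = equilibrium_susceptibility(particle, medium.temperature)
    tau = tau_override if tau_override is not None else _effective_tau(
        particle, medium
    )
    dfac = dissipation_factor(field.f, tau)
    spa = MU0 * np.pi * chi0 * field.H0**2 * field.f * dfac / particle.density
    return LrtResult(chi0=chi0, dissipation_factor=float(dfac), spa=float(spa))


def spa_frequency_curve(
    particle: ParticleSpec,
    medium: MediumSpec,
    f_grid,
    H0: float,
) -> list[tuple[float, float]]:
    """LRT SPA evaluated on an ascending frequency grid at fixed H0.

    Rises as f² well below 1/(2πτ) and saturates (per unit H0²) well above
    it, where f·dissipation_factor → 1/(2πτ).
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size == 0:
        raise ValueError("frequency grid is empty")
    if np.any(f_grid <= 0) or np.any(np.diff(f_grid) <= 0):
        raise ValueError("frequency grid must be positive and ascending")
    out = []
    for f in f_grid:
        res = lrt_spa(
            particle,
            medium,
            FieldProtocol(H0=H0, f=float(f)),
        )
        out.append((float(f), res.spa))
    return out
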