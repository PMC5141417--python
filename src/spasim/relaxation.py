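"""Néel, Brownian and effective relaxation times, and the Ω = K_eff/η regime
classifier used for in-silico screening of heating agents.

Two mechanisms dephase the moment of a single-domain particle from an AC
field: Brownian rotation of the whole particle in the carrier
(τ_B = 3ηV_H/k_BT) and Néel reversal of the moment over the anisotropy
barrier (τ_N = τ₀·exp(K_effV/k_BT), zero-field Arrhenius form — the
field-dependent barrier lives in :mod:`spasim.hysteresis`).  Whichever is
faster dominates; the rates combine in parallel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .core import K_B, MediumSpec, ParticleSpec, sphere_volume

__all__ = [
    "Regime",
    "RelaxationReport",
    "brown_time",
    "neel_time",
    "effective_time",
    "omega_parameter",
    "classify_regime",
    "relaxation_report",
]

#: Largest allowed Arrhenius exponent; beyond this the particle is fully
#: blocked on any laboratory timescale and exp() would overflow anyway.
_MAX_EXPONENT = 700.0


class Regime(enum.Enum):
    NEEL_DOMINANT = "neel_dominant"
    MIXED = "mixed"
    BROWN_DOMINANT = "brown_dominant"


def brown_time(
    hydrodynamic_diameter: float, viscosity: float, temperature: float
) -> float:
    """Brownian rotational relaxation time τ_B = 3ηV_H/(k_B·T) in seconds.

    Exactly linear in viscosity and in hydrodynamic volume: an intracellular
    viscosity of 100 mPa·s slows rotation 100-fold relative to water.
    """
    if hydrodynamic_diameter <= 0 or viscosity <= 0 or temperature <= 0:
        raise ValueError("all brown_time inputs must be positive")
    v_h = sphere_volume(hydrodynamic_diameter)
    return 3.0 * viscosity * v_h / (K_B * temperature)


def neel_time(
    particle: ParticleSpec,
    temperature: float,
    volume_override: float | None = None,
) -> float:
    """Néel relaxation time τ_N = τ₀·exp(K_eff·V/(k_B·T)) in seconds.

    This is the zero-field magnetization relaxation time of the two-level
    system (sum of the two well-escape rates equals 1/τ_N).

    Parameters
    ----------
    volume_override : float, optional
        Magnetic volume (m³) to use instead of the mean-diameter sphere,
        e.g. for one member of a polydisperse ensemble.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    volume = particle.volume_mean if volume_override is None else volume_override
    if volume <= 0:
        raise ValueError("volume must be positive")
    exponent = particle.K_eff * volume / (K_B * temperature)
    if exponent > _MAX_EXPONENT:
        raise OverflowError(
            f"K_eff·V/k_BT = {exponent:.1f} > {_MAX_EXPONENT:.0f}: the "
            "particle is fully blocked at this size/temperature and τ_N is "
            "beyond any physical timescale"
        )
    return particle.tau0 * math.exp(exponent)


def effective_time(tau_n: float, tau_b: float) -> float:
    """Parallel-rate (Rosensweig) combination 1/τ = 1/τ_N + 1/τ_B.

    Symmetric in its arguments and bounded above by each of them; recovers
    τ_N when rotation is blocked (τ_B → ∞, the in-vitro regime).
    """
    if tau_n <= 0 or tau_b <= 0:
        raise ValueError("relaxation times must be positive")
    return tau_n * tau_b / (tau_n + tau_b)


def omega_parameter(k_eff: float, viscosity: float) -> float:
    """Ω = K_eff/η (s⁻¹), the single screening parameter merging magnetic
    and rheological conditions."""
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if k_eff < 0:
        raise ValueError("K_eff must be non-negative")
    return k_eff / viscosity


def classify_regime(
    k_eff: float,
    viscosity: float,
    thresholds: tuple[float, float] | None = None,
) -> Regime:
    """Classify the dominant relaxation mechanism from Ω = K_eff/η.

    ``thresholds = (Ω_low, Ω_high)`` is mandatory configuration — no
    literature consensus pins universal cutoffs, so they must be supplied
    explicitly.  Ω ≥ Ω_high → Néel-dominant; Ω ≤ Ω_low → Brown-dominant;
    in between → mixed.
    """
    if thresholds is None:
        raise ValueError(
            "Ω regime thresholds (omega_low, omega_high) are mandatory "
            "configuration and have no defaults"
        )
    omega_low, omega_high = thresholds
    if not omega_low < omega_high:
        raise ValueError("thresholds must satisfy omega_low < omega_high")
    omega = omega_parameter(k_eff, viscosity)
    if omega >= omega_high:
        return Regime.NEEL_DOMINANT
    if omega <= omega_low:
        return Regime.BROWN_DOMINANT
    return Regime.MIXED


@dataclass(frozen=True)
class RelaxationReport:
    """All relaxation timescales of one particle/medium combination."""

    tau_N: float  # s
    tau_B: float  # s
    tau_eff: float  # s
    omega: float  # K_eff/η, s⁻¹
    regime: Regime

    def to_dict(self) -> dict:
        return {
            "tau_N_s": self.tau_N,
            "tau_B_s": self.tau_B,
            "tau_eff_s": self.tau_eff,
            "omega_per_s": self.omega,
            "regime": self.regime.value,
        }


def relaxation_report(
    particle: ParticleSpec,
    medium: MediumSpec,
    thresholds: tuple[float, float],
) -> RelaxationReport:
    """Compute τ_N, τ_B, τ_eff and the Ω regime for one configuration.

    Requires ``medium.hydrodynamic_diameter``; falls back to the magnetic
    core diameter (bare particle) when it is not set.
    """
    d_h = medium.hydrodynamic_diameter or particle.d_mean
    tau_n = neel_time(particle, medium.temperature)
    tau_b = brown_time(d_h, medium.viscosity, medium.temperature)
    return RelaxationReport(
        tau_N=tau_n,
        tau_B=tau_b,
        tau_eff=effective_time(tau_n, tau_b),
        omega=omega_parameter(particle.K_eff, medium.viscosity),
        regime=classify_regime(particle.K_eff, medium.viscosity, thresholds),
    )
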