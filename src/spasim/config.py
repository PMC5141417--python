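"""Run configuration: schema-validated, unit-suffixed, JSON or TOML.

Every numeric key carries its unit in the name (``H0_kA_per_m``,
``viscosity_mPa_s`` ...), unknown keys are rejected, and the provenance of
each value (file vs documented default) is recorded so a run manifest can
state exactly what was simulated.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .core import MAGNETITE_DENSITY, FieldProtocol, MediumSpec, ParticleSpec
from .calorimetry import MAGNETITE_SPECIFIC_HEAT, WATER_SPECIFIC_HEAT
from .dipolar import DipolarConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class ParticleSection(_Section):
    d_mean_nm: float = Field(gt=0)
    d_sd_nm: float = Field(default=0.0, ge=0)
    Ms_Am2_per_kg: float = Field(gt=0)
    density_kg_per_m3: float = Field(default=MAGNETITE_DENSITY, gt=0)
    H_A_kA_per_m: float | None = Field(default=None, ge=0)
    K_eff_J_per_m3: float | None = Field(default=None, ge=0)
    tau0_s: float = Field(default=1.0e-9, gt=0)


class MediumSection(_Section):
    viscosity_mPa_s: float = Field(default=1.0, gt=0)
    temperature_K: float = Field(default=300.0, gt=0)
    hydrodynamic_diameter_nm: float | None = Field(default=None, gt=0)


class FieldSection(_Section):
    H0_kA_per_m: float = Field(ge=0)
    f_kHz: float = Field(gt=0)
    steps_per_cycle: int = Field(default=2000, ge=100)
    n_cycles: int = Field(default=3, ge=2)


class DipolarSection(_Section):
    gap_nm: float = Field(default=5.0, ge=0)
    distortion_sd: float = Field(default=0.0, ge=0)
    coupling_min: float = Field(default=0.02, ge=0, lt=1)
    coupling_max: float = Field(default=0.05, ge=0, lt=1)


class SimulationSection(_Section):
    n_particles: int = Field(default=500, ge=2)
    seed: int = 0
    size_distribution: str = Field(default="gaussian", pattern="^(gaussian|lognormal)$")


class CalorimetrySection(_Section):
    c_l_J_per_kg_K: float = Field(default=WATER_SPECIFIC_HEAT, gt=0)
    c_np_J_per_kg_K: float = Field(default=MAGNETITE_SPECIFIC_HEAT, gt=0)
    window_s: float = Field(default=30.0, gt=0)


class RegimesSection(_Section):
    omega_low_per_s: float | None = Field(default=None, gt=0)
    omega_high_per_s: float | None = Field(default=None, gt=0)


class RunConfig(_Section):
    """Validated run configuration with SI conversion helpers."""

    particle: ParticleSection
    field: FieldSection
    medium: MediumSection = MediumSection()
    dipolar: DipolarSection = DipolarSection()
    simulation: SimulationSection = SimulationSection()
    calorimetry: CalorimetrySection = CalorimetrySection()
    regimes: RegimesSection = RegimesSection()

    def particle_spec(self) -> ParticleSpec:
        p = self.particle
        return ParticleSpec(
            d_mean=p.d_mean_nm * 1e-9,
            d_sd=p.d_sd_nm * 1e-9,
            Ms_mass=p.Ms_Am2_per_kg,
            density=p.density_kg_per_m3,
            H_A=None if p.H_A_kA_per_m is None else p.H_A_kA_per_m * 1e3,
            K_eff=p.K_eff_J_per_m3,
            tau0=p.tau0_s,
        )

    def medium_spec(self) -> MediumSpec:
        m = self.medium
        d_h = m.hydrodynamic_diameter_nm
        return MediumSpec(
            viscosity=m.viscosity_mPa_s * 1e-3,
            temperature=m.temperature_K,
            hydrodynamic_diameter=None if d_h is None else d_h * 1e-9,
        )

    def field_protocol(self, H0: float | None = None) -> FieldProtocol:
        f = self.field
        return FieldProtocol(
            H0=f.H0_kA_per_m * 1e3 if H0 is None else H0,
            f=f.f_kHz * 1e3,
            steps_per_cycle=f.steps_per_cycle,
            n_cycles=f.n_cycles,
        )

    def dipolar_config(self) -> DipolarConfig:
        d = self.dipolar
        return DipolarConfig(
            gap=d.gap_nm * 1e-9,
            distortion_sd=d.distortion_sd,
            coupling_min=d.coupling_min,
            coupling_max=d.coupling_max,
            seed=self.simulation.seed,
        )

    def provenance(self) -> dict[str, str]:
        """Per-field record of whether a value came from the file or from a
        documented package default."""
        out: dict[str, str] = {}
        for section_name in type(self).model_fields:
            section = getattr(self, section_name)
            provided_section = section_name in self.model_fields_set
            for key in type(section).model_fields:
                provided = provided_section and key in section.model_fields_set
                out[f"{section_name}.{key}"] = "file" if provided else "default"
        return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or TOML run configuration.

    Raises ``ValueError`` naming the offending field (and its expected,
    unit-suffixed spelling) on any schema violation, including unknown keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        raw = json.loads(path.read_text())
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise ValueError(
            "invalid configuration (all numeric keys need their unit "
            "suffix, e.g. H0_kA_per_m): " + "; ".join(lines)
        ) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration as JSON; load(save(x)) == x."""
    Path(path).write_text(
        json.dumps(config.model_dump(), indent=2, sort_keys=True) + "\n"
    )


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the fully resolved configuration."""
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
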