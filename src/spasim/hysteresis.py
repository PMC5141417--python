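"""Thermally activated two-level Stoner–Wohlfarth dynamic hysteresis.

The moment of a uniaxial single-domain particle whose easy axis makes an
angle ψ with the AC field axis lives in a two-well energy landscape

    e(θ) = sin²(θ − ψ) − 2·h_app·cosθ − 2·h_bias·cos(θ − ψ)

written in units of K_eff·V with all fields reduced by the anisotropy field
H_A (θ is the moment angle from the field axis; the zero-field barrier is
exactly 1).  ``h_bias`` is a static mean-field dipolar term collinear with
the easy axis.  At each step of the discretized sinusoidal sweep the two
minima, their moment projections and the barriers to the lowest saddle are
located numerically; the well populations obey the two-level master
equation with Arrhenius escape rates

    1/τ_i = (1/(2τ₀))·exp(−ΔE_i/k_B T),

whose sum reproduces the zero-field Néel relaxation rate 1/τ_N =
(1/τ₀)·exp(−K_effV/k_BT).  The recorded magnetization blends the
superparamagnetic (instantaneous Boltzmann) and blocked (population)
limits through the observation-time probability L = 1 − exp(−Δt/τ_total):

    M = L·⟨M⟩_SP + (1 − L)·Σᵢ nᵢ·Mᵢ .

The loop area over the last full cycle times μ₀·f gives the specific power
absorption.  Ensembles average over random easy-axis orientations, a
truncated-Gaussian size distribution and per-particle dipolar bias fields,
weighting each particle by its mass (SPA is power per unit mass of magnetic
material).  Brownian rotation is deliberately absent: easy axes are static,
matching the agglomerated, rotation-blocked intracellular regime.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import K_B, MU0, FieldProtocol, MediumSpec, ParticleSpec, sphere_volume
from .dipolar import DipolarConfig, sample_interaction_field

__all__ = [
    "TwoLevelState",
    "HysteresisLoop",
    "sw_energy",
    "energy_barriers",
    "switching_field",
    "advance_populations",
    "simulate_loop",
    "ensemble_spa",
    "spa_vs_field",
]

_EXP_CAP = 745.0  # exp() underflow guard on the Arrhenius exponent
_RATE_INSTANT = 1.0e30  # athermal stand-in for "well has vanished" (1/s)


def sw_energy(h, psi, phi):
    """Reduced Stoner–Wohlfarth energy e(φ) = sin²(φ−ψ) − 2h·cosφ.

    Units of K_eff·V; h = H/H_A; ψ is the easy-axis angle and φ the moment
    angle, both measured from the field axis.  Normalized so the zero-field
    barrier equals 1; the aligned-case (ψ=0) barriers are (1∓h)².
    """
    h, psi, phi = np.asarray(h), np.asarray(psi), np.asarray(phi)
    return np.sin(phi - psi) ** 2 - 2.0 * h * np.cos(phi)


def _refine(e: np.ndarray, idx: np.ndarray, dphi: float):
    """Quadratic (3-point) refinement of extrema located on a periodic grid.

    Returns refined energies and angular offsets from the grid point.
    """
    n = e.shape[1]
    rows = np.arange(e.shape[0])
    y0 = e[rows, idx]
    ym = e[rows, (idx - 1) % n]
    yp = e[rows, (idx + 1) % n]
    denom = ym - 2.0 * y0 + yp
    safe = np.abs(denom) > 1e-300
    delta = np.where(safe, 0.5 * (ym - yp) / np.where(safe, denom, 1.0), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    e_ref = np.where(safe, y0 - 0.125 * (ym - yp) ** 2 / np.where(safe, denom, 1.0), y0)
    return e_ref, delta * dphi


def _landscape(psi: float, h_app: np.ndarray, h_bias: float, n_phi: int = 720):
    """Locate the two wells and the lowest saddle for each applied field.

    Well 1 holds the moment component along +ê (cos(θ−ψ) ≥ 0), well 2 the
    opposite.  For a vanished well the returned energy/projection duplicate
    the surviving well and its barrier is 0.

    Returns dict of arrays over ``len(h_app)``: well energies ``e1, e2``,
    moment projections on the field axis ``c1, c2`` (cosθ at the minima),
    barriers ``b1, b2`` (reduced units, to the lowest saddle) and existence
    flags ``exists1, exists2``.
    """
    h_app = np.asarray(h_app, dtype=float)
    theta = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    dphi = 2.0 * np.pi / n_phi
    base = np.sin(theta - psi) ** 2 - 2.0 * h_bias * np.cos(theta - psi)
    drive = -2.0 * np.cos(theta)
    e = base[None, :] + h_app[:, None] * drive[None, :]

    left = np.roll(e, 1, axis=1)
    right = np.roll(e, -1, axis=1)
    min_mask = (e < left) & (e <= right)
    max_mask = (e > left) & (e >= right)

    region1 = np.cos(theta - psi) >= 0.0
    inf = np.inf
    rows = np.arange(e.shape[0])

    def well(region):
        masked = np.where(min_mask & region[None, :], e, inf)
        idx = np.argmin(masked, axis=1)
        exists = np.isfinite(masked[rows, idx])
        e_ref, dth = _refine(e, idx, dphi)
        c = np.cos(theta[idx] + dth)
        return e_ref, c, exists, idx

    e1, c1, exists1, _ = well(region1)
    e2, c2, exists2, _ = well(~region1)

    masked_max = np.where(max_mask, e, inf)
    idx_s = np.argmin(masked_max, axis=1)
    saddle, _ = _refine(e, idx_s, dphi)

    # duplicate the surviving well into a vanished slot
    only1 = exists1 & ~exists2
    only2 = exists2 & ~exists1
    e2 = np.where(only1, e1, e2)
    c2 = np.where(only1, c1, c2)
    e1 = np.where(only2, e2, e1)
    c1 = np.where(only2, c2, c1)

    b1 = np.where(exists1, np.maximum(saddle - e1, 0.0), 0.0)
    b2 = np.where(exists2, np.maximum(saddle - e2, 0.0), 0.0)
    return {
        "e1": e1, "e2": e2, "c1": c1, "c2": c2,
        "b1": b1, "b2": b2, "exists1": exists1, "exists2": exists2,
    }


def energy_barriers(h: float, psi: float, n_phi: int = 4096) -> tuple[float, float]:
    """Barriers (ΔE₊, ΔE₋) out of the two wells, in units of K_eff·V.

    ΔE₊ is the barrier out of the energetically unfavoured (metastable)
    well, ΔE₋ out of the favoured one; for the aligned case ψ = 0 these are
    the closed forms (1−h)² and (1+h)².  A vanished well reports 0.
    """
    if h < 0:
        raise ValueError("reduced field h must be non-negative")
    tab = _landscape(psi, np.array([h]), 0.0, n_phi=n_phi)
    b1, b2 = float(tab["b1"][0]), float(tab["b2"][0])
    e1, e2 = float(tab["e1"][0]), float(tab["e2"][0])
    if not tab["exists1"][0]:
        return 0.0, b2
    if not tab["exists2"][0]:
        return 0.0, b1
    return (b2, b1) if e2 >= e1 else (b1, b2)


def switching_field(psi: float, tol: float = 1e-6, n_phi: int = 4096) -> float:
    """Athermal Stoner–Wohlfarth switching field h_sw(ψ) (units of H_A).

    Found by bisection on the disappearance of the metastable minimum; the
    closed form is the astroid h_sw = (cos^{2/3}ψ + sin^{2/3}ψ)^{−3/2}.
    """

    def two_wells(h: float) -> bool:
        tab = _landscape(psi, np.array([h]), 0.0, n_phi=n_phi)
        return bool(tab["exists1"][0] and tab["exists2"][0])

    lo, hi = 0.0, 1.0
    if two_wells(hi):  # ψ = 0 or 90°: switching exactly at h = 1
        hi = 1.0 + 1e-9
        if two_wells(hi):
            hi = 1.1
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if two_wells(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class TwoLevelState:
    """Instantaneous state of the two-level system.

    ``L`` is the probability of superparamagnetic behaviour over the current
    step, ``n`` the well occupations (sum to 1) and ``M`` the magnetization
    projection on the field axis in the units of the supplied projections.
    """

    L: float
    n: tuple[float, float]
    M: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 1.0):
            raise ValueError("L must lie in [0, 1]")
        if abs(self.n[0] + self.n[1] - 1.0) > 1e-9:
            raise ValueError("well populations must sum to 1")


def advance_populations(
    state: TwoLevelState,
    barriers: tuple[float, float],
    k_eff: float,
    volume: float,
    tau0: float,
    temperature: float,
    dt: float,
    projections: tuple[float, float] = (1.0, -1.0),
) -> TwoLevelState:
    """One master-equation step with piecewise-constant Arrhenius rates.

    ``barriers`` are (ΔE₁, ΔE₂) in reduced K_eff·V units for the wells
    matching ``state.n`` and ``projections``.  The populations relax exactly
    (exponentially) toward the instantaneous Boltzmann equilibrium; the
    returned ``M`` blends the superparamagnetic average and the blocked
    populations through L = 1 − exp(−dt/τ_total).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    b1, b2 = barriers
    if temperature > 0:
        sigma = k_eff * volume / (K_B * temperature)
        nu1 = math.exp(-min(sigma * b1, _EXP_CAP)) / (2.0 * tau0)
        nu2 = math.exp(-min(sigma * b2, _EXP_CAP)) / (2.0 * tau0)
        # Boltzmann weights of the wells: e_i = saddle − ΔE_i ⇒ w_i ∝ e^{σΔE_i}
        bmax = max(b1, b2)
        w1 = math.exp(min(sigma * (b1 - bmax), 0.0))
        w2 = math.exp(min(sigma * (b2 - bmax), 0.0))
    else:  # athermal limit: transitions only when a well has vanished
        nu1 = _RATE_INSTANT if b1 == 0.0 and b2 > 0.0 else 0.0
        nu2 = _RATE_INSTANT if b2 == 0.0 and b1 > 0.0 else 0.0
        w1 = 1.0 if b1 >= b2 else 0.0
        w2 = 1.0 if b2 >= b1 else 0.0
    total = nu1 + nu2
    if total > 0:
        neq1 = nu2 / total
        decay = math.exp(-min(dt * total, _EXP_CAP))
    else:
        neq1, decay = 0.5, 1.0
    n1 = neq1 + (state.n[0] - neq1) * decay
    n1 = min(max(n1, 0.0), 1.0)
    L = 1.0 - decay
    p1, p2 = projections
    m_sp = (p1 * w1 + p2 * w2) / (w1 + w2)
    m_blocked = n1 * p1 + (1.0 - n1) * p2
    return TwoLevelState(L=L, n=(n1, 1.0 - n1), M=L * m_sp + (1.0 - L) * m_blocked)


@dataclass(frozen=True)
class HysteresisLoop:
    """Steady-state simulated loop: the last full cycle, closed.

    ``area`` is the enclosed loop integral (−∮M dH ≥ 0 in steady state, in
    (A·m²/kg)·(A/m)); ``spa`` = μ₀·f·area in W per kg of magnetic material.
    """

    H_trace: np.ndarray  # A/m
    M_trace: np.ndarray  # A·m²/kg
    area: float
    spa: float
    n_cycles_run: int = 0
    converged: bool = True


def _loop_area(H: np.ndarray, M: np.ndarray) -> float:
    """−∮M dH over one closed cycle (trapezoidal, periodic)."""
    dH = np.roll(H, -1) - H
    return float(-np.sum(0.5 * (M + np.roll(M, -1)) * dH))


def simulate_loop(
    particle: ParticleSpec,
    field: FieldProtocol,
    temperature: float,
    interaction_field: float = 0.0,
    psi: float = 0.0,
    *,
    diameter: float | None = None,
    n_phi: int = 720,
    area_rtol: float = 0.01,
    max_cycles: int = 12,
    warn: bool = True,
) -> HysteresisLoop:
    """Dynamic M(H) loop of a single particle at easy-axis angle ψ.

    ``temperature = 0`` runs the athermal (deterministic Stoner–Wohlfarth)
    limit.  ``interaction_field`` is the signed static dipolar bias along
    the easy axis (A/m); ``diameter`` overrides the mean core diameter for
    polydisperse ensembles.  The first cycle is discarded as a transient;
    the loop area is measured on the last cycle and cycles are appended (up
    to ``max_cycles``) until consecutive areas agree to ``area_rtol``.
    """
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    d = particle.d_mean if diameter is None else diameter
    volume = sphere_volume(d)
    h_a = particle.H_A
    if h_a <= 0:
        raise ValueError("particle must have a positive anisotropy field")
    steps = field.steps_per_cycle
    dt = field.dt
    h_app = (field.H0 / h_a) * np.sin(2.0 * np.pi * np.arange(steps) / steps)
    tab = _landscape(psi, h_app, interaction_field / h_a, n_phi=n_phi)

    athermal = temperature == 0.0
    if athermal:
        nu1 = np.where(~tab["exists1"], _RATE_INSTANT, 0.0)
        nu2 = np.where(~tab["exists2"], _RATE_INSTANT, 0.0)
        msp = np.where(
            tab["e1"] < tab["e2"],
            tab["c1"],
            np.where(tab["e2"] < tab["e1"], tab["c2"], 0.5 * (tab["c1"] + tab["c2"])),
        )
        n1 = 1.0 if tab["e1"][0] < tab["e2"][0] else (
            0.0 if tab["e2"][0] < tab["e1"][0] else 0.5
        )
    else:
        sigma = particle.K_eff * volume / (K_B * temperature)
        nu1 = np.exp(-np.minimum(sigma * tab["b1"], _EXP_CAP)) / (2.0 * particle.tau0)
        nu2 = np.exp(-np.minimum(sigma * tab["b2"], _EXP_CAP)) / (2.0 * particle.tau0)
        de = sigma * (tab["e2"] - tab["e1"])  # e2 − e1 in kT units
        w2 = np.exp(-np.minimum(np.maximum(de, 0.0), _EXP_CAP))
        w1 = np.exp(np.maximum(np.minimum(de, 0.0), -_EXP_CAP))
        msp = (tab["c1"] * w1 + tab["c2"] * w2) / (w1 + w2)
        n1 = float(w1[0] / (w1[0] + w2[0]))  # Boltzmann start at H = H(0)

    total = nu1 + nu2
    decay = np.exp(-np.minimum(dt * total, _EXP_CAP))
    neq1 = np.where(total > 0, nu2 / np.where(total > 0, total, 1.0), 0.5)
    L = 1.0 - decay
    c1, c2 = tab["c1"], tab["c2"]

    decay_l = decay.tolist()
    neq_l = neq1.tolist()
    H = h_app * h_a
    area_scale = 4.0 * particle.Ms_mass * max(field.H0, 1e-30)

    areas: list[float] = []
    m_last = None
    n_run = 0
    for cycle in range(max_cycles):
        n1_trace = np.empty(steps)
        x = n1
        for k in range(steps):
            x = neq_l[k] + (x - neq_l[k]) * decay_l[k]
            n1_trace[k] = x
        n1 = x
        n_run += 1
        m_cycle = particle.Ms_mass * (
            L * msp + (1.0 - L) * (n1_trace * c1 + (1.0 - n1_trace) * c2)
        )
        areas.append(_loop_area(H, m_cycle))
        m_last = m_cycle
        if n_run >= field.n_cycles and len(areas) >= 2:
            if abs(areas[-1] - areas[-2]) <= area_rtol * abs(areas[-1]) + 1e-9 * area_scale:
                break
    else:
        cycle = max_cycles  # noqa: F841 - loop exhausted

    converged = (
        len(areas) >= 2
        and abs(areas[-1] - areas[-2])
        <= area_rtol * abs(areas[-1]) + 1e-9 * area_scale
    )
    if not converged and warn:
        warnings.warn(
            f"loop area not steady to {area_rtol:.0%} after {n_run} cycles",
            stacklevel=2,
        )
    area = max(areas[-1], 0.0)
    h_closed = np.append(H, H[0])
    m_closed = np.append(m_last, m_last[0])
    return HysteresisLoop(
        H_trace=h_closed,
        M_trace=m_closed,
        area=area,
        spa=MU0 * field.f * area,
        n_cycles_run=n_run,
        converged=converged,
    )


def _draw_ensemble(
    particle: ParticleSpec,
    dipolar: DipolarConfig,
    n_particles: int,
    rng: np.random.Generator,
    size_distribution: str = "gaussian",
):
    """Diameters, easy-axis angles and coupling draws for one ensemble.

    Diameters follow the TEM moments: Gaussian truncated at ±3 s.d. and at a
    5 nm floor (lognormal with matched moments is config-selectable); easy
    axes are uniform on the sphere; coupling fractions are uniform in the
    configured range with random sign.
    """
    if size_distribution not in ("gaussian", "lognormal"):
        raise ValueError("size_distribution must be 'gaussian' or 'lognormal'")
    d_mean, d_sd = particle.d_mean, particle.d_sd
    if d_sd == 0:
        diam = np.full(n_particles, d_mean)
    elif size_distribution == "lognormal":
        s2 = math.log(1.0 + (d_sd / d_mean) ** 2)
        mu = math.log(d_mean) - 0.5 * s2
        diam = rng.lognormal(mu, math.sqrt(s2), size=n_particles)
        diam = np.clip(diam, 5.0e-9, None)
    else:
        lo = max(5.0e-9, d_mean - 3.0 * d_sd)
        hi = d_mean + 3.0 * d_sd
        diam = np.empty(n_particles)
        filled = 0
        while filled < n_particles:
            draw = rng.normal(d_mean, d_sd, size=n_particles - filled)
            keep = draw[(draw >= lo) & (draw <= hi)]
            diam[filled : filled + keep.size] = keep
            filled += keep.size
    psi = np.arccos(rng.uniform(-1.0, 1.0, size=n_particles))
    # signed coupling fractions (bias field per unit H0), so one draw can be
    # reused across a whole amplitude grid
    fractions = sample_interaction_field(dipolar, 1.0, n_particles, rng=rng)
    return diam, psi, fractions


def _weighted_mean_se(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    wsq = float(np.sum(w**2))
    if values.size < 2 or wsq >= 1.0:
        return mean, 0.0
    var = float(np.sum(w * (values - mean) ** 2)) / (1.0 - wsq)
    return mean, math.sqrt(max(var * wsq, 0.0))


def ensemble_spa(
    particle: ParticleSpec,
    medium: MediumSpec,
    field: FieldProtocol,
    dipolar: DipolarConfig,
    n_particles: int,
    seed: int | None = None,
    *,
    size_distribution: str = "gaussian",
    n_phi: int = 720,
) -> tuple[float, float]:
    """Monte-Carlo ensemble SPA (W/kg of magnetic material) and its
    standard error.

    Averages single-particle loop SPA over random easy-axis orientations,
    the truncated size distribution and signed mean-field dipolar biases of
    ``dipolar.coupling_min``–``coupling_max``·H0, weighting each particle by
    its mass.  Bit-reproducible under a fixed seed.
    """
    if n_particles < 2:
        raise ValueError("n_particles must be at least 2")
    rng = np.random.default_rng(seed)
    diam, psi, coupling = _draw_ensemble(
        particle, dipolar, n_particles, rng, size_distribution
    )
    bias = coupling * field.H0
    spa = np.empty(n_particles)
    n_bad = 0
    for i in range(n_particles):
        loop = simulate_loop(
            particle,
            field,
            medium.temperature,
            interaction_field=float(bias[i]),
            psi=float(psi[i]),
            diameter=float(diam[i]),
            n_phi=n_phi,
            warn=False,
        )
        spa[i] = loop.spa
        n_bad += not loop.converged
    if n_bad:
        warnings.warn(
            f"{n_bad}/{n_particles} particle loops did not reach a steady "
            "area within the cycle cap",
            stacklevel=2,
        )
    weights = diam**3  # particle mass ∝ d³ at equal density
    return _weighted_mean_se(spa, weights)


def spa_vs_field(
    particle: ParticleSpec,
    medium: MediumSpec,
    field: FieldProtocol,
    H0_grid,
    dipolar: DipolarConfig,
    n_particles: int,
    seed: int | None = None,
    *,
    size_distribution: str = "gaussian",
    n_phi: int = 720,
) -> list[tuple[float, float, float]]:
    """Ensemble SPA along an ascending H0 grid with common random numbers.

    The same particle draw (diameters, orientations, coupling fractions) is
    reused at every amplitude — the bias field scales with H0, as the
    mean-field picture prescribes — which smooths the SPA(H0) curve for
    power-law fitting.  ``field`` supplies f and the discretization; its own
    H0 is ignored.  Returns (H0, spa, stderr) tuples.
    """
    H0_grid = np.asarray(H0_grid, dtype=float)
    if H0_grid.size == 0:
        raise ValueError("H0 grid is empty")
    if np.any(np.diff(H0_grid) <= 0):
        raise ValueError("H0 grid must be strictly ascending")
    if n_particles < 2:
        raise ValueError("n_particles must be at least 2")
    rng = np.random.default_rng(seed)
    diam, psi, coupling = _draw_ensemble(
        particle, dipolar, n_particles, rng, size_distribution
    )
    weights = diam**3
    out = []
    for H0 in H0_grid:
        fp = FieldProtocol(
            H0=float(H0),
            f=field.f,
            steps_per_cycle=field.steps_per_cycle,
            n_cycles=field.n_cycles,
        )
        spa = np.empty(n_particles)
        for i in range(n_particles):
            loop = simulate_loop(
                particle,
                fp,
                medium.temperature,
                interaction_field=float(coupling[i] * H0),
                psi=float(psi[i]),
                diameter=float(diam[i]),
                n_phi=n_phi,
                warn=False,
            )
            spa[i] = loop.spa
        mean, se = _weighted_mean_se(spa, weights)
        out.append((float(H0), mean, se))
    return out
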