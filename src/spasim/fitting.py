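"""The two regression analyses around the simulator: the SPA = Φ·H₀^λ
power law and the FMR H_res vs cos²θ anisotropy line.

λ = 2 signals the linear-response regime; λ ≈ 4–6 is the signature of
dynamic hysteresis approaching the irreversibility field.  The FMR line's
slope magnitude is reported as the uniaxial anisotropy-field estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerLawFit",
    "FmrFit",
    "fit_power_law",
    "fit_fmr_line",
    "generate_spa_curve",
    "generate_fmr_scan",
]


@dataclass(frozen=True)
class PowerLawFit:
    """SPA = Φ·H0^λ fit result; ``covariance`` is the 2×2 matrix for (Φ, λ)."""

    phi: float
    lam: float
    covariance: np.ndarray
    r_squared: float

    @property
    def lam_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))


@dataclass(frozen=True)
class FmrFit:
    """OLS of H_res against cos²θ; H_A_estimate = |slope| (A/m)."""

    intercept: float
    slope: float
    H_A_estimate: float
    slope_stderr: float
    residuals: np.ndarray


def fit_power_law(H0s, spas, errors=None) -> PowerLawFit:
    """Nonlinear least squares of SPA = Φ·H0^λ.

    Initialized from the log–log OLS line; ``errors`` (same units as
    ``spas``) switch on inverse-variance weighting.  Raises on non-positive
    data or non-convergence (reporting the log–log fallback in the message).
    """
    H0s = np.asarray(H0s, dtype=float)
    spas = np.asarray(spas, dtype=float)
    if H0s.size < 3:
        raise ValueError("at least 3 points are required")
    if np.any(H0s <= 0) or np.any(spas <= 0):
        raise ValueError("power-law fitting requires strictly positive data")
    loglog = stats.linregress(np.log(H0s), np.log(spas))
    p0 = (float(np.exp(loglog.intercept)), float(loglog.slope))
    try:
        popt, pcov = optimize.curve_fit(
            lambda h, phi, lam: phi * h**lam,
            H0s,
            spas,
            p0=p0,
            sigma=None if errors is None else np.asarray(errors, dtype=float),
            absolute_sigma=errors is not None,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"power-law fit did not converge ({exc}); log–log OLS gives "
            f"phi = {p0[0]:.4g}, lambda = {p0[1]:.4g}"
        ) from exc
    pred = popt[0] * H0s ** popt[1]
    ss_res = float(np.sum((spas - pred) ** 2))
    ss_tot = float(np.sum((spas - spas.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        phi=float(popt[0]), lam=float(popt[1]), covariance=pcov, r_squared=r2
    )


def fit_fmr_line(theta_deg, H_res) -> FmrFit:
    """OLS of the FMR resonance field against cos²θ.

    A uniaxial sample shows a straight H_res(cos²θ) line; the slope
    magnitude is taken as the anisotropy-field estimate (the identity-slope
    convention — no Smit–Beljers conversion is applied).
    """
    theta = np.asarray(theta_deg, dtype=float)
    h_res = np.asarray(H_res, dtype=float)
    if theta.size < 3:
        raise ValueError("at least 3 angles are required")
    if np.unique(theta).size < 2:
        raise ValueError("all angles are identical; the line is undetermined")
    x = np.cos(np.deg2rad(theta)) ** 2
    res = stats.linregress(x, h_res)
    fitted = res.intercept + res.slope * x
    return FmrFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        H_A_estimate=abs(float(res.slope)),
        slope_stderr=float(res.stderr),
        residuals=h_res - fitted,
    )


def generate_spa_curve(
    phi: float,
    lam: float,
    H0_grid,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (H0, SPA) data from an exact power law.

    Noise is multiplicative log-normal (SPA uncertainty grows with SPA in
    repeat calorimetry): spa = Φ·H0^λ·exp(ε), ε ~ N(0, noise_sd²).
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    H0_grid = np.asarray(H0_grid, dtype=float)
    if np.any(H0_grid <= 0):
        raise ValueError("H0 grid must be positive")
    spa = phi * H0_grid**lam
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spa = spa * np.exp(rng.normal(0.0, noise_sd, size=H0_grid.size))
    return H0_grid, spa


def generate_fmr_scan(
    H_A: float,
    H_res_perp: float,
    theta_deg,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic uniaxial FMR scan H_res(θ) = H_res_perp − H_A·cos²θ.

    ``H_res_perp`` is the resonance field at θ = 90° (hard direction);
    additive Gaussian noise of s.d. ``noise_sd`` (A/m).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    theta = np.asarray(theta_deg, dtype=float)
    h_res = H_res_perp - H_A * np.cos(np.deg2rad(theta)) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        h_res = h_res + rng.normal(0.0, noise_sd, size=theta.size)
    return theta, h_res
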