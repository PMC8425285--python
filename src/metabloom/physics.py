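"""Water-column physics: salinity, potential density, stability, mixed layer.

Converts temperature/conductivity profiles into potential density, the
buoyancy (Brunt–Väisälä) frequency N², the surface mixed-layer depth and a
detected metalimnion.  Depth is metres below the surface, positive
downward, so stable stratification (density increasing downward) yields
N² > 0 under

    N²(z) = (g / ρ) · (∂ρ/∂z_down)

which is the usual −(g/ρ)(∂ρ/∂z) written for an upward axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PhysicsConstants

__all__ = [
    "StratificationSummary",
    "salinity_from_conductivity",
    "potential_temperature",
    "potential_density",
    "density",
    "buoyancy_frequency",
    "mixed_layer_depth",
    "detect_metalimnion",
    "summarize_stratification",
]

# Pure-water density polynomial (Chen–Millero type), ρ in kg m⁻³, T in °C.
# Maximum density close to 3.98 °C.
_RHO_COEF = np.array(
    [999.8395, 6.7914e-2, -9.0894e-3, 1.0171e-4, -1.2846e-6, 1.1592e-8, -5.0125e-11]
)

# specific heat capacity used in the adiabatic lapse correction (J kg⁻¹ K⁻¹)
_CP = 4186.0


@dataclass
class StratificationSummary:
    """Per-profile stratification state.

    ``n2_profile`` is reported on the same grid depths as the density
    profile (centred differences inside, one-sided at the ends).
    ``full_mixing`` marks profiles on which the mixed-layer criterion was
    never met, interpreted as holomixis.
    """

    n2_profile: np.ndarray
    z_mix: float
    metalimnion_upper: float | None
    metalimnion_center: float | None
    metalimnion_lower: float | None
    metalimnion_valid: bool
    n2_max: float
    full_mixing: bool = False


def salinity_from_conductivity(
    cond25: np.ndarray | float, constants: PhysicsConstants = PhysicsConstants()
) -> np.ndarray | float:
    """Salinity (‰) from conductivity normalised to 25 °C (µS cm⁻¹).

    A lake-specific multiplicative factor for calcium-carbonate dominated
    water; vectorises over profiles.
    """
    cond = np.asarray(cond25, dtype=float)
    if np.any(cond[~np.isnan(cond)] < 0):
        raise ValueError("conductivity must be non-negative")
    out = cond * constants.cond_to_salinity
    return float(out) if np.isscalar(cond25) else out


def _thermal_expansion(t: np.ndarray) -> np.ndarray:
    """α(T) = −(1/ρ)(dρ/dT) of pure water (K⁻¹)."""
    rho = _poly(t)
    drho = sum(k * c * t ** (k - 1) for k, c in enumerate(_RHO_COEF) if k >= 1)
    return -drho / rho


def _poly(t: np.ndarray) -> np.ndarray:
    return sum(c * t**k for k, c in enumerate(_RHO_COEF))


def potential_temperature(
    t_insitu: np.ndarray | float,
    depth: np.ndarray | float,
    constants: PhysicsConstants = PhysicsConstants(),
) -> np.ndarray | float:
    """In-situ temperature corrected adiabatically to the surface (°C).

    Uses the freshwater adiabatic lapse rate Γ = g·α(T)·T_abs/c_p applied
    over the hydrostatic pressure head of ``depth`` metres; the correction
    is below 0.02 K anywhere above 140 m, and exactly zero at the surface.
    Above the temperature of maximum density α < 0 flips the sign, as it
    must for water.
    """
    t = np.asarray(t_insitu, dtype=float)
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    gamma = constants.g * _thermal_expansion(t) * (t + 273.15) / _CP
    theta = t - gamma * z
    if np.isscalar(t_insitu) and np.isscalar(depth):
        return float(theta)
    return theta


def potential_density(theta: np.ndarray | float) -> np.ndarray | float:
    """Pure-water density (kg m⁻³) at potential temperature θ (°C)."""
    t = np.asarray(theta, dtype=float)
    valid = ~np.isnan(t)
    if np.any((t[valid] <= 0) | (t[valid] >= 35)):
        raise ValueError("potential temperature outside (0, 35) °C")
    rho = _poly(t)
    return float(rho) if np.isscalar(theta) else rho


def density(
    theta: np.ndarray | float,
    salinity: np.ndarray | float,
    constants: PhysicsConstants = PhysicsConstants(),
) -> np.ndarray | float:
    """Density including the haline contribution: ρ = ρ_θ(θ)·(1 + β·S)."""
    s = np.asarray(salinity, dtype=float)
    if np.any(s[~np.isnan(s)] < 0):
        raise ValueError("salinity must be non-negative")
    rho = potential_density(theta) * (1.0 + constants.beta_haline * s)
    if np.isscalar(theta) and np.isscalar(salinity):
        return float(rho)
    return rho


def buoyancy_frequency(
    density_profile: np.ndarray,
    depth_grid: np.ndarray | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
) -> np.ndarray:
    """N²(z) (s⁻²) from a density profile on a depth grid.

    Centred differences at interior points, one-sided at the ends; N² is
    assigned to the grid depths themselves for alignment with the other
    per-depth quantities.
    """
    rho = np.asarray(density_profile, dtype=float)
    if rho.size < 2:
        raise ValueError("need at least 2 depth points")
    if depth_grid is None:
        depth_grid = np.arange(rho.size, dtype=float)
    z = np.asarray(depth_grid, dtype=float)
    drho = np.gradient(rho, z)
    return constants.g * drho / rho


def mixed_layer_depth(
    density_profile: np.ndarray,
    depth_grid: np.ndarray | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
) -> tuple[float, bool]:
    """Mixed-layer depth (m) and a full-column-mixing flag.

    z_mix is the shallowest depth where density strictly exceeds the
    near-surface reference (mean over the top ``surface_reference_span``
    metres) by ``mld_density_offset``.  If no depth exceeds the criterion
    the whole column is considered mixed: z_mix is the deepest grid depth
    and the flag is set.
    """
    rho = np.asarray(density_profile, dtype=float)
    if depth_grid is None:
        depth_grid = np.arange(rho.size, dtype=float)
    z = np.asarray(depth_grid, dtype=float)
    surf = z <= constants.surface_reference_span
    if not np.any(surf & ~np.isnan(rho)):
        raise ValueError("no near-surface density data for the reference")
    rho_ref = np.nanmean(rho[surf])
    exceed = rho > rho_ref + constants.mld_density_offset
    idx = np.flatnonzero(exceed)
    if idx.size == 0:
        return float(z[np.isfinite(rho)].max()), True
    return float(z[idx[0]]), False


def _half_max_crossing(
    z: np.ndarray, n2: np.ndarray, i_max: int, half: float, direction: int
) -> float:
    """First half-max crossing walking outward from the argmax.

    Linear interpolation between bracketing grid points; clipped to the
    grid end when the profile never falls to half maximum.
    """
    i = i_max
    while 0 <= i + direction < n2.size:
        j = i + direction
        if n2[j] <= half:
            # interpolate between i (above half) and j (at/below half)
            if n2[i] == n2[j]:
                return float(z[j])
            frac = (n2[i] - half) / (n2[i] - n2[j])
            return float(z[i] + frac * (z[j] - z[i]))
        i = j
    return float(z[i])


def detect_metalimnion(
    n2_profile: np.ndarray,
    depth_grid: np.ndarray | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
) -> tuple[float | None, float | None, float | None, bool]:
    """Metalimnion (upper, center, lower, valid) from an N² profile.

    The center is the depth of the global N² maximum (ties broken toward
    the shallower depth); boundaries are the first crossings of half the
    maximum walking outward, with sub-grid linear interpolation.  The
    detection is valid only if the maximum exceeds ``n2_validity_min`` and
    the thickness stays below ``meta_thickness_max``; invalid detections
    still report boundaries (flagged) unless the column is fully unstable.
    """
    n2 = np.asarray(n2_profile, dtype=float)
    if depth_grid is None:
        depth_grid = np.arange(n2.size, dtype=float)
    z = np.asarray(depth_grid, dtype=float)
    finite = np.isfinite(n2)
    if not finite.any() or np.nanmax(n2) <= 0:
        return None, None, None, False
    i_max = int(np.nanargmax(n2))
    n2_max = float(n2[i_max])
    half = 0.5 * n2_max
    upper = _half_max_crossing(z, n2, i_max, half, -1)
    lower = _half_max_crossing(z, n2, i_max, half, +1)
    valid = (n2_max > constants.n2_validity_min) and (
        (lower - upper) < constants.meta_thickness_max
    )
    return upper, float(z[i_max]), lower, valid


def summarize_stratification(
    temperature: np.ndarray,
    conductivity25: np.ndarray,
    depth_grid: np.ndarray | None = None,
    constants: PhysicsConstants = PhysicsConstants(),
) -> StratificationSummary:
    """Full chain: T/cond profiles → StratificationSummary."""
    t = np.asarray(temperature, dtype=float)
    if depth_grid is None:
        depth_grid = np.arange(t.size, dtype=float)
    z = np.asarray(depth_grid, dtype=float)
    s = salinity_from_conductivity(conductivity25, constants)
    theta = potential_temperature(t, z, constants)
    rho = density(theta, s, constants)
    n2 = buoyancy_frequency(rho, z, constants)
    z_mix, full = mixed_layer_depth(rho, z, constants)
    upper, center, lower, valid = detect_metalimnion(n2, z, constants)
    n2_max = float(np.nanmax(n2)) if np.isfinite(n2).any() else float("nan")
    return StratificationSummary(
        n2_profile=n2,
        z_mix=z_mix,
        metalimnion_upper=upper,
        metalimnion_center=center,
        metalimnion_lower=lower,
        metalimnion_valid=valid,
        n2_max=n2_max,
        full_mixing=full,
    )
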