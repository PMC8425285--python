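"""Underwater light structure from PAR profiles.

Derives the vertical attenuation coefficient K_d of downwelling PAR, the
euphotic depth z_eu = ln(100)/K_d (1 % light level), and the three
species-intrinsic irradiance depths of the low-light-adapted cyanobacterium
(buoyancy gain z_comp at 0.8, neutral buoyancy z_buoy at 6.5, buoyancy loss
z_sat at 25 µmol photons m⁻² s⁻¹).

Dense metalimnetic cyanobacterial layers attenuate PAR far more strongly
than the water above them, so K_d is by default fitted only over the
near-surface depth range where the log-linear (Beer–Lambert) decay still
holds; a full-profile mode exists for autumn/winter profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import IrradianceThresholds, LightFitRule

__all__ = [
    "LightSummary",
    "NoFitError",
    "attenuation_coefficient",
    "euphotic_depth",
    "irradiance_depth",
    "intrinsic_depths",
    "summarize_light",
]


class NoFitError(ValueError):
    """Raised when no valid attenuation fit exists for a profile."""


@dataclass
class LightSummary:
    k_d: float            # m⁻¹
    fit_top: float        # m
    fit_bottom: float     # m
    fit_r2: float
    z_eu: float           # m
    z_comp: float | None  # m
    z_buoy: float | None  # m
    z_sat: float | None   # m


def _running_fit_range(z: np.ndarray, ln_e: np.ndarray, rule: LightFitRule) -> int:
    """Number of leading points kept by the running linearity rule.

    The fit grows downward from the surface; it stops just before the
    first point that either breaks the exponential decay (ln(E_d)
    residual from the current fit above ``rule.resid_max``) or drops the
    running R² below ``rule.r2_min``.
    """
    n = z.size
    k = rule.min_points
    while k < n:
        cur = stats.linregress(z[:k], ln_e[:k])
        predicted = cur.intercept + cur.slope * z[k]
        if abs(ln_e[k] - predicted) > rule.resid_max:
            break
        r = stats.linregress(z[: k + 1], ln_e[: k + 1])
        if r.rvalue**2 < rule.r2_min:
            break
        k += 1
    return k


def attenuation_coefficient(
    depths: np.ndarray,
    par: np.ndarray,
    rule: LightFitRule = LightFitRule(),
    sensor_floor: float = IrradianceThresholds().sensor_floor,
) -> tuple[float, float, float, float]:
    """(k_d, fit_top, fit_bottom, fit_r2) from a PAR profile.

    k_d is minus the OLS slope of ln(E_d) on depth over the fit range.
    Non-positive and below-floor readings are excluded before fitting.
    """
    z = np.asarray(depths, dtype=float)
    e = np.asarray(par, dtype=float)
    ok = np.isfinite(e) & (e > sensor_floor)
    if rule.drop_surface:
        ok &= z >= 1.0
    z, e = z[ok], e[ok]
    order = np.argsort(z)
    z, e = z[order], e[order]
    if z.size < rule.min_points:
        raise NoFitError("fewer than %d usable PAR readings" % rule.min_points)
    ln_e = np.log(e)
    if rule.mode == "full-profile":
        n_fit = z.size
    else:
        n_fit = _running_fit_range(z, ln_e, rule)
    res = stats.linregress(z[:n_fit], ln_e[:n_fit])
    k_d = -res.slope
    if not k_d > 0:
        raise NoFitError("attenuation fit yielded non-positive k_d")
    return float(k_d), float(z[0]), float(z[n_fit - 1]), float(res.rvalue**2)


def euphotic_depth(k_d: float) -> float:
    """Euphotic-zone thickness z_eu = ln(100)/k_d (1 % surface light)."""
    if not k_d > 0:
        raise ValueError("k_d must be positive")
    return math.log(100.0) / k_d


def irradiance_depth(
    depths: np.ndarray, par: np.ndarray, threshold: float
) -> tuple[float | None, bool]:
    """Depth (m) at which E_d crosses ``threshold``, or absent.

    Interpolation is linear in ln(E_d) between the bracketing grid points
    (exponential decay between samples).  Returns ``(None, False)`` when
    the surface irradiance is already below the threshold, and
    ``(deepest_depth, True)`` — an *unbounded* crossing — when the whole
    recorded profile stays at or above it.  With several crossings of a
    non-monotone profile, the shallowest is taken (thresholds delimit the
    top of each light zone).
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(depths, dtype=float)
    e = np.asarray(par, dtype=float)
    ok = np.isfinite(e) & (e > 0)
    z, e = z[ok], e[ok]
    order = np.argsort(z)
    z, e = z[order], e[order]
    if z.size == 0:
        return None, False
    if e[0] < threshold:
        return None, False
    below = np.flatnonzero(e < threshold)
    if below.size == 0:
        return float(z[-1]), True
    j = below[0]
    if j == 0:  # e[0] == threshold handled above; defensive
        return float(z[0]), False
    i = j - 1
    ln_hi, ln_lo, ln_t = np.log(e[i]), np.log(e[j]), math.log(threshold)
    frac = (ln_hi - ln_t) / (ln_hi - ln_lo)
    return float(z[i] + frac * (z[j] - z[i])), False


def intrinsic_depths(
    depths: np.ndarray,
    par: np.ndarray,
    thresholds: IrradianceThresholds = IrradianceThresholds(),
) -> tuple[float | None, float | None, float | None]:
    """(z_comp, z_buoy, z_sat) — the three intrinsic irradiance depths.

    Because E_d decreases with depth, z_sat ≤ z_buoy ≤ z_comp whenever all
    exist; an absent z_sat means no saturating layer.
    """
    z_comp, _ = irradiance_depth(depths, par, thresholds.e_comp)
    z_buoy, _ = irradiance_depth(depths, par, thresholds.e_buoy)
    z_sat, _ = irradiance_depth(depths, par, thresholds.e_sat)
    return z_comp, z_buoy, z_sat


def summarize_light(
    depths: np.ndarray,
    par: np.ndarray,
    rule: LightFitRule = LightFitRule(),
    thresholds: IrradianceThresholds = IrradianceThresholds(),
) -> LightSummary:
    """Full chain: PAR profile → LightSummary."""
    k_d, top, bottom, r2 = attenuation_coefficient(
        depths, par, rule, thresholds.sensor_floor
    )
    z_comp, z_buoy, z_sat = intrinsic_depths(depths, par, thresholds)
    return LightSummary(
        k_d=k_d,
        fit_top=top,
        fit_bottom=bottom,
        fit_r2=r2,
        z_eu=euphotic_depth(k_d),
        z_comp=z_comp,
        z_buoy=z_buoy,
        z_sat=z_sat,
    )
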