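"""Depth-integrated cyanobacterial population metrics.

Turns class-resolved chlorophyll *a* profiles (µg L⁻¹ on a 1-m grid) into
whole-lake population mass via the hypsographic volume table, partitions it
into 20-m strata, computes net growth rates between sampling dates,
overwinter survival / recovery ratios from annual extremes, and labels the
growth regime (mixed vs metalimnetic) of each date.

Units chain: µg L⁻¹ ≡ mg m⁻³; mass per 1-m layer = concentration × layer
volume (mg); metric tons = Σ mg / 10⁹.  Rounding happens only at
presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PopulationConfig
from .physics import StratificationSummary

__all__ = [
    "Hypsography",
    "PopulationState",
    "AnnualExtremes",
    "depth_integrated_mass",
    "net_growth_rate",
    "chl_max_depth",
    "regime_label",
    "annual_extremes",
    "congruence_series",
    "summarize_population",
]


@dataclass
class Hypsography:
    """Lake volume (m³) per 1-m depth layer, ``layer_top`` to ``layer_bottom``."""

    layer_top: np.ndarray
    layer_bottom: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        self.layer_top = np.asarray(self.layer_top, dtype=float)
        self.layer_bottom = np.asarray(self.layer_bottom, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if np.any(self.volume <= 0):
            raise ValueError("layer volumes must be strictly positive")
        if np.any(np.diff(self.volume) > 1e-9 * self.volume[:-1]):
            raise ValueError("layer volumes must be non-increasing with depth")

    @property
    def total_volume(self) -> float:
        return float(self.volume.sum())


@dataclass
class PopulationState:
    """Whole-lake population on one sampling date."""

    timestamp: pd.Timestamp
    total_mass: float                     # metric tons in-vivo Chl a
    layer_mass: dict[str, float]          # tons per 20-m stratum
    layer_fraction: dict[str, float]
    z_plankt: float | None                # depth of the Chl-a maximum (m)
    below_detection: bool
    n_missing: int = 0


@dataclass
class AnnualExtremes:
    """Vernal minimum and following maximum of one bloom year.

    Years are labelled by the time of vernal deep mixing; the maximum is
    the highest population value between two successive minima.
    """

    bloom_year: int
    vernal_min: float
    following_max: float
    survival_ratio: float | None   # min ÷ preceding year's following max
    recovery_ratio: float          # min ÷ following max
    min_below_detection: bool = False
    floored: bool = False


def _strata(hyps: Hypsography, step: float) -> list[tuple[float, float]]:
    zmax = float(hyps.layer_bottom.max())
    edges = np.arange(0.0, zmax + step, step)
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


def depth_integrated_mass(
    chla_profile: np.ndarray,
    hyps: Hypsography,
    strata_step: float = 20.0,
) -> tuple[float, dict[str, float], int]:
    """(total tons, tons per stratum, number of missing cells).

    ``chla_profile`` holds one concentration per hypsographic layer,
    indexed by layer top (grid value at the top of each 1-m layer).
    Missing (NaN) cells contribute zero mass and are counted — absence is
    not evidence of absence, but integration needs a number.
    """
    c = np.asarray(chla_profile, dtype=float)
    if c.size != hyps.volume.size:
        raise ValueError(
            f"profile has {c.size} cells but hypsography has {hyps.volume.size} layers"
        )
    missing = ~np.isfinite(c)
    cc = np.where(missing, 0.0, c)
    if np.any(cc < 0):
        raise ValueError("chlorophyll concentrations must be non-negative")
    mass_mg = cc * hyps.volume  # µg/L == mg/m³ → mg per layer
    per_stratum: dict[str, float] = {}
    for top, bottom in _strata(hyps, strata_step):
        sel = (hyps.layer_top >= top) & (hyps.layer_top < bottom)
        per_stratum[f"{top:g}-{bottom:g}m"] = float(mass_mg[sel].sum() / 1e9)
    total = float(mass_mg.sum() / 1e9)
    return total, per_stratum, int(missing.sum())


def net_growth_rate(b0: float, b1: float, t0, t1) -> float:
    """Net growth rate µ = (ln b1 − ln b0) / Δt (day⁻¹).

    ``b0``/``b1`` are whole-lake masses (tons) on two sampling dates.
    """
    if not (b0 > 0 and b1 > 0):
        raise ValueError("growth rate undefined for non-positive biomass")
    dt = (pd.Timestamp(t1) - pd.Timestamp(t0)) / pd.Timedelta(days=1)
    if dt <= 0:
        raise ValueError("t1 must be after t0")
    return (math.log(b1) - math.log(b0)) / dt


def chl_max_depth(
    chla_profile: np.ndarray,
    depth_grid: np.ndarray | None = None,
    detection_limit: float = PopulationConfig().detection_limit,
) -> tuple[float | None, bool]:
    """(depth of the Chl-a maximum, below-detection flag).

    Ties break toward the shallower depth; an all-zero or below-detection
    profile reports an absent depth with the flag set.
    """
    c = np.asarray(chla_profile, dtype=float)
    if depth_grid is None:
        depth_grid = np.arange(c.size, dtype=float)
    z = np.asarray(depth_grid, dtype=float)
    if not np.isfinite(c).any():
        return None, True
    i = int(np.nanargmax(c))  # first occurrence → shallower on ascending grid
    peak = c[i]
    if not peak > 0:
        return None, True
    return float(z[i]), bool(peak < detection_limit)


def regime_label(z_plankt: float | None, strat: StratificationSummary) -> str:
    """``"metalimnetic"`` iff a valid metalimnion exists and the population
    maximum sits at or below its upper boundary; otherwise ``"mixed"``."""
    if (
        strat.metalimnion_valid
        and z_plankt is not None
        and strat.metalimnion_upper is not None
        and z_plankt >= strat.metalimnion_upper
    ):
        return "metalimnetic"
    return "mixed"


def annual_extremes(
    mass_series: pd.Series,
    vernal_window: tuple[int, int] = PopulationConfig().vernal_window,
    detection_floor: float = PopulationConfig().detection_floor_tons,
) -> list[AnnualExtremes]:
    """Per-year vernal minima, following maxima, survival/recovery ratios.

    ``mass_series`` is total mass (tons) indexed by timestamp.  For each
    calendar year the vernal minimum is searched within the configured
    month window (default April–July, after deep mixing); the following
    maximum is the highest value between this minimum and the next year's
    minimum.  survival = min ÷ preceding year's following max (absent for
    the first year); recovery = min ÷ following max.  Minima below the
    detection floor are floored and flagged.
    """
    s = mass_series.dropna().sort_index()
    if s.empty:
        return []
    years = sorted(set(s.index.year))
    m0, m1 = vernal_window
    minima: dict[int, tuple[pd.Timestamp, float]] = {}
    for y in years:
        win = s[(s.index.year == y) & (s.index.month >= m0) & (s.index.month <= m1)]
        if win.empty:
            continue
        t_min = win.idxmin()
        minima[y] = (t_min, float(win.min()))
    yrs = sorted(minima)
    if len(yrs) < 2:
        return []
    out: list[AnnualExtremes] = []
    prev_max: float | None = None
    for k, y in enumerate(yrs):
        t_min, v_min = minima[y]
        t_end = minima[yrs[k + 1]][0] if k + 1 < len(yrs) else s.index[-1]
        seg = s[(s.index >= t_min) & (s.index <= t_end)]
        v_max = float(seg.max()) if not seg.empty else v_min
        below = v_min < detection_floor
        v_min_eff = max(v_min, detection_floor) if below else v_min
        out.append(
            AnnualExtremes(
                bloom_year=y,
                vernal_min=v_min,
                following_max=v_max,
                survival_ratio=None if prev_max is None else min(v_min_eff / prev_max, 1.0),
                recovery_ratio=min(v_min_eff / v_max, 1.0) if v_max > 0 else 1.0,
                min_below_detection=below,
                floored=below,
            )
        )
        prev_max = v_max
    return out


def congruence_series(
    z_plankt: pd.Series, comparison_depth: pd.Series
) -> pd.Series:
    """Per-date deviation (m) = comparison depth − z_plankt.

    Positive values mean the population maximum sits shallower than the
    comparison depth; absent inputs propagate as absent.
    """
    zp, cd = z_plankt.align(comparison_depth)
    return cd - zp


def summarize_population(
    timestamp,
    chla_profile: np.ndarray,
    hyps: Hypsography,
    config: PopulationConfig = PopulationConfig(),
) -> PopulationState:
    """Full chain: one chlorophyll profile → PopulationState."""
    total, per_stratum, n_missing = depth_integrated_mass(
        chla_profile, hyps, config.strata_step
    )
    fractions = {
        k: (v / total if total > 0 else 0.0) for k, v in per_stratum.items()
    }
    z_plankt, below = chl_max_depth(
        chla_profile, hyps.layer_top, config.detection_limit
    )
    return PopulationState(
        timestamp=pd.Timestamp(timestamp),
        total_mass=total,
        layer_mass=per_stratum,
        layer_fraction=fractions,
        z_plankt=z_plankt,
        below_detection=below,
        n_missing=n_missing,
    )
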