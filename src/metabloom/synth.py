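"""Synthetic multi-year lake monitoring scenarios with known ground truth.

Emulates the statistical and physical structure the analysis pipeline
assumes: weekly/biweekly profiles on a 1-m grid over 0–120 m across many
years, a seasonally deepening tanh thermocline, interannually variable
winter mixing depth (holomixis versus incomplete mixing), an exponentially
attenuated light field with biomass self-shading, and a buoyancy-regulated
cyanobacterial layer with a bimodal annual growth schedule (metalimnetic
growth in summer, epilimnetic growth in autumn, decay during winter
mixing, gas-vesicle collapse losses below the critical pressure depth).

The generator is *kinematic*: it imposes observed structure rather than
solving hydrodynamics, but every imposed quantity is recorded as ground
truth so that analysis-on-synthesis recovery can be measured.  Ground
truth for derived quantities (z_mix, metalimnion, survival ratios) is
obtained by applying their definitions to the noise-free fields.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import light, physics
from .constants import PhysicsConstants
from .population import Hypsography, annual_extremes

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "make_hypsography",
    "generate_scenario",
    "generate_closed_budget_meteo",
    "write_scenario",
]

# winter mixing depths (m) of the default 12-year scenario: five holomictic
# winters, three incomplete (47/82/61 m), one deep (115 m), holomixis, then
# two more incomplete winters (81/86 m)
DEFAULT_MIX_DEPTHS = (120, 120, 120, 120, 120, 47, 82, 61, 115, 120, 81, 86)


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic monitoring scenario.

    Defaults describe a deep prealpine monomictic lake sampled 26 times a
    year for 12 years; see ``docs/methods.md`` for the reasoning behind
    each value.
    """

    n_years: int = 12
    start_year: int = 2009
    profiles_per_year: int = 26
    winter_mix_depths: tuple[float, ...] = DEFAULT_MIX_DEPTHS
    # hypsography
    total_volume: float = 3.3e9     # m³
    basin_max_depth: float = 136.0  # m
    shape_exponent: float | None = None  # None → solve for 98 % above 120 m
    lake_area: float = 6.66e7       # m²
    # thermal structure
    t_surf_mean: float = 13.25      # °C, seasonal sinusoid mean
    t_surf_amp: float = 9.0         # °C, sinusoid amplitude
    t_surf_phase_doy: int = 220     # day of year of the surface maximum
    t_hypo: float = 4.5             # °C, deep hypolimnion
    t_winter_mixed: float = 4.9     # °C, convectively mixed layer
    thermocline_width: float = 1.5  # m (tanh half-width)
    z_th_start: float = 8.0         # m, thermocline depth at onset
    z_th_end: float = 30.0          # m, thermocline depth at year end
    strat_onset_doy: int = 95       # stratification begins (early April)
    mix_ramp_end_doy: int = 70      # winter mixing reaches its maximum
    # conductivity
    cond_surface: float = 200.0     # µS cm⁻¹
    cond_gradient: float = 0.08     # µS cm⁻¹ per m (stratified season)
    cond_mix_step: float = 20.0     # µS cm⁻¹ jump below the mixed layer
    cond_mix_ramp: float = 4.0      # m over which the jump develops
    # light
    par_surface_base: float = 200.0     # winter midday surface PAR
    par_surface_amp: float = 800.0      # seasonal amplitude
    par_weather_sigma: float = 0.15     # lognormal day-to-day weather factor
    kd_background: float = 0.25         # m⁻¹
    kd_per_chla: float = 0.015          # m⁻¹ per (µg L⁻¹)
    # biomass
    b_init: float = 10.0            # tons at the start of the record
    mu_meta: float = 0.012          # d⁻¹, metalimnetic summer growth
    mu_autumn: float = 0.008        # d⁻¹, epilimnetic autumn growth
    mu_winter: float = -0.015       # d⁻¹, decay during winter mixing
    mu_spring: float = -0.002       # d⁻¹, slight decline before mid-June
    summer_start_doy: int = 166     # metalimnetic growth window (mid-June)
    autumn_start_doy: int = 274     # epilimnetic growth window (October)
    layer_sigma: float = 3.0        # m, vertical SD of the stratified layer
    layer_tilt: float = 0.3         # shallow-bias of mixed distributions
    collapse_depth: float = 100.0   # m, gas-vesicle collapse depth
    e_buoy: float = 6.5             # µmol m⁻² s⁻¹, neutral-buoyancy target
    euk_summer: float = 2.5         # µg L⁻¹ epilimnetic eukaryote Chl a
    euk_winter: float = 0.5
    detection_limit: float = 0.05   # µg L⁻¹
    survival_fractions: tuple[float, ...] | None = None  # explicit override
    # "disrupted spring" preset: year indices whose vernal metalimnion is
    # repeatedly eroded by wind/cooling events, with the extra decay the
    # entrained population suffers under epilimnetic light stress
    disrupted_spring_years: tuple[int, ...] = ()
    disruption_mix_depth: float = 35.0  # m, depth of the erosion events
    mu_spring_disrupted: float = -0.025  # d⁻¹
    # measurement noise
    temp_noise_sd: float = 0.01     # °C additive
    cond_noise_sd: float = 1.0      # µS cm⁻¹ additive
    par_noise_sigma: float = 0.02   # lognormal multiplicative
    chla_noise_sigma: float = 0.02  # lognormal multiplicative
    sensor_floor: float = 0.05      # µmol m⁻² s⁻¹
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.winter_mix_depths) < self.n_years:
            # cycle the schedule over longer runs
            reps = -(-self.n_years // len(self.winter_mix_depths))
            self.winter_mix_depths = tuple(self.winter_mix_depths) * reps
        if any(not (0 < m <= 120) for m in self.winter_mix_depths):
            raise ValueError("winter mixing depths must lie in (0, 120]")
        if self.winter_mix_depths and min(self.winter_mix_depths) < self.z_th_start:
            raise ValueError("winter mixing shallower than the thermocline top")
        if self.survival_fractions is not None and any(
            not (0 < s <= 1) for s in self.survival_fractions
        ):
            raise ValueError("survival fractions must lie in (0, 1]")


@dataclass
class ScenarioResult:
    """Generated scenario: data streams plus ground truth."""

    profiles: pd.DataFrame       # long format, one row per (date, depth)
    meteo: pd.DataFrame          # daily meteorology
    hypsography: Hypsography
    truth_profiles: pd.DataFrame  # per-date ground truth
    truth_survival: pd.DataFrame  # per-year ground truth survival
    truth_biomass: pd.Series      # noise-free total biomass by date
    config: ScenarioConfig


def make_hypsography(
    total_volume: float = 3.3e9,
    max_depth: float = 136.0,
    shape_exponent: float | None = None,
    grid_max: float = 120.0,
) -> Hypsography:
    """Per-metre lake volumes from a power-law basin shape.

    The cross-section area decays as (1 − z/max_depth)**shape_exponent, so
    0 is a cylinder and 2 a cone.  When ``shape_exponent`` is None it is
    solved so the grid (0 to ``grid_max``) holds 98 % of ``total_volume``,
    mirroring a deep basin whose monitoring grid truncates a small bottom
    wedge.
    """
    if total_volume <= 0 or max_depth <= grid_max or grid_max <= 0:
        raise ValueError("non-physical hypsography arguments")
    if shape_exponent is None:
        shape_exponent = math.log(0.02) / math.log(1.0 - grid_max / max_depth) - 1.0
    if shape_exponent < 0:
        raise ValueError("shape exponent must be non-negative")
    p1 = shape_exponent + 1.0
    tops = np.arange(0.0, grid_max)
    rem_top = (1.0 - tops / max_depth) ** p1
    rem_bot = (1.0 - (tops + 1.0) / max_depth) ** p1
    volumes = total_volume * (rem_top - rem_bot)
    return Hypsography(tops, tops + 1.0, volumes)


def _doy(date: pd.Timestamp) -> int:
    return int(date.dayofyear)


def _surface_temp(cfg: ScenarioConfig, doy: int) -> float:
    return cfg.t_surf_mean + cfg.t_surf_amp * math.cos(
        2 * math.pi * (doy - cfg.t_surf_phase_doy) / 365.0
    )


def _phase(cfg: ScenarioConfig, doy: int) -> str:
    if doy < cfg.strat_onset_doy:
        return "mixing"
    if doy < cfg.summer_start_doy:
        return "spring"
    if doy < cfg.autumn_start_doy:
        return "summer"
    return "autumn"


def _winter_mix_depth(cfg: ScenarioConfig, year_idx: int, doy: int) -> float:
    """Mixed-layer depth schedule during the convective phase."""
    target = float(cfg.winter_mix_depths[year_idx])
    frac = min(doy / cfg.mix_ramp_end_doy, 1.0)
    return cfg.z_th_end + frac * (target - cfg.z_th_end)


def _thermocline_depth(cfg: ScenarioConfig, doy: int) -> float:
    frac = (doy - cfg.strat_onset_doy) / (365.0 - cfg.strat_onset_doy)
    return cfg.z_th_start + frac * (cfg.z_th_end - cfg.z_th_start)


def _clean_physics_profiles(
    cfg: ScenarioConfig,
    year_idx: int,
    doy: int,
    z: np.ndarray,
    force_mix_depth: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free temperature and conductivity profiles.

    ``force_mix_depth`` emulates a transient wind/cooling erosion event:
    the column is near-isothermal down to that depth regardless of season.
    """
    phase = _phase(cfg, doy)
    if phase == "mixing" or force_mix_depth is not None:
        m = (
            force_mix_depth
            if force_mix_depth is not None
            else _winter_mix_depth(cfg, year_idx, doy)
        )
        # finite transition so the density step is resolved on the grid
        trans = np.clip((z - m) / cfg.cond_mix_ramp, 0.0, 1.0)
        temp = cfg.t_winter_mixed + (cfg.t_hypo - cfg.t_winter_mixed) * trans
        cond = cfg.cond_surface + cfg.cond_mix_step * trans + 0.05 * np.clip(
            z - m, 0.0, None
        )
    else:
        ts = max(_surface_temp(cfg, doy), cfg.t_hypo + 0.3)
        z_th = _thermocline_depth(cfg, doy)
        temp = cfg.t_hypo + (ts - cfg.t_hypo) * 0.5 * (
            1.0 - np.tanh((z - z_th) / cfg.thermocline_width)
        )
        cond = cfg.cond_surface + cfg.cond_gradient * z
    return temp, cond


def _surface_par(cfg: ScenarioConfig, doy: int, weather: float) -> float:
    seasonal = cfg.par_surface_base + cfg.par_surface_amp * math.sin(
        math.pi * doy / 365.0
    ) ** 2
    return seasonal * weather


def _epilimnion_depth(cfg: ScenarioConfig, year_idx: int, doy: int) -> float:
    if _phase(cfg, doy) == "mixing":
        return _winter_mix_depth(cfg, year_idx, doy)
    return _thermocline_depth(cfg, doy)


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioResult:
    """Generate a full scenario: profiles, meteorology, hypsography, truth.

    Deterministic given ``config.rng_seed``.
    """
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    hyps = make_hypsography(
        cfg.total_volume, cfg.basin_max_depth, cfg.shape_exponent
    )
    z = np.arange(0.0, 121.0)  # grid points 0..120
    layer_vol = hyps.volume    # 120 layers, indexed by layer top
    constants = PhysicsConstants()

    # sampling dates: profiles_per_year equally spaced within each year
    dates: list[pd.Timestamp] = []
    year_of: list[int] = []
    for k in range(cfg.n_years):
        year = cfg.start_year + k
        offsets = np.round(np.linspace(7, 361, cfg.profiles_per_year)).astype(int)
        for off in offsets:
            dates.append(pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(off) - 1))
            year_of.append(k)

    prof_rows = []
    truth_rows = []
    biomass_truth = {}
    b = cfg.b_init  # tons, noise-free state
    b_peak_since_min = cfg.b_init
    prev_date: pd.Timestamp | None = None
    forced_done: set[int] = set()

    for date, yi in zip(dates, year_of):
        doy = _doy(date)
        phase = _phase(cfg, doy)
        dt = 0.0 if prev_date is None else (date - prev_date).days

        # --- biomass dynamics ---------------------------------------
        disrupted = (
            yi in cfg.disrupted_spring_years
            and phase == "spring"
            and (doy // 14) % 2 == 0  # repeated, not continuous, erosion
        )
        mu = {
            "mixing": cfg.mu_winter,
            "spring": cfg.mu_spring_disrupted if disrupted else cfg.mu_spring,
            "summer": cfg.mu_meta,
            "autumn": cfg.mu_autumn,
        }[phase]
        b *= math.exp(mu * dt)
        m_now = _winter_mix_depth(cfg, yi, doy) if phase == "mixing" else 0.0
        if (
            phase == "mixing"
            and cfg.survival_fractions is None
            and m_now > cfg.collapse_depth
            and dt > 0
        ):
            # gas-vesicle collapse: the fraction mixed below the critical
            # depth loses buoyancy and is removed from the viable stock
            frac_below = (m_now - cfg.collapse_depth) / m_now
            b *= 1.0 - frac_below
        if (
            cfg.survival_fractions is not None
            and phase != "mixing"
            and yi not in forced_done
            and yi < len(cfg.survival_fractions)
        ):
            b = cfg.survival_fractions[yi] * b_peak_since_min
            forced_done.add(yi)
        b = max(b, 1e-6)
        b_peak_since_min = b if phase == "spring" and doy < 130 else max(
            b_peak_since_min, b
        )
        biomass_truth[date] = b

        # --- physical profiles (noise-free) --------------------------
        force_mix = cfg.disruption_mix_depth if disrupted else None
        temp, cond = _clean_physics_profiles(cfg, yi, doy, z, force_mix)
        strat = physics.summarize_stratification(temp, cond, z, constants)

        # --- eukaryote chlorophyll ----------------------------------
        z_epi = force_mix if disrupted else _epilimnion_depth(cfg, yi, doy)
        euk_level = cfg.euk_winter + (cfg.euk_summer - cfg.euk_winter) * math.sin(
            math.pi * doy / 365.0
        ) ** 2
        c_euk = np.where(z <= z_epi, euk_level, 0.02)

        # --- cyanobacterial placement -------------------------------
        weather = math.exp(rng.normal(0.0, cfg.par_weather_sigma))
        e0 = _surface_par(cfg, doy, weather)
        kd_surf = cfg.kd_background + cfg.kd_per_chla * euk_level
        layer_mode = phase in ("spring", "summer") and strat.metalimnion_valid
        if layer_mode and e0 > cfg.e_buoy:
            z_c = math.log(e0 / cfg.e_buoy) / kd_surf
            z_c = min(z_c, 60.0)
            w = np.exp(-0.5 * ((hyps.layer_top - z_c) / cfg.layer_sigma) ** 2)
        else:
            layer_mode = False
            zm = max(z_epi, 1.0)
            w = np.where(
                hyps.layer_top < zm,
                layer_vol * (1.0 - cfg.layer_tilt * hyps.layer_top / zm),
                0.0,
            )
            z_c = float("nan")
        w = np.clip(w, 0.0, None)
        mass_mg = b * 1e9 * w / w.sum()
        c_plank = mass_mg / layer_vol  # µg L⁻¹ per layer (indexed by top)
        c_plank_grid = np.append(c_plank, c_plank[-1])
        c_euk_layers = c_euk[:-1]

        # --- light field --------------------------------------------
        kd_grid = cfg.kd_background + cfg.kd_per_chla * (c_plank_grid + c_euk)
        kd_mid = 0.5 * (kd_grid[:-1] + kd_grid[1:])
        optical_depth = np.concatenate([[0.0], np.cumsum(kd_mid)])
        par = e0 * np.exp(-optical_depth)
        # terminate the record one point below the sensor floor
        below = np.flatnonzero(par < cfg.sensor_floor)
        par_rec = par.copy()
        if below.size > 1:
            par_rec[below[1]:] = np.nan
        # true surface-fit attenuation: the fit a perfect sensor would give
        try:
            kd_true = light.attenuation_coefficient(
                z, par_rec, sensor_floor=cfg.sensor_floor
            )[0]
        except light.NoFitError:
            kd_true = float("nan")

        # --- oxygen (plausible filler channel) ----------------------
        o2 = 11.0 - 0.2 * np.sqrt(z) - 1.5 * np.sin(math.pi * doy / 365.0) ** 2 * (
            z / 120.0
        )

        # --- measurement noise --------------------------------------
        temp_n = temp + rng.normal(0.0, cfg.temp_noise_sd, z.size)
        cond_n = cond + rng.normal(0.0, cfg.cond_noise_sd, z.size)
        par_n = par_rec * np.exp(rng.normal(0.0, cfg.par_noise_sigma, z.size))
        cp_n = c_plank_grid * np.exp(rng.normal(0.0, cfg.chla_noise_sigma, z.size))
        ce_n = c_euk * np.exp(rng.normal(0.0, cfg.chla_noise_sigma, z.size))

        for i, depth in enumerate(z):
            prof_rows.append(
                (
                    date.isoformat(),
                    float(depth),
                    round(float(temp_n[i]), 4),
                    round(float(cond_n[i]), 3),
                    round(float(o2[i]), 3),
                    round(float(cp_n[i]), 5),
                    round(float(ce_n[i]), 5),
                    round(float(par_n[i]), 5) if np.isfinite(par_n[i]) else np.nan,
                )
            )

        truth_rows.append(
            {
                "date": date,
                "z_mix_true": strat.z_mix,
                "full_mixing_true": strat.full_mixing,
                "meta_upper_true": strat.metalimnion_upper,
                "meta_center_true": strat.metalimnion_center,
                "meta_lower_true": strat.metalimnion_lower,
                "meta_valid_true": strat.metalimnion_valid,
                "kd_true": kd_true,
                "e0_true": e0,
                "layer_center_true": z_c,
                "biomass_true": b,
                # a coherent layer lying above the metalimnion top counts
                # as mixed-zone (autumn entrainment geometry)
                "regime_true": "metalimnetic"
                if (
                    layer_mode
                    and strat.metalimnion_upper is not None
                    and z_c >= strat.metalimnion_upper
                )
                else "mixed",
            }
        )
        prev_date = date

    profiles = pd.DataFrame(
        prof_rows,
        columns=[
            "timestamp",
            "depth_m",
            "temp_c",
            "cond25_uScm",
            "o2_mgL",
            "chla_plank_ugL",
            "chla_euk_ugL",
            "par_umol_m2_s",
        ],
    )
    truth_profiles = pd.DataFrame(truth_rows)
    tb = pd.Series(biomass_truth).sort_index()
    extremes = annual_extremes(tb)
    truth_survival = pd.DataFrame(
        [
            {
                "bloom_year": e.bloom_year,
                "survival_true": e.survival_ratio,
                "vernal_min_true": e.vernal_min,
                "following_max_true": e.following_max,
            }
            for e in extremes
        ]
    )
    meteo = _generate_meteo(cfg, rng)
    return ScenarioResult(
        profiles=profiles,
        meteo=meteo,
        hypsography=hyps,
        truth_profiles=truth_profiles,
        truth_survival=truth_survival,
        truth_biomass=tb,
        config=cfg,
    )


def _generate_meteo(cfg: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Daily meteorology with seasonal cycles and autocorrelated noise."""
    start = pd.Timestamp(f"{cfg.start_year}-01-01")
    days = pd.date_range(start, periods=cfg.n_years * 365, freq="D")
    doy = days.dayofyear.to_numpy()
    n = days.size
    ar = np.zeros(n)
    for i in range(1, n):
        ar[i] = 0.8 * ar[i - 1] + rng.normal(0.0, 1.0)
    tair = 9.5 + 9.5 * np.cos(2 * np.pi * (doy - 205) / 365.0) + 1.5 * ar
    rh = np.clip(75 + rng.normal(0.0, 8.0, n), 20, 100)
    pressure = 965 + rng.normal(0.0, 5.0, n)
    wind = np.clip(rng.lognormal(0.7, 0.5, n), 0.0, 20.0)
    clear = 0.75 * 1367 / np.pi * (
        np.cos(np.radians(47.3))
        * np.cos(0.409 * np.sin(2 * np.pi * doy / 365 - 1.39))
    )
    cloud = np.clip(rng.beta(2.0, 3.0, n), 0, 1)
    sw = np.clip(clear * (1 - 0.75 * cloud), 5.0, None)
    tsurf = np.maximum(
        cfg.t_surf_mean
        + cfg.t_surf_amp * np.cos(2 * np.pi * (doy - cfg.t_surf_phase_doy) / 365.0),
        cfg.t_hypo,
    )
    return pd.DataFrame(
        {
            "date": days,
            "tair_c": np.round(tair, 2),
            "rh_pct": np.round(rh, 1),
            "pressure_hpa": np.round(pressure, 1),
            "wind_ms": np.round(wind, 2),
            "swdown_wm2": np.round(sw, 1),
            "tsurf_c": np.round(tsurf, 2),
        }
    )


def generate_closed_budget_meteo(
    n_days: int = 730,
    a_true: float = 1.02,
    lake_area: float = 6.66e7,
    h0: float = 4e17,
    noise_frac: float = 0.0,
    seed: int = 0,
    start: str = "2015-01-01",
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Meteorology plus a heat-content series that closes the budget.

    The heat-content series is constructed by integrating the package's
    own flux model evaluated with ``a_true``, so the budget closes exactly
    in the noise-free case; ``noise_frac`` adds Gaussian observation noise
    scaled by the standard deviation of the heat-content series.
    Returns (meteo, heat_content [J], lake_area).
    """
    from .heatflux import compute_fluxes  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    cfg = ScenarioConfig(n_years=max(1, -(-n_days // 365)), rng_seed=seed)
    meteo = _generate_meteo(cfg, rng).iloc[:n_days].copy()
    meteo["date"] = pd.date_range(start, periods=len(meteo), freq="D")
    fx = compute_fluxes(meteo, a=a_true)
    h = h0 + (fx["q_net"] * 86400.0 * lake_area).cumsum()
    h.index = fx["date"]
    if noise_frac > 0:
        h = h + rng.normal(0.0, noise_frac * h.std(), h.size)
    return meteo, h, lake_area


def write_scenario(result: ScenarioResult, outdir: str | Path) -> dict[str, Path]:
    """Write the scenario CSVs plus a ground-truth file and a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "meteo": out / "meteo.csv",
        "hypsography": out / "hypsography.csv",
        "truth_profiles": out / "truth_profiles.csv",
        "truth_survival": out / "truth_survival.csv",
        "manifest": out / "manifest.json",
    }
    result.profiles.to_csv(paths["profiles"], index=False)
    result.meteo.to_csv(paths["meteo"], index=False)
    pd.DataFrame(
        {
            "layer_top_m": result.hypsography.layer_top,
            "layer_bottom_m": result.hypsography.layer_bottom,
            "volume_m3": result.hypsography.volume,
        }
    ).to_csv(paths["hypsography"], index=False)
    result.truth_profiles.to_csv(paths["truth_profiles"], index=False)
    result.truth_survival.to_csv(paths["truth_survival"], index=False)
    cfg_json = json.dumps(asdict(result.config), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "n_profiles": int(result.profiles["timestamp"].nunique()),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
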