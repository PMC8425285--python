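"""Pipeline orchestration: gridding → physics → light → population →
fluxes → trends.

Per-profile failures are logged and skipped, never abort a run; the
returned bundle records which dates were dropped at which step.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import heatflux, light, physics, population, trends
from .constants import PipelineConfig
from .io import GriddedProfile, iter_gridded_profiles, write_output
from .light import NoFitError
from .population import Hypsography

__all__ = ["run_pipeline", "analyze_profiles"]

log = logging.getLogger("metabloom")


def _analyze_one(
    prof: GriddedProfile, hyps: Hypsography, config: PipelineConfig
) -> tuple[dict, dict | None, dict]:
    """(stratification row, light row or None, population row) for one date."""
    strat = physics.summarize_stratification(
        prof.temperature, prof.conductivity25, prof.depth_grid, config.physics
    )
    srow = {
        "timestamp": prof.timestamp,
        "z_mix": strat.z_mix,
        "full_mixing": strat.full_mixing,
        "meta_upper": strat.metalimnion_upper,
        "meta_center": strat.metalimnion_center,
        "meta_lower": strat.metalimnion_lower,
        "meta_valid": strat.metalimnion_valid,
        "n2_max": strat.n2_max,
    }
    lrow = None
    try:
        ls = light.summarize_light(
            prof.depth_grid, prof.par, config.light_fit, config.thresholds
        )
        lrow = {
            "timestamp": prof.timestamp,
            "k_d": ls.k_d,
            "fit_top": ls.fit_top,
            "fit_bottom": ls.fit_bottom,
            "fit_r2": ls.fit_r2,
            "z_eu": ls.z_eu,
            "z_comp": ls.z_comp,
            "z_buoy": ls.z_buoy,
            "z_sat": ls.z_sat,
        }
    except NoFitError as exc:
        log.warning("%s: light summary skipped (%s)", prof.timestamp.date(), exc)
    chla_layers = prof.chla_planktothrix[: hyps.volume.size]
    chla_layers = np.where(np.isfinite(chla_layers), np.clip(chla_layers, 0, None), np.nan)
    pstate = population.summarize_population(
        prof.timestamp, chla_layers, hyps, config.population
    )
    prow = {
        "timestamp": prof.timestamp,
        "total_mass_t": pstate.total_mass,
        "z_plankt": pstate.z_plankt,
        "below_detection": pstate.below_detection,
        "regime": population.regime_label(pstate.z_plankt, strat),
        "n_missing": pstate.n_missing,
    }
    for name, mass in pstate.layer_mass.items():
        prow[f"mass_{name}"] = mass
    return srow, lrow, prow


def analyze_profiles(
    profiles: pd.DataFrame, hyps: Hypsography, config: PipelineConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Per-date stratification, light and population tables.

    Returns a dict with keys ``stratification``, ``light``, ``population``,
    ``growth`` and ``skipped``.
    """
    config = config or PipelineConfig()
    srows, lrows, prows, skipped = [], [], [], []
    for prof in iter_gridded_profiles(profiles):
        try:
            srow, lrow, prow = _analyze_one(prof, hyps, config)
        except Exception as exc:  # per-profile fault isolation
            log.warning("%s: profile skipped (%s)", prof.timestamp, exc)
            skipped.append({"timestamp": prof.timestamp, "reason": str(exc)})
            continue
        srows.append(srow)
        if lrow is not None:
            lrows.append(lrow)
        prows.append(prow)
    strat_df = pd.DataFrame(srows)
    light_df = pd.DataFrame(lrows)
    pop_df = pd.DataFrame(prows)

    grows = []
    floor = config.population.detection_floor_tons
    for i in range(1, len(pop_df)):
        b0, b1 = pop_df["total_mass_t"].iloc[i - 1], pop_df["total_mass_t"].iloc[i]
        t0, t1 = pop_df["timestamp"].iloc[i - 1], pop_df["timestamp"].iloc[i]
        floored = b0 < floor or b1 < floor
        mu = population.net_growth_rate(max(b0, floor), max(b1, floor), t0, t1)
        grows.append(
            {
                "t0": t0,
                "t1": t1,
                "mu": mu,
                # an interval spanning a regime change takes the t0 regime
                "regime": pop_df["regime"].iloc[i - 1],
                "floored": floored,
            }
        )
    growth_df = pd.DataFrame(grows)
    return {
        "stratification": strat_df,
        "light": light_df,
        "population": pop_df,
        "growth": growth_df,
        "skipped": pd.DataFrame(skipped, columns=["timestamp", "reason"]),
    }


def _trend_tables(
    tables: dict[str, pd.DataFrame], config: PipelineConfig
) -> dict[str, pd.DataFrame]:
    pop = tables["population"].set_index("timestamp")
    strat = tables["stratification"].set_index("timestamp")
    light_df = tables["light"].set_index("timestamp") if not tables["light"].empty else None

    corr_rows = []
    candidates = {
        "z_buoy": light_df["z_buoy"] if light_df is not None else None,
        "z_eu": light_df["z_eu"] if light_df is not None else None,
        "meta_lower": strat["meta_lower"],
        "meta_center": strat["meta_center"],
    }
    for name, series in candidates.items():
        if series is None:
            continue
        pair = pd.concat([pop["z_plankt"], series], axis=1).dropna()
        if len(pair) < 3:
            continue
        try:
            res = trends.spearman(
                pair.iloc[:, 0], pair.iloc[:, 1], names=("z_plankt", name)
            )
        except ValueError:
            continue
        corr_rows.append(
            {
                "pair": f"z_plankt~{name}",
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    trend_rows = []
    mass = pop["total_mass_t"]
    if mass.index.year.nunique() >= 3:
        smk = trends.seasonal_mann_kendall(mass)
        trend_rows.append(
            {
                "series": "total_mass_t",
                "method": "smk",
                "statistic": smk.statistic,
                "p_value": smk.p_value,
                "n": smk.n,
            }
        )
    extremes = population.annual_extremes(
        mass,
        config.population.vernal_window,
        config.population.detection_floor_tons,
    )
    ext_df = pd.DataFrame(
        [
            {
                "bloom_year": e.bloom_year,
                "vernal_min_t": e.vernal_min,
                "following_max_t": e.following_max,
                "survival_ratio": e.survival_ratio,
                "recovery_ratio": e.recovery_ratio,
                "min_below_detection": e.min_below_detection,
            }
            for e in extremes
        ]
    )
    if len(ext_df) >= 3:
        for col, label in [("following_max_t", "annual_max"), ("vernal_min_t", "annual_min")]:
            res = trends.linear_trend(ext_df["bloom_year"], ext_df[col])
            trend_rows.append(
                {
                    "series": label,
                    "method": "ols",
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "n": res.n,
                    "r2": res.r2,
                }
            )
    return {
        "correlations": pd.DataFrame(corr_rows),
        "trends": pd.DataFrame(trend_rows),
        "extremes": ext_df,
    }


def run_pipeline(
    profiles: pd.DataFrame,
    meteo: pd.DataFrame | None,
    hyps: Hypsography,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Execute the full analysis chain; optionally write the CSV bundle.

    Deterministic given inputs and configuration.
    """
    config = config or PipelineConfig()
    tables = analyze_profiles(profiles, hyps, config)
    tables.update(_trend_tables(tables, config))
    if meteo is not None and not meteo.empty:
        fx = heatflux.compute_fluxes(meteo, config.flux)
        tables["fluxes"] = fx
        anomalies = heatflux.seasonal_climatology(fx.set_index("date")["q_net"])
        tables["seasonal_anomalies"] = anomalies
    if outdir is not None:
        outdir = Path(outdir)
        for name, df in tables.items():
            write_output(df, outdir / f"{name}.csv", config)
    return tables
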