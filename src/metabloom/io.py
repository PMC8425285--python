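"""Readers, writers, 1-m gridding and configuration.

All text interfaces are comma-separated, dot-decimal, UTF-8 with ISO-8601
timestamps.  Depth is metres below the surface, positive downward.  Output
CSVs carry a ``#``-prefixed header block with the software version and a
configuration hash so runs are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import (
    FluxParams,
    IrradianceThresholds,
    LightFitRule,
    PhysicsConstants,
    PipelineConfig,
    PopulationConfig,
)
from .population import Hypsography

__all__ = [
    "GriddedProfile",
    "PROFILE_COLUMNS",
    "grid_profile",
    "read_profiles",
    "iter_gridded_profiles",
    "read_hypsography",
    "write_hypsography",
    "read_meteo",
    "load_config",
    "config_hash",
    "write_output",
]

PROFILE_COLUMNS = [
    "timestamp",
    "depth_m",
    "temp_c",
    "cond25_uScm",
    "o2_mgL",
    "chla_plank_ugL",
    "chla_euk_ugL",
    "par_umol_m2_s",
]

_CHANNELS = PROFILE_COLUMNS[2:]

GRID = np.arange(0.0, 121.0)  # the standard 1-m grid, 0–120 m


@dataclass
class GriddedProfile:
    """One sampling date's measurements on the 1-m grid (0–120 m).

    Channels outside the sampled depth range are NaN (no extrapolation);
    PAR may terminate early at the sensor floor.
    """

    timestamp: pd.Timestamp
    depth_grid: np.ndarray
    temperature: np.ndarray
    conductivity25: np.ndarray
    oxygen: np.ndarray
    chla_planktothrix: np.ndarray
    chla_eukaryote: np.ndarray
    par: np.ndarray


def _interp_channel(depths: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Linear interpolation onto the grid; duplicates averaged, no
    extrapolation beyond the sampled range."""
    ok = np.isfinite(depths) & np.isfinite(values)
    d, v = depths[ok], values[ok]
    if d.size < 2:
        return np.full(GRID.size, np.nan)
    df = pd.DataFrame({"d": d, "v": v}).groupby("d", as_index=False).mean()
    d, v = df["d"].to_numpy(), df["v"].to_numpy()
    out = np.interp(GRID, d, v, left=np.nan, right=np.nan)
    return out


def grid_profile(raw: pd.DataFrame) -> GriddedProfile:
    """Interpolate one date's irregular downcast onto the 1-m grid.

    ``raw`` is long-format rows of a single timestamp with the standard
    profile columns; duplicate depths are averaged before interpolation.
    """
    ts = pd.Timestamp(raw["timestamp"].iloc[0])
    depths = raw["depth_m"].to_numpy(dtype=float)
    channels = {
        col: _interp_channel(depths, raw[col].to_numpy(dtype=float))
        if col in raw
        else np.full(GRID.size, np.nan)
        for col in _CHANNELS
    }
    return GriddedProfile(
        timestamp=ts,
        depth_grid=GRID.copy(),
        temperature=channels["temp_c"],
        conductivity25=channels["cond25_uScm"],
        oxygen=channels["o2_mgL"],
        chla_planktothrix=channels["chla_plank_ugL"],
        chla_eukaryote=channels["chla_euk_ugL"],
        par=channels["par_umol_m2_s"],
    )


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read the long-format profile CSV."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PROFILE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"profile file lacks required columns: {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def iter_gridded_profiles(df: pd.DataFrame):
    """Yield a GriddedProfile per unique timestamp, in time order."""
    df = df.sort_values(["timestamp", "depth_m"])
    for _, group in df.groupby("timestamp", sort=True):
        yield grid_profile(group.assign(timestamp=group["timestamp"].astype(str)))


def read_hypsography(path: str | Path) -> Hypsography:
    df = pd.read_csv(path, comment="#")
    return Hypsography(
        df["layer_top_m"].to_numpy(),
        df["layer_bottom_m"].to_numpy(),
        df["volume_m3"].to_numpy(),
    )


def write_hypsography(hyps: Hypsography, path: str | Path) -> None:
    pd.DataFrame(
        {
            "layer_top_m": hyps.layer_top,
            "layer_bottom_m": hyps.layer_bottom,
            "volume_m3": hyps.volume,
        }
    ).to_csv(path, index=False)


def read_meteo(
    path: str | Path, fallback: str | Path | None = None
) -> pd.DataFrame:
    """Read daily meteorology; gaps filled from a secondary station file.

    The primary file wins wherever it has data (priority merge).
    """
    df = pd.read_csv(path, comment="#", parse_dates=["date"])
    if fallback is not None:
        fb = pd.read_csv(fallback, comment="#", parse_dates=["date"])
        df = (
            df.set_index("date")
            .combine_first(fb.set_index("date"))
            .reset_index()
            .sort_values("date")
        )
    return df


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {k: v for k, v in data.items() if k in names}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML configuration; every omitted key keeps its default."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "physics": PhysicsConstants,
        "thresholds": IrradianceThresholds,
        "light_fit": LightFitRule,
        "flux": FluxParams,
        "population": PopulationConfig,
    }
    kwargs = {}
    for key, cls in sections.items():
        if key in data:
            kwargs[key] = _build(cls, data[key])
    if "smk_season" in data:
        kwargs["smk_season"] = data["smk_season"]
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_output(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write an output CSV with a traceability header block."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metabloom {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        df.to_csv(fh, index=False)
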