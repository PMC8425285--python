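"""Default physical constants and thresholds of the analysis chain.

Every value here is overridable through the YAML/key-value configuration
(see :mod:`metabloom.io`); the defaults are the published values for the
Lake Zurich monitoring programme where such a value exists, and documented
package choices otherwise (see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class PhysicsConstants:
    """Constants of the density / stratification calculations.

    Attributes
    ----------
    g : gravitational acceleration (m s⁻²).
    beta_haline : haline contraction coefficient (per ‰), appropriate for
        calcium-carbonate dominated lake water.
    cond_to_salinity : lake-specific factor converting conductivity
        normalised to 25 °C (µS cm⁻¹) into salinity (‰).
    mld_density_offset : density excess over the near-surface reference
        that defines the mixed-layer depth (kg m⁻³).
    surface_reference_span : depth span averaged for the near-surface
        reference density (m).
    n2_validity_min : minimum N² maximum (s⁻²) for a metalimnion to count
        as properly established.
    meta_thickness_max : maximum metalimnion thickness (m) for validity.
    """

    g: float = 9.81
    beta_haline: float = 0.807e-3
    cond_to_salinity: float = 0.7999e-3
    mld_density_offset: float = 0.01
    surface_reference_span: float = 2.0
    n2_validity_min: float = 2e-4
    meta_thickness_max: float = 20.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")


@dataclass(frozen=True)
class IrradianceThresholds:
    """Species-intrinsic irradiance thresholds (µmol photons m⁻² s⁻¹).

    e_comp : irradiance at which buoyancy gain (compensation-like depth
        for minimal growth) applies — defines z_comp.
    e_buoy : neutral-buoyancy irradiance — defines z_buoy.
    e_sat : saturating irradiance forcing buoyancy loss — defines z_sat.
    sensor_floor : underwater PAR sensor detection floor.
    """

    e_comp: float = 0.8
    e_buoy: float = 6.5
    e_sat: float = 25.0
    sensor_floor: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.e_comp < self.e_buoy < self.e_sat):
            raise ValueError("thresholds must satisfy 0 < e_comp < e_buoy < e_sat")
        if self.sensor_floor <= 0:
            raise ValueError("sensor_floor must be positive")


@dataclass(frozen=True)
class LightFitRule:
    """Fit-range rule for the PAR attenuation regression.

    The attenuation coefficient is the negative slope of ln(E_d) on depth.
    In ``surface-linear`` mode the fit extends downward from the surface
    while the running regression stays strictly linear: the overall R²
    must stay at or above ``r2_min`` and each added point must continue
    the exponential decay (its ln(E_d) residual from the current fit must
    stay below ``resid_max``, which separates a dense absorbing layer
    from ordinary sensor noise).  ``full-profile`` mode uses every
    ln-positive point (appropriate for autumn/winter profiles without a
    dense self-shading layer).
    """

    r2_min: float = 0.99
    resid_max: float = 0.3
    min_points: int = 4
    mode: str = "surface-linear"  # or "full-profile"
    drop_surface: bool = False  # drop the 0–1 m bin (wave contamination)


# detection limit of the class-resolved in-vivo Chl a channels (µg L⁻¹)
CHLA_DETECTION_LIMIT = 0.05

# specific heat capacity of water used for heat content (J kg⁻¹ K⁻¹)
CP_WATER = 4186.0


@dataclass(frozen=True)
class FluxParams:
    """Configurable coefficients of the surface heat-flux budget.

    All are documented package defaults (see docs/methods.md), not claims
    about any particular station's calibration, except ``a`` which defaults
    to the calibrated longwave absorption constant.
    """

    albedo: float = 0.07              # shortwave albedo of the water surface
    emissivity_water: float = 0.97    # longwave emissivity of the surface
    a: float = 1.02                   # longwave absorption calibration constant
    c_dn: float = 1.3e-3              # neutral drag coefficient (10 m)
    c_en: float = 1.35e-3             # neutral latent transfer coefficient
    c_hn: float = 1.35e-3             # neutral sensible transfer coefficient
    wind_height: float = 10.0         # anemometer height (m)
    latitude: float = 47.3            # lake latitude (degrees N)
    transmissivity: float = 0.75      # clear-sky atmospheric transmissivity
    atm_emissivity: float | None = None  # fixed ε_atm override (None = model)
    max_iter: int = 50
    rtol: float = 1e-4


@dataclass(frozen=True)
class PopulationConfig:
    """Windows and floors of the population metrics."""

    detection_limit: float = CHLA_DETECTION_LIMIT  # µg L⁻¹
    detection_floor_tons: float = 0.1  # whole-lake mass floor at detection
    vernal_window: tuple[int, int] = (4, 7)  # months, April 1 – July 31
    strata_step: float = 20.0  # thickness of reporting strata (m)


@dataclass
class PipelineConfig:
    """Bundle of all tunables consumed by the orchestrated pipeline."""

    physics: PhysicsConstants = field(default_factory=PhysicsConstants)
    thresholds: IrradianceThresholds = field(default_factory=IrradianceThresholds)
    light_fit: LightFitRule = field(default_factory=LightFitRule)
    flux: FluxParams = field(default_factory=FluxParams)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    smk_season: str = "month"  # seasonal blocking of the SMK trend test
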