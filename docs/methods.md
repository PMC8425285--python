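# Methods

This note documents the models implemented in `metabloom`, the defaults
of every tunable that matters, the numerical choices made where the
underlying procedure leaves freedom, what the synthetic-lake generator
does and does not emulate, and the package's known limitations.

## Density and stratification

Salinity is obtained from conductivity normalised to 25 °C by a single
multiplicative factor, 0.7999 × 10⁻³ ‰ (µS cm⁻¹)⁻¹, appropriate for lakes
whose dissolved load is dominated by calcium carbonate. Potential
temperature corrects the in-situ reading adiabatically to surface
pressure with the freshwater lapse rate Γ = g·α(T)·T_abs/c_p, where α(T)
is the thermal-expansion coefficient implied by the pure-water density
polynomial; over 0–140 m this correction is below 0.02 K for hypolimnetic
temperatures, so the choice of lapse formulation is immaterial at the
grid resolution. Potential density uses a Chen–Millero-type pure-water
polynomial (maximum near 3.98 °C) times the haline factor (1 + βS) with
β = 0.807 × 10⁻³.

Buoyancy frequency N² = −(g/ρ)(∂ρ/∂z) is computed with centred finite
differences at interior grid points and one-sided differences at the
ends, and assigned to the grid depths themselves (not midpoints) so every
per-depth quantity shares one grid. With depth positive downward, stable
stratification gives N² > 0.

The mixed-layer depth is the shallowest grid depth whose density
*strictly* exceeds the reference — the mean density over the top 2 m,
which suppresses transient diurnal near-surface stratification — by
0.01 kg m⁻³. Whether the exceedance is strict or inclusive is a genuine
free choice; strict was chosen and is asserted by test. A profile that
never meets the criterion is reported with z_mix at the deepest grid
depth plus a `full_mixing` flag, because such winter profiles are
interpreted as holomixis rather than as missing data.

Metalimnion detection takes the centre at the global N² maximum (ties
broken toward the shallower depth), then walks outward in each direction
to the *first* crossing of half the maximum, interpolating linearly
between grid points for sub-grid precision. The detection is valid only
if N²_max > 2 × 10⁻⁴ s⁻² and the thickness is below 20 m; invalid
detections still carry boundaries (flagged) so plots can show them, but a
fully unstable column reports no boundaries at all. Multimodal N²
profiles are resolved by the global maximum; boundaries therefore always
bracket the argmax, thickness is invariant to scaling the profile, and
validity is not — all property-tested.

## Light field

K_d is minus the OLS slope of ln(E_d) on depth. The default
`surface-linear` mode grows the fit downward from the surface while the
regression stays strictly log-linear, judged by two criteria together:

1. each candidate point's ln(E_d) residual from the current fit must stay
   below `resid_max` = 0.3 ln units (≈ 35 % irradiance), and
2. the running R² must stay at or above `r2_min` = 0.99.

The residual guard is what separates a dense absorbing layer (the first
point below it sits ~0.5 ln units off the extrapolated line) from
ordinary sensor noise (~0.02 ln units at 2 % multiplicative error); R²
alone cannot make this separation at both small and large point counts,
because it is scale-sensitive: with four or five points even pure noise
drags R² below thresholds that a layer outlier passes at fourteen. Both
thresholds are configurable; with the defaults the fit truncates exactly
at the top of an artificial opaque layer while K_d from 1,000 noisy
exponential profiles stays unbiased within 1 %. `full-profile` mode
(autumn/winter) fits every reading above the sensor floor. Readings at or
below the floor (0.05 µmol m⁻² s⁻¹) are excluded everywhere; a
`drop_surface` flag removes the 0–1 m bin when wave contamination is
suspected (off by default).

Threshold depths (z_comp at 0.8, z_buoy at 6.5, z_sat at
25 µmol m⁻² s⁻¹, and z_eu = ln(100)/K_d) are found by interpolating
ln(E_d) linearly between bracketing grid points — exponential decay
between samples, consistent with Beer–Lambert physics — rather than
interpolating E_d itself. A threshold above the surface irradiance yields
an absent depth ("no saturating layer"); a threshold never reached within
the recorded profile yields the deepest recorded depth with an
`unbounded` flag. Non-monotone noisy profiles take the shallowest
crossing, since each threshold delimits the *top* of its light zone.

## Population metrics

The units chain is fixed: µg L⁻¹ ≡ mg m⁻³; layer mass = concentration ×
layer volume; tons = Σ mg / 10⁹. Each 1-m hypsographic layer takes the
concentration at its top grid depth, and the 20-m reporting strata are
half-open [top, bottom) so every layer belongs to exactly one stratum.
Missing cells contribute zero mass and are counted in `n_missing` — a
documented divergence from the absent-propagates rule used elsewhere,
since integration requires a number but absence is not evidence of
absence.

Net growth µ = (ln B₁ − ln B₀)/Δt is undefined for non-positive mass; the
pipeline substitutes a detection-limit floor (default 0.1 t, the
order-of-magnitude whole-lake mass at the fluorometric detection limit of
0.05 µg L⁻¹ spread over the upper strata) and flags every floored
interval. An interval spanning a regime change is labelled by the regime
at its start date.

A date is `metalimnetic` when a valid metalimnion exists and the
chlorophyll maximum lies at or below its upper boundary, `mixed`
otherwise — including the autumn situation where a still-coherent layer
has risen above the metalimnion top into the turbulent zone.

Annual extremes: the vernal minimum is searched within April 1 – July 31
(configurable), the window in which post-mixing minima occur; the
following maximum is the highest value between this minimum and the next
year's; survival = minimum ÷ the *preceding season's* maximum (the
alternative, an all-time preceding maximum, was rejected as it conflates
years); recovery = minimum ÷ following maximum. Minima below the
detection floor are floored and flagged rather than dropped.

## Surface heat budget

All fluxes are positive into the lake. Latent and sensible fluxes use
bulk-aerodynamic formulas (Magnus saturation vapour pressure, specific
humidity from vapour pressure, air density from virtual temperature) with
neutral transfer coefficients C_DN = 1.3 × 10⁻³ and
C_EN = C_HN = 1.35 × 10⁻³ at 10 m, adjusted iteratively for stability:
Businger–Dyer ψ-functions on the unstable branch, the linear −5ζ form on
the stable branch, ζ clipped to ±10, convergence at relative coefficient
change < 10⁻⁴ or 50 iterations with a flagged neutral fallback. Wind
below 0.1 m s⁻¹ keeps neutral coefficients (the similarity scaling is
singular and the fluxes vanish anyway). The vectorised implementation is
checked against an independently written scalar transcription.

Shortwave: q_sw = (1 − albedo)·SW↓ with albedo 0.07. Longwave out:
ε_w σT_s⁴ with ε_w = 0.97. Longwave in: a·ε_atm·σT_a⁴, where ε_atm blends
a Brutsaert clear-sky emissivity 1.24(e_a/T_a)^{1/7} toward unity with
the cloud fraction, taken as one minus the ratio of observed to
theoretical clear-sky radiation (daily extraterrestrial radiation from
solar geometry times a fixed transmissivity of 0.75). These coefficient
choices are this package's documented defaults, all config-overridable;
the pipeline's validity rests on closure and recovery properties, not on
any particular coefficient set. The calibration constant *a* defaults to
1.02 and is fitted, when heat-content observations are available, by
one-dimensional least squares on the mismatch between cumulative
q_net × area and ΔH — unique because q_net is affine in *a*.

Heat content is Σ ρ(T,S)·c_p·T·V over layers with c_p = 4186 J kg⁻¹ K⁻¹,
relative to 0 °C. Seasonal climatology uses DJF/MAM/JJA/SON with December
assigned to the following year's winter; a season's anomaly is flagged
beyond one standard deviation of that season's yearly means.

## Trend statistics

Spearman correlations drop incomplete pairs, use average ranks for ties
(via `scipy.stats.spearmanr`) and the large-sample t approximation for p;
an independent hand-rolled ranking serves as the test oracle. The
seasonal Mann–Kendall test blocks the series by calendar month (the
standard choice for biweekly environmental series; configurable),
averages multiple values within a season-year, sums per-season Kendall S
statistics and tie-corrected variances, normalises ΣS by the summed pair
counts to get tau, and applies the continuity-corrected normal
approximation two-sided. Seasons with fewer than three yearly values are
skipped; observation gaps are simply absent seasons. Exact small-sample
p-tables and autocorrelation-corrected variants are out of scope. Under
an i.i.d. null (12 years × 26 samples) the empirical type-I error at
α = 0.05 is 4.5–5.8 % across seeds. Multiple correlations are reported
without multiplicity adjustment (a Holm option exists, off by default).

## Synthetic-lake generator

The generator is kinematic: it imposes the observed structure of a deep
prealpine monomictic lake rather than solving hydrodynamics, and records
everything it imposes as ground truth. Defaults (all `ScenarioConfig`
fields): 12 years × 26 profiles on the 0–120 m grid; a winter-mixing
schedule alternating holomictic (120 m) and incomplete (47–115 m) years;
surface temperature 13.25 ± 9 °C peaking in early August, hypolimnion
4.5 °C, winter mixed layer 4.9 °C, a tanh thermocline of 1.5 m half-width
deepening from 8 m at the April onset to 30 m at year end; conductivity
200 µS cm⁻¹ with a weak stabilising gradient; midday surface PAR
200–1000 µmol m⁻² s⁻¹ seasonally with a lognormal weather factor
(σ = 0.15); background K_d 0.25 m⁻¹ plus 0.015 m⁻¹ per µg L⁻¹ chlorophyll
(self-shading); growth ±0.008–0.015 d⁻¹ by seasonal window (metalimnetic
mid-June–September, epilimnetic October–December, decay during mixing),
chosen so survival times seasonal regrowth roughly balances and the
standing stock stays in the 1–50 t range with winter maxima near 20 t;
gas-vesicle collapse removes the biomass fraction mixed below 100 m at
each mixing-phase step, which is what makes holomictic winters strictly
more lethal than incomplete ones. The stratified-season layer is a
Gaussian (σ = 3 m) centred on the depth where the generator's own
epilimnetic light field reaches 6.5 µmol m⁻² s⁻¹ — the layer tracks
irradiance, *not* the N² maximum, so the correlation structure the
analysis probes is present in the truth by construction. Mixed-phase
biomass is spread over the mixed layer with a mild shallow bias
(buoyant filaments). Measurement noise: additive Gaussian on temperature
(0.01 °C) and conductivity (1 µS cm⁻¹), multiplicative lognormal (σ = 2 %)
on PAR and chlorophyll.

Ground truth for derived quantities (z_mix, metalimnion, survival ratios,
K_d) is obtained by applying their *definitions* to the noise-free
fields — e.g. true K_d is the surface fit a perfect sensor would produce,
since with the population itself shading the water column no closed-form
scalar "true K_d" exists. Recovery tests therefore measure exactly what
they should: robustness of the analysis to measurement noise and grid
discretisation. An optional per-year `survival_fractions` override
rescales biomass at the vernal date for controlled experiments, and a
"disrupted spring" preset (`disrupted_spring_years`) erodes the vernal
metalimnion on alternating dates with extra decay, reproducing the
breakdown-and-autumn-recovery pattern qualitatively.

A closed-budget companion (`generate_closed_budget_meteo`) integrates the
package's own flux model at a known a_true into a heat-content series, so
budget closure is exact by construction in the noise-free case and the
calibration can be tested for recovery under observation noise.

What the generator does **not** emulate — and hence what passing
recovery tests do not show about real data: nutrient dynamics and
long-term nutrient limitation (so multi-year biomass trends in the
default scenario follow the mixing schedule, not a decline), internal
waves and short-term thermocline displacement, sub-daily variability,
instrument drift and spectral effects of the fluorometric class
separation, and any feedback of the biology on the physics.

## Problem sizes

The shipped defaults keep the full validation cheap: the 12-year
scenario (312 profiles × 121 depths) analyses in a few seconds; the
brute-force oracle comparisons use 500 random profiles; the trend-test
calibration uses 2,000 null series; the closed-budget lake uses two years
of daily meteorology. These sizes give comfortable statistical resolution
for every asserted tolerance while the whole suite runs in about a
minute.

## Known limitations

- The density polynomial is a pure-water + haline-contraction
  formulation; no TEOS-10, no pressure term in density itself (only in
  the potential-temperature correction). Fine for prealpine lakes, wrong
  for brackish systems.
- z_mix is grid-snapped to 1 m; the metalimnion boundaries are sub-grid
  but their validity thresholds are lake-specific tuning, not universal
  constants.
- The attenuation fit-range rule approximates what is in practice a
  manual judgement; its two thresholds are exposed in config rather than
  claimed to be anyone's exact practice.
- The bulk-flux coefficient set is one documented choice among several in
  common use; fitted *a* values partially absorb that choice, which is
  precisely why *a* is calibrated by closure rather than transcribed.
- The SMK p-value is asymptotic; for very short records (< 5 years) it is
  anti-conservative and the test refuses series with under three yearly
  values per season.
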