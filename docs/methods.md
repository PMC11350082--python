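# Methods

## Scope and model

`stemflux` partitions the net CO₂ flux measured at a stem surface into three
process terms under the mass balance `-R + P + T = FCO2` (flux negative when
directed out of the stem). The terms are parameterised per tree × calendar
month:

- **Respiration** `R'(temp) = R0 exp(b temp)` — the classical exponential
  temperature response; `R0` (µmol m⁻² s⁻¹) is the rate at 0 °C, `b` (°C⁻¹)
  the sensitivity (`Q10 = e^{10b}`; `b = 0.07` ≈ Q10 2).
- **Bark photosynthesis** `P'(PPFD) = Pmax f PPFD / (f PPFD + Pmax)` — a
  rectangular hyperbola with saturation `Pmax` (µmol m⁻² s⁻¹) and quantum
  yield `f` (µmol CO₂ µmol⁻¹ quanta).
- **Sap transport** `T'(J) = e J` — linear, zero intercept; `e` is the slope
  against sap flux density and proxies the axial CO₂ concentration gradient
  across the chamber section. `e` (and `T`) may be negative.

Identification strategy and its assumptions: the dark chamber suppresses light
(`P = 0` there); sap flow, xylem temperature and tissue properties are assumed
identical at the two chamber positions; transport is in steady state over the
averaging interval. Then

1. `R0, b` are fitted to `-dFCO2` on the *low-sap-flow subset*
   (`J < 5 g m⁻² h⁻¹`), where `T ≈ 0` and the dark flux is pure respiration.
   The subset is dominated by night hours; the diurnal + synoptic temperature
   variation across those hours identifies both parameters.
2. `R'` is predicted over the full record from xylem temperature.
3. `T = dFCO2 + R'` (residual), `P = tFCO2 - dFCO2` (daytime chamber
   difference), and `P'`, `T'` are fitted to those series.

The low-sap-flow conditioning fits `-dFCO2` directly, treating any residual
transport below the threshold as negligible; the synthetic generator makes
this exact (see below), while on real data it is an approximation of order
`e · 5` µmol m⁻² s⁻¹.

## Estimation and inference

All nonlinear fits go through one wrapper (`nls_fit`) around
`scipy.optimize.least_squares` (trust-region reflective; tolerances 1e-14 so
zero-residual problems solve to machine precision). Covariance is
`RSE² (JᵀJ)⁻¹` at the solution; a Jacobian condition number above 1e12 raises
a rank-deficiency error (e.g. constant temperature makes `R0` and `b`
inseparable); hitting the iteration cap flags the fit rather than raising.
Initial values: log-linear regression of `ln(-dFCO2)` on temperature for the
respiration fit (rows with nonpositive response excluded from the init only,
with a Q10≈2 fallback if none remain); 95th percentile of `P` and an
origin-constrained OLS slope over the lowest PPFD quartile for the light
response. The transport slope has the closed form `e = Σ TJ / Σ J²`
(`RSE²` on `n-1` dof) and is cross-checked against the iterative NLS path in
the tests.

Inference is `t = estimate/SE` against `H0: θ = 0`, two-sided p from the t
distribution on `n - p` dof, and 95 % CIs `estimate ± t₀.₉₇₅ SE`. One
deliberate extension: because `T` is a *derived* response (`dFCO2 + R̂'`), the
respiration-parameter error is shared by every row of the transport fit and
invisible to its residual variance. `Var(ê)` therefore adds the delta-method
term `g Cov(R̂0, b̂) gᵀ`, `g = Σᵢ Jᵢ ∇R'(tempᵢ)/ΣJ²`. Without it the nominal
95 % interval for `e` covered truth in only ~40 % of noisy replicates; with it
coverage is nominal (~94 %). The plain closed form remains available by
calling `fit_transport` without the respiration fit.

Weighting is uniform (no weighted fits are reported); the free-intercept
transport variant is deliberately not the default, matching `T' = eJ` exactly.

## Measurement-level computations

**Closure fluxes.** The chamber is a dynamic flow-through system (volume
~1.17–1.40 L, closed-lid throughflow 1.0–1.2 L min⁻¹, CO₂ sampled every 5 s
over 100-s closures each half hour). Its mass balance during a closure is
`V dC/dt = S·A + q(C_in − C)` with source `S = −FCO2` (an efflux raises
chamber concentration), giving
`C(t) = C_eq + (C0 − C_eq) e^{−qt/V}`, `C_eq = C_in + S·A/q_mol`, where
`q_mol` is the molar throughflow from the ideal-gas law at chamber temperature
and pressure (both carried on each trace so the inversion is exact). With a
turnover time `V/q ≈ 70 s`, dilution bends the trace well within the 100-s
closure, so the default estimator fits the full analytic solution — linear in
`(C0, C_eq)` for known `q/V`, hence a deterministic least-squares solve — and
converts the equilibrium offset to a flux. An initial-slope estimator (first
five samples) is retained as a cross-check; it is biased low by design and
documented as such. Fit RMSE above a configurable ceiling flags the record
(`NOISY_FIT`) rather than dropping it. Discarding the first sample
(dead-volume flushing) is a config option, off by default.

**Sap flux.** Thermal-dissipation probes: flow index `K = (dT0 − dT)/dT`
clipped at 0, `J = 119 K^1.231` with the original calibration coefficients.
The zero-flow baseline `dT0` is per night the *maximum* dT (standard
practice — flow minimises probe cooling at night) averaged over a centred
window of 7 consecutive nights, truncated at the record edges and
piecewise-constant per night; it is by construction independent of daytime
data. Unit convention: the campaign convention this package follows prints
sap flux density in "g m⁻² h⁻¹" with seasonal maxima near 100 and a
near-zero-flow threshold at 5; a literal SI conversion of the native
calibration value (10⁻⁶ m³ m⁻² s⁻¹) would be 3600× larger. The default output
unit (`g_m2_h_field`) maps the native coefficient value one-to-one onto that
printed scale; `si_g_m2_h` applies the strict factor. Only flow *dynamics*
matter to the partitioning (the threshold is equivalently 5 % of the seasonal
maximum), so the convention choice does not affect any fitted flux component —
it rescales `e` inversely to `J`.

**Stem temperature in the chamber** is estimated by a one-parameter coupling
model `temp = stem_outside + k (chamber_air − ambient_air)`, `k ∈ [0, 1]`
(default 0.5). This is a stand-in for a full differential heat-balance
solution; with synthetic data the driver temperature is used directly.

## QC

Flag-then-drop: filters append named flags (`TECH_FAIL`, `OUTLIER_3SD`,
`RH_HIGH`, `RH_MISSING`) and never delete or alter values; the aligned
dark/transparent table excludes rows carrying any drop-flag and reports the
tally, so removal accounting is exact and the flag sets commute (order of
filters is irrelevant). The 3-SD filter uses a single-pass mean/SD per
tree × chamber over the whole season's unflagged records (monthly grouping is
a config option); groups under 10 records are skipped with a warning. The RH
filter removes records whose closure-window mean relative humidity exceeds
85 % (condensation risk). The low-sap-flow subset uses the fixed
5 g m⁻² h⁻¹ threshold by default; a fraction-of-maximum mode (5 % of seasonal
max, scale-invariant) is equivalent on data following the campaign convention.

## Synthetic generator

The generator emulates a boreal June–September season at 61° N on a 30-min
grid: photoperiod shrinking from ~20 h to ~13 h (half-sine PPFD, peak
1500 µmol m⁻² s⁻¹ around solstice), xylem temperature with a 4 °C diurnal
cycle peaking at 15:00 riding on seasonal (±5 °C, peak late July) and
synoptic (±2.5 °C, ~6.5-d period) components plus small AR(1) jitter;
relative humidity peaking before dawn (≤ ~84 % unless artifacts are planted);
sap flux tracking light with mild saturation, seasonal maximum ~110 in the
campaign's g m⁻² h⁻¹ convention. Values below the 5-unit detection threshold
are reported as 0 — mirroring what nightly-max baselining plus K-clipping do
to real thermal-dissipation records — which makes the low-sap-flow subset
exactly transport-free, so the noiseless pipeline is an exact-recovery fixture.

Default monthly truth follows the observed seasonal shapes: `R0` declining
0.80→0.30 within the 0.3–0.8 range, `b` rising 0.075→0.12, `Pmax` 1.5→0.5,
`f` 0.018→0.006, `e` 0.020→0.005; parameters step at calendar-month
boundaries, matching the monthly fitting windows. Chamber noise is additive
i.i.d. Gaussian, sd 0.1 µmol m⁻² s⁻¹ per chamber (the simplest model that
supports SE/coverage checks; a heteroscedastic alternative can be layered on
the clean components, which are always stored noise-free). QC artifacts —
spikes at ±10 group SD, forced-high-RH windows, gaps — are planted from a
separate seed and logged individually so filter tests can check exact
bookkeeping.

What the generator does *not* emulate: within-crown shading (light reaching
the bark equals above-canopy PPFD), storage dynamics and non-steady transport,
heteroscedastic or autocorrelated instrument noise, and driver measurement
error. Passing tests therefore demonstrate correctness of the estimators and
workflow under the model's own assumptions, not that the model is adequate
for any particular field dataset.

## Problem sizes and numerical choices

The standard season is 5 856 half-hour rows (≈1 440/month; 270–690 low-flow
rows per month), on which the full pipeline runs in well under a second. The
replicate coverage study uses 100 seeds on shared drivers. Minimum fit size
is 30 rows per month. Daytime is `PPFD > 10 µmol m⁻² s⁻¹` (configurable);
sensitivity is negligible here because the generator's PPFD crosses the
threshold within one grid step of sunrise/sunset.

Contribution fractions are computed from monthly means of the components
(mean-of-components over mean flux), not means of per-row ratios: per-row
ratios explode where `FCO2` crosses zero. The per-row variant is available as
a diagnostic. In the ratio normalisation the budget identity
`-R̄'/F̄ + P̄/F̄ + T̄/F̄ = 1` holds exactly because `P` is taken as the chamber
difference on *all* rows (at night it is pure noise around zero); the
daytime-only `P` series is what enters the light-response fit. The share
normalisation divides `|R'|, |P|, |T|` by their sum (= 100 %).

`R²` in the holdout validation is the squared Pearson correlation of measured
vs reconstructed flux (negative values cannot arise; a floor-and-flag guard
exists for degenerate inputs). The 8:2 split is stratified by month by
default so every month appears in both sets.

## Known limitations

- The transport term absorbs every process not captured by `R'` and `P`
  (PEP-carboxylase fixation, storage changes, axial diffusion); on real data
  `e` is a lumped slope, not a pure advection coefficient.
- The respiration fit's low-flow conditioning leaves a bias of up to `e·J`
  at the threshold on real data (zero here by the detection-limit convention).
- The closure-flux estimator is validated against its own forward model; an
  instrument-specific estimator may differ in its treatment of dead volume
  and analyzer lag.
- Chamber-temperature coupling (`k`) is not identifiable from the data this
  package handles; it must come from an external calibration.
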