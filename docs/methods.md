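# Methods

This note documents the models leafopt implements, the parameter defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the published
formulations leave freedom.

## Models and assumptions

### Least-cost χ

χ = Γ\*/cₐ + ξ(1 − Γ\*/cₐ)/(ξ + √D₀) with ξ = √[β(K + Γ\*)/(1.6η)].
Assumes leaves adjust stomatal behaviour so that the marginal unit costs of
maintaining transpiration and carboxylation capacity are equal; β = 146 is
a global estimate of that cost ratio at 25 °C and is treated as universal
across species — the dominant term of the χ uncertainty budget for
exactly that reason.

**Units.** D₀ enters the square root in Pa. The API takes D₀ in kPa (the
unit the bioclimate tables use) and converts internally; with kPa inside
the root, ξ/(ξ+√D₀) would saturate near 1 and χ would lose essentially all
VPD sensitivity, which is diagnostic of the wrong convention.

### Coordination V꜀ₘₐₓ and the 25 °C standard

V꜀ₘₐₓ = φ₀R₀ (cᵢ+K)/(cᵢ+2Γ\*) √(1 − (c/m)^⅔), m = (cᵢ−Γ\*)/(cᵢ+2Γ\*).
Assumes photosynthetic capacity acclimates so light-limited and
Rubisco-limited rates coincide at average daytime conditions; φ₀ = 0.085
µmol C µmol⁻¹ photon, c = 0.41. The model fails physically (and raises)
when m ≤ c — extremely low cᵢ — rather than returning a complex number.

Standardisation uses the peaked Arrhenius factor f_v with
Hₐ = 71 513 J mol⁻¹, H_d = 200 000 J mol⁻¹ and the entropy term
ΔS = 668.39 − 1.07·T_g. The published notation mixes conventions; we read
**temperatures in Kelvin inside the exponentials and T_g in °C inside the
linear ΔS relation**, which makes f_v(25 °C) = 1 identically — the
anchoring property the standardisation requires. This reading is a
documented switch, not a hidden assumption.

### Leaf mass per area

Two forms exist deliberately:

* `lma_theoretical` — the uncalibrated optimality expression
  Mₐ = φ₀I_abs·LL·k·√[(cᵢ−Γ\*)(cᵢ+K)/(2uCC·f_v·(cᵢ+2Γ\*)²)], used for
  derivative and elasticity work only. The construction-cost constant CC
  has no published value (it cancels in the calibrated form); we default
  CC = 1.5 gC gC⁻¹, a mid-range literature value for leaf construction
  cost. Its value shifts the level of Mₐ, never the temperature
  elasticity, which is the quantity this form exists to produce
  (≈3 % decline in ln Mₐ per °C at 25 °C, sea level, cₐ = 40 Pa,
  D₀ = 1 kPa — conditions we fix and document because "standard
  conditions" are otherwise underdetermined).
* `lma_deciduous` — the calibrated regression form
  ln Mₐ = 1.22 ln R_LAI + 0.78 ln f − 0.06 T_g − 0.60 ln αₚ + 1.70, used
  for all site prediction. Its light elasticity (1.22) differs from the
  theoretical value (exactly 1); both are asserted in tests as a
  documented difference, not reconciled.

Evergreen Mₐ is out of scope: the model needs leaf longevity, which a
single site visit cannot constrain for evergreens.

### Leaf nitrogen

The direct model N_area = 0.02Mₐ + 0.003V꜀ₘₐₓ₂₅ (no intercept) is the
default; the two-step decomposition N_area = alloc·0.003135·V꜀ₘₐₓ₂₅ +
10⁻²·⁶⁷Mₐ⁰·⁹⁹ is kept with alloc = 7.2 (locally refit) or 9.5 (published).
The two routes are *not* algebraically equivalent — the direct Mₐ
coefficient (0.02) absorbs metabolic nitrogen that covaries with Mₐ,
whereas the structural coefficient is 10⁻²·⁶⁷ ≈ 0.002 — and the test suite
checks their code-path agreement only under explicit coefficient
substitution.

## Bioclimate derivations

* **Pressure**: standard-atmosphere barometric formula
  (p₀ = 101.325 kPa, lapse 0.0065 K m⁻¹, T₀ = 288.15 K). No formula is
  prescribed by the modelling literature this follows; this is the
  conventional choice.
* **Ambient CO₂**: fixed mole fraction (410 ppm, ~2018–2019) times total
  pressure, so cₐ declines with elevation alongside p.
* **Rubisco kinetics**: Arrhenius scaling from 25 °C references
  K꜀ = 39.97 Pa, K_o = 27.48 kPa, Γ\*₂₅ = 4.332 Pa with activation
  energies 79 430, 36 380 and 37 830 J mol⁻¹ (Bernacchi-style). Γ\* scales
  linearly with pressure; K꜀ and K_o do not (enzyme properties). All are
  config-overridable.
* **Water viscosity**: Vogel equation η = 0.024263·10^(247.8/(T_K−140))
  mPa s; only the ratio to 25 °C enters χ.
* **Daytime temperature**: sine-curve diurnal cycle; errors explicitly on
  polar day/night.
* **Canopy light R_LAI**: the "LAI-weighted" radiation has no published
  formula; we use Beer–Lambert canopy averaging
  R_LAI = R_daily·(1−e^(−kL))/(kL) with k = 0.5, and a 12-hour daylight
  convention for converting mean daytime PAR (µmol m⁻² s⁻¹) to daily
  totals (mol m⁻² day⁻¹). Both are stand-ins flagged as open choices and
  are configurable; they scale Mₐ levels but not its elasticities.
* **Growing season**: days with mean temperature above 0 °C
  (configurable); T_g defaults to the mean over those days. A monthly
  climatology can be supplied instead of derived bioclimate; it is
  interpolated to daily values (periodic, mid-month anchors), with PAR
  from sunshine fraction via Ångström–Prescott coefficients (0.25, 0.50)
  on a configurable clear-sky value.

## Temperature bases

χ and V꜀ₘₐₓ₂₅ acclimate within weeks and default to the July daytime mean
(T_dJ); Mₐ is built once per season and defaults to the growing-season
mean (T_g). Both are selectable per run.

## Attribution

Baseline = arithmetic mean of every driver across sites, with pressure and
cₐ *recomputed* from mean elevation (the barometric formula is convex, so
averaging pressures would break driver consistency). One driver moves at a
time; for V꜀ₘₐₓ₂₅ the predicted χ itself is one of the drivers. Because
the χ and V꜀ₘₐₓ models are non-additive, one-at-a-time deltas do not sum
to the total; the interaction residual is computed and reported as its own
row, never folded into a driver. For ln Mₐ the model is additive in the
transformed drivers and the decomposition is exact (asserted to 1e-10).
Perturbing "pressure/elevation" carries the pressure-dependent cₐ by
default (switchable), since cₐ is not an independent driver.

## Uncertainty

First-order propagation u²(y) = Σᵢ(∂m/∂nᵢ)²u²(nᵢ) with central differences
(relative step 1e-4), parameters assumed independent. A seeded Monte-Carlo
companion verifies the budget: exact agreement for linear models, ≤15 %
divergence required for the trait models at reference conditions, and a
deliberate disagreement on a curved toy (y = x² at x = 0) documenting the
first-order method's blind spot. Default standard uncertainties
(u(β) = 30, u(c) = 0.08, u(φ₀) = 0.008) are package choices standing in
for supplementary values not reproduced here; faithful replication of any
particular study requires supplying its own u(nᵢ) via config.

## Synthetic data: what a green test establishes

The generator emulates: an 18-site transect spanning 1143–4361 m at 29.6°
N; monotone temperature decline (T_dJ lapse 5.5 K km⁻¹ from 22 °C; T_g
lapse 3.3 K km⁻¹ from 16 °C — flatter because season truncation removes
cold days from the mean); a hump-shaped moisture index peaking near
2800 m (0.55 base + 0.30 Gaussian amplitude, width 1100 m); VPD from
saturation pressure at T_dJ times a humidity deficit tied to the moisture
index; radiation increasing and LAI and season fraction decreasing with
elevation; 15 species per site (5 trees, 5 shrubs, 5 forbs), 20 % of woody
species evergreen, 10 % nitrogen fixers (+0.3 g m⁻² N_area). Species
traits are lognormal around the site-level model predictions (ln-sd 0.2
for Mₐ, 0.15 for V꜀ₘₐₓ₂₅, 0.05 for χ, 0.10 for N_area); leaf δ¹³C is the
exact inversion of the discrimination model at the species' χ.

It does **not** emulate: east–west rain-shadow structure, within-canopy
light gradients, trait–trait residual correlation (off by default),
measurement error distinct from species-level variation, or real
phylogenetic structure. A green evaluation test therefore establishes that
the pipeline recovers the structure it generated — self-consistency and
estimator correctness — not field skill. Calibration-recovery experiments
use independent uniform designs rather than the transect, because transect
drivers are strongly collinear (as they are in reality; that is why the
published Mₐ coefficients were fitted on a continental database, not the
gradient itself).

## Numerical choices

* Central differences everywhere a derivative is needed (propagation step
  1e-4 relative; elasticity checks 1e-6; the temperature-sensitivity
  target 0.01 °C).
* `expm1` keeps the LAI → 0 canopy-averaging limit exact.
* Out-of-range isotope-derived χ (outside (0, 1.2)) is flagged, never
  clipped or dropped silently; filtering is an explicit pipeline step.
* Out-of-range kinetics temperatures warn (extrapolation) rather than
  fail; domain violations that make the physics meaningless (cₐ ≤ Γ\*,
  m ≤ c, log of non-positive drivers) raise typed errors naming the
  failing quantity.
* OLS fits are ordinary least squares (statsmodels), listwise deletion of
  incomplete records with a logged count, rank checks that name the
  offending column.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; pipelines echo a config hash into their
  manifest so outputs are attributable.

## Known limitations

* The Mₐ level (not elasticity) depends on the R_LAI convention; absolute
  comparisons against external Mₐ data must match light units first.
* No soil-moisture limitation beyond the empirical αₚ term; the models
  overpredict χ under strong edaphic drought.
* Parameter covariances are ignored in propagation (the published formula
  does the same).
* β and c are treated as universal constants; their interspecific
  variation appears only through the uncertainty budget.
* The statistical benchmark shares driver *sets* with the optimality
  models but fits freely; on synthetic data generated from the models both
  score near 1 and the comparison is only a schema demonstration.
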