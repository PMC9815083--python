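# Methods

## Scope and model chain

`picophys` closes the classical biochemical-engineering balance around a
single *E. coli* cell growing on glucose, using the observables that
microfluidic cultivation makes available: quantitative phase images (dry
mass), mother-machine division records (growth kinetics), and sealed
picoliter-batch colony areas (yield stoichiometry). The chain is

1. **Dry mass and density.** The optical path difference (OPD) of a phase
   image integrates dry-matter concentration along the optical axis, so
   `m = (px² / α) · ΣOPD` over the segmented object, with α the specific
   refraction increment. Density is `ρ = m / V`, with V from the
   spherocylinder shape model `V = π(w/2)²(l − w) + (4/3)π(w/2)³`.
2. **Monod kinetics.** Per-level doubling times give geometric-mean growth
   rates; nonlinear least squares of `μ = μmax·S/(KS + S)` on a log₁₀(S)
   axis (where the curve is sigmoidal) yields μmax and KS, plus
   upper/lower boundary fits to μ ± SD.
3. **Yield and balance.** `Y_X,S = (m_end − m_0)/S0` per chamber; the Cmol
   balance `q_S = μ/(Y_X,S·M_S)`, `r_P = q_S − μ/M_X`,
   `Y_P,S = 1 − Y_X,S·M_S/M_X` lumps all carbon by-products (CO₂, organic
   acids) into one product pool, closing the balance exactly.
4. **Dynamic model.** The batch balance `dX/dt = μX`,
   `dS/dt = −μX/Y_X,S`, `dP/dt = r_P·X` is integrated with fixed-step RK4;
   ensembles sample per-phenotype KS from a zero-truncated normal while
   sharing μmax and stoichiometry.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| pixel size | 0.045 | µm/px | 160× magnification of the imaging setup |
| α (cells) | 0.18 | mL/g | literature-standard increment for cellular dry matter; configurable, since instrument vendors do not publish theirs |
| α (beads) | 0.244 | mL/g | polystyrene; with n_bead = 1.59, n_medium = 1.333 the recovered bead density is (1.59−1.333)/0.244 ≈ 1.053 pg/µm³ |
| μmax | 0.66 | 1/h | the fitted maximum specific growth rate the generator emulates |
| KS mean ± CV | 486 µg/L, 0.481 | — | the observed affinity distribution (486 ± 234 µg/L) |
| timing noise CV | 0.40 | — | the ~±40% division-timing heterogeneity observed under constant conditions |
| frame intervals | 5 / 20 | min | mother machine / picoliter batch imaging cadence |
| reactor volume | 606 | pL | chamber + medium reservoir |
| M_X, M_S | 24.63, 30.03 | g/Cmol | biomass CH₁.₈O₀.₅N₀.₂ and glucose CH₂O; both configurable and surfaced in every report since elemental composition is strain- and condition-dependent |
| RK4 step | 0.001 | h | halving it changes final states by <10⁻⁴ relative |
| ensemble size | 200 | — | CLI default; envelope quantiles are stable well below this |

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical structure* the estimators
assume: Monod-governed doubling times with per-cell KS drawn from a
zero-truncated normal, multiplicative lognormal timing noise, frame-
quantized division detection with occasional consecutive-division
artifacts (default 1%, exercising the weight-0 outlier rule);
spherocylindrical cells rendered as ideal projected-thickness OPD maps
with additive Gaussian background noise; and batch colonies that grow to
substrate exhaustion with area as the observable.

It deliberately omits: diffraction, halo and shot-noise optics; cell–cell
mechanics, colony compression and nutrient gradients; segmentation error
on real images; per-cell μmax variation (only KS varies, matching the
observed affinity distribution); maintenance metabolism and product
inhibition. Passing tests therefore demonstrate that the estimators are
*correct and well-calibrated under the stated noise model* — not that
they are robust to real-microscope artifacts, which the original
workflow handled with manual curation and learned segmentation.

The timing noise is parameterized with unit **median** (log-mean 0,
log-SD √ln(1+CV²)). This makes the geometric-mean doubling time — the
estimator the analysis prescribes precisely because of its outlier
robustness — an unbiased estimate of the noise-free doubling time. A
unit-mean parameterization would bias all fitted rates upward by
≈ √(1+CV²) ≈ 7% at CV 0.4.

## Numerical choices

- **Rendering:** projected thickness is evaluated at 2× supersampling and
  box-averaged to the pixel grid; the 1 µm bead integral is then within
  0.1% of the analytic sphere volume (center sampling alone is within
  0.3%).
- **Segmentation:** plain connected-component labelling above an OPD
  threshold (default 0.01 µm — below the ≈0.02 µm peak of the faintest
  0.13 pg/µm³ cells, above the 0.002 µm background noise), minimum object
  size 10 px.
- **Width from area, not bounding box:** pixel-grid minor-axis extents
  overestimate rod width by about half a pixel per side (+12% on volume),
  so width is solved from the mask area via the capsule footprint
  relation `A = w(l − w) + πw²/4`; density recovery is then within 4%
  across the 0.13–0.28 pg/µm³ envelope.
- **Monod fit:** `scipy.optimize.curve_fit` with positivity bounds;
  initial μmax from the largest observed rate and initial KS from the
  concentration nearest half-maximum. Noiseless data are recovered to
  optimizer tolerance; a warning is emitted when all concentrations
  saturate (KS unidentifiable).
- **Weighted SD** of per-event rates uses frequency weights with a
  (Σw − 1) denominator; weight 0 for doubling times ≤ 1 frame.
- **Integration:** fixed-step classical RK4. The carbon total
  `X/M_X + S/M_S + P` is a linear invariant of the right-hand side, which
  RK4 preserves to machine precision; the substrate-exhaustion step is
  handled by consuming exactly the remaining substrate (scaling the last
  increment), which keeps the invariant exact. Substrate is floored at 0
  and μ = 0 thereafter. A step changing biomass by >10% raises an error
  advising a smaller `dt`.
- **Exhaustion marker:** S ≤ 10⁻⁶·S(0), since S reaches zero only
  asymptotically when KS is comparable to S.

## Design choices on genuinely open points

- **Boundary fits** are defined as fits to μ ± SD per concentration; the
  original boundary-curve construction is not documented. The naming
  convention is kept: the *upper* boundary (faster growth) has the
  *smaller* KS.
- **Pooled-lineage points** enter the fit with equal weight.
- **Per-cell KS inversion** uses each admissible doubling time as one
  observation; truncation of the KS distribution at zero lifts the
  realised mean a few percent above the nominal mean at CV ≈ 0.5, which
  the recovery tests account for.
- **Chamber exclusion:** chambers below a configurable initial-biomass
  floor, or whose apparent yield exceeds the carbon ceiling
  M_X/M_S ≈ 0.82 g/g, are flagged `excluded` but their values are
  reported unchanged — the analysis reports, never corrects, implausible
  regimes.

## Problem sizes

The default test-suite and acceptance computations use 8 glucose levels ×
60 division events, 200×200 px single-cell renderings, and ensembles of
tens of members at RK4 steps of 0.001–0.005 h; these sizes put every
estimator comfortably in its asymptotic regime (the bias-vs-n test shows
the μmax error falling from ~5% at 10 events/level to <1% at 200) while
keeping any run under a couple of minutes on one CPU.

## Known limitations

- Density recovery degrades for cells thinner than ~10 px across; the
  0.045 µm pixel scale keeps real-sized rods well above that.
- The KS estimate from a single campaign has ~10–15% sampling spread at
  60 events/level; μmax is much tighter (~2–4%).
- The carbon balance attributes *all* non-biomass carbon to the lumped
  product pool; maintenance and measurement error are indistinguishable
  from product formation by construction.
- Yields at very low S0 (sparse monolayers) are reported with an
  exclusion flag rather than corrected; no adsorption or evaporation
  model is included.
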