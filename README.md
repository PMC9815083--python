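# picophys

Quantitative single-cell physiology at the picoliter scale: a Python
toolkit that brings the balancing concepts of biochemical engineering —
growth kinetics, uptake rates, yield coefficients, carbon balances — down
to individual bacterial cells cultivated in microfluidic devices.

It is written for microbial physiologists and bioprocess engineers who
work with mother-machine or picoliter-batch cultivations of *E. coli* (or
similar rod-shaped organisms) and want absolute, balance-closing numbers
from image-derived observables rather than relative fluorescence readouts.

## What it computes

**Dry mass and density from quantitative phase imaging.** The optical
path difference (OPD) of a phase image is proportional to the dry-matter
column density, so the dry mass of a segmented cell is

    m = (px² / α) · Σ OPD,        ρ = m / V

with α the specific refraction increment (≈0.18 mL/g for cellular dry
matter) and V the spherocylinder volume from the cell's length and width.
A rendered polystyrene bead (n = 1.59 in n = 1.333 medium, α = 0.244 mL/g)
serves as the absolute calibration control.

**Monod growth kinetics from division records.** Per-concentration
geometric-mean growth rates μ(S) are fitted with

    μ = μmax · S / (KS + S)

by nonlinear least squares on a log₁₀ S axis, returning μmax, the
whole-cell substrate affinity KS, and upper/lower boundary fits to
μ ± SD that bracket the cell-to-cell heterogeneity. Inverting the fit per
cell, `KS = S (μmax/μ − 1)`, characterises the affinity distribution.

**Yield stoichiometry and Cmol closure.** Sealed 606 pL batch chambers
give `Y_X,S = (m_end − m_0)/S0`; the carbon balance on a Cmol basis then
yields the uptake and lumped by-product rates

    q_S = μ / (Y_X,S·M_S),   r_P = q_S − μ/M_X,   Y_P,S = 1 − Y_X,S·M_S/M_X

with M_X = 24.63 g/Cmol (biomass CH₁.₈O₀.₅N₀.₂) and M_S = 30.03 g/Cmol
(glucose).

**Ensemble batch dynamics.** A Monod batch model (RK4, carbon-conserving
to machine precision) simulated across KS phenotypes sampled from the
observed distribution maps the physiological space a heterogeneous
population spans.

A synthetic-data module generates all three input kinds — OPD images,
division tracks, batch area series — with the noise structure the
estimators assume, so the full pipeline runs and is testable without any
experimental data.

## Worked example

```python
from picophys import GeneratorConfig, MonodModel, simulate_mother_machine_tracks
from picophys.stoichiometry import close_stoichiometry

# synthetic mother-machine campaign: 8 glucose levels, 60 divisions each
tracks = simulate_mother_machine_tracks(GeneratorConfig(seed=1))
res = MonodModel.from_dataframe(tracks, frame_interval_min=5.0).fit()
print(res.summary())
```

```
Monod growth-kinetics fit
============================================================
variant           mu_max [1/h]     KS [ug/L]       R^2
mean                    0.6754         550.2    0.9970
upper_boundary          0.9886         565.3    0.9874
lower_boundary          0.3619         499.0    0.9849
------------------------------------------------------------
n growth points: 8 (glucose 1e-05..10 g/L)
```

The tracks were generated with μmax = 0.66 1/h and mean KS = 486 µg/L
under ~40% timing heterogeneity; the fit recovers both within their
sampling spread (μmax to 2%, KS to 13% here), and the boundary fits
bracket the heterogeneity band. Closing the balance at μ = 0.61 1/h and a
measured yield of 0.44 g/g:

```python
print(close_stoichiometry(mu=0.61, y_xs=0.44).to_json())
```

```json
{
  "y_xs": 0.44,
  "y_px": 0.03508100064406121,
  "y_ps": 0.4635322777101096,
  "q_s": 1.3863636363636362,
  "r_p": 0.021399410392877335,
  "m_x_cmol": 24.63,
  "m_s_cmol": 30.03
}
```

i.e. the cell takes up 1.39 g glucose per g biomass per hour, and 46% of
the substrate carbon leaves as CO₂/by-products (0.0214 Cmol g⁻¹ h⁻¹) —
the balance `y_ps + y_xs·M_S/M_X = 1` closes exactly.

The same steps are available from the shell:

```bash
picophys simulate-tracks --seed 1 --out tracks.csv
picophys monod-fit --tracks tracks.csv --out fit.json
picophys balance --mu 0.61 --yxs 0.44 --out stoich.json
picophys batch-sim --n 200 --seed 1 --out ensemble.csv
picophys run-all --seed 1 --out-dir out/        # full chained pipeline
```

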