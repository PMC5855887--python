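# steppewater

Analysis pipeline for a multi-year precipitation-manipulation experiment in a
semi-arid sagebrush steppe: does the *ecosystem functional response* — the
regression of aboveground net primary productivity (ANPP) on soil moisture —
change under sustained drought or irrigation, and does plant community
composition shift with it?

The package is aimed at ecologists analysing rainfall-manipulation
experiments (drought shelters / irrigation plots with paired soil-moisture
sensors, radiometric biomass estimates, and yearly species censuses).  It
provides statsmodels-style model/results objects for each stage, a seeded
synthetic-data generator that reproduces the statistical structure of every
input table, and a CLI driver that runs the whole chain.

## The models

**Soil-moisture reconstruction.** Treated-plot volumetric water content
(VWC) is observed only on some plot-days.  Within each paired plot group *g*
the treatment deviation is standardized by local ambient variability,
Δx<sub>g,d,trt</sub> = (x<sub>g,d,trt</sub> − x<sub>g,d,amb</sub>) /
s.d.(x<sub>g,amb</sub>), modelled on treatment, season, rain-day and all
two-way interactions (weighted by sensor counts), and the fixed-effect
predictions are added back to the daily ambient mean.  Remaining gaps are
filled from a surrogate process-model series, and the covariate for the
response model is cumulative VWC over March–June.

**ANPP calibration.** Ground reflectance in two red (626, 652 nm) and two
near-infrared (859, 875 nm) bands is reduced to a greenness index
(NIR − Red)/(NIR + Red); per year, the index is regressed on harvested
calibration biomass for a MODIS-like and an AVHRR-like band pairing and the
higher-R² fit predicts plot ANPP (g m⁻²).

**Functional response.** With y = standardized log(ANPP) and v =
standardized cumulative spring VWC,

    μᵢ = β·xᵢ + γ_{j(i)}·zᵢ + η_t ,   yᵢ ~ Normal(μᵢ, σ²)

where xᵢ = (1, I_drought, I_irr, v, I_drought·v, I_irr·v), zᵢ = (1, v),
plot effects γⱼ ~ MVN(0, Σ) (correlated random intercept and slope), year
effects η_t ~ Normal(0, σ²_year); priors are β ~ Normal(0, 5), half-Cauchy(2.5)
scales, uniform random-effect correlation.  Posteriors come from a blocked
Gibbs sampler (joint conjugate update of all linear coefficients; slice
sampling for scales).  Two one-tailed hypotheses are evaluated on the slope
offsets: drought × VWC > 0, irrigation × VWC < 0.

**Sensitivity.** Per treated plot-year,
(mean control ANPP − plot ANPP)/(ambient VWC − treated VWC), regressed on
year of treatment.

**Community composition.** Species columns (mixed density/cover metrics) are
z-scored and shifted +2, Bray–Curtis distances computed, and each year is
tested with first-principles PERMANOVA (pseudo-F, label permutation) and
PERMDISP (distances to PCoA group centroids with negative-eigenvalue
correction), plus a 2-D NMDS (Kruskal stress-1 via isotonic regression +
Guttman updates).

## Worked example

```python
import numpy as np
from steppewater import datagen, response, sensitivity

cfg = datagen.SimConfig(seed=42, n_years=8, n_control=10, n_drought=10, n_irrigation=10)
true = datagen.TrueParams(beta=np.array([0.0, 0.0, 0.0, 0.5, 1.2, 0.0]),
                          Sigma=0.02 * np.eye(2), sigma_year=0.1, sigma_obs=0.3)
records, _ = datagen.gen_anpp_dataset(cfg, true, datagen.default_vwc_table(cfg))

results = response.FunctionalResponseModel(records).fit(
    chains=2, iterations=3000, thin=2, seed=1)
print(results.summary().round(2).to_string(index=False))
```

```
coefficient  treatment  mean  median  lower95  upper95  rhat_offset
  Intercept    Control  0.29    0.28     0.18     0.39          1.0
  Intercept    Drought  0.28    0.28     0.13     0.42          1.0
  Intercept Irrigation  0.24    0.24     0.11     0.37          1.0
      Slope    Control  0.50    0.50     0.37     0.64          1.0
      Slope    Drought  1.54    1.54     1.38     1.70          1.0
      Slope Irrigation  0.55    0.55     0.43     0.68          1.0
```

The drought slope (control slope + offset) is well above the control slope —
the simulation injected a drought × VWC offset of 1.2 on the standardized
scale, and the posterior medians recover it (1.54 − 0.50 ≈ 1.05 offset, true
1.2 within the 95% interval).  The one-tailed hypothesis probabilities:

```python
print(results.offsets()[["coefficient", "treatment", "median",
                         "direction", "tail_probability"]].round(2))
```

```
     coefficient  treatment  median direction  tail_probability
intercept_offset    drought   -0.01         <              0.56
intercept_offset irrigation   -0.05         <              0.74
    slope_offset    drought    1.05         >              1.00
    slope_offset irrigation    0.06         <              0.24
```

`Pr(drought × VWC > 0) = 1.00`: the injected increase in drought-plot
sensitivity to soil moisture is detected with certainty; the irrigation
offset (true 0) stays uninformative.  The matching sensitivity trend on the
same records gives a strongly significant year trend
(`sensitivity_trend(...)["p_value"] ≈ 8e-06`), because the drought plots'
ANPP deficit per unit of VWC difference grows as VWC-slope effects compound.

The full pipeline (soil-moisture reconstruction through community tests) runs
from the shell:

```sh
steppewater all --seed 4 --outdir run   # writes CSV tables + manifest.json
```

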