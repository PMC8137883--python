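# sedarich

Infer plant taxa richness through time from lake sedimentary ancient DNA
(sedaDNA) metabarcoding, relate it to simulated glacier retreat and
alpine-habitat change in a mountain catchment, and project richness under
future warming.

The package is aimed at palaeoecologists working with sedaDNA
metabarcoding records from alpine lake catchments. It covers the whole
chain:

- **QC** of sequence-type count tables (identity thresholds, low-count
  zeroing, contaminant and occurrence filters, control screening,
  replicate pooling) with full provenance logging;
- **richness** by rarefaction to a common read depth, with percentile
  confidence intervals, within-family variants, constrained (CONISS-style)
  zonation and zonal turnover, and Procrustes/protest replicate-stability
  diagnostics;
- **glacier & habitat**: a shallow-ice-approximation glacier model driven
  by a temperature-anomaly series through the equilibrium-line altitude
  (ELA = ELA₀ + ΔT/lapse), plus hypsometric accounting of habitable and
  alpine (above-treeline) area in 100-m elevation bands;
- **driver statistics**: richness vs temperature, habitat areas, glacier
  decay, Mg/Ca and land use in three time windows, as Spearman's rho with
  Bonferroni correction, autocorrelation-adjusted degrees of freedom
  (n_eff = n(1 − r₁r₂)/(1 + r₁r₂)) and critical-value alpha bracketing;
- **projection**: an identity-link Gaussian GLM of richness on alpine
  habitat area (D² = 1 − residual/null deviance) applied to a simulated
  2050–2300 CE habitat series with 95% confidence bands;
- a **synthetic-data generator** that emulates every input with a planted
  richness–area relationship, so the full chain is testable with known
  ground truth and no downloads.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from sedarich import simulate_scenario
from sedarich.pipeline import analyze_scenario

bundle = simulate_scenario(seed=1)          # DEM, climate, glacier, dataset
result = analyze_scenario(bundle, seed=1)   # QC, richness, correlations, GLM

print(result.correlations.loc["10-0", ["rho", "p_adj", "adj_df", "alpha_level"]])
print(f"\nGLM: richness = {result.fit.params['const']:.1f} "
      f"+ {result.fit.params['alpine_habitat']:.2f} * alpine_km2 "
      f"(D^2 = {100 * result.fit.d_squared:.1f}%)")
print(result.projection[["alpine_km2", "richness", "ci_low", "ci_high"]].round(1))
```

which prints (the glacier spin-up takes about a minute):

```
                     rho         p_adj  adj_df  alpha_level
predictor
temperature    -0.980662  1.525711e-28       1         0.25
alpine_habitat  0.979774  3.634159e-28       1         0.25
forested_area  -0.979774  3.634159e-28       1         0.25
mgca            0.812021  5.848278e-10       1         0.25
land_use        0.784669  6.345591e-09       1         0.25

GLM: richness = 17.3 + 1.82 * alpine_km2 (D^2 = 86.2%)
        alpine_km2  richness  ci_low  ci_high
year
2050.0         5.4      27.2    25.6     28.7
2100.0         3.7      24.0    22.1     26.0
2150.0         2.4      21.7    19.4     23.9
2200.0         1.2      19.5    17.0     22.0
2250.0         0.4      18.1    15.4     20.8
2300.0         0.1      17.5    14.7     20.2
```

In the youngest window (10–0 ka) richness correlates positively with
alpine habitat area and negatively with temperature — warming expands
forest into alpine habitat and richness falls with it. The fitted GLM
(here 1.82 taxa per km² of alpine area against a planted truth of 2.0,
explaining 86% of deviance) translates the simulated future loss of
alpine area into a ~36% richness decline by 2300. The adjusted df of 1
reflects the very strong serial dependence of these smooth synthetic
series, which makes the alpha bracketing deliberately conservative.

A command-line interface mirrors the stages
(`sedarich simulate|qc|diversity|habitat|correlate|project --help`).

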