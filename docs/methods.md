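# Methods

`sedarich` implements an inference chain from sedimentary ancient DNA
(sedaDNA) metabarcoding count tables and a temperature-anomaly series to
(i) rarefaction-based plant richness time series, (ii) simulated glacier
cover and alpine-habitat area in a mountain catchment, (iii) windowed
driver–richness correlations, and (iv) a projection of future richness
under warming. This note records the models, the defaults and why they
hold, the numerical choices, and what the synthetic scenarios do and do
not demonstrate.

## Quality control of sequence-type tables

The input is a table of sequence types × (sample, PCR replicate) read
counts, with per-sequence taxonomy and a *best identity* (similarity to
the closest reference-database match), plus sample roles (lake sediment,
extraction control, no-template control). The filtering chain is fixed
and logged:

1. **identity filter** — keep best identity ≥ 0.95 (`bestid095`) or
   exactly 1 (`bestid1`);
2. **low-count zeroing** — per-cell counts < 10 are set to 0 (a cell of
   exactly 10 survives), removing tag-jump/low-copy noise;
3. **contaminant removal** — a blacklist of fruit/cultivar/non-regional
   taxa (matched on taxon or family name) and, optionally, a regional
   whitelist;
4. **occurrence filter** — sequence types detected in fewer than 2
   sediment horizons (replicates pooled) are dropped;
5. **empty-sample drop** — sediment horizons left without reads are
   removed; control columns never reach the statistical datasets.

The chain is idempotent, no step increases a count or adds a record, and
`bestid1` is always a record subset of `bestid095`. Occurrence is counted
over horizons, not replicates (the alternative is one switch away).
Control screening is report-only by default — sequences found in a
control are noted, not subtracted — with an optional strict mode, because
a single contaminated control does not prove the sediment signal is
contamination. The `single` dataset keeps, per horizon, only the
replicate with the largest read total (ties break to the lowest replicate
index, deterministically); `pooled` sums replicates.

## Richness estimation

Richness is compared across unequal sequencing effort by rarefaction:
sampling without replacement (multivariate hypergeometric) to a common
depth, by default the smallest per-horizon total in the dataset, repeated
100 times; the mean number of detected taxa is the richness estimate and
the 2.5/97.5 percentiles of the replicate values give the 95% interval.
The expectation has the closed form Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], which
the tests use as an independent oracle. Within-family richness rarefies
each family sub-table to a 100-read cutoff so low-abundance families are
comparable with dominant ones; horizons whose family total falls below
the cutoff are *missing*, not zero — reporting them as zero would
conflate detectability with absence.

A Spearman check of per-horizon read depth against rarefied richness
(df = n − 2) guards against residual depth dependence; constant inputs
return rho 0 with a degenerate flag instead of raising, to keep batch
runs alive.

## Zonation and turnover

Stratigraphic zones come from constrained incremental sum-of-squares
clustering: only adjacent clusters may merge, each merge minimises the
increase in total within-cluster dispersion of the relative-abundance
rows, and reported heights are the cumulative within-cluster sum of
squares (non-decreasing). Dissimilarity is computed on relative
abundances without further transformation. Turnover between consecutive
zones is computed on zonal assemblages (zone-summed counts rarefied to
the minimal zonal total, 100 draws): with P the taxa present in either
zone, total turnover = (gained + lost)/|P|, and the appearance and
disappearance fractions are gained/|P| and lost/|P|, summing to the
total. The appearance fraction doubles as a "proportional immigration"
readout.

## Ordination stability diagnostics

To check that pooling PCR replicates does not distort the signal, the
first two principal components of the pooled and deepest-replicate
datasets are compared. Taxa with maximum relative read abundance below
0.25% are screened out; a double-square-root transform (x → x^¼) tames
dominant types; columns are centred, not scaled. The configurations are
compared by Procrustes rotation (m² = minimised residual sum of squares
after centring, scaling and optimal rotation; 0 means identical shapes)
with a permutation ("protest") p-value using the plus-one rule.

## Glacier and habitat simulation

Ice flow uses the shallow-ice approximation: thickness H evolves by
∂H/∂t = b(z) + ∇·(D∇s) with surface s = z + H and diffusivity
D = (2A/(n+2)) (ρg)ⁿ H^(n+2) |∇s|^(n−1). Defaults (configurable):
Glen n = 3, softness A = 10⁻¹⁶ Pa⁻³ yr⁻¹, ρ = 910 kg m⁻³, g = 9.81 m s⁻²,
no basal sliding. The mass balance is a capped linear profile
b = min(0.0115 · (z − ELA), 0.25) m yr⁻¹, and the equilibrium line
altitude follows temperature through the integrated lapse rate:
ELA = 5200 m + ΔT / 0.0055 (0.55 °C per 100 m), so +2.5 °C lifts the ELA
by 454.5 m.

Numerics: explicit flux-form finite differences; face diffusivity uses
the donor-cell (higher-surface) thickness, so ice-free cells never export
mass and volume is conserved exactly in the interior (verified to 10⁻⁶
relative over 100 steps with b ≡ 0); the |∇s| factor uses the
face-normal gradient only — a mild anisotropy accepted for robustness;
time steps respect the explicit diffusion bound (oversized steps raise an
error carrying a suggested step); thickness is clipped at 0 after
ablation. Steady state means the relative volume change per century
drops below 10⁻³ *or* the ice mask (H > 1 m, suppressing thin halos) is
unchanged over three consecutive checks — the latter covers the
all-accumulation regime, where extent is fixed while volume still grows.

Ice extent through time is looked up from steady states precomputed on a
50-m ladder of ELA values (nearest entry per time step), treating glacier
cover as an equilibrium response to the slowly varying (500-yr step)
forcing; transient spin-up at every step would add cost without changing
the extent at this cadence. Habitat accounting is hypsometric: ice-free
catchment cells are habitable; cells at or above the effective treeline
(4,400 m shifted by ΔT/lapse — algebraically identical to shifting every
pixel's relative elevation, but cheaper) are alpine; 100-m elevation
bands from 1,000 to 6,000 m partition the habitable area exactly.
Ice-covered cells are excluded from *all* band sums (the alternative —
excluding them only from the total — is one flag away). Areas are cell
count × cell size²; grids are planar, so real DEMs must arrive in a
metric projection.

## Driver correlations

Richness and drivers are linearly interpolated onto a common age grid of
0.25-ka spacing (anchored at the oldest common age; no extrapolation) and
analysed in three windows pairing consecutive vegetation zones — 18–10,
14–3.6 and 10–0 ka, endpoints inclusive. Deglaciation drivers (total
habitat, glacier decay — operationalised as the ice-area series) are
tested only in 18–10 ka; the alpine/forest partition once the catchment
is ice-free; land use only in the youngest window. Richness and Mg/Ca
are loess-smoothed (span 0.5, local linear, tricube weights); the
zero-inflated land-use indicator gets a penalised cubic smoothing spline
with GCV-chosen roughness; other drivers pass through.

Correlation is Spearman's rho with two-tailed p Bonferroni-corrected
within each window's predictor family. Because smoothing induces serial
dependence, degrees of freedom are adjusted with the lag-1
autocorrelation formula n_eff = n(1 − r₁r₂)/(1 + r₁r₂), floored at 3
effective samples, adjusted df = ⌊n_eff⌋ − 2. Observed rho is then
bracketed against one-sided critical values of Spearman's rho (t
approximation, r_crit = t_α/√(t_α² + df)) at levels
{0.0005, 0.01, 0.025, 0.05, 0.25}; the smallest reached level is
reported, or "none" (> 0.25). The t approximation is adequate at the
df ≥ 10 typical of real series; on heavily smoothed synthetic series the
adjusted df often hits the floor, which makes the alpha bracketing
conservative there — a property of the data, not the formula.

## GLM and projection

Richness is regressed on alpine habitat area with an identity-link
Gaussian GLM over the 10–0 ka window, the warmest and most recent part of
the record. The fit uses the record's native horizon resolution
(~250-yr spacing, drivers interpolated onto horizon ages): regressing a
response that was itself interpolated onto a finer grid would
pseudo-replicate observations and understate the slope's standard error.
Explained deviance D² = 1 − residual/null deviance equals R² for this
family (asserted to 10⁻¹⁰). Variable importance is |t| scaled so the top
predictor scores 100. Projection applies the fitted line to the
simulated 2050–2300 CE alpine-area series (50-yr steps) with 95%
confidence intervals for the mean response; future predictor values more
than 10% beyond the fitted range are flagged as extrapolation but still
predicted — the far future *is* below anything observed, and silently
clipping would hide that.

## Synthetic scenarios and what they show

The generator plants a known truth: expected horizon richness =
baseline (15 taxa) + slope (2 taxa per km²) × alpine area + N(0, 2)
noise. Taxa live in niche pools — alpine taxa are eligible only when
alpine area exists, montane taxa when forested (ice-free, below-treeline)
area exists, ubiquitous taxa always — encoding habitat tracking at
minimal complexity. Reads are multinomial over log-normal relative
abundances (σ = 0.7) at 20,000–60,000 reads per PCR replicate (the scale
of real runs: ~6M reads over 138 replicates), two replicates per horizon,
72 horizons spanning 18–0 ka of which one is read-free and drops out in
QC. A fixed fraction (80%) of taxa carry best identity 1, the rest
uniform in [0.95, 1); four contaminant taxa are injected at low counts;
controls are empty by default (configurable budget). The catchment DEM
is a noisy bowl between 4,200 and 4,900 m (48 × 48 cells of 90 m); the
temperature curve is a logistic deglacial warming (midpoint 15 ka, about
−6 °C glacial) plus a mid-record warm bump (+0.9 °C), zero anomaly at
0 ka by construction, so the catchment deglaciates near the 14-ka
analogue; the future leg ramps to +2.5 °C by 2300 CE. The land-use
indicator is exactly zero before 3.6 ka and positive after; Mg/Ca is a
smooth positive curve. All generators are bit-reproducible under a fixed
seed.

What passing tests show: the chain recovers a *planted, linear,
instantaneous* richness–area relationship through QC, rarefaction,
alignment, correlation and GLM, with correct driver signs and calibrated
slope coverage (≥ 90% of 50 seeds). What they do not show: realism of
the read-abundance model (the true read–abundance relationship in
sediments is poorly constrained), taxonomic misassignment, lagging
treeline or vegetation response, or transient glacier dynamics. The
quantitative slope-recovery check runs on the `bestid095` dataset; the
exact-identity dataset excludes the planted 20% of imperfect-identity
taxa and therefore scales detected richness below truth by construction.

## Problem sizes

Default simulations are sized for a desk machine: a 48 × 48 catchment
grid (≈ 18.7 km², scaled down from the real 128 km² catchment), a 37-step
past forcing, ≈ 25 ladder ELAs with a 10,000-model-year budget each, and
100 rarefaction replicates; one full scenario plus analysis runs in about
a minute, and the whole test suite (including a 50-seed end-to-end
calibration) in under two.
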