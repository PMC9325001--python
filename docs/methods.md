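# Methods notes

## Model and assumptions

The response is the **total** SOC change of a plot over the resampling
interval (g kg⁻¹ per interval, default 9 years). It follows a two-component
Gaussian scale mixture with a shared mean: a narrow component (SD σ₁,
weight π) for plots whose resampling location matched the original, and a
wide component (SD σ₃ = σ₁ + σ₂) for plots where relocation error exposes
the metre-scale spatial variability of SOC. Sharing the mean encodes the
assumption that relocation error is unbiased — a mislocated plot still
experiences the same climate and management — so mislocated plots inform
the covariate effects, only with less precision. Parameterising the wide SD
as σ₁ + σ₂ with σ₂ bounded away from zero makes the components ordered by
construction; no label switching can occur and π is identified.

The linear predictor combines climate-window deltas, farm type, the log
SOC-to-fine-fraction ratio, rotation-class dummies and a measurement-group
random effect u_g ~ N(0, σGroup²) that absorbs shared field-team /
regional effects. Independence across plots given u is assumed; there is
no explicit spatial correlation beyond the group level.

**Response scale.** The likelihood is evaluated on total change, and
per-year numbers are produced afterwards by dividing location/scale
summaries by the interval length. The σ₂ ~ U(5, 20) prior only makes sense
on the total scale (a wide-component SD of ≈ 1.18 g kg⁻¹ yr⁻¹ corresponds
to ≈ 10.6 over nine years, inside σ₁ + (5, 20), whereas no per-year value
could reach the box). The annualization divides by a constant, so P(θ>0)
is identical on either scale.

## Priors and tunable parameters

| parameter | default | units / support | rationale |
|---|---|---|---|
| coefficient prior | N(0, 10⁵) | (g kg⁻¹ /unit)² | effectively flat over the plausible range while remaining proper |
| (π, 1−π) prior | Dirichlet(½, ½) | — | Jeffreys-type, mildly favors decisive weights |
| σ₁, σGroup | U(0.01, 6) | g kg⁻¹ per interval | weakly informative box; lower bound avoids the degenerate spike at 0 |
| σ₂ | U(5, 20) | g kg⁻¹ per interval | keeps the wide component genuinely wide (identification) |
| chains × iterations | 4 × 20,000, burn-in 5,000 | — | desk-scale default; `McmcConfig.paper_scale()` gives 5 × 300,000 / 50,000 |
| split-R̂ / ESS thresholds | 1.05 / 400 | — | automated replacement for graphical convergence checks |

`pi_fixed=1.0` collapses the likelihood to a single Gaussian (used to
demonstrate that the min/max posterior-predictive check detects the missing
heavy tail).

## Sampler

Gibbs with augmented component indicators:

1. indicator z_i | rest: Bernoulli from the two weighted normal densities;
2. π | z: Beta(½ + n_narrow, ½ + n_wide);
3. coefficient block | z, u: conjugate multivariate normal
   (precision XᵀWX + I/10⁵, W the per-plot inverse variances);
4. u_g | rest: independent conjugate normals;
5. σGroup, σ₁, σ₂: 1-D conditional draws on a dense grid (512 cells over
   the prior box, Gumbel-max categorical draw plus uniform jitter within
   the winning cell). The conditionals depend on the data only through the
   per-component counts and residual sums of squares, so a grid evaluation
   costs O(grid), not O(n·grid). Grid resolution (≈0.01 on a U(0.01, 6)
   box) is two orders of magnitude below the posterior SDs of the SDs, and
   the in-cell jitter keeps the support continuous.

The target density is exactly `log_likelihood + log_prior` as exposed in
`soctrend.mixture`; the module-level functions are kept independent of the
sampler so tests can compare the chain against dense-grid quadrature on
reduced models. Chains are seeded from one SeedSequence spawn; results are
bit-reproducible for a fixed `random_state`.

Convergence is checked with split-R̂ and bulk ESS (arviz) on every reported
parameter; failures attach `convergence_warnings_` and emit a warning, never
silently pass. π and σ₁ mix slowest (they trade off through the indicator
allocation); at the desk-scale defaults their ESS is in the thousands.

## Covariate construction choices

- **Organic-soil exclusion**: the inclusion rule is organic matter ≤ 20%,
  but only SOC is measured; OM = 1.724 × SOC (Van Bemmelen factor) is used,
  i.e. exclusion at SOC ≥ 116 g kg⁻¹ at either sampling. Exclusions are
  logged with reasons, never silent.
- **Rotation classifier**: Shannon index over the seven crop groups
  (cereals, legumes, vegetables, oilseeds, grasses, green fallow, others)
  with N = number of recorded years in the window; grasses and green fallow
  count as perennial. All thresholds are strict (H > 0.8, share > 0.8), so
  an exactly-80% plot falls through to "Rotation".
- **Climate deltas**: mean summertime (May–Sep) values over 1998–2018 minus
  1989–2009, both inclusive; monthly precipitation is summed within a year
  before averaging. A linear trend of b per year yields exactly 9·b.
  Incomplete series raise an error listing the missing (year, month) pairs.
  Precipitation windows mirror the temperature windows.
- **Nearest grid point**: planar Euclidean distance, ties to the lowest
  grid-point id.
- **Log-ratio centering**: the log SOC-to-fine ratio is centered to the
  post-exclusion sample mean by default (the intercept is then the expected
  change for an average-ratio annual plant-production plot under no climate
  change); `center_log_ratio=False` keeps the raw ratio so the intercept
  refers to OrgC/fine = 1. Farm type is treated as fixed per plot.

## Bootstrap

Percentile bootstrap (100,000 resamples) for the mean change; p-value is
the doubled smaller tail proportion of resampled means about zero, clipped
to [0, 1] — the standard convention for a two-tailed resampling test, since
no closed-form definition is canonical. BCa intervals are deliberately not
used; the percentile interval is what the method is specified to report.

## Posterior-predictive check

Ten stratified-by-group 80/20 splits; the model is refitted on each
training set. For each split, 100 predictive datasets of test size are
drawn, each from one joint posterior draw (full uncertainty propagation,
not a plug-in mean); groups unseen in training receive a fresh
N(0, σGroup²) effect. p(max) is the fraction of predictive maxima ≥ the
observed test maximum, p(min) the fraction of minima ≤ the observed
minimum; inclusive comparisons avoid spurious p = 0. Values in
(.025, .975) count as adequate fit. With 100 predictive draws the binomial
standard error of a p-value is ≤ 0.05. The API accepts arbitrary
statistic callbacks with a tail direction.

Because the observed data enter only through one min/max per split while
the predictive replicates carry posterior parameter spread, well-specified
data give p-values pulled toward ½; data generated from the fitted
predictive itself give approximately uniform p-values (this distinction is
what the calibration tests assert).

## Synthetic generator

The generator produces the full input surface — plot table, per-year crop
records, and two monthly May–Sep climate grids — with the exact generative
structure the model assumes, at defaults chosen to mirror the published
study conditions: 385 plots, 20 measurement groups, 9-year interval,
per-year coefficients (ν 0.048, βP −0.003, βT −0.404, βFT 0.011, βfine
−0.193, βper 0.152, βdiv 0.081, βrot 0.137), π = 0.734, σ₁ = 0.267,
σ₃ = 1.178, σGroup = 0.112 (per-year scale; multiplied by the interval on
the fitted scale). Where the source material states only ranges, the
defaults are conventions, documented in `SynthConfig`: ΔT ~ N(0.46, 0.12²)
truncated to [0.2, 0.7] °C, ΔP ~ N(14, 5²) mm, SOC₂₀₀₉ lognormal with mean
34.1 g kg⁻¹ truncated below the organic-soil limit, log SOC-to-fine ratio
~ N(−3.0, 0.6²) (median ratio ≈ 0.05), 35% livestock farms, rotation mix
45/20/10/25% Annual/Perennial/Diverse/Rotation. Crop records are drawn
from per-class year patterns and verified against the classifier; the
second climate grid is an affine transform of the first whose window
deltas regress on the first's with slopes 0.90 (temperature) and 0.98
(precipitation) plus small noise. Group membership is assigned by slicing
the easting-sorted plots into contiguous blocks, giving the random effect
a geographic interpretation. All randomness flows from one seed through a
SeedSequence.

What the generator does **not** emulate: spatial autocorrelation of soil
properties and climate beyond the group/grid structure, interannual
weather variability (the climate series are exact trend + seasonal shape,
so the window deltas are noise-free), measurement drift between
laboratories, covariate measurement error, and any dependence of
relocation probability on plot properties (wide-component membership is
iid Bernoulli). Passing recovery tests therefore demonstrates correctness
of the inference machinery under the model's own assumptions — not
robustness of the model to real-data violations of them. Two small
physicality guards (SOC₂₀₀₉ capped below the exclusion limit; resampled
SOC floored at 1 g kg⁻¹ by redrawing, which touches ≲1% of plots) truncate
the tails slightly relative to the pure model.

## Stock conversion and reporting

Stock change = E[θ|y] × multiplier / 34.09 × 54 × 1000 kg C ha⁻¹ yr⁻¹,
with the multiplier 1 for categorical contrasts and the period-average
covariate change (0.46 °C / 14 mm for the first grid variant, 0.45 °C /
16 mm for the second) for climate rows. The conversion input is the
**rounded** per-year posterior mean, so a printed table is consistent with
its own cells; feeding unrounded means can shift climate-row cells by a
couple of kg. The intercept's conversion inherits the centered-covariate
interpretation of ν and should be read with that caveat. Stratified
medians/IQRs (former-organic, long-cultivated, all plots) take the stratum
flags as input columns; identifying them from historical maps or earlier
campaigns is outside this package's scope.

## Problem sizes used by the test suite

Sampler-equivalence and recovery checks run at the full network size
(n = 385) with desk-scale MCMC (4 × 20,000); replicate-based checks use 10
replicates, which gives binomial tolerances of roughly ±0.13 on an 80%
coverage proportion pooled over 8 coefficients (the pooled test uses 80
intervals). Bootstrap coverage uses 200 replicates at 5,000 resamples.
Larger replicate counts tighten these bands but do not change the
conclusions; the full published MCMC length is available via
`--paper-settings` / `McmcConfig.paper_scale()`.

## Known limitations

- No spatially correlated random effects, measurement error in covariates,
  or model selection; the model is exactly the one described above.
- The mean trend of a single generated network has a between-realization
  SD of ≈ 0.04 g kg⁻¹ yr⁻¹ around the configured −0.10; individual seeds
  can yield non-significant bootstrap trends. This mirrors the sampling
  variability a real network of this size has.
- The grid-based SD draws discretize a continuous conditional; with the
  default 512-cell grid the approximation error is far below Monte Carlo
  error, but pathological custom bounds (boxes much wider than the
  posterior) would deserve a finer grid.
- Posterior-predictive p-values with 100 draws have a resolution of 0.01;
  occasional boundary values (0 or 1) on well-specified data occur with
  probability ≈ 1/101 per statistic and are expected, not a defect.
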