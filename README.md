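# soctrend

Bayesian analysis of decadal soil-organic-carbon (SOC) change in resampled
arable-soil monitoring networks.

National soil monitoring programs revisit fixed plots roughly once a decade
and remeasure topsoil SOC content (g C per kg dry soil, 0–15 cm). The
resulting change signal is small (tenths of g kg⁻¹ per year) and buried in
heavy-tailed measurement scatter, largely because a revisited plot is never
relocated perfectly and SOC varies strongly at the metre scale. `soctrend`
implements an analysis chain built for exactly this situation: it separates
climate, management and soil-property effects on SOC change while treating
relocation error explicitly, and it ships a synthetic-network generator so
the whole chain is testable without access to (typically restricted)
monitoring data.

Intended users are agro-environmental statisticians and soil scientists
working with twice-sampled plot networks plus per-year crop registers and
gridded climate products.

## The model

For plot *i*, the total SOC change over the resampling interval is a
two-component Gaussian scale mixture with a **shared mean**:

```
ΔSOC_i | μ_i, s_i ~ N(μ_i, s_i²)
s_i | π          ~ Cat(σ₁, σ₁+σ₂ ; π, 1−π)         σ₃ ≡ σ₁+σ₂
μ_i = ν + βP·ΔP_i + βT·ΔT_i + βFT·FT_i + βfine·log(OrgC/fine)_i
        + βper·Per_i + βdiv·Div_i + βrot·Rot_i + u_g(i)
u_g ~ N(0, σGroup²)
```

The narrow component (weight π) holds well-relocated plots; the wide one
absorbs relocation error. Because both components share μ_i, every covariate
effect is estimated from all plots jointly. Covariates: summertime (May–Sep)
changes in precipitation sum ΔP (mm) and mean temperature ΔT (°C) between
two 21-year windows; farm type FT (livestock vs plant production); the log
SOC-to-fine-fraction (<0.06 mm) ratio; and crop-rotation class dummies
(Perennial / Diverse / Rotation against an Annual reference) classified from
the Shannon diversity of the recorded crop groups. Priors are N(0, 10⁵) on ν
and every β, Dirichlet(½, ½) on (π, 1−π), and uniform boxes σ₁, σGroup ~
U(0.01, 6), σ₂ ~ U(5, 20). Inference is Gibbs sampling with augmented
component indicators; summaries report posterior means, equal-tailed 80%
intervals and P(θ>0), annualized to per-year units.

Around the model sit: a rotation classifier (Diverse if H > 0.8, else
Annual/Perennial if > 80% of recorded years, else Rotation), nearest-grid-
point climate matching and window deltas, organic-soil exclusion (OM ≈
1.724 × SOC > 20%), a 100,000-resample nonparametric bootstrap for the mean
trend, cross-validated posterior-predictive p-values for the sample min/max,
and conversion of effects to SOC-stock terms
(E[θ|y]/34.09 × 54 × 1000 kg C ha⁻¹ yr⁻¹).

## Worked example

```python
import soctrend as st

cfg = st.SynthConfig(seed=7)                      # 385 plots, 9-year interval
data = st.generate_network(cfg)
design, excluded = st.build_design(
    data.plots, data.crop_records, data.climate["grid_a"]
)
print(f"retained {len(design)} plots, excluded {len(excluded)}")

trend = st.bootstrap_mean_change(
    design["delta_soc_total"] / cfg.interval_years, seed=1
)
print(f"mean change {trend.mean_change:+.3f} g/kg/yr, "
      f"95% CI ({trend.ci_low:.3f}, {trend.ci_high:.3f}), p = {trend.p_two_tailed:.4g}")

model = st.SOCMixtureRegression(random_state=1)   # 4 chains x 20,000 iterations
model.fit(design, design["delta_soc_total"], groups=design["group_id"])
print(model.summary_.round(3))
```

Output:

```
retained 385 plots, excluded 0
mean change -0.106 g/kg/yr, 95% CI (-0.171, -0.039), p = 0.0016
              mean  pi80_low  pi80_high  p_positive   rhat        ess
parameter
nu           0.150    -0.016      0.317       0.875  1.000  19047.345
beta_p      -0.006    -0.012      0.000       0.107  1.000  27435.155
beta_t      -0.529    -0.784     -0.273       0.004  1.000  27792.810
beta_ft     -0.003    -0.060      0.054       0.480  1.000  30425.833
beta_fine   -0.233    -0.284     -0.182       0.000  1.000  29812.549
beta_per     0.284     0.209      0.360       1.000  1.000  23149.893
beta_div     0.014    -0.102      0.129       0.566  1.000  17058.909
beta_rot     0.106     0.040      0.173       0.980  1.000  30748.417
pi           0.749     0.682      0.813       1.000  1.001   3809.527
sigma1       0.306     0.272      0.340       1.000  1.001   4249.775
sigma3       1.167     1.018      1.332       1.000  1.000   6388.668
sigma_group  0.165     0.119      0.216       1.000  1.000  15193.904
```

Reading it: the network-mean SOC trend for this realization is −0.106
g kg⁻¹ yr⁻¹ (clearly negative by the bootstrap test). Warming reduces SOC
(βT mean −0.53 g kg⁻¹ yr⁻¹ per °C, P(θ>0) = 0.4%), perennial-dominated
rotations gain SOC relative to annual cropping (βper +0.28, P(θ>0) ≈ 1),
and a high SOC-to-fine ratio predicts loss (βfine < 0). About 75% of plots
fall in the narrow measurement component (per-year SD 0.31); the rest sit
in the relocation-error component (SD 1.17). `effects_table(model)` adds
the stock conversions; `bayesian_pvalue_cv(design)` checks that the fitted
tails reproduce the observed extremes.

The same stages are available from a shell:
`soctrend simulate | design | bootstrap | fit | diagnose | report`
(`soctrend fit --paper-settings` runs 5 chains × 300,000 iterations).

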