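# Methods

This note records the models, parameter choices and numerical decisions
behind `soilrich`, and what the synthetic-data validation does and does
not demonstrate about real data.

## Climatic covariates

**PET.** Daily Jensen–Haise potential evapotranspiration,
`(0.025·T + 0.08)·R_s/λ_w` (T in °C, R_s in MJ m⁻² day⁻¹,
λ_w = 2.45 MJ kg⁻¹ converting energy flux to mm of evaporation).
The empirical formula goes negative below −3.2 °C; negative demand is
unphysical and is replaced by zero *before* any averaging. Annual PET
is formed by calendar aggregation: daily PET is averaged within each of
the twelve calendar months (pooled across years), the monthly means are
averaged, and the mean daily rate is scaled by 365.25.

**Rainfall events and DRY.** A day is an event when its precipitation
exceeds the daily-equivalent mean annual PET (`PET_annual/365.25`) —
an annual total cannot sensibly be compared against a daily amount, so
the threshold is normalised to a daily rate. DRY is the mean gap (in
days) between successive event days; events on consecutive days give a
gap of 1, which is also the lower bound. With fewer than two events
DRY is capped at the series length rather than at one year: deserts
can legitimately exceed 365 days between effective rains.

**AWC.** A linear pedotransfer in clay, silt, organic carbon and bulk
density, deliberately excluding pH and CEC so the wetness covariates
carry no chemical signal. The shipped coefficients
(0.150 + 0.30·CLY + 0.25·SLT + 0.002·ORC − 5·10⁻⁵·BLD, clipped to
[0.01, 0.45]) are configuration defaults with the standard qualitative
behaviour — AWC rises with fine texture and carbon and falls with
packing density; any published pedotransfer of the same four inputs can
be substituted through the `coeffs` argument. The clip bounds keep the
drying rate finite.

**CWC.** The top metre of soil is modelled as a store of capacity AWC
that refills completely at every rainfall event and is depleted
exponentially by PET between events, with rate
`k = (PET_annual/365.25)/(AWC·depth·1000)` per day. CWC is the time
average of the store over a dry spell of length DRY:
`CWC = AWC·(1 − e^(−k·DRY))/(k·DRY)`. This closed form satisfies every
qualitative property required of the covariate — equal to AWC when
drying vanishes (`k·DRY → 0`, evaluated by its series limit below
10⁻⁸ for numerical stability), strictly decreasing in DRY, bounded by
(0, AWC], and decaying as 1/DRY for long droughts. It is a documented
interpretation: other exponential-store summaries (e.g. the end-of-spell
rather than time-averaged content) would share these properties, and
the tests pin the properties, not the particular summary.

**Covariate clustering.** Pairwise Spearman correlation; distance
`1 − |ρ_s|`; average linkage; tree cut at 0.15, so covariates
correlated above |ρ_s| ≈ 0.85 collapse into one cluster. The sand
fraction is removed before clustering (texture is compositional — SND
is determined by SLT and CLY). "Simpler physical interpretation" is not
operational, so retention within a cluster follows an explicit
configurable priority list (CWC > PH > MAT > MAP > PET > DRY > RAD >
NPP > AWC > SLT > CLY > ORC > BLD > CEC).

## Diversity estimation

Taxa labelled Archaea or kingdom-Unassigned are removed (the labels are
inputs; classification itself is upstream of this package), as are
global singletons (total count 1 across all samples). Rarefaction
draws without replacement (multivariate hypergeometric); repeated
rarefaction averages 100 independent draws per sample, so averaged
abundances are generally non-integer while column totals still equal
the depth exactly. Each (repetition, sample) pair has its own seeded
generator stream, making the result independent of iteration order.

The rarefaction depth is chosen by grid search over 2,500–15,000. The
selection criterion — maximise `retained_fraction · log(depth)` — is a
documented package choice that reproduces the intended trade-off
(keeping samples versus sampling each deeply); the full diagnostic
table is returned so any other criterion can be applied, and the
conventional realized depth (7,500) is what the default synthetic
study selects.

A taxon is *present* in a sample when its averaged abundance is
positive (equivalently: it appeared in at least one repetition);
richness, Hill numbers and the rare/common counts are computed on this
rule. Computing instead the mean of per-repetition richness values is
possible from the same primitives but is not the default. Hill numbers
use the exponential-entropy limit at q = 1 (tolerance 10⁻¹² on |q−1|).
The rare/common split is at 0.005% global relative abundance on the
averaged table; the log-ratio uses a Haldane ½ correction by default so
samples with an empty class stay finite (switchable off, in which case
both counts must be positive).

Sites are 0.1° × 0.1° cells, half-open with inclusive lower-left
corner, keyed by `floor(lat/0.1), floor(lon/0.1)` on signed degrees;
site metrics are arithmetic means of member samples. Biome contrasts
use the two-sided Wilcoxon rank-sum test (exact null for small untied
samples, tie-corrected normal approximation otherwise).

## Additive models

Gaussian additive models with one penalized cubic B-spline smooth per
covariate: basis dimension k = 10 (interior knots at data quantiles),
sum-to-zero constraint absorbed by a null-space transform, second-order
difference penalty. Smoothing parameters are estimated by REML
(profiled scale), optimized in log-λ by L-BFGS-B from three starts
(neutral, heavily and lightly smoothed) because the restricted
likelihood can be multimodal. Every smooth carries a second penalty on
its penalty null space (the double penalty), so a term's effective
degrees of freedom can shrink essentially to zero and the term drop out
of the model; terms with EDF < 10⁻³ are reported as negligible. The
engine reproduces mgcv (REML, `select=TRUE`) on shared datasets to
within ~0.5 EDF and a few percent of fitted-curve RMS, and that
agreement is enforced by a test that runs mgcv through Rscript as an
independent oracle.

AIC uses the Gaussian log-likelihood at the ML scale with
`edf_total + 1` parameters. Forward selection greedily adds the
candidate with the lowest AIC while the best ΔAIC is negative (ties
broken by candidate order); each step records ΔAIC and a
likelihood-ratio p-value conditional on the estimated smoothing
parameters (deviance difference on the larger model's scale,
EDF-difference degrees of freedom — approximate, as conditioning on
selected smoothing parameters always is). Leave-one-out validation
holds the smoothing parameters at their full-data REML estimates; at
fixed penalties the model is a linear smoother, so the held-out
residuals `e_i/(1−h_ii)` are exactly those of n coefficient refits.
LOO R² can be negative. The `diversity_profile_fit` helper repeats a
fit across Hill orders to expose whether rare-weighted diversity is the
more predictable response.

## Causal additive models

Structure search is greedy edge insertion over additive regressions
with a small (k = 6) unpenalized spline basis. The insertion score is
the gain in the node's Gaussian log-likelihood minus a BIC charge of
`(log n)/2` per added basis degree of freedom; insertion stops when no
admissible edge (acyclicity, ≤ 4 parents) has positive gain. The BIC
charge is essential: the raw likelihood gain of an unpenalized
regression is strictly positive for every candidate, so an unpenalized
stop-at-zero rule would never halt, and the penalized rule is also what
delivers correct null behaviour (no edges on independent data).

Pruning avoids using the same data for selection and testing: each of
B = 100 random 50/50 splits learns the structure on one half and, on
the other half, tests each learned parent by the F-test of dropping its
basis columns from the node's regression. Per-edge p-values are
aggregated across splits by the quantile rule
`Q(γ) = min(1, q_γ({p_b/γ}))` at γ = 0.5 — twice the median, capped at
one — with splits that did not learn the edge contributing p = 1
(absence is evidence against the edge). Edges survive at
p ≤ α = 0.0005. Aggregation is a set operation, so split order is
irrelevant, and a fixed master seed reproduces the graph exactly.

## Stacked spatial prediction

Random forest and gradient boosting (learning rate fixed at 0.05; its
effect trades off against the number of iterations) are tuned
independently by inner cross-validation over n_estimators,
max_features, max_depth and min_samples_leaf, and combined by simple
averaging — the stack prediction is exactly the mean of the two
components, hence bounded by them. Outer folds score the selected
stack on held-out sites; the whole nested procedure is repeated with
fresh splits and the reported R²/RMSE are means over repeats. The
shipped model is refit on all data with the modal hyperparameters
across outer folds (the nested procedure itself does not single out
one configuration). The documented default grid (trees {200, 500},
max_features {1/3, √p, all}, depth {None, 10, 20}, leaf {1, 3, 5}) is
a package choice; the acceptance script and tests use a reduced grid
with 5 folds and 3 repeats, which keeps the full pipeline run in a few
minutes on one CPU without changing the estimator's structure.

Prediction rasters are plain-text ESRI ASCII grids (nodata −9999),
with predictions only where every covariate layer is finite.

## Synthetic studies: what they emulate, and what they do not

The generator plants the statistical structure the analysis assumes:

* **Abundance pool**: lognormal relative abundances (σ_log = 2.0) over
  5,000 taxa, so most taxa are globally rare — the family is a
  modelling choice, as amplicon data do not identify it.
* **Weather**: wet-day occurrence log-uniform in frequency along an
  aridity gradient (rain frequency spans orders of magnitude between
  deserts and humid biomes), gamma-distributed wet-day amounts,
  latitude-driven seasonal temperature and radiation.
* **Soils**: Dirichlet texture (closing exactly to 1), uniform bulk
  density and CEC, lognormal organic carbon. pH is a decreasing linear
  function of the *realized* CWC plus Gaussian noise whose variance is
  calibrated from the sample variance of the deterministic part so the
  realized coefficient of determination matches the 0.61 target.
* **Richness**: `round(S_max · f(CWC) · g(pH) · e^ε)` with Gaussian
  bumps f (peak 0.175, width 0.12, floor 0.35) and g (peak 7, width
  1.5, floor 0.40) and log-normal noise (SD 0.15) that leaves variance
  the models should not explain. S_max defaults to 40% of the pool.
* **Rare suppression**: taxa below 0.005% global relative abundance
  have their site-inclusion weight multiplied by
  `max(0, 1 − (rare_sensitivity − 1)·4·max(0, CWC − 0.175))`, the
  simplest mechanism producing a steeper decline of rare than common
  taxa towards wet soils. Site taxa are drawn by Gumbel top-k weighted
  sampling without replacement; reads are multinomial at fixed depth,
  so column sums equal the read depth exactly.
* **Design**: 320 sites, 1–4 samples per site (~2.5 on average, so
  ~840 samples aggregate back to ~320 cells), two years of daily
  weather, a small fraction of Archaea (1.5%) and kingdom-unassigned
  (0.5%) labels to exercise the filter.

All randomness flows from one seed through keyed generator streams;
identical configurations reproduce bit-identical studies.

Passing the planted-recovery tests shows the *estimators* do what they
claim under the assumed structure. It does not show that real soil
communities follow lognormal abundance, Gaussian response curves or
additive noise; nor does the generator emulate sequencing error,
primer bias, compositional artefacts, spatial autocorrelation of
residuals, or real geographic climate fields. Fitted univariate R²
on synthetic studies (~0.5) runs higher than in field data (~0.25–0.3),
because real covariates are measured at mismatched spatial supports —
an error source deliberately not simulated.

## Known limitations

* The GAM scale of inference is Gaussian on richness; a log-link
  alternative is a config switch away conceptually but only the
  Gaussian family is implemented.
* CAM assumes no hidden confounders and additive mechanisms; the
  multi-split p-values are conditional on the learned half-sample
  structures.
* LOO re-estimates coefficients, not smoothing parameters; fully
  re-smoothing each fold would be slower and usually indistinguishable.
* The rarefaction-depth criterion and the CWC closed form are
  documented interpretations of under-specified procedures; both are
  isolated behind single functions with the alternatives reachable
  through their arguments.
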