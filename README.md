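# soilrich

Global biogeography of soil bacterial richness: an end-to-end, tested
pipeline linking soil-climate physics to 16S amplicon diversity.

## The scientific problem

Soil bacterial richness varies enormously across biomes, and the most
commonly cited driver — soil pH — is strongly entangled with climate:
humid regions tend to be acidic and arid regions basic. This package
implements an analysis chain built around a composite covariate, the
**climatic water content (CWC)**, that describes the typical wetness
state of the top metre of soil:

* **PET** (potential evapotranspiration, Jensen–Haise):
  `PET = max(0, (0.025·T + 0.08) · R_s / λ_w)` with `λ_w = 2.45 MJ kg⁻¹`,
  clipped at zero where the empirical formula goes negative;
* **DRY**: the mean spacing in days between rainfall events, where an
  event is a day whose precipitation exceeds the daily-equivalent mean
  annual PET (DRY may exceed one year in deserts);
* **AWC**: available water capacity from a linear pedotransfer function
  of clay, silt, organic carbon and bulk density only (no soil
  chemistry, so AWC cannot leak pH information);
* **CWC**: the store refills to AWC at each rain event and dries
  exponentially under PET; its time average over a dry spell of length
  DRY is `CWC = AWC · (1 − e^(−k·DRY)) / (k·DRY)` with
  `k = (PET/365.25)/(AWC·1000)` per day.

Diversity is estimated by **repeated rarefaction** (depth chosen by grid
search over 2,500–15,000; 100 repetitions averaged) with **Hill
numbers** `^qD = (Σ pᵢ^q)^(1/(1−q))` and a **rare/common log-ratio**
`ln(n_rare/n_common)` splitting taxa at 0.005% global relative
abundance. Samples aggregate into 0.1° × 0.1° sites. Richness–
environment relationships are fitted with penalized-spline **additive
models** (REML smoothing, double-penalty shrinkage, AIC forward
selection, leave-one-out validation), direct vs indirect drivers are
separated by **causal additive model** structure learning with
multi-split pruning (p ≤ 0.0005), and spatial prediction uses a
**stacked random-forest + gradient-boosting** model (learning rate
0.05) validated by nested cross-validation.

Because the original ~8,000-sample sequence corpus and global raster
products are not desk-reproducible, the package ships a first-class
**synthetic-study generator** that emulates the statistical structure
of the real data — a lognormal species-abundance pool, unimodal
richness responses peaking at CWC ≈ 0.175 and pH ≈ 7, a pH–wetness
coupling calibrated to R² ≈ 0.61, and a suppression of globally rare
taxa in wet soils — so every stage can be validated against planted
truth.

## Worked example

```python
import numpy as np, pandas as pd
from soilrich import SimulationConfig, simulate_study
from soilrich.climate import cluster_covariates
from soilrich.gam import fit_gam, forward_select, loo_cv

study = simulate_study(SimulationConfig(seed=4))      # 320 sites
cov = study.covariates
rich = (study.asv_table.counts > 0).sum(axis=0)
y = (rich.groupby(study.asv_table.sample_meta["site"]).mean()
     .loc[cov.index].to_numpy())

fit = fit_gam(y, cov[["CWC"]])
grid = np.linspace(cov["CWC"].min(), cov["CWC"].max(), 400)
peak = grid[np.argmax(fit.predict(pd.DataFrame({"CWC": grid})))]
print(fit.adj_r2, fit.edf["CWC"], peak)

path = forward_select(y, cov[cluster_covariates(cov).retained])
print(path.as_frame())
```

Output (seed 4):

```
univariate richness~s(CWC): adj R^2 56.8%, EDF 3.9, fitted peak at CWC 0.191 (planted 0.175)
 step covariate  delta_aic  lrt_p
    1       CWC   -265.080  0.000
    2        PH    -48.010  0.000
    3       BLD     -0.424  0.116
    4       CEC     -0.026  0.335
    5       MAP     -0.080  0.161
final model LOO R^2 62.4%, RMSE 140 taxa
```

The smooth of richness on CWC recovers the planted optimum (0.191 vs
0.175, inside the generator's noise); CWC enters the forward-selection
path first and with by far the largest AIC drop, ahead of pH — the
hierarchy the analysis is designed to expose. The `examples/` directory
holds one short script per capability (simulation, covariate
derivation, diversity estimation, additive models, causal graph,
stacked mapping); each prints the numbers it computes and what they
mean. A thin CLI mirrors the same stages
(`soilrich simulate|covariates|diversity|fit-gam|cam|predict-map`).

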