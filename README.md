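# submort

Joint Bayesian estimation of age-specific mortality rates for multiple
subpopulations in small subnational areas.

## The problem

Age-specific death rates for counties (or any small administrative areas),
split further by sex or another demographic dimension, cannot be read off
raw counts: most cells hold a handful of deaths, many hold zero, and the
resulting crude rates jump erratically over age.  `submort` implements a
Bayesian hierarchical principal-components model that stabilizes these
estimates by pooling in three directions at once — over age (mortality
schedules are combinations of a few characteristic shapes), over areas
within a jurisdiction (a shared, temporally smoothed mean), and **across
subpopulations within an area** (explicitly estimated correlation
matrices, instead of the usual independence assumption).  The correlation
estimates are themselves interpretable outputs: they show which features
of mortality move together across groups, and where they decouple.

## The model

Deaths follow a Poisson likelihood with person-year exposures
$P_{a,s,c,t}$ as offsets, and the log rate is a small linear combination
of principal-component age schedules $Y_i$ plus an age-specific
overdispersion term:

$$y_{a,s,c,t} \sim \mathrm{Poisson}(P_{a,s,c,t}\lambda_{a,s,c,t}), \qquad
\log\lambda_{a,s,c,t} = \sum_{i=1}^{P} \beta_{i,s,c,t} Y_{i,a} + \gamma_{a,s,c,t}.$$

Coefficients decompose as $\beta = \mu_\beta + \omega$: group-level means
$\mu_\beta$ follow a second-order random walk over time, and area
deviations $\omega$ (per component) and overdispersion $\gamma$ (per age
group) are multivariate normal over the $S$ subpopulations with
LKJ(1)-distributed correlation matrices — the joint structure.  The basis
$Y$ comes from the uncentred SVD of a reference matrix of log-mortality
schedules.  Sampling is by the No-U-Turn Sampler with hand-derived
analytic gradients (non-centred parameterization; see
`docs/methods.md`).

## Worked example

Simulate a small three-subpopulation dataset, fit the joint model, and
look at the estimated cross-subpopulation correlations:

```python
import numpy as np
from submort import (
    SimulationConfig, generate_dataset, basis_from_curves,
    MortalityPCModel,
)

cfg = SimulationConfig(n_areas=8, n_years=5, n_subpops=3, n_ages=6, seed=1)
data, truth = generate_dataset(cfg)          # deaths, exposures + known truth
basis = basis_from_curves(truth.curves)      # standard curves as the basis

model = MortalityPCModel(n_components=2, chains=2, warmup=250,
                         samples=250, seed=11, adapt_delta=0.9)
model.fit(data, basis)

rates = model.predict_rates(levels=(0.95,))
print(rates.head(3)[["age_group", "subpopulation", "area",
                     "rate_median", "rate_lower_95", "rate_upper_95"]])

corr = model.correlation_summary()
pc1 = corr[(corr["kind"] == "beta") & (corr["index"] == "PC1")]
print("PC1 correlation, posterior median over years:",
      round(pc1["median"].mean(), 2))
```

Output from this exact script:

```
  age_group subpopulation     area  rate_median  rate_lower_95  rate_upper_95
0     age_0       group_1  area_01     0.021455       0.019019       0.023929
1     age_0       group_1  area_01     0.014089       0.012179       0.016005
2     age_0       group_1  area_01     0.017395       0.014778       0.019766
```

```
PC1 correlation, posterior median over years: 0.8
```

The first table gives the posterior median and 95% interval of the
mortality rate for the infant age group of the smallest subgroup in the
first area's first three years — the point estimates and their uncertainty
that a raw-count analysis cannot provide for sparse cells.  The second number is the posterior median correlation
between subpopulation deviations on the first (overall-level) component:
the generator used 0.9, and the model recovers a strong positive estimate
from eight areas of data.

The same pipeline is available from the shell:

```bash
submort simulate --config sim.yaml --seed 5 --out run/
submort fit --data run/dataset.csv --basis run/standard_curves.csv \
        --chains 4 --warmup 500 --iter 2500 --seed 1 --out run/fit/
submort holdout --data run/dataset.csv --fraction 0.2 --seed 2 --out run/ho/
```

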