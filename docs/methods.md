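# Methods

## The estimation problem

Death counts in small subnational areas, split further by demographic
subgroup, are too noisy to convert directly into age-specific mortality
rates: many age–subgroup–area–year cells hold zero or near-zero deaths even
when the underlying risk is far from zero.  `submort` estimates the full
age schedule of mortality jointly for several subpopulations per area by
combining three sources of regularity: (i) mortality age schedules are
well described by a few principal-component shapes; (ii) areas within a
larger jurisdiction resemble each other; and (iii) subpopulations within an
area experience correlated shocks.  The third ingredient — modelling the
cross-subpopulation correlation instead of assuming independence — is the
distinguishing feature of the model.

## Model

For age group $a$, subpopulation $s$, area $c$ and year $t$:

$$y_{a,s,c,t} \mid \lambda_{a,s,c,t} \sim \mathrm{Poisson}(P_{a,s,c,t}\,\lambda_{a,s,c,t})$$

$$\log \lambda_{a,s,c,t} = \sum_{i=1}^{P} \beta_{i,s,c,t} Y_{i,a} + \gamma_{a,s,c,t}$$

where $P_{a,s,c,t}$ is the person-year exposure (mid-year population), the
$Y_i$ are principal-component age schedules, and $\gamma$ is an additive
age-specific overdispersion term.  Coefficients split into a group-level
mean and an area deviation, $\beta_{i,s,c,t} = \mu_{\beta_{i,s,t}} +
\omega_{i,s,c,t}$.  Across the $S$ subpopulations of one area,

$$\omega_{i,\cdot,c,t} \sim \mathcal N_S\!\big(0,\; \sigma_{\beta_{i,t}}^2\, L^{(\beta)}_{i,t} L^{(\beta)\top}_{i,t}\big),\qquad
\gamma_{a,\cdot,c,t} \sim \mathcal N_S\!\big(0,\; \sigma_a^2\, L^{(\gamma)}_{a,t} L^{(\gamma)\top}_{a,t}\big),$$

with LKJ(1) priors (uniform over valid correlation matrices) on every
Cholesky factor, half-normal(0, 1) on $\sigma_{\beta_{i,t}}$, and
half-normal(0, 0.25) on the age-specific $\sigma_a$.  Group-level means are
smoothed over time by a second-order random walk,
$\mu_{\beta_{i,s,t}} \sim \mathcal N(2\mu_{\beta_{i,s,t-1}} -
\mu_{\beta_{i,s,t-2}}, \sigma_{\mu_{\beta_i}})$ with improper flat priors
on the first two time points and
$\sigma_{\mu_{\beta_i}} \sim \text{log-Normal}(-1.5, 0.5)$.

### Basis construction

The $Y_i$ are right singular vectors of an **uncentred** $N \times A$
matrix of reference log-mortality schedules.  Uncentredness is deliberate:
the first component then carries the overall level of mortality, so a
single coefficient shifts a whole curve.  Under the default sign
convention, component 1 is oriented elementwise non-positive (the "J"
shape of log mortality: a component-1 coefficient increase lowers
mortality everywhere) and component 2 is oriented positive at young-adult
ages (the accident hump).  The orientation rule is: flip component 1 if
its mean entry is positive, flip component 2 if its entry at the 20–24 age
position (or one third of the way through the age range when labels do not
identify that group) is negative; matching left-singular-vector columns are
flipped too, so all products — and the likelihood — are unchanged.
Component-count diagnostics are the variance-explained profile and Welch
two-sample location tests on the left singular values split by
subpopulation: a component whose coefficients separate by subpopulation
carries structure worth modelling.

### Identifiability of beta versus gamma

Both $\beta$ and $\gamma$ enter the linear predictor additively, so an
age-schedule deviation of magnitude below the overdispersion prior scale
(0.25) can be represented either way.  The model follows the original
specification: the tight half-normal prior on $\sigma_a$ keeps $\gamma$
small, and $\gamma$ is interpreted as residual age-specific deviation.  No
sum-to-zero constraint is imposed.

## Inference

Posterior sampling uses the No-U-Turn Sampler (dynamic Hamiltonian Monte
Carlo with slice-sampled tree doubling, Hoffman & Gelman 2014 Algorithm 6)
implemented in `submort._nuts`, with Stan-style warmup: dual-averaging
step-size adaptation, expanding memoryless windows estimating a diagonal
metric, and a terminal step-size phase.  The gradient of the log posterior
is computed analytically in `submort._posterior` and is verified against
finite differences in the test suite under every configuration flag.

Parameterization choices that matter for sampling geometry:

- **Non-centring.**  All hierarchical vectors are sampled as standard
  normal innovations: $\omega = \sigma_\beta L^{(\beta)} z$,
  $\gamma = \sigma_a L^{(\gamma)} z$.  With sparse data the centred
  geometry is a funnel; non-centring makes it nearly isotropic.
- **Scales on the log axis**, with Jacobians folded into the density (the
  log-normal prior on $\sigma_\mu$ becomes exactly normal on
  $\log\sigma_\mu$).
- **Correlation Cholesky factors** via tanh-transformed canonical partial
  correlations (the C-vine construction of Lewandowski, Kurowicka & Joe).
  The LKJ(η) prior has the closed form $\sum_e c_e \log(1-z_e^2)$ in the
  unconstrained space with $c_e = \eta + (S-1-k_e)/2$ for an edge in
  column $k_e$ (1-indexed); for $S=2$, $\eta=1$ this makes the implied
  correlation exactly uniform on $(-1,1)$, which the tests verify by
  simulation, as well as the Beta$((S+1-k)/2,\cdot)$ marginals for larger
  $S$.
- **Initialization.**  Group means start at the least-squares projection of
  pooled crude log rates onto the basis; innovations start near zero;
  chains are jittered.  Defaults: `adapt_delta=0.95`, `max_treedepth=10`,
  4 chains × 500 warmup + 2500 retained draws (no thinning).  Reduced
  chain lengths are used in the packaged experiments; see below.

Cells with zero exposure are excluded from the likelihood (their rate
remains defined by the linear predictor).  Divergent transitions and split
R-hat above 1.01 are recorded in the fit metadata and raised as warnings,
never silently dropped.  R-hat and effective sample sizes come from arviz.

Degenerate inputs handled explicitly: constant chains yield NaN
diagnostics rather than an exception; a single chain is rejected for
R-hat; trajectories that overflow the Poisson mean are treated as
divergent (log density $-\infty$), so the sampler rejects them.

## Synthetic data

The generator (`submort.simulate`) emulates the recovery-study design: 25
areas over 10 years with 5 subpopulations at shares (0.10, 0.10, 0.15,
0.15, 0.50) — endpoints matching the 10%–50% range of the study design; an
exact linear gradient from 10% to 50% cannot sum to one.  True log rates
are linear combinations of two standard curves: a J-shaped baseline
(infant mortality elevated, childhood minimum near $e^{-8.2}$, Gompertz
rise to the oldest group) and a unit-peak young-adult hump.  Subpopulation
coefficients are drawn multivariate normal around subpopulation means with
known correlation matrices: exchangeable 0.9 for the level coefficient and
a signed block pattern (within-block 0.8, cross-block −0.3) for the hump
coefficient.  Deaths are Poisson; exposures come from log-uniform area
populations spread over a mildly declining age pyramid.

Two generator defaults are set on identifiability grounds rather than
taken from any published table (the original study's generating constants
are not public).  First, the hump-coefficient spread is 0.35: the
overdispersion term can absorb any age-pattern deviation smaller than its
prior scale (0.25), so a recovery experiment with sub-0.25 coefficient
deviations would ask the data a question they cannot answer — the
correlation posterior would simply reproduce its prior.  Second, area
populations default to $5\times10^4$–$5\times10^6$ so that young-adult
cells in mid-sized areas hold enough deaths for the per-area hump
coefficient to be estimated with error smaller than its cross-area spread
(a Fisher-information argument: the coefficient's information is
$\sum_a Y_{2,a}^2\, P_a \lambda_a$, which must exceed
$1/\text{scale}^2$).  With these defaults, expected deaths per cell range
from under one (young ages, small areas, small subgroups) to thousands.

What the generator does **not** emulate: real age-misclassification,
migration-driven exposure error, time-varying subgroup shares,
time-varying true correlations (supported via configuration, off by
default), or spatially structured (CAR-type) dependence between areas.
Passing recovery tests therefore demonstrate correctness of the
implementation under the model's own assumptions, not robustness to
real-data artifacts.

## Validation metrics

Entrywise coverage is the fraction of true values inside their equal-tailed
posterior intervals, $\tfrac1n\sum_i \mathbf 1\{l_i \le \theta_i \le
u_i\}$ (closed intervals), applied to the lower-triangle off-diagonals of
the correlation matrices and to all true log rates.  Hold-out validation
masks 20% of each area's observed death counts (exposures stay observed —
they come from a census-type source), refits, draws one Poisson count per
posterior rate draw for each masked cell, and reports MAD and MSE of the
predictive medians plus coverage of the predictive intervals at 80/90/95%.
The "independent" comparison model is the same code with every
cross-subpopulation correlation matrix fixed to the identity — a controlled
ablation isolating the contribution of the joint structure.

## Packaged experiment sizes

The recovery study in `scripts/acceptance.py` and the acceptance tests run
the full 25-area × 10-year × 5-subpopulation design with A = 10 age groups
and 2 chains × (250 warmup + 250 retained) draws; the hold-out comparison
uses a smaller strongly-correlated design (8 areas, 5 years, 3
subpopulations).  These problem sizes were chosen so a complete run
finishes in minutes on one CPU while keeping enough entries for stable
coverage estimates.  Because the generating correlations are
time-constant, the recovery fit shares one correlation matrix per
component (and per age group) across years — the configuration the model
description itself recommends for time-invariant correlation structure;
with per-year matrices each correlation is informed by only 25 area
deviations and its posterior is visibly pulled toward the LKJ prior's
near-zero marginals, attenuating recovery.

## Known limitations

- The NUTS implementation uses a diagonal metric; strongly correlated
  posteriors (tiny datasets with huge counts) can force deep trajectories.
- Entrywise coverage for a *fixed* generating correlation pattern is not
  guaranteed to equal the nominal level: with weakly informative data the
  Bayesian interval is calibrated only on average over the prior, and the
  generating values 0.9/0.8 sit in the tail of the S=5 LKJ marginal.
  Conversely, with highly informative data (correlations shared over
  years) the intervals become narrow enough that the small recovery bias
  introduced by the overdispersion block — which can absorb part of any
  correlated deviation — dominates them, so correlation coverage varies
  substantially across generator seeds even when the recovered medians
  are accurate to a few hundredths.  Log-rate coverage does not share
  this fragility.
- The RW2 prior leaves the first two time points improper; with the
  likelihood removed entirely (prior-recovery checks) those directions are
  ballistic for HMC and require a tree-depth cap.
- One model fit covers one area group (one "state"); multi-state analyses
  are shell loops over invocations, not internal parallelism.
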