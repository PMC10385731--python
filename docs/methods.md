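# Methods

## Model

The package models the size of an individual tree (DBH in cm or height in
m) as a bounded function of age `T` with environment entering through the
curve's parameters.  The base curve is the Mitscherlich (monomolecular)
form `y = a·(1 − e^(−b·T))`: size rises from zero toward an asymptote `a`
at relative rate `b`, with no inflection point — a reasonable description
of diameter growth after establishment in even-aged plantation conditions.
Three alternatives (Gompertz, Logistic, Richards) are fitted and ranked by
test R² (ties resolved by RMSE, then by parameter count) before the base
form is committed to.

Re-parameterization replaces `a` and `b` by linear predictors
`ω0 = α0 + Σ αᵢxᵢ` (response units) and `ω1 = β0 + Σ βᵢxᵢ` (per year) over
plot covariates: stand density `N` (stems per ~667 m² plot, the
competition proxy), site factors, and annual climate variables.  One
variable list is shared by ω0 and ω1; coded site factors (slope position
PW, landform DM, …) enter as their numeric survey codes, carrying a single
coefficient each.  The model is deliberately linear in covariates: it
stays interpretable, nests the age-only curve (all αᵢ = βᵢ = 0 for i ≥ 1),
and keeps the parameter count small relative to the number of plots.
Nothing constrains ω0, ω1 > 0 for arbitrary covariates; predictions carry
a validity flag instead, because a hard constraint would hide
extrapolation problems rather than reveal them.

### Fitting

`fit_rp` minimizes the sum of squared residuals of `ω0·(1 − e^(−ω1·T))`
with `scipy.optimize.least_squares` (trust-region reflective).  Covariates
are standardized internally — raw covariate scales differ by five orders
of magnitude (elevation in hundreds of metres vs. rate coefficients of
1e-6 per unit) and an unscaled Jacobian is numerically hopeless — and the
coefficients are transformed back to raw scale for reporting.  The start
point takes (α0, β0) from the age-only fit with all covariate coefficients
zero; up to five seeded restarts perturb it before the result is flagged
non-convergent (flagged, never silently dropped).  Tolerances are 1e-14 on
step, cost and gradient, which on noiseless data recovers generating
coefficients to machine precision and comfortably inside the 0.1 % band
the tests assert.

### Covariate screening

Three screens are exposed independently and composed in the default
pipeline:

* **Impurity importance.**  Random-forest mean decrease in impurity; for a
  continuous response the split criterion is variance reduction (regression
  trees have no Gini index — the field's phrase "Gini importance" is
  classification vocabulary, which is worth stating plainly).  The ranking
  forest regresses the response on age, density and *both* covariate
  groups, then renormalizes importances within the group of interest.
  Using one group at a time instead lets continuous site variables act as
  proxies for plot-level climate variance (and vice versa) and badly
  inflates noise variables: with a few hundred plots, any nearly
  plot-unique continuous covariate can memorize plot identity.  For the
  same reason the ranking forest uses generous leaves (min 40 samples) and
  draws 60 % of features per split; the feature subsampling lets strongly
  correlated proxies share split credit the way a practitioner's mtry
  does.
* **Correlation screen.**  Within a ranked group, pairs with |r| > 0.7 are
  resolved in descending |r| by dropping the lower-importance member; any
  variable dropped this way is afterwards reinstated if it is no longer
  strongly correlated with anything retained.  Without reinstatement a
  variable can be eliminated by a proxy that is itself eliminated one step
  later — e.g. reference evaporation knocked out by the coldest-month
  temperature just before that temperature is removed as redundant with
  the heat sum — which leaves the survivor set depending on sample-level
  ordering accidents.  The screen compares |r|: negative collinearity is
  as harmful as positive.
* **VIF and stepwise AIC.**  VIFⱼ = 1/(1 − R²ⱼ) from regressing column j on
  the others with intercept (computed directly via least squares; the
  common library shortcut omits the intercept and overstates VIF for
  uncentered data); iterative elimination runs while max VIF ≥ 5, dropping
  the later-listed column on ties.  Stepwise selection is both-direction
  over the nonlinear model itself with AIC = n·ln(SSE/n) + 2k, k counting
  all free α/β coefficients (two per variable plus two intercepts); a
  variable enters or leaves ω0 and ω1 together.

### Machine-learning baselines

The BP network is a three-layer perceptron: logistic hidden units,
identity output, hidden width from the sizing rule
`floor(sqrt(n_in + n_out)) + m` with `m = 3` by default (10 inputs → 6
hidden nodes).  Inputs and output are min–max scaled to [0, 1] with bounds
frozen from the training split; training runs epoch-by-epoch with
adaptive-moment gradient updates at learning rate 0.01 and stops when the
training MSE on the scaled output reaches 0.001 or after 1000 epochs.
That target-loss threshold is an accuracy floor by construction: on a
response spanning ~17 units it corresponds to an RMSE near 0.5 units, so
sanity checks that need near-interpolation train with a tighter target.

The random forest uses bootstrap-resampled regression trees, `mtry`
features per split, minimum leaf of 5 and mean-of-trees prediction;
defaults ntree = 160, mtry = 4.  The tuner grids ntree over {1, 20, 40, …,
500} and mtry over 1..10 with k-fold RMSE, breaking ties toward smaller
ntree then smaller mtry.  On the synthetic conditions the cross-validated
optimum sits at large mtry (a single dominant age signal rewards greedy
split selection); the p/3 rule of thumb is what it is — a heuristic.

All three methods are compared on the four-rung nested ladder f(T) ⊂
f(T, Comp) ⊂ f(T, Comp, Site) ⊂ f(T, Comp, Site, Clim) with one shared
seeded 80/20 observation-level split.

### Evaluation

R² defaults to 1 − SSE/SST, the quantity consistent with "the model
explains X % of the variance"; the explained-variance ratio
Σ(ŷ−ȳ)²/Σ(y−ȳ)², which exceeds 1 for over-dispersed biased predictors, is
available as a variant.  Percent improvements are rounded half away from
zero to one decimal.  Heteroscedasticity is summarized numerically as the
ratio of residual standard deviations across equal-population bins of the
predicted value.  Group importance sums cross-validated forest importances
within {T, Comp, Site, Clim} and scales to 100 %.

## Data cleaning and splitting

The Pauta (3σ) filter treats the plot as the unit: within each plot the
response mean and sample standard deviation (n − 1 denominator) are
computed once on the original values and observations deviating by more
than three standard deviations are removed in a single pass.  Iterating to
convergence would make the result depend on removal order; plots with
fewer than three observations pass through, since their sample sd is
meaningless.  The train/test split is by observation with an explicit
seed; a by-plot option exists for leakage-averse workflows but is off by
default.

## The synthetic generator

Because the original survey data are not public, the generator is the
package's study system.  It emulates: ~667 m² plots resurveyed at 5-year
intervals (4 surveys for DBH, 3 for H); site factors drawn independently
and uniformly within the published ranges with the survey coding scheme
(landform 3–5, aspect 1–8, slope position 1–6, soil 12/13); 17 annual
climate variables drawn from a clipped multivariate normal whose
correlation matrix encodes a subtropical warm/wet gradient — mean annual
temperature strongly tied to coldest-month temperature, evaporation and
precipitation (r = 0.76–0.85), coldest-month temperature to the heat sum
and evaporation — with weaker fill-in values chosen to keep the matrix
positive semi-definite; and responses drawn from the RP law plus Gaussian
noise (2 cm for DBH, 1 m for H, matching residual spreads of ±6 cm / ±3 m
at the three-sigma level), floored at a small positive value.

Ages follow an even-aged plot structure: a plot age uniform on [4, 26] for
DBH (so that four 5-yearly surveys stay within the published 4–41 range
and the mean age lands near 23), ±3 years of per-tree jitter; a mixed-age
option draws per-tree ages independently.  Plots whose sampled covariates
would make ω0 or ω1 non-positive are resampled with a warning.

The default generating coefficients are a **synthetic truth**, not the
published estimates.  The published vectors (shipped untouched as fixtures
and used directly in the parameter-recovery tests) cannot serve as a
generative law for importance experiments: multiplied by the published
covariate ranges, their standardized contributions are dominated by
evaporation and soil thickness, which contradicts the importance structure
the study reports.  The default truth instead fixes per-covariate
standardized asymptote contributions (in cm: heat sum 3.8, slope position
3.0, elevation 2.2, precipitation and soil thickness 1.7, aspect 1.6,
landform 1.4, evaporation 1.1, density 0.8; signs: density, slope
position, elevation and landform negative) with a mean asymptote of 22 cm
and a constant rate of 0.045/yr.  Slope aspect and precipitation get real
effects although the RP variable list omits them — the screening stage is
supposed to discover them.  Slope gradient and soil name are pure noise.
The default size is 800 plots × 3 trees × 4 surveys: the covariate signal
lives at plot level, and a few hundred plots are the minimum at which
importance rankings stabilize; this is deliberately denser than a single
county's CFI grid.

What the generator does **not** emulate: spatial structure and
distance-dependent competition, mortality and recruitment, measurement
error in age, non-Gaussian residuals, plot-level random effects beyond
what the covariates induce, and genuine climate time series (climate is a
static plot attribute).  Tests passing on this generator therefore show
the pipeline's correctness and its qualitative behaviour under known
ground truth — not that the fitted coefficients or accuracy levels carry
over to real inventories.

## Numerical choices and degenerate inputs

* Growth-curve fits start from a₀ = 1.05·max(y) and a log-linearized rate;
  bounded multi-start (5 seeded restarts) precedes any non-convergence
  flag.  Constant-response data yield a flagged degenerate rate.
* Perfect collinearity reports VIF = ∞ rather than raising.
* Pearson matrices flag constant columns as NaN with a warning.
* Equal-population residual bins merge duplicate quantile edges.
* The sample standard deviation (ddof = 1) is used wherever a plot-level
  spread is estimated.
* All stochastic components (generator, splits, forests, network
  initialization, restarts) take explicit integer seeds; identical seeds
  give byte-identical CSV output.

## Known limitations

* The stepwise-AIC search refits the nonlinear model per candidate move;
  it is quadratic-ish in the candidate count and meant for the ~10-variable
  setting it serves.
* AIC assumes independent observations; repeated surveys of one tree
  violate this, so the selection is liberal on clustered data (a caveat
  inherited from the emulated workflow, which uses the same criterion).
* The BP baseline is a fixed three-layer architecture; it is a comparison
  point, not a tuned deep model.
* Height and diameter are modelled independently; no allometric coupling.
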