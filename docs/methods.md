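# Methods

This note documents the statistical models implemented in `foreststab`,
the choices made where the design was genuinely open, and what the
synthetic-data validation does and does not demonstrate.

## Relative density and the stability index

For a population of trees within a stand of community type *i*, relative
density is the tree-level sum RD = Σ_h N_h / N_max(s_h), where N_h is the
stems-per-hectare represented by tree *h* under the plot design and
N_max(s) = a_i·s^{r_i} is the type's maximum size-density frontier
evaluated **at the tree's own size**. Two consequences drive the design:

* **Exact additivity.** Any partition of the tree list — species,
  size-class deciles — has RDs that sum exactly to the whole. Size-class
  change estimates therefore decompose the whole-species estimate without
  approximation error.
* **No aggregation bias.** The aggregate index TPH/N_max(S̄) equals the
  tree-level sum only when all trees are the same size; for 0 < |r| < 1 it
  is strictly larger otherwise (Jensen's inequality on the concave s^{|r|}),
  inflating apparent stocking in uneven-sized stands. The package computes
  the tree-level form everywhere; the aggregate form is provided only for
  bias diagnostics.

RD is deliberately **not capped at 1**: the frontier is a 99th conditional
percentile, so about 1% of legitimate stands sit above it, and capping
would bias change estimates downward.

FSI = ΔRD/Δt per year. %FSI = 100·FSI/RD_t1 is computed **only at the
population level**, as the ratio of the mean FSI to the mean baseline RD.
Plot-level ratios are undefined by design wherever a population appears on
a previously empty plot (range expansion, RD_t1 = 0), and a ratio of means
is the estimand the index is meant to summarise. Conversion of %FSI to a
study-period total is linear (%FSI × years), which makes −100/18 ≈
−5.56 %/yr the floor corresponding to complete loss over an 18-year window.

## Frontier estimation

The frontier is fit in log-log space: the 99th percentile of log TPH given
log S̄, with intercept and slope varying by forest community type. Choices:

* **Working likelihood.** Asymmetric Laplace at τ = 0.99, the standard
  Bayesian quantile-regression device; its location parameter converges to
  the conditional quantile regardless of the true error law.
* **Priors.** Intercept (log a at S̄ = 1 m²) normal(7, 1); exponent r
  normal(−0.8025, 0.1). The exponent prior is the Reineke-type expectation
  expressed on mean basal area (TPH ∝ QMD^−1.605 ⟹ exponent −0.8025 on
  basal area) and is **negative**, consistent with r < 0 in the model
  definition. Type deviations for both parameters are exchangeable
  normal(0, σ) with half-normal(1) hyperpriors (partial pooling keeps rare
  types sane); the AL scale gets a half-Cauchy(1).
* **Eligibility.** Training stands are the most recent census of each plot
  with no disturbance or silvicultural treatment in the interval or the
  preceding 5 years, and Pearson moment skewness g1 (n-denominator central
  moments, on the unweighted measured DBH list) inside the closed interval
  [−1, 1]. Stands with fewer than three measured stems cannot be screened
  for shape and are excluded from training (they remain in change
  analysis).
* **Sampling.** Several (default 4) independent emcee ensembles with
  differential-evolution moves; the covariate is centred during sampling
  (the intercept/slope posterior at an extreme quantile is otherwise a
  near-degenerate ridge) and type deviations are non-centred (σ·ũ) to avoid
  the usual funnel. Convergence is judged by split-R̂ **across the
  independent ensembles** (walkers within one ensemble interact and are not
  valid chains); R̂ > 1.05 flags the model rather than raising. Point
  predictions use posterior medians, robust under the skewed AL posterior.

Identification notes: with ~2000 stands only ~20 lie above a 99th
percentile line, so the likelihood alone leaves a sizeable ridge-shaped
uncertainty (intercept and slope errors correlated through the data
centroid near S̄ ≈ 0.02 m²); the informative exponent prior resolves most of
it. Per-type intercepts quoted at S̄ = 1 m² are extrapolations ~4 log-units
from the data and carry correspondingly wider uncertainty than predictions
at typical stand sizes, which is what the RD ratios actually consume.

## Population estimation

Plot-level FSI records are combined with the standard post-stratified
estimators: mean Σ_s W_s ȳ_s and variance Σ_s W_s² s_s²/n_s with known
stratum area weights W_s. Strata observed with a single plot are collapsed
into the heaviest co-occurring stratum (sample variance is undefined at
n = 1; weights pool). Estimates are computed separately per annual
remeasurement panel and combined by the equal-weight moving average (mean
of panel means; variance Σvar_p/P²). 95% intervals are normal-theory
(±1.96 SE); classification is declining/expanding/stable according to
whether the FSI interval lies below, above, or across zero.

%FSI uncertainty uses the first-order delta method for the ratio of two
correlated means, with the plot-level FSI–RD_t1 covariance carried through
both estimation stages (post-stratified covariance per panel, then panel
averaging). The species *range* is the set of areal subsections with at
least one detection at either census; range-averaged estimates are
restricted to in-range plots, and absent populations on in-range plots
enter as exact zeros (RD 0 → 0), which is what makes the range average a
net measure of performance including expansion.

## Disturbance attribution

Two models are fit independently per species and multiplied:

* **Severity.** y_k ~ normal(α + Σ_l β_l x_lk, ς²) with binary interval
  indicators for fire, insects, and disease; flat normal(0, 10²) priors on
  α and β, uniform(0, 10) on ς. β_l is the mean FSI difference between
  disturbed and undisturbed plots; because events fall mid-interval on
  average, it folds in several years of pre- and post-event change and is
  not an instantaneous impact.
* **Annual probability.** The interval flag is treated as a binomial count
  over Δt annual trials with a beta(1, 1) prior, Δt rounded to the nearest
  integer ≥ 1 (intervals are ~10 years, so rounding is negligible). With
  binary flags this posterior is exactly Beta(1+Σx, 1+Σ(Δt−x)); the package
  still samples it through the common MCMC path, and the test suite uses
  the closed form as an independent oracle. Note the flag **censors**
  multi-event intervals at one, biasing ψ downward when ψΔt is not small;
  the recovery tests quantify the effect (a ~13% relative understatement
  at ψ = 0.03 over 10-year intervals), and no correction is applied since
  the binary field datum carries no more information.

The standardized effect for species j and disturbance l is the pairwise
product of posterior draws β_jl·ψ_jl (drawn independently, multiplied in
given order) times 100/mean RD_t1(j): the annual percent of baseline
relative density attributable to that disturbance. Significance is a
central 95% credible interval of the product excluding zero. Default 5000
retained draws per parameter.

## Synthetic landscape generator

The generator emulates a remeasured national-inventory panel: paired
censuses within a 2001–2018 window, remeasurement years 2011–2018 (eight
annual panels), interval length ~normal(9.78, 1) years, four strata with
fixed area weights, ten areal subsections nested in two divisions, and
forest-type-specific frontiers. Mechanics:

* Stand states are sampled as (S̄, RD_agg) with log RD_agg normal and its
  99th percentile located exactly at the frontier, so the generated
  exceedance fraction equals the configured 1% and the true conditional
  99th percentile of log TPH is exactly log a + r·log S̄. The default log-SD
  of 0.35 concentrates stands between roughly 20% and 90% stocking —
  typical of established forestland and informative about the frontier.
* Tree lists are drawn from a lognormal DBH family and rescaled so the
  stand summary reproduces the sampled (TPH, S̄) exactly; the log-scale
  spread controls diameter skewness ("normal" stands pass the |g1| ≤ 1
  screen, "skewed" stands fail it).
* Per-species relative density evolves as RD_t2 = RD_t1 + Δt·(drift +
  Σβ_l x_l + ε), ε ~ normal(0, ς²) — exactly the severity model — with
  interval flags from annual Bernoulli(ψ) events (flag = any event in Δt,
  reproducing the binary-datum censoring). Negative targets floor at zero
  with the realised change recorded in the ground truth.
* Second-census tree lists keep first-census diameters and rescale
  represented densities to hit the target RD exactly. Diameter growth is a
  config knob defaulting to zero: RD is the state variable every
  downstream model consumes, and fixed sizes make the generated FSI exact
  rather than approximate. A consequence worth knowing: plot-level
  distortions from frontier-estimation error then cancel exactly in %FSI
  ratios, so end-to-end recovery isolates estimator behaviour from
  frontier error.
* All randomness flows through per-plot substreams keyed by (seed, plot
  index): identical configs and seeds are byte-identical, and subsetting
  plots does not reshuffle others.

What the generator does **not** emulate: spatial autocorrelation beyond
categorical labels, within-plot condition mapping, measurement error in
DBH or expansion factors, species-specific diameter distributions, tree
recruitment as a size-structured process, or temporally varying disturbance
regimes. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generating model, not robustness to these
real-data features.

## Problem sizes and tolerances in the validation suite

Frontier recovery uses a 2000-stand landscape (posterior medians within
±0.15 of log a and ±0.05 of r); the conjugate oracle 10 random designs of
20–150 plots (3 Monte-Carlo SEs); the least-squares oracle 5 designs of
100–300 plots (4 MC SEs); end-to-end recovery an 800-plot landscape with a
species calibrated to −1 %/yr (classification plus a delta-method 95%
interval covering −1). Reduced chain counts/lengths are used where the
oracle checks only need moderate Monte-Carlo precision; the frontier
recovery runs the default settings (4 × 4000 steps, 48 walkers).

## Known limitations

* The AL working likelihood gives asymptotically valid point estimates of
  the quantile but its posterior spread is not automatically calibrated at
  extreme quantiles; interval coverage for (a, r) should be read
  qualitatively.
* ψ inherits the binary-flag censoring bias described above.
* The severity and probability posteriors are multiplied as independent;
  any real dependence between disturbance occurrence and severity is not
  modelled.
* Normal-theory confidence intervals assume group sizes large enough for
  the CLT; sparse groups (rare species × small subsections) should be
  interpreted with care — the estimator reports n_plots for exactly this
  reason.
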