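# Methods

## Data-generating model and quota sampling

Each simulated dataset is drawn from a first-order logistic model
`logit P(Y=1|x) = β₀ + βᵀx` with covariates from one of three laws:
independent standard normal, equicorrelated multivariate normal (unit
variances, common correlation ρ), or independent Bernoulli(0.5).
Pairs (x, y) are sampled i.i.d. and the first `n_events` events plus the
first `n_total − n_events` non-events are retained, in draw order.
This *quota sampling* fixes the sample size and the event count — hence
EPV — exactly in every replicate. Conditioning on the outcome this way
tilts only the intercept of the retrospective model, so the slope
coefficients remain the estimands; we verify empirically that summaries
are invariant (within Monte Carlo error) to the choice of β₀.

β₀ is nevertheless calibrated so that the *marginal* event probability
equals the scenario prevalence, which maximizes sampling efficiency and
makes raw-draw counts interpretable. For the normal laws the marginal
probability is a one-dimensional integral (βᵀX is normal with variance
βᵀΣβ) evaluated by 80-node Gauss–Hermite quadrature; for Bernoulli
covariates it is an exact enumeration over the 2ᴾ support. Root-finding
is by Brent's method; accuracy is far below 1e-4 on the probability
scale. A safety cap of 10⁷ raw draws per dataset guards against
degenerate models; no in-scope scenario comes near it.

Randomness: every replicate owns a `SeedSequence(master_seed,
spawn_key=(study, scenario_index, replicate))` stream, so results are
bit-reproducible and independent of execution order or worker count.

## Estimators

**Maximum likelihood.** IRLS / Fisher scoring implemented with the exact
semantics of mainstream GLM software, because part of what this package
studies *is* those semantics: initialization from the working response
built at μ = (y + ½)/2; the weighted least-squares step solved by QR on
√w-scaled rows; fitted probabilities clamped to [ε, 1−ε] (ε machine
epsilon); convergence declared when the relative deviance change
`|dev − dev_old| / (|dev| + 0.1)` falls below the tolerance. No step
control is applied: on separated data the iterates diverge, and the last
iterate is returned with `converged` reported honestly — this is what
the "naive/keep" handling policy and the threshold and tracing detectors
need to see. We validated this fitter against R's `glm` on thousands of
simulated low-EPV datasets during development: coefficients agree to all
printed digits even on divergent fits, and the non-convergence rates
under all four tolerance/iteration presets (1e-8/25, 1e-6/25, 1e-10/25,
1e-10/50) match exactly. Standard errors are square roots of the inverse
expected information; for capped-refit paths they are computed from the
weights that produced the iterate, which is what a GLM summary reports
for a fit stopped at that iteration.

**Firth's correction.** The Jeffreys-penalized log-likelihood
`l*(β) = l(β) + ½ log det I(β)` is maximized by modified-score scoring:
the score component `Σᵢ (yᵢ − πᵢ + hᵢ(½ − πᵢ)) xᵢᵣ` (hᵢ the hat-matrix
leverage) is the exact gradient of `l*` for the canonical-link logistic
model, and each step solves against the expected information, with step
halving (≤10) whenever a step fails to increase `l*`. The Firth fitter
starts at β = 0. Its estimates are finite on separated data; the test
suite cross-checks them against direct numerical maximization of an
independently coded `l*`.

**Intervals.** ML: Wald, `β̂ ± z·SE` with the normal quantile computed
at run time. Firth: profile penalized likelihood — endpoints solve
`2[l*(β̂) − l*_profile(b)] = χ²₁,level`, where the profile fixes the
target coefficient and re-maximizes over the others (the restricted
modified-score iteration). Roots are bracketed by geometric expansion
from the estimate (initial step one SE) and solved by Brent to 1e-6.
`profile_ci` searches ±50 on the logit scale by default; heavily
separated N=8 datasets can genuinely place the upper endpoint beyond
that, because the penalized profile decays extremely slowly along the
separating direction, so the study drivers search ±500. Those very wide
intervals are real features of the penalized profile at such sample
sizes and are the main reason mean interval width is the least stable
summary in the EPV-4 cell.

## Separation detection

* **Exact LP oracle.** With sᵢ = 2yᵢ − 1 and Z the intercept-augmented
  design: the data are *completely* separated iff
  max{t : sᵢ(Zᵢb) ≥ t, ‖b‖∞ ≤ 1} > 0, and otherwise *quasi-completely*
  separated iff max{Σuᵢ : sᵢ(Zᵢb) ≥ uᵢ, 0 ≤ uᵢ ≤ 1, ‖b‖∞ ≤ 1} > 0.
  The box normalization keeps the LPs bounded without excluding any
  direction; optima above 1e-9 count as strictly positive to absorb
  solver round-off. Overlap (both optima zero) is equivalent to
  existence of a finite MLE, which the tests verify on random small
  datasets. Solved with HiGHS via `scipy.optimize.linprog`; a solver
  failure raises rather than silently reporting overlap.
* **Tracing (re-estimation).** The model is refit with iteration caps
  k = 1..30; each parameter's SE path is scaled by its k = 1 value and
  the dataset is flagged when any parameter's sample variance (n−1
  denominator) of the scaled path exceeds 20. All parameters, including
  the intercept, are monitored; the flagged set is recorded per
  parameter. Capped refits honour the deviance tolerance by default,
  exactly as `glm(maxit=k)` would (the SE path flattens once the fit
  converges); a variant with the tolerance disabled is available. The
  cutoff 20 has no theoretical derivation and is configurable.
* **Threshold.** Any non-intercept |β̂ⱼ| > log 50 on the ML fit.
* **Non-convergence.** The deviance criterion not met within the
  iteration cap, under any of the four presets.

## Handling policies

Per scenario the ML estimates are summarized under: *remove* (drop
flagged replicates; the part-I default removes tracing-flagged or
non-converged fits), *keep-naive* (use the software's last iterate
regardless of flags), and *replace-max* (substitute flagged primary
estimates with the largest non-flagged estimate in the scenario; an
absolute-value switch exists for negative-effect scenarios). Firth
summaries always use every dataset. Rank-deficient simulated datasets
(a constant Bernoulli covariate column, probability ~2×10⁻⁴ per
replicate at the smallest binary-covariate cells) identify no slope for
either estimator; they are recorded as degenerate and excluded from all
summaries.

## Accuracy summaries

For the primary coefficient: bias (mean estimate minus truth), relative
bias (undefined at zero truth, excluded from cross-scenario relative
summaries), coverage and mean width of the 90% interval, and
MSE = bias² + SD² with the n−1 sample SD. Banded aggregation reports
mean/max/min per band plus the share of scenarios with relative bias
above +10% and with coverage outside nominal ±1%. Banded *bias* rows
exclude zero-effect scenarios by default in the reproduction checks:
the published band minima are strictly positive, which is only possible
under that convention.

## Study designs

Part I (continuous covariates, separation rare): Ia — EPV 15..150 step 5
× odds ratio {¼, ½, 1, 2, 4}, P = 1, prevalence ½; Ib — same EPV × P
{2, 3, 4} × odds ratio {2, 4} (equal slopes), prevalence ½; Ic — EPV
6..30 step 2 × prevalence {½, ⅓, ¼, ⅕, 1/10}, P = 2, odds ratio 2;
Id — EPV 6..30 step 2 × ρ {0.10, 0.15, 0.20, 0.25}, P = 2, odds ratio
2, prevalence ¼. Part II: IIa — EPV 6..30 step 2 × β₁ {log 1, log 2,
log 4}, one Bernoulli(0.5) covariate, events:non-events 1:1 (the ratio
is not pinned down by the source design description; 1:1 matches the
other prevalence-½ designs); IIb — a single cell with EPV 4, one
standard-normal covariate, β₁ = log 4, 4 events and 4 non-events
(N = 8). Non-integral N (prevalence ⅓) is rounded to the nearest
integer.

## Problem sizes used in the checks

The acceptance script runs study IIb at its full 10,000 replicates and
the part-I rarity scan at 3,000 replicates per candidate scenario
(about a minute in total). The test suite re-runs study IIb at 10,000
replicates and the part-I EPV 15–30 band at 2,000 replicates per
scenario (the published runs used 10,000; at 2,000 the Monte Carlo SEs
of the banded averages are several times smaller than the tolerances
used). Tolerances are three Monte Carlo standard errors at those sizes.

## Known discrepancy: separation rates in the EPV-4 cell

Under the stated IIb design the *true* probability that 4 events and 4
non-events drawn this way are completely separated is ≈19% (closed-form
integration over the conditional order statistics; the LP oracle on
simulated data agrees). The tracing detector flags ≈21%, the threshold
criterion ≈30%, and default-criterion non-convergence ≈10% — all
roughly 2.5–4× the published rates (8.06%, 16.64%, 5.12%), and the
same holds when the published procedure is executed verbatim in the
reference statistical software on the same simulated datasets. By
contrast, quantities conditional on a detector verdict reproduce
closely (ML bias after tracing removal 0.570 vs 0.569; Type I/III
non-convergence 0.36%/0.06% vs 0.34%/0.09%). The published rates are
therefore consistent with a somewhat larger cell than the one stated
(e.g. 4 events vs 8 non-events, or 6 vs 6), and the corresponding
reproduction checks are expected to fail under the stated design; they
are kept failing deliberately rather than recalibrated. The same effect
makes the published Firth bias (+0.012) and profile-interval coverage
(0.919) in that cell sit slightly off our values (−0.08, 0.933): with a
fifth of all datasets separated, the penalized estimates' shrinkage on
those datasets pulls the mean below the truth.

## Limitations

* The synthetic designs cover main-effects logistic models with
  normal or Bernoulli covariates only; no misspecification,
  missingness, retrospective sampling, or categorical expansions.
  Passing checks say nothing about predictive accuracy (calibration,
  discrimination), which these studies do not measure.
* Keep-naive summaries on separated data are dominated by where the
  divergent iteration happens to stop; their moments (especially mean
  width and MSE) are software artefacts by construction and are
  reported for exactly that reason.
* The tracing cutoff (variance > 20 of scaled SEs) is an empirical
  convention; its operating characteristics beyond the designs studied
  here are unknown.
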