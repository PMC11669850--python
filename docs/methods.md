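# Methods

## Model and estimands

The observed data are `{mᵢ, Cᵢ, N°ᵢ(t); 0 ≤ t ≤ τ}` for `n` independent
subjects: a baseline scalar marker, a censoring time, and the observed
counting process `N°(t) = N(t ∧ C)`. The event process and censoring are
assumed independent given the marker. High risk at horizon `t` means
`N(t) ≥ r` on the *underlying* (uncensored) process; all accuracy
quantities — TPF/FPF/ROC/AUC and the quantile-indexed PPV/NPV curves — are
functionals of the conditional count distribution
`f_j(t, m) = Pr(N(t) = j | M = m)` and the marker law `G`.

The working model is a mixed Poisson process: conditional on a frailty
`u ~ Gamma(mean 1, variance θ)` and `m`, the process is Poisson with
cumulative mean `u μ₀(t) exp(β m)`. Marginally the count is negative
binomial, which gives `f_j` in closed form; the accuracy estimators plug the
fitted `q̂ᵢ = Pr(N(t) ≥ r | mᵢ)` into weighted indicator sums over the
sample, with `G` estimated by the empirical CDF. Tail probabilities are
always computed as `1 − Σ_{j<r} f_j`, so no truncation constant (the
maximum observed count `K`) enters; this is exact because the pmf sums
to one.

## EM algorithm

- **E-step.** The gamma posterior of `uᵢ` given the observed history is
  conjugate: shape `1/θ + nᵢ`, scale `θ/(1 + θ μᵢ(Cᵢ))`, giving
  `E[uᵢ] = (1 + nᵢθ)/(1 + μᵢ(Cᵢ)θ)` and
  `E[log uᵢ] = ψ(1/θ + nᵢ) + log(θ/(1 + θ μᵢ(Cᵢ)))`.
- **M-step, baseline + β.** The baseline maximizer given `β` and the
  posterior frailty means is the Breslow-type step function
  `dμ̂₀(s) = d(s) / Σ_{Cᵢ ≥ s} ũᵢ e^{β mᵢ}` with jumps at the pooled observed
  event times (across-subject ties counted by multiplicity; risk sets are
  closed at `s`). `β` solves `Σ mᵢ(nᵢ − ũᵢ μ₀(Cᵢ)e^{β mᵢ}) = 0`, which is
  strictly decreasing in `β`, by safeguarded Newton with bracket expansion.
  The two updates are alternated (up to 20 cycles, inner tolerance one tenth
  of the EM tolerance) because the profile structure couples them; the pair
  of exact coordinate updates makes every EM iteration a generalized EM
  step, so the marginal log-likelihood never decreases (verified to 1e−8 in
  the tests).
- **M-step, θ.** The expected gamma log-density term is maximized by Brent
  search on `log θ ∈ [log 1e−6, log 50]`; a maximizer below `theta_floor`
  (default 1e−4) is mapped to 0, the Poisson submodel. The search on the log
  scale is robust near the boundary, where Newton steps on the digamma score
  are not. `theta_floor = ∞` forces the Poisson fit, which reproduces the
  Poisson GLM estimate exactly under complete follow-up (cross-checked
  against statsmodels in the tests).
- **Start / stop.** `β` starts at the Poisson profile fit; `θ` at the moment
  estimator `max(0.01, (var(n) − mean(n))/mean(n)²)`. Iteration stops when
  the maximum relative change of `(β, θ, μ₀(τ))` drops below `tol`
  (default 1e−6, `max_iter` 500); non-convergence returns a fit flagged
  `converged=False` with a warning rather than raising.

Evaluating `μ₀(t)` beyond a subject's follow-up (needed for the common
horizon `t`) uses the population step function from all subjects, constant
beyond the largest observed event time.

## Numerical conventions

- Count pmf in log space via log-gamma; underflow clamped at `exp(−745)`;
  `θ < 1e−10` switches to the Poisson mass.
- Empirical quantiles are the left-continuous inverse (smallest order
  statistic with cdf ≥ v), so thresholds are observed marker values and the
  PPV (`m > Ĝ⁻¹(v)`) and NPV (`m ≤ Ĝ⁻¹(v)`) indicators partition the
  sample; the conservation identity
  `(1−v)·PPV(v) + v·(1−NPV(v)) = P̂r(N(t) ≥ r)` then holds to machine
  precision whenever `v·n` is an integer and the markers are tie-free.
  A 1e−9 guard absorbs floating jitter of `v·n` at integer breakpoints.
- The ROC is traced at all distinct marker thresholds, duplicated FPF values
  collapsed to their best TPF, read at `p₀` by linear interpolation in FPF,
  and integrated by the trapezoid rule — equivalent to the weighted
  Mann-Whitney statistic with ½-credit for ties (verified against the
  O(n²) enumeration).
- Within-subject tied event times are rejected, not jittered: the model is
  an orderly counting process and the simulator cannot produce them.

## Oracle (population truth)

Marker integrals use Gauss-Legendre quadrature on `[−8, 8]` (801 nodes by
default; normal mass outside is < 1.3e−15). The control sub-CDF needed for
the AUC is built by cumulative Simpson integration on an 8193-point grid;
ROC inversion `FPF(c) = p₀` is by bisection. Doubling the node count moves
the AUC by < 1e−6. For lognormal frailty the Poisson tail is mixed over the
frailty by 180-node Gauss-Hermite quadrature in `log u`, which agrees with
adaptive quadrature to ~1e−12 and vectorizes over the marker grid. The
Monte-Carlo cross-oracle simulates latent counts directly (the conditional
count over `[0, t]` is Poisson, so event times are not needed) and computes
empirical rank-based accuracy with binomial / Hanley-McNeil standard errors.

## Simulator

The generator reproduces the study conditions: `M ~ N(0,1)`; frailty gamma
or lognormal with mean 1 and variance θ (lognormal: log-scale variance
`log(1+θ)`, log-scale mean `−log(1+θ)/2`); linear baseline `Λ₀(t) = v·t`
with `v = 0.5`, `τ = 5` by default; inter-event gaps exponential with rate
`u·v·e^{β₁m}`. Censoring scenarios: complete (`C = τ`); independent uniform
`C = min(U[0, b], τ)` — `b = τ` is the classical fully-uniform scenario,
while `b = τ/p` calibrates the fraction of subjects censored before `τ` to
`p` (the ~10%-censoring runs use `b = 50`); covariate-dependent
(`U[1, τ+1]` if `m > 0`, else `Exp(1)+1`, truncated at `τ`, with `m = 0`
assigned to the uniform branch — a measure-zero convention). Each subject
draws from a counter-derived substream of the master seed, so datasets are
reproducible and prefix-stable in `n`.

True case status for validation is defined on the **latent** full process,
not the censored one: that is the only internally consistent reading of the
case definition, and the retained latent event lists make it exact.

What the generator does *not* emulate: terminal events, gap-time/renewal
dependence, time-varying markers, informative censoring beyond the
covariate-dependent scenario, or non-linear baselines (a general `Λ₀` would
need only an inverse-transform of the linear-time process, but every study
condition here is linear). Passing tests therefore certify the estimators
under an orderly mixed-Poisson world; they do not certify robustness to,
e.g., event-dependent dropout.

## Inference and the study harness

Standard errors are subject-resampling bootstrap SDs; intervals are
percentile intervals (default level 0.90) — the minimal-assumption choice
where the construction is not otherwise pinned down. Resamples whose fit
fails are dropped with a warning; more than 10% failures aborts. The
simulation-study harness repeats simulate → fit → estimate, aggregates bias
(against the quadrature-oracle truth), SD of the estimates, mean bootstrap
SE and CI coverage, and is deterministic given its seed; replicates are
independent so they can be parallelized and aggregated order-free.

The first-event comparator truncates each subject at the first event and
computes the IPCW cumulative/dynamic AUC with Kaplan-Meier censoring weights
(scikit-survival). It is a deliberately *crude* benchmark — any consistent
cumulative/dynamic estimator supports the qualitative comparison that
discarding recurrences lowers the estimated AUC.

## Problem sizes and default scales

Replicated computations are run at 200 replicates of n = 500 subjects
(150 replicates for the paired first-event comparison, 12 replicates of
n = 2000 for large-sample parameter recovery); these reduced-replicate
scales keep every check to seconds-to-minutes while leaving Monte-Carlo
standard errors an order of magnitude below the tolerances being asserted.
Full 1000-replicate tables remain available through `StudyConfig`.

## Known limitations

- Single scalar baseline marker; no covariate adjustment, time-varying
  markers, or joint comparison of multiple markers.
- Gamma frailty only in the *fitting* step; misspecification is exercised
  through the lognormal generator, where the estimators remain nearly
  unbiased for an uninformative marker but inherit the usual pseudo-true
  caveats for an informative one.
- No analytic (sandwich / functional-delta) variance formulas: they require
  density smoothing, and the bootstrap is used instead.
- EM convergence is linear; heavily degenerate data (e.g., all subjects
  identical) can exhaust `max_iter` near the θ boundary and return a
  non-converged flag.
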