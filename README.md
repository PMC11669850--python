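# recurroc

Time-dependent prognostic accuracy of a baseline marker when the outcome is a
**recurrent event process**.

In many clinical settings (pulmonary exacerbations in cystic fibrosis, asthma
attacks, seizures) a patient can experience the event of interest repeatedly,
and the question is whether a scalar marker `M` measured at enrollment
separates patients who will accumulate many events from those who will not.
Standard time-dependent ROC methods handle only the time to the *first*
event; collapsing a recurrent process to its first event discards information
and understates the marker's discriminative ability.

`recurroc` defines high risk by the event count: a subject is a *case* at
horizon `t` if `N(t) ≥ r`. The accuracy summaries are

    TPF⁽ʳ⁾(c, t) = Pr(M > c | N(t) ≥ r)         (true positive fraction)
    FPF⁽ʳ⁾(c, t) = Pr(M > c | N(t) < r)         (false positive fraction)
    ROC⁽ʳ⁾(p₀, t) = TPF at the threshold where FPF = p₀, with area AUC⁽ʳ⁾(t)
    PPV⁽ʳ⁾(v, t) = Pr(N(t) ≥ r | G(M) > v)      (risk above the v-th marker quantile)
    NPV⁽ʳ⁾(v, t) = Pr(N(t) < r | G(M) ≤ v)

Because follow-up is right-censored, these cannot be estimated by counting
alone. The package estimates the conditional count distribution with a
**semiparametric gamma-frailty mixed Poisson model**: given a frailty
`u ~ Gamma(mean 1, var θ)` and marker `m`, the process is Poisson with
cumulative mean `u · μ₀(t) · exp(β m)`, so that marginally

    Pr(N(t) = j | m) = Γ(j + 1/θ) / (j! Γ(1/θ)) · (θμ)ʲ / (1 + θμ)^{j + 1/θ},
    μ = μ₀(t) e^{βm}   (negative binomial),

with `μ₀(·)` an unspecified, nonparametrically estimated baseline mean.
`Θ = (β, θ, μ₀)` is fitted by EM: the gamma posterior of each frailty is
conjugate (closed-form E-step), and the M-step combines a frailty-weighted
Breslow baseline, a Newton solve of the marker-coefficient score, and a
bounded 1-D search for θ. Accuracy estimates are weighted indicator sums of
the fitted case probabilities `q̂ᵢ = Pr(N(t) ≥ r | mᵢ)` over the observed
marker sample; standard errors come from a subject-resampling bootstrap.

The package also ships:

- a **simulator** for the study design (standard-normal marker, gamma or
  lognormal frailty, linear baseline `Λ₀(t) = v·t`, three censoring
  scenarios) that retains the latent truth,
- a **quadrature oracle** for population accuracy values plus a brute-force
  Monte-Carlo cross-oracle,
- a **simulation-study harness** (bias / bootstrap SE / SD / coverage
  tables) and a first-event IPCW "crude AUC" comparator.

## Worked example

```python
from recurroc import (DGPSpec, RiskDefinition, simulate_dataset, fit_em,
                      evaluate_accuracy, true_accuracy)

spec = DGPSpec(n=500, beta1=0.5, theta=0.5, seed=42)   # Λ0 = 0.5 t, τ = 5
ds = simulate_dataset(spec)
fit = fit_em(ds.observed)
print(f"beta={fit.beta:.3f} theta={fit.theta:.3f} iters={fit.n_iter}")

risk = RiskDefinition(r=2, t=5.0)                      # case: ≥2 events by t=5
curves = evaluate_accuracy(fit, ds.markers, risk)
print(f"AUC={curves.auc:.3f}  ROC(0.9)={float(curves.roc(0.9)):.3f} "
      f"marginal risk={curves.marginal_risk:.3f}")

oracle = true_accuracy(spec, risk)                     # population values
print(f"true AUC={oracle.auc:.3f}  true marginal risk={oracle.marginal_risk:.3f}")
```

prints

```
beta=0.494 theta=0.545 iters=42
AUC=0.691  ROC(0.9)=0.975 marginal risk=0.558
true AUC=0.693  true marginal risk=0.575
```

The fitted rate ratio per marker unit is `exp(0.494) ≈ 1.64`, the frailty
variance 0.545 indicates substantial residual heterogeneity, and the marker's
estimated AUC of 0.691 for discriminating subjects with ≥2 events by `t = 5`
agrees with the population value 0.693 under this design. The same analysis
runs on user CSVs from the command line:

```bash
recurroc fit      --subjects s.csv --events e.csv --tau 5
recurroc accuracy --subjects s.csv --events e.csv --tau 5 --r 2 --boot 200
```

(`--reverse-marker` negates the marker when *lower* values mean higher risk,
as with forced expiratory volume.)

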