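# flexaft

Flexible parametric accelerated failure time (AFT) models for survival
analysis: a restricted cubic spline models the log cumulative hazard of
*accelerated time*, so the baseline can take essentially any smooth shape
while covariate effects keep their clean AFT interpretation as
multiplicative effects on survival time.

## Who this is for

Epidemiologists and biostatisticians who want AFT-metric effect estimates —
"survival time is shortened by 26%" rather than "the event rate is 35%
higher" — from registry or trial data whose baseline hazard is too complex
for the Weibull, generalized gamma, or generalized F families.  Log
acceleration factors are also collapsible over omitted covariates that are
independent of the exposure, which hazard ratios are not, making the AFT
metric attractive for causal questions.

## The model

With covariates `X` and time-rescaling factor `φ(X) = exp(−Xβ)`,

```
S(t | X) = S₀(t · φ(X)),      log H(t | X) = s( log(t · φ(X)) | γ, k₀ ),
```

where `s(·)` is a restricted cubic spline (truncated power basis, linear
beyond the boundary knots) with coefficients `γ` and knots `k₀` placed at
quantiles of the uncensored log accelerated times.  With spline df = 1 the
model is exactly a Weibull AFT.  `β` is the log acceleration factor:
`exp(β)` multiplies survival time (values below 1 shorten it).

Time-dependent acceleration factors act on the cumulative time scale,

```
φ(X, t) = exp( −Xβ − Σₚ xₚ s(log t | γₚ, kₚ) ),
```

and the interpretable instantaneous factor is recovered without integration
via `η(X, t) = d/dt [ t · φ(X, t) ] = φ(X, t)(1 − Σₚ xₚ s′(log t))`.

Estimation is full maximum likelihood with delayed entry (left truncation),
Newton iterations with step halving, an analytic score, and the inverse
observed information as the covariance.  Predictions carry delta-method
intervals built on the `log(−log S)` scale for survival and the log scale
for acceleration factors.

## Worked example

```python
import flexaft as fa

scn = fa.MixtureWeibullScenario(p=1.0, lambda1=0.2, gamma1=1.3, beta=-0.3,
                                n=3000, seed=1, admin_censor=8.0)
data = fa.simulate_mixture_weibull_aft(scn)

f = fa.fit(data, fa.ModelSpec(df=3, covariates=["x"]))
print(f"loglik {f.loglik:.2f}  AIC {f.aic:.2f}  BIC {f.bic:.2f}")

s = fa.summarize_af(f, "x")
print("log AF {estimate:.3f} (se {se:.3f})".format(**s["log_af"]))
print("AF {estimate:.3f} (95% CI {ci_low:.3f}-{ci_high:.3f})".format(**s["af"]))

print(fa.predict_survival(f, [1.0], [1, 2, 5]).to_frame().round(4))
```

prints

```
loglik -5690.73  AIC 11391.46  BIC 11421.34
log AF -0.274 (se 0.029)
AF 0.760 (95% CI 0.718-0.805)
 time  estimate     se  ci_low  ci_high
  1.0    0.7396 0.0373  0.7229   0.7555
  2.0    0.4779 0.0297  0.4572   0.4982
  5.0    0.0920 0.0268  0.0808   0.1039
```

The generating log acceleration factor was −0.3; the fit estimates −0.274
with a 95% interval covering the truth, i.e. treated subjects' survival
times are multiplied by about 0.76.  The prediction table gives survival in
the treated arm with delta-method intervals (the `se` column is on the
`log(−log S)` scale).

The same fits are available from the shell:

```
flexaft simulate mixweib --preset weibull --n 3000 --seed 1 --out sim.csv
flexaft fit sim.csv -c x --df 3
flexaft predict sim.csv -c x --df 3 --profile 1 --times 1,2,5
flexaft study table1 --nsim 50 --seed 1
```

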