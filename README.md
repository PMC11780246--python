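# cavtesim

Simulation toolkit for studying how the **time-averaged concentration to
event (CavTE)** exposure metric biases logistic exposure-response (ER)
analyses of binary safety endpoints when the event time of censored
subjects must be imputed.

## The problem

In ER analyses of binary endpoints (e.g. "any treatment-emergent adverse
event"), CavTE is the cumulative AUC from treatment start to the event
divided by the time to the event.  Subjects with no event by the end of
treatment (EoT) are censored: they have no event time, so an analyst must
pick a reference time — EoT, or EoT plus 7/14/21/28 days of protocol
follow-up — to compute their CavTE.  Because dosing has stopped, the AUC
barely grows during follow-up while the divisor keeps growing, so every
added week of imputed follow-up pushes censored subjects' CavTE down
("left shift") while responders' exposures are untouched.  That widens the
apparent exposure gap between responders and non-responders and
mechanically strengthens the fitted ER relationship: the slope p-value of

&nbsp;&nbsp;&nbsp;&nbsp; logit P(responder_i) = β₀ + β·X_i,&nbsp;&nbsp; X_i = CavTE_i

falls monotonically as the imputed follow-up grows, potentially turning a
non-significant trend significant (or vice versa) with no change in the
underlying data.

`cavtesim` reproduces this phenomenon end to end with a fully synthetic
virtual trial:

- **`pk`** — one-compartment oral PK (first-order absorption, lag time,
  first-order elimination) with closed-form superposition concentration
  and cumulative-AUC functions; log-normal inter-individual variability
  (IIV) on CL, V and Ka.  Defaults: CL 17.7 L/h, V 229 L, Ka 4.23 /h,
  lag 0.154 h; 60 mg once daily for four 28-day cycles.
- **`ae`** — ordinal grade 0/1/2 adverse events from a proportional-odds
  model with Markov components: cumulative logits anchored by the previous
  grade and shifted by a saturable drug effect
  s·Emax_prev·C/(EC50 + C) evaluated weekly.
- **`metrics`** — CavTE under the five imputation policies, Cav,ss =
  F·D/(CL·τ), and tidy per-subject ER datasets.
- **`er_fit`** — Newton-Raphson logistic regression with Wald and
  likelihood-ratio slope p-values, separation detection, and quartile
  event-rate summaries with Wilson confidence intervals.
- **`scenarios`** — the replicate study grid (cohort sizes 50/100/200 ×
  Emax multipliers 0.25–1.5 × 5 policies), the <5 % censoring-balance
  skip rule, and long/pivoted result tables.

## Worked example

```python
import cavtesim as cs

cfg = cs.ScenarioConfig(n_subjects=200, emax_scale=0.75, n_replicates=50, seed=7)
table = cs.run_grid(cfg, sample_sizes=(200,), emax_scales=(0.75,))
print(table.pivot())                       # median slope p by policy
```

```
policy                      EoT     EoT+7   EoT+14    EoT+21    EoT+28
n_subjects emax_scale
200        0.75        0.536341  0.253988  0.05268  0.008924  0.001381
```

One identical set of 50 simulated trials, analysed five ways: the median
slope p-value drops almost 400-fold purely because censored subjects'
CavTE was referenced to a later time.  At EoT the relationship looks
non-significant; with +28 days of imputed follow-up it looks highly
significant.  The same engine exposes the feasibility edge of the design:

```python
summ = table.summary()
print(summ[["metric", "median_p", "median_frac_censored", "skip_rate"]])
```

At Emax multipliers ≥ 1.25 fewer than 5 % of subjects stay event-free, the
balance rule fires, and the logistic regression is skipped.

A command line mirrors the library: `cavtesim simulate`, `cavtesim fit`,
`cavtesim grid`, `cavtesim report` (see `--help`; model parameters can be
overridden from a TOML/YAML file with blocks `pk`, `ae`, `regimen`,
`study`).

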