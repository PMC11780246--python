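# Methods

## Model overview

`cavtesim` simulates a single-arm virtual trial and its exposure-response
(ER) analysis.  Three stochastic layers feed each other:

1. **Pharmacokinetics.**  A one-compartment model with first-order
   absorption (rate Ka), an absorption lag (Alag), first-order elimination
   (ke = CL/V) and repeated oral dosing (default 60 mg every 24 h, 112
   doses).  Concentration and cumulative AUC are closed-form dose
   superpositions of the Bateman function; when |Ka − ke| is within a
   relative 1e-9 the analytic Ka→ke limit is used instead of the
   catastrophically cancelling general form.  Units are hours, mg, L;
   concentrations are reported in ng/mL.  Per-subject CL, V, Ka are
   log-normal around the typical values with σ² = ln(1 + CV²) — the
   standard population-PK convention, so the typical value is the median
   and the fractional CV is exact.  Defaults: CL 17.7 L/h (CV 54.0 %),
   V 229 L (34.1 %), Ka 4.23 /h (95.5 %), Alag 0.154 h (no IIV).
   Bioavailability F is an explicit parameter defaulting to 1; it is kept
   separate because the steady-state exposure definitions (AUCss = F·D/CL,
   Cav,ss = F·D/(CL·τ)) carry it.

2. **Adverse events.**  Ordinal grades 0/1/2 on a discrete assessment grid
   (default weekly over the 16-week treatment) form a first-order Markov
   chain.  Conditional on the previous grade, cumulative probabilities are
   proportional-odds logits shifted by a saturable drug effect
   DE = s·Emax_prev·C/(EC50 + C), with Emax₀ = 4.73 when the previous
   grade is 0 and Emax₁ = 1.09 when it is ≥ 1; EC50 = 6.05 ng/mL; the
   multiplier s (0.25–1.5) sets the strength of the true ER relationship.
   The mapping is: the transition parameter targeting grade 1 anchors
   P(grade ≥ 1) and the parameter targeting grade 2 forms the ≥2
   increment, i.e. prev 0 → (B01, B02), prev 1 → (B11, B12), prev 2 →
   (B21, B22).  This rule is applied uniformly across previous states,
   keeps P(≥2) ≤ P(≥1) at the default values (all increments negative),
   and is isolated behind `transition_probabilities` so an alternative
   parameterisation can be swapped in.  IIV of 10 % CV applies to every AE
   parameter: log-normally for the strictly positive ones (Emax₀, Emax₁,
   EC50) and additively (normal, SD = 0.10·|typical|) for the
   sign-indefinite logit parameters, for which a log-normal is undefined.

3. **ER analysis.**  Grade ≥ 1 at any assessment is "any-grade" response;
   only the first event counts, and a subject with grade 0 throughout is
   censored.  Responders' CavTE is cumulative AUC to the first-event
   assessment divided by that time (no interpolation inside the interval —
   the chain only defines states at assessments).  Censored subjects'
   CavTE uses an imputed reference time: EoT (2688 h) plus 0/7/14/21/28
   days.  The AUC at imputed times includes the post-EoT washout tail,
   because the metric is defined as cumulative AUC up to the reference
   time; freezing the AUC at EoT would contradict that definition and is
   deliberately not offered.  The logistic model logit P = β₀ + β·X is
   fitted by Newton-Raphson with step halving (internally standardised X,
   exactly back-transformed), convergence at relative log-likelihood
   change < 1e-10 within 100 iterations.  Separation is flagged when a
   standardised coefficient passes 1e3 or the fit predicts the outcome
   perfectly.  Exposure is untransformed, as the slope p-value is
   invariant to linear rescaling (tested to 1e-10).  Inference is the
   two-sided Wald test; a likelihood-ratio p-value is reported alongside
   under its own label.  Quartile summaries use type-7 quantile cuts
   (ties to the lower bin) and Wilson 95 % intervals for the per-bin event
   proportion.

## The concentration driver

The transition logits depend on the concentration in the central
compartment, which leaves open *which* concentration summarises a weekly
assessment interval.  Two drivers are implemented: the pre-dose trough at
the assessment time and the interval-average concentration (AUC over the
interval divided by its length).  The **interval-average is the default**.
With median steady-state exposure ≈ 141 ng/mL against EC50 = 6.05 ng/mL,
it reproduces the intended feasibility profile of the study design: the
censored fraction falls from ≈ 80 % at s = 0.5 through ≈ 50 % at 0.75 and
≈ 20 % at 1.0 to ≈ 4 % at 1.25 and < 1 % at 1.5, so the < 5 % balance rule
fires exactly at strong drug effects (reliably for cohorts of 50–100, and
for every cohort size at s = 1.5).  The trough driver (median ≈ 50 ng/mL,
much wider spread) leaves 10–20 % censored even at the strongest effects
under the default IIV and therefore never triggers the imbalance regime;
it remains available via `driver="trough"` for sensitivity analyses.

## Randomness and reproducibility

Every stochastic element derives from one master seed.  Trials use
content-derived entropy (seed, cohort size, Emax-scale token, replicate
index), so the grid can be run in any order or subset without changing any
cell.  Within a sampling call each subject gets an independent spawned
child stream: enlarging a cohort never reshuffles earlier subjects, and
the vectorised cohort simulator is draw-for-draw identical to the
per-subject path (asserted in the tests).  Results are pure functions of
the configuration; long-format CSVs are written with 12 significant
digits so round trips are lossless.

## The balance (skip) rule

A logistic fit is attempted only when the smaller outcome class holds at
least 5 % of the cohort.  The stated rule concerns too few censored
subjects; the symmetric case (too few events, relevant at s = 0.25 with
small cohorts) is applied as well because the fit is equally fragile
there, and is labelled separately (`imbalance` vs `single-class` when one
class is empty).

## Study sizes and defaults

The default grid is cohort sizes {50, 100, 200} × Emax multipliers
{0.25, 0.5, 0.75, 1.0, 1.25, 1.5} with the five imputation policies and
Cav,ss, 200 replicates per cell, significance level 0.05.  Replicates are
summarised by the median slope p-value, the fraction of replicates below
α, the median censored fraction and the skip rate; a single-realization
mode emits one p-value matrix (policies as columns) for illustration.  The
acceptance script runs five scenario cells at 200 replicates each (about
half a minute on one CPU); the full grid at 200 replicates takes a couple
of minutes.

## What the generator does and does not emulate

The virtual trial is idealised: fixed nominal dosing with no dose
modifications, interruptions or titration; no dropout other than absence
of events; assessments exactly on schedule; the ER model fitted is
deliberately mis-specified relative to the generating mechanism (a linear
logit in a summary exposure vs a saturable weekly hazard), which is the
point of the exercise.  Passing tests therefore demonstrate the internal
bias mechanism of CavTE imputation — they do not validate the PK or AE
parameter values against any real drug, and real trials add sources of
variability (dosing-history noise, irregular visits, informative dropout)
that this generator does not contain.

## Known limitations

- The event process defines states only at assessment times; event-time
  resolution is the assessment interval, and denser grids materially
  change event rates (a daily grid nearly saturates the event probability
  at moderate Emax multipliers).
- With exposures far above EC50 the drug effect saturates, so the
  power of the linear-logit fit is limited even at n = 200 — a feature of
  the design, but it makes single-trial p-values extremely variable;
  medians over ≥ 200 replicates are the stable summary.
- Recurrent events, grade-specific endpoints and time-to-event analyses
  are out of scope.
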