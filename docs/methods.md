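# Methods

`amikpk` re-creates, as a tested pipeline, a nonparametric population
pharmacokinetic analysis of amikacin in ICU patients with septic shock and
the first-dose nomogram built on top of it. This note documents the models,
the estimation algorithm, the synthetic data that stand in for the
(undeposited) clinical dataset, the numerical choices, and the known
limitations.

## Structural model

Amikacin disposition follows a linear two-compartment model with zero-order
infusion input and first-order elimination from the central compartment:

    dA1/dt = R(t) − (CL/V)·A1 − (Q/V)·A1 + (Q/Vp)·A2
    dA2/dt =        (Q/V)·A1 − (Q/Vp)·A2,        C(t) = A1/V

with amounts in mg, volumes in L, clearances in L/h, time in h and
concentration in mg/L. Infusion windows are half-open
`[start, start + duration)`; the default regimen is a single 30-minute
infusion of 30 mg per kg of total body weight (TBW).

Covariate submodel (the final model):

    CL = CL1 · (eGFR/70)^CL2        V = V1 · (TBW/76.5)

where eGFR is the CKD-EPI (2009) estimate in mL/min/1.73 m², 70 and
76.5 kg are the cohort medians used for normalization, and Q is fixed at
5.43 L/h. Typical values used throughout as defaults (population weighted
medians, with MAWD dispersions in parentheses): CL1 4.41 (1.24) L/h,
CL2 0.72 (0.29), V1 20.40 (5.45) L, Vp 16.32 (7.20) L.

A note on units: the source estimates label CL as an elimination rate
constant in h⁻¹ while printing values that are only physiological as
clearances in L/h (CL/V ≈ 0.22 h⁻¹ gives the observed ~7 h terminal
half-life; a rate constant of 4.4 h⁻¹ would not). The package therefore
treats CL and Q as clearances; a `parameterization="rate_constant"` switch
in the solver preserves the literal reading.

The solver evaluates the exact piecewise bi-exponential solution with
hybrid rate constants α, β derived from (k10, k12, k21), using `expm1` for
the small-rate limit so that β → 0 (no elimination) and Q → 0
(one-compartment) degenerate cleanly. Against a 50-digit arbitrary-precision
evaluation the implementation agrees to ~2·10⁻¹⁵ relative; against an
independent `solve_ivp` integration, to better than 10⁻⁶ over wide random
parameter/regimen draws. Because the system is linear, concentrations scale
exactly with dose; the Monte-Carlo machinery exploits this by simulating
unit-dose exposures once and rescaling across the dose grid.

## Residual-error model

The assay SD is a polynomial of the observation,
`SD(obs) = C0 + C1·obs + C2·obs² + C3·obs³` with defaults
(1.25, 0.05, 0, 0) mg/L, inflated by process noise either multiplicatively
("gamma": total SD = SD·γ) or additively ("lambda":
total SD = √(SD² + λ²)). Observations enter the likelihood as independent
Gaussians with these SDs.

## Covariates

Body mass index, Dubois body surface area, Lorentz ideal body weight,
Traynor adjusted body weight (factor 0.4, the standard aminoglycoside
correction), CKD-EPI 2009, Cockcroft-Gault and MDRD renal-function
estimates. Serum creatinine is µmol/L at every interface (French laboratory
convention; 88.4 µmol/L per mg/dL internally). The CKD-EPI/MDRD race
coefficients are omitted because ethnicity is not recorded in the emulated
cohorts. Lorentz IBW degrades to `height − 100` below 150 cm with a warning
rather than failing, since synthetic cohorts may sample short statures.

## Nonparametric estimation

The between-subject distribution of (CL1, CL2, V1, Vp) is estimated as a
discrete distribution — support points with probabilities — maximizing the
marginal likelihood Π_i Σ_j w_j p(y_i|θ_j) over both the weights and the
point locations, with no parametric shape assumption. The optimal mixing
distribution is discrete with at most one point per subject, which the
adaptive grid exploits:

1. **Initial grid** — scrambled Sobol points (default 256) over the
   pre-set search box (CL1 0.01–15, CL2 0.01–10, V1 0.01–60, Vp 0.1–100;
   Q fixed).
2. **Weights** — EM/multiplicative updates for the convex weight problem,
   run until the per-iteration gain falls below 10⁻⁸ (cap 5000
   iterations). On small instances the solution matches a direct
   simplex-constrained maximization within 10⁻⁴ log-likelihood.
3. **Pruning** — points below 10⁻¹⁰ relative weight are dropped; points
   closer than 10⁻⁴ of the range in every dimension are merged (weights
   summed, heavier location kept).
4. **Refinement** — every surviving point proposes ±ε moves per dimension
   (ε starts at 20% of the range and halves when a full cycle gains less
   than 10⁻⁴ log-likelihood; stop at ε < 10⁻⁴ of range or the cycle cap).
   Old points are retained in the candidate set, so the log-likelihood
   never decreases.
5. **Noise scalar** — γ (or λ) is optimized by bounded one-dimensional
   search (default bounds 0.1–10, start 3) interleaved with refinement;
   predictions are cached so the γ search costs only likelihood
   re-evaluations.

All likelihood work is in log space with per-subject max subtraction. AIC
uses p = (number of structural dimensions) + 1 if the noise scalar is
estimated; the nonparametric effective dimension is ill-defined, and AIC is
used only as a relative criterion between structural/covariate variants.

**Known bias.** With ~3 observations per subject and a 4-dimensional
support, the joint maximum-likelihood solution overfits: the support grows
to roughly one point per subject and the noise scalar γ is driven low
(≈0.9 when the generating value is 1.5), because between-subject freedom
absorbs residual noise. The typical-value medians CL1 and V1 are recovered
essentially unbiased (within a few percent at n = 138); the exponent CL2 is
recovered with a modest upward bias (~+0.2) by the same mechanism. Users
should treat the fitted γ as a lower bound on process noise under sparse
designs.

**Summaries.** Per-parameter weighted median (smallest value with
cumulative weight ≥ 0.5) and MAWD (weighted median of absolute deviations
from the weighted median). 95% CIs come from a subject-level bootstrap that
re-optimizes only the weights over the fixed support (200 resamples by
default) — a deliberate simplification; full refits would multiply the cost
by the resample count.

## Covariate selection

Forward/backward stepwise search over candidate (parameter, covariate,
form) terms; a term enters if it improves −2·log-likelihood by more than
the χ²(0.95) critical value with df = number of added support dimensions,
floored at 1 because a linear term adds none and a 0-df χ² test is
degenerate. Ties prefer the larger AIC improvement; the trace records every
tested combination.

Nested comparisons of nonparametric fits are dominated by optimization
noise unless both sides are converged comparably. Candidate fits are
therefore warm-started by embedding the incumbent support into the
candidate space (new shape dimensions filled with log-spaced levels;
typical values rescaled by the covariate factor at cohort quantiles when a
linear term is added), and any comparison landing near the χ² boundary is
*stabilized*: the two models are alternately refit, each warm-started from
the other's support, until neither improves. Without this, accept/reject
decisions at the threshold reflect which side happened to converge better
rather than the data.

**Calibration caveat.** The χ²(1) reference badly under-states the null
distribution of this statistic when the added term brings a new support
dimension: the mixture then gains a genuine extra random effect and can
exploit subject-level noise correlated with the covariate, inflating the
null improvement to tens of log-likelihood units at n = 138, so the
false-inclusion rate on null data is far above the nominal 5% at every
fitting budget tried (roughly half of null replicates admit a spurious
term at the default budget, more at deeper budgets). Power for the
weight-volume link is budget-dependent in the opposite direction: its
fully converged likelihood gain hovers near the critical value on some
replicates, so lighter budgets — whose under-converged reduced models
flatter included terms — find both true terms in ~9/10 replicates, while
near-converged comparisons drop to ~6-7/10; the eGFR→CL power term is
found essentially always. A permutation-based reference would be needed
for honest type-I control; this is documented rather than patched,
because the χ² rule is the procedure being reproduced.

## Synthetic cohort

Covariates emulate the study population (n = 138, 407 concentrations):

* TBW — log-normal, median 76.5 kg, quartiles 62.0–88.5 (σ from the
  geometric mean of the quartile ratios);
* height — truncated normal, median 170 cm, quartiles 163–177, bounds
  140–210;
* age — two-piece normal (skewed), median 62, quartiles 49–72, bounds
  18–95;
* sex — Bernoulli, 65.2% male;
* eGFR — truncated log-normal, median 70, quartiles 41.9–111.5, bounds
  10–180. The parent parameters are solved so the *truncated* distribution
  matches the targets: clipping the heavy upper tail of a naive fit at 180
  would otherwise drag the realized median to ~64.

The model consumes the sampled eGFR directly; serum creatinine is
back-solved through the exact CKD-EPI inverse so written datasets stay
internally consistent without introducing circular error in the covariate
of record.

Sampling design: every subject is observed at 1 h (the clinical peak
sample, drawn 30 min after the end of the infusion); 6, 12 and 24 h samples
are each included with probability 0.65, giving 1 + 3·0.65 = 2.95 expected
observations per subject (≈ 407/138). The real schedule beyond the 1-h
sample is not reported; this design is an assumption. Observation noise is
additive Gaussian with SD = total error SD at the true concentration,
truncated at zero. Per-subject RNG substreams spawn from one master seed,
so generation is order-independent.

What the generator does **not** emulate: time-varying covariates (renal
function drifting within 48 h), renal replacement therapy, multi-dose
regimens, below-LOQ censoring mechanics, and any correlation between PK
parameters and covariates beyond the modelled CL–eGFR and V–TBW links.
Passing recovery tests on these data therefore demonstrates correctness of
the estimation machinery under the stated model, not robustness to the
full messiness of ICU data.

## Surrogate population distribution

The fitted joint nonparametric distribution behind the published estimates
is not available, so simulation stages use a surrogate: independent
log-normal marginals for (CL1, CL2, V1, Vp) with medians (4.41, 0.72,
20.40, 16.32) and log-scale σ solved numerically so each marginal's median
absolute deviation about its median equals the published MAWD (1.24, 0.29,
5.45, 7.20); Q fixed at 5.43. The σ solver inverts
median(|e^{σZ} − 1|) = MAWD/median by bisection and is verified by
simulation to <1%.

The independence and log-normal-shape assumptions matter in the tails: a
discrete fitted support is bounded, while these marginals are not, and the
CL2 exponent's upper tail multiplies clearance at high eGFR. Consequently
the nomogram built on the surrogate recommends somewhat higher doses than
the published chart at the high-eGFR/low-TBW corner (maximum ~4600 mg and
~58 mg/kg vs 4200 mg and 49 mg/kg), and the 24-h trough PTA at the median
profile comes out ~0.28 vs 0.20. The 48-h trough PTA (~0.80 vs 0.81) and
the simulate-refit recovery of CL1/V1 (within ~3%) reproduce closely.

## PTA and nomogram

Efficacy target: C1h ≥ 8×MIC with MIC 8 mg/L → 64 mg/L, evaluated 1 h
after the start of the 30-min infusion. Safety marker: trough ≤ 2.5 mg/L
at exactly 24.0 and 48.0 h from infusion start. Exposures are true
concentrations (no assay noise) — the PK-PD target concerns true exposure —
with an `add_residual_error` flag preserving the alternative.

For each (eGFR, TBW) cell the recommended dose is the lowest grid dose
(1300–5800 mg, step 100 — the published optima are multiples of 100) whose
PTA reaches 0.9 over 1000 draws. One draw set is shared by the entire
table (common random numbers), which makes PTA exactly non-decreasing in
dose and the recommended dose exactly non-decreasing in eGFR and TBW. The
eGFR grid is 20–135 in steps of 5 (chart granularity is not stated); TBW
takes the cohort's 10th/50th/90th percentiles {52, 76.5, 125} kg. At
n_sim = 1000 the Monte-Carlo SE of a PTA near 0.9 is ±0.0095, i.e. about
±100 mg on a recommended dose.

## Visual predictive check

Subject-level VPC: for each subject, n_sim (default 1000) parameter
vectors are drawn from the population distribution, the subject's own
design is re-simulated with residual noise, and observed and simulated
concentrations are pooled into time bins. Binning is quantile-based
(equal observation counts) because sampling concentrates at 1 h; when the
design has few distinct times each gets its own bin, and bins holding
fewer than two observations merge into a neighbor. The reported coverage
statistic is the fraction of bins whose observed median lies inside the
simulated 5th–95th band.

## Problem sizes and determinism

Default experiment sizes used by the test suite and the acceptance script:
138 subjects per replicate, 10 replicates for recovery medians, 1000
Monte-Carlo draws per PTA cell, 500–1000 simulations per subject for VPC,
and fit settings of 128–256 initial support points with 5–8 refinement
cycles — sizes at which every reported quantity is stable to well within
its comparison tolerance while a full run of everything completes in
minutes. All randomness flows from explicit seeds (scrambled Sobol for
grids, `numpy` Generators elsewhere); re-running any stage with the same
seed reproduces it bit-for-bit.

## Limitations

* Single-dose analysis only; no interoccasion variability, no
  Michaelis-Menten elimination, no renal-replacement-therapy submodel.
* The nonparametric solver is an adaptive local-search implementation of
  the maximum-likelihood problem, not a re-implementation of the published
  interior-point NPAG; it matches convex-oracle solutions for the weight
  step and recovers generating typical values, but support-point
  geometries are not comparable point-for-point.
* γ and CL2 estimates carry the sparse-design biases described above.
* Everything downstream of the surrogate distribution inherits its
  independence/shape assumptions; the published chart's exact dose values
  are reproduced only to within the tail-sensitivity discussed.
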