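# Methods

## The model

Let `y_ij ∈ {0,1}` indicate whether patient `i` showed an over-50% reduction
in seizure frequency (relative to the pre-treatment baseline) at visit `j`,
and let `C_i` be the patient's predicted steady-state trough VPA
concentration in μg/ml. The exposure-response model is a logistic regression
with one normal random effect per patient:

    logit Pr(y_ij = 1) = A_i + S_i · (C_i / 100) + η_i,   η_i ~ N(0, ω²)

    A_i = intercept + β_age·age_i + β_CBZ·CBZ_i + β_CZP·CZP_i
          + β_GA·[scn1a=G/A] + β_AA·[scn1a=A/A]
    S_i = slope + β_partial·[partial] + β_PHT·PHT_i + β_TPM·TPM_i
          + β'_GA·[G/A] + β'_AA·[A/A]

Age enters in **years** and concentration in units of **100 μg/ml**; this
is the unique scaling under which the packaged estimates reproduce all six
shipped worked-example optima to within 1 μg/ml, and it fixes an
inconsistency between alternative renderings of the published equation. All
visits of a patient share a single η (dose, hence predicted concentration,
is treated as constant within patient). An alternative quadratic form
`θ1 + (C/100 − θ2)²·θ3 + η` is supported for the concentration term.

The packaged final estimates (`vpapkpd/data/final_model.json`): intercept
6.09, age 0.98/yr, CBZ −1.75, CZP −1.18, G/A −5.87, A/A −4.88 on the
intercept; slope −13.5 with partial +2.41, PHT −3.62, TPM −1.73, G/A +10.1,
A/A +9.48; ω² = 11.3.

## Exposure prediction

The PK model is fixed, not re-estimated: `Vd` and `CL` are power functions
of the daily dose with multiplicative covariate effects on `CL` (female
0.875, CBZ 1.22, PB 1.10, PHT 1.40, CLB 0.915). Absorption rate, lag time
and bioavailability are not identifiable from the inputs this package
consumes, so they are explicit configuration (defaults `ka = 1.0 /h`,
`tlag = 0.5 h`, `F = 1`, `τ = 12 h` — sustained-release VPA is typically
dosed twice daily). The default exposure summary handed to the PD model is
the steady-state **average** concentration `F·dose/(24·CL)`, which depends
on none of those three parameters; `exposure_mode="trough"` evaluates the
full one-compartment superposition profile at `t = τ` instead. The two
differ by a within-interval fluctuation factor; because the PD slope is
estimated against whichever summary is used, the choice matters only when
mixing a model fitted under one mode with predictions under the other.
Concentrations are μg/ml ≡ mg/L throughout.

## Estimation

The marginal likelihood integrates η out per subject. Two integrators are
implemented:

- **Laplace** (default): the per-subject posterior mode η̂ solves
  `Σ_j (y_ij − p_ij) = η/ω²`, found by a bracketed, safeguarded Newton
  iteration (the left side is strictly decreasing in η; bisection fallback
  guarantees progress when curvature is tiny, as happens for saturated
  subjects with large ω²). The approximation is
  `log L_i ≈ Σ_j bern_ij(η̂) − η̂²/(2ω²) − ½log ω² − ½log(−H_i)` with `H_i`
  the total curvature; the 2π factors of the prior and the Laplace integral
  cancel exactly, so the reported objective (−2 log L) carries no additive
  constant beyond that convention. Only differences between nested fits are
  interpreted.
- **Gauss–Hermite quadrature** (≥64 nodes) as the numerical reference.

The outer optimisation is BFGS on `(β, log ω)` with an **exact analytic
gradient** of the Laplace objective: the mode-dependent terms use the
envelope theorem, and the log-curvature term is differentiated through η̂
via the implicit function theorem (verified against central finite
differences in the test suite). Three optimiser starts are used (one
data-driven, the rest seeded perturbations), followed by damped Newton
polishing with a finite-difference Hessian of the exact gradient; the same
Hessian supplies standard errors (delta method for ω² = e^{2u}). ω is
parameterised as log ω so the variance stays nonnegative. Convergence
requires the gradient norm to be small relative to the objective;
separation (unbounded estimates) is flagged through a standard-error
overflow warning or a non-positive-definite curvature warning.

Accuracy of the Laplace approximation, measured against dense numerical
integration: worst-case error over random subjects (1–12 records) is
7×10⁻³ for ω² ≤ 0.5, 1.4×10⁻² for ω² ≤ 1, and grows to O(0.1) at ω² ≈ 16,
where a saturating sigmoid times a wide Gaussian gives a strongly skewed
posterior — an intrinsic property of the approximation, not of this
implementation. 64-node quadrature agrees with 128-node to 10⁻⁸ for
ω² ≤ 1; at very large ω² the integrand develops a near-step kink and node
convergence slows. The tests assert each tolerance in the regime where it
genuinely holds and separately characterise the degradation.

## Covariate selection

Candidates (14 clinical covariates plus the genotype pair, each on
intercept and slope) are screened in a fixed canonical order. The forward
pass tests each candidate one at a time against the base model and admits
every candidate whose objective-function drop reaches the 95% χ² quantile
for its degrees of freedom (3.84 for df = 1, 5.99 for the two genotype
indicators; ties at the threshold count as significant); the full model
refits all admitted covariates jointly. The backward pass repeatedly
removes the covariate whose deletion costs least, as long as that cost is
below its threshold. Non-converged candidate fits are recorded in the trace
and treated as not significant. The procedure is deterministic for a given
dataset and seed. Under a pure-noise covariate the forward-inclusion
acceptance rate is calibrated to ~5% (asserted over 400 seeded replicates).

## Validation

The bootstrap resamples **subjects** with replacement, stratified by SCN1A
genotype × seizure locus (the final model's categorical covariates) so each
replicate preserves stratum counts; replicates refit from the original
estimates (single start) and count as *successful minimisations* only when
the optimiser converged **and** the curvature is positive definite (finite
SEs) — NONMEM-style semantics. Summaries are medians and percentile
2.5/97.5 intervals over successful replicates only.

The visual predictive check simulates the responder outcome at the original
design points, one new η per subject per replicate, bins records by deciles
of predicted concentration (configurable), and compares the observed
responder proportion per bin with the simulated 2.5/50/97.5 percentile
band. Empty bins are dropped with a warning.

## ROC and the optimal concentration

ROC analysis scores the **population** logits (η = 0, per visit record)
against observed outcomes: whether the original analysis used population or
individual predictions is not determinable, and η = 0 is the reproducible
choice. AUC is the Mann–Whitney concordance probability (ties count ½);
its 95% CI is a percentile bootstrap stratified by outcome (2,000
resamples). The Youden cut-off maximises sensitivity + specificity − 1 over
the observed logits, ties resolving to the smallest threshold (the lower
required concentration). The pipeline recomputes a cut-off from its input
data but accepts a user-supplied one; 0.1 — the published operating point —
is the packaged default.

Inversion at η = 0: with adjusted intercept `A` and slope `S` (per
100 μg/ml), a falling response curve (`S < 0`) crosses the cut-off at
`100·(A − cut)/(−S)`; patients whose logit is everywhere above the cut-off
are flagged `any_concentration`, and those who can never reach it
`unattainable`. The quadratic form returns the smallest positive root, or
`unattainable` when the discriminant is negative.

## Synthetic cohorts

The generator emulates the study cohort's margins: 77 patients; ages
truncated-normal 15.2 ± 8.2 on [0.8, 36.9] years; 37.7% female; 87% partial
seizures; 49.4% symptomatic; 76.6% intellectual disability; the nine
co-medication prevalences as reported; SCN1A A-allele frequency 0.617 with
Hardy–Weinberg genotype draws; daily dose truncated-normal 1120 ± 592.5 mg
on [50, 3200]; visit counts Poisson with mean 729/77 ≈ 9.5 clipped to ≥1
(the clip's probability mass is negligible, so the expected record total is
≈729). Exposure is the PK module's average-concentration summary, and the
responder outcome is drawn per visit from the final-model truth with one
normal random effect per patient.

What it does **not** emulate, hence what passing tests do not show about
real data: covariates are sampled independently (the joint distribution was
never reported), dose titration and dropout are absent, dose (and so
exposure) is constant within patient, and the responder outcome is
generated directly from the Bernoulli model rather than through seizure
counts (an optional lognormal-baseline/Poisson-count layer exists for I/O
testing). One consequential property of the published effect sizes: with
the reported age effect and exposure distribution, the implied per-record
responder rate is ≈0.95, so a 77-subject cohort is close to separation for
the 13-parameter final model — parameter-recovery and bootstrap experiments
in the test suite therefore run at 500 subjects (where the model is well
identified) or on a moderate truth chosen to give a balanced outcome.

## Problem sizes used in the test suite

Chosen as the package's own scaling of the published procedures:
bootstrap experiments use 100 replicates (study: 1,000); the recovery
experiment uses four 500-subject cohorts; the type-I calibration uses 400
replicates of 60-subject cohorts; the VPC uses 1,000 simulated datasets
(matching the study).

## Known limitations

- Laplace estimates on saturated binary data are noticeably variable; on
  occasional cohorts the MLE inflates all logit-scale coefficients together
  (a ridge direction of the likelihood), which percentile bootstrap
  intervals then track rather than correct.
- The trough-vs-average exposure ambiguity above cannot be resolved from
  the packaged inputs; `css_avg` is the default and documented as such.
- The optimal-concentration inversion targets efficacy only; it encodes no
  toxicity ceiling, and values far above the usual therapeutic range should
  be read as "raising the dose is unlikely to achieve the target", not as
  dosing advice.
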