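# Methods

## Models

Infused fluid is tracked as *expansions* of body fluid spaces.  With
central expansion x₁ = v_c − V_c and peripheral expansion x₂ = v_p − V_p
(both 0 before infusion), the one- and two-volume fluid-space models are

    1-VOFS:  dx₁/dt = R₀(t) − k₁₀ x₁
    2-VOFS:  dx₁/dt = R₀(t) − k₁₀ x₁ − k₁₂ x₁ + k₂₁ x₂
             dx₂/dt = k₁₂ x₁ − k₂₁ x₂

Only expansions appear in the dynamics, so the peripheral baseline volume
V_p is never needed and is not a model parameter.  Model dilution is
x₁/V_c, matching the observable (v − V)/V; the alternative (v − V)/v is not
used.  Parameters and units: V_c (mL), k₁₀, k₁₂, k₂₁ (/min), R₀ (mL/min),
time in minutes from infusion start.

Within each constant-rate segment the solution is evaluated in closed form
(scalar exponential, or the 2×2 matrix exponential via its spectral
decomposition) with exact state handoff between segments; cumulative
elimination is k₁₀∫x₁ dt, also closed form, so the volume balance
infused = x₁ + x₂ + eliminated holds to rounding error on every output
grid.  An adaptive LSODA integration of the same ODEs is available as an
independent cross-check (`simulate(..., method="numeric")`; agreement is
asserted at 1e-8 relative in the tests) and serves as the automatic
fallback in the measure-zero case of nearly coincident eigenvalues
(relative gap < 1e-10).  The default output grid is 1 min over [0, 180],
the study's observation window.

## Plasma dilution

Dilution at each sampling time is the mean of the hemoglobin- and
red-cell-derived terms, each (C(0)/C(t) − 1)/(1 − HCT(0)).  Only the
*baseline* hematocrit enters: (1 − HCT₀) converts whole-blood dilution to
plasma dilution at baseline.  Serial HCT values are carried for QC but not
used.  When one analyte is missing the available term is used and the
point flagged; points missing both are kept as NaN and counted, never
silently dropped.

Baselines are the arithmetic means of the duplicate time-0 draws; the
duplicate coefficient of variation uses the unbiased two-point SD
|x₁ − x₂|/√2.  The optional correction for hemoglobin lost to serial
sampling models each 0.4-mL draw as removing hemoglobin mass from a
well-mixed pool of BW × 60 mL/kg blood (configurable 40–66 mL/kg, the
feline literature range), multiplying the expected baseline by
(1 − v_s/BV) per preceding draw; returned saline flush volume carries no
hemoglobin mass and is ignored.  The correction is off by default — the
0.4-mL draws make it a ≲3% effect over the whole experiment — and
monotonically lowers dilution when on.

The cohort exclusion screen computes pointwise z-scores of each series
against the leave-one-out cohort mean and SD at each shared post-baseline
time (leave-one-out so a gross outlier cannot mask itself by inflating the
cohort SD) and flags a series when at least half its points exceed 3 SD.
The statistic behind the original 3-SD rule is not fully specified; this
pointwise rule with a 50% fraction threshold is our documented choice.
Exclusion only sets a flag — data are never deleted.

## Estimation

**Individual fits** maximize the Gaussian likelihood of the dilution
series (additive residual error) by least squares on log-parameters, with
multi-start initialization (default 10 starts: a plasma-volume heuristic
for V, log-uniform rate constants, seeded RNG).  The time-0 point is
identically zero by construction and is not counted as an observation.

**Population fits** are non-linear mixed-effects: log-normal random
effects on the structural parameters (diagonal covariance, reported as
CV% = √(e^ω²−1)), a single additive residual SD on dilution shared across
subjects, and multiplicative covariate effects (e^coefficient level shifts
for categorical covariates, (value/reference)^coefficient power laws for
continuous ones; reference = cohort mean).  The marginal likelihood uses
the Laplace approximation at the conditional modes with Gauss-Newton
curvature (a FOCE-class approximation; exact proprietary FOCE-ELS
internals are not reproduced).  The inner penalized problem is solved by a
damped, batched Gauss-Newton warm-started across outer iterations; the
outer problem by L-BFGS-B on log-scale parameters.  The approximation was
checked against exact Gauss-Hermite integration of the marginal likelihood
on two-parameter cases (agreement within a few units of −2LL across a wide
parameter range, identical optimum location).  Wald CIs come from the
numerically differentiated information matrix, inverted on its
well-conditioned eigenspace; a coordinate with material leverage on flat
directions reports NaN rather than a fabricated interval.

**Identifiability and stabilization.**  Under the study sampling grid the
distribution transient has a half-time of ~1.3 min at the reported
k₁₂/k₂₁, so it is ~93% complete by the first post-bolus sample: the data
sharply determine the quasi-steady effective volume V_eff = V_c(1+k₁₂/k₂₁)
and the terminal slope, but the split of V_eff into V_c versus k₁₂/k₂₁ is
nearly flat in the likelihood (profile −2LL changes by ~1–2 units while
V_c moves ±40%, matching the wide reported CIs).  Unstabilized maximum
likelihood drifts into a degenerate small-V_c/fast-k₁₂ corner on a
substantial fraction of cohorts — verified against exact quadrature, so it
is a property of the likelihood, not of the approximation.  The population
estimator therefore uses two stabilizers, both documented, configurable
and removable (`urine_totals=None`, `vc_stabilizer_sd=None` recover pure
ML):

* **Urine anchoring.**  Renal loss equals k₁₀·V_c·∫dilution dt, so each
  subject's urine-to-dilution-AUC ratio estimates its log(k₁₀·V_c).  The
  fit adds a Gaussian pull (log-scale SD 0.2, from the urine
  observation-noise budget: ~30% CV per 30-min increment → ~15% on the
  total, plus AUC noise) on each subject's log product.  This is the
  stabilizing role urine output plays in this kind of analysis.
* **Plasma-volume pull on V_c (2-VOFS only).**  The central space of the
  two-volume model is physiologically the plasma volume, measurable as
  BW × 45 mL/kg × (1 − HCT).  A weakly-informative log-normal pull
  (SD 0.3, i.e. ×/÷1.8 at 2 SD) of the typical V_c toward the cohort mean
  of that quantity keeps the estimator off the degenerate ridge.  It is
  not applied to the one-volume V, which is the whole expandable space.

With both stabilizers, simulated operating characteristics at the study
design (10 subjects, 18 samples, 3.5% measurement CV, 100 seeded cohorts)
are: typical V_c bias +6%, k₁₀ bias −3%, and 88%/80% of replicates within
±25% of truth for V_c/k₁₀ respectively.  Without them the V_c estimate is
essentially unusable at this design — a single experiment of this shape
cannot resolve V_c from dilution alone, and adding early (<5 min) samples
would be the design fix.

**Model comparison** uses the −2LL reduction against the fixed critical
value 6.64 (χ², p<0.01, 1 df) with strict inequality, regardless of the
number of added parameters — mirroring the original rule; a
degrees-of-freedom-correct χ²(0.99, Δparams) threshold is available via
`df_correct=True` and is what the type-I-error simulations use.  Because
the V_c pull applies only to the two-volume model, the penalized −2LL
comparison is slightly conservative against the richer model.

**Covariate search** is forward inclusion then backward elimination over
(parameter, covariate) pairs.  A candidate is accepted when (a) it lowers
−2LL by more than 6.64, (b) every added coefficient is individually
significant at 95% — assessed by per-coefficient *profile* likelihood-ratio
tests (−2LL rises by more than 3.84 when that single coefficient is
removed), which is the robust equivalent of "the multiplicative effect's
CI excludes 1" and avoids Wald intervals on a ridged surface — and (c) the
affected parameter's IIV CV stays below 50%.  Continuous covariates enter
as subject-level means (the slowly varying pressure/heart-rate series make
the subject mean the natural summary); nearly collinear candidates
(|r| > 0.95) trigger a warning and deterministic candidate ordering.
Every tested step is written to an audit trail.

## Synthetic cohorts

The generator reproduces the cross-over design: n subjects (default 10)
with truncated-normal body weight 4.79 ± 0.69 kg (> 2 kg), each receiving
PLA 20, HS 3.3 and HES 5 mL/kg over 15 min; sampling at 0, 5, 10, 15, 20,
30, 40, 50, 60 then every 15 min to 180 min with duplicate baselines;
bladder volumes every 30 min.  Individual parameters are typical values
(defaults: the justified per-fluid models, or the group model when true
covariate effects are supplied) times e^η with per-parameter log-normal
IIV at the reported CVs (~17–33%).  Hematology is generated by inverting
the dilution relation (Hb(t) = Hb₀/(1 + d(1−HCT₀)), RBC analogous, with
the red-cell baseline tied to hemoglobin through a fixed 14.2 g/L per
10¹²/L ratio with 5% subject scatter) and applying independent
multiplicative log-normal measurement noise at the duplicate-baseline CVs
(Hb 3.53%, RBC 3.38%).  Serial HCT follows the noise-free blood dilution.
Arterial pressures and heart rate are log-normal subject levels around the
reported medians (MAP 86, SAP 116, HR 157) with AR(1) within-subject
jitter so continuous-covariate searches see realistic signal; DAP closes
the MAP = DAP + (SAP−DAP)/3 identity.  Urine observations apply unit-mean
log-normal noise (CV 30%, a documented stand-in — no observation-error
model is reported for the ultrasound estimates, only that they were
imprecise for small volumes) to the true per-interval eliminated volumes,
so observed urine is mean-preserving.  An optional mode depletes the
hemoglobin pool by 0.4 mL per draw to carry the sampling artifact the Hb
correction removes.  Every cohort is accompanied by a truth ledger
(individual parameters, noiseless curves, eliminated volumes) and is
bit-reproducible from its seed (numpy PCG64).

What the generator does **not** emulate: splenic contraction and
catecholamine-driven red-cell release, anesthesia or drug effects on
vascular tone, analyzer drift or settling artifacts, osmotic fluid shifts
(the hypertonic-saline arm uses the same two-volume structure that was
ultimately retained for it), and ongoing fluid losses.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the stated statistical assumptions, not robustness to those biological
effects.

## Simulation study sizes

The test suite's calibration studies use: 100 seeded cohorts for the
population recovery study; 10 replicates each for the covariate-selection
and null-selection operating characteristics; 20 replicates for the
model-comparison type-I study; 40 replicates for single-subject fit
calibration.  These sizes give stable pass/fail behaviour under fixed
seeds while keeping the default test run short.

## Numerical choices and edge cases

* Log-scale optimization everywhere enforces positivity; box bounds keep
  exponentials finite.  Closed-form curve evaluation clips elapsed times
  into each phase so every exponent is non-positive (no overflow anywhere
  in the search region).
* Inner Gauss-Newton stops on step < 3e-7 (the finite-difference Jacobian's
  accuracy floor) or stagnation; ω is bounded in [0.01, 3] and a parameter
  excluded from the IIV set is pinned at ω = 1e-3.
* Degenerate inputs: identical cohort series produce no exclusions; zero
  infusion produces identically zero curves; a zero-IIV generator yields
  fitted CVs < 5%; duplicate mean at time 0 makes dilution(0) exactly 0.
* The regimen designer defines "achieve" as dilution = target at the end
  of the bolus, computed by exact linear scaling in R₀ (the model is
  linear), and the maintenance CRI as the steady-state identity
  R₀ = k₁₀·target·V_c.  For two-volume fluids the post-bolus dilution
  transiently dips *below* target while the peripheral space fills before
  converging back — the redistribution dip; the one-volume model holds the
  target exactly.  Relaxation times are governed by the slow eigenvalue
  ≈ k₁₀k₂₁/(k₁₀+k₁₂+k₂₁), which is several-fold longer than ln2/k₁₀.
* Published prescription-table maintenance rates reproduce exactly from
  the steady-state identity.  The published bolus doses "to achieve" a
  target do not follow from the end-of-bolus criterion (they yield ~19%
  at a 15% target under the group model); the exact design criterion
  behind them is not stated, so the package emits its own exact-criterion
  doses and leaves the comparison to the user rather than guessing.

## Known limitations

* V_c is weakly identified by design (see above); results for it lean on
  the physiologic stabilizer and should be read with that in mind.
* The half-life t½ = ln2/k₁₀ describes elimination from the central space,
  not the terminal decay of total expansion in the two-volume model.
* No three-volume (osmotic) model for hypertonic saline and no saturable
  elimination; fitting assumes a single constant-rate bolus from time 0
  (the study design); arbitrary schedules are supported in simulation.
* No correlated random effects and no Bayesian posterior — CIs are
  asymptotic or profile-based.
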