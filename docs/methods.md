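# Methods

## Structural model and solution

The disposition model is a linear mamillary three-compartment system with a
first-order absorption depot. States are amounts (µg) in depot, central
(volume V2), shallow peripheral (V3, exchange clearance Q3) and deep
peripheral (V4, Q4); elimination is first-order from central with clearance
CL. Concentration is the central amount divided by V2; with doses in mg and
volumes in L, the single mg→µg conversion (×1000) inside the engine makes
amount/volume come out in µg/L ≡ ng/mL. The parameter set
(CL, V2, V3, V4, Q3, Q4, KA, F1) is the standard interpretation of a
three-compartment oral popPK model; no absorption lag is modelled.

The rate matrix is solved exactly: an eigendecomposition yields the
central-compartment impulse response as a sum of four exponentials, which
is superposed over the dose history. Multiple-dose steady state is the
closed-form geometric-series limit Σᵢ wᵢ e^{λᵢt}/(1 − e^{λᵢτ}); a
simulate-to-convergence fallback (relative tolerance 1e−8, with the
achieved tolerance reported on failure) covers defective rate matrices,
which do not occur for admissible parameters except on measure-zero
coincidences such as KA equal to a disposition eigenvalue (detected via
eigenvector conditioning; the engine then steps with the matrix
exponential). Mass balance — depot + compartments + cumulative eliminated
equals F1 × administered dose — is verified in the tests at relative 1e−6
via an augmented five-state system.

A batched code path realizes many log-normal parameter draws at once
through a vectorized eigendecomposition; it is bit-compatible with the
scalar path and is what makes 1000-replicate simulation diagnostics cheap.

## Typical parameter values

The shipped default vector is the fixed published typical values (medians):
CL 1.76 L/h, V2 227.32 L, V3 176.03 L, V4 39.30 L, Q3 26.56 L/h,
Q4 0.56 L/h, KA 1.68 h⁻¹, F1 0.75. Where the source tabulation and its
accompanying text disagree (V2 227.32 vs 212.9 L; KA 1.68 vs 1.67; Q3 26.56
vs 26.36), the tabulated medians are used. KE is always derived as CL/V2
(0.0077 h⁻¹, printed as 0.01 at two decimals) and never stored. The
terminal half-life implied by these medians is ≈182 h, driven by the slow
deep compartment (Q4/V4); the tabulated ≈82 h half-life corresponds to an
effective (ln 2/KE-scale) rather than terminal slope, a discrepancy we
surface rather than resolve.

## Random effects and residual error

Inter-individual variability is log-normal on (CL, V2, F1, KA):
realized = typical × e^η, η ~ MVN(0, Ω), diagonal by default. The published
validation does not report Ω or σ magnitudes, so the repository defaults —
30 % CV on CL and V2, 20 % on F1, none on KA; proportional residual SD 20 %
plus additive 1 ng/mL — are this package's own choices of a realistic
sparse-TDM error structure, not literature values. Bioavailability under a
positive η draw may exceed 1; realized individual parameter sets are
therefore constructed with relaxed validation (conventional popPK
behaviour), while user-supplied base parameters must keep F1 ∈ (0, 1].

Observed concentrations are DV = C(1 + ε_prop) + ε_add; negative draws are
resampled (bounded retries, then clamped at zero).

## MAP individual estimation

Each subject's η is the minimizer of
Σⱼ[(DVⱼ − Cⱼ(η))²/varⱼ + log varⱼ] + ηᵀΩ⁻¹η with
varⱼ = (σ_prop Cⱼ)² + σ_add², optimized over the η slots with nonzero Ω
variance only. The optimizer starts at η = 0 (L-BFGS-B, tight tolerances),
adds up to three jittered restarts on failure (lowest objective wins,
flagged rather than raised), and finishes with a Nelder–Mead polish because
quasi-Newton steps with finite-difference gradients stall in the sharp
valleys that near-noiseless residual models produce. Two properties bound
what MAP can recover and are exercised in the tests: the estimate is pulled
toward zero by the prior (shrinkage O(Ω⁻¹/H), with H the likelihood
curvature), and the log-variance term biases fitted concentrations low by
O(σ_prop²) even on noiseless data.

## External-validation metrics

PE(%) = (Cpred − Cobs)/Cobs × 100 and APE = |PE|: the percent factor is
applied once, in PE — the only reading consistent with the magnitudes the
metric suite is meant to reproduce. MPE = mean(Cpred − Cobs) in ng/mL
carries an SD and a one-sample t-test p-value (Wilcoxon signed-rank by
flag). MdPE/MdAPE are medians, F20/F30 are percentages of |PE| ≤ 20/30.
Records with Cobs ≤ 0 are excluded with a logged count. Stratification uses
half-open bands [0, 100), [100, 150], (150, ∞) ng/mL so that "100–150" is
inclusive; an empty band is reported as absent, never as zero. R² is the
squared Pearson correlation of observed vs predicted, reported as a
fraction and a percentage. Gate boundaries are inclusive (MdAPE = 30.0
passes).

## NPDE

Per subject, observed and simulated vectors are centred on the simulated
mean and decorrelated with the Cholesky factor of the simulated covariance
(variance-only decorrelation, with a logged warning, when the covariance is
singular); the decorrelated observation's rank fraction among its
decorrelated simulations is inverse-normal transformed. Ties are broken by
seeded uniform jitter; boundary ranks are clamped to [0.5/K, (K − 0.5)/K].
K ≥ 100 is enforced. At the default K = 1000 the finite-K variance
inflation is negligible; the null-calibration test (1000 simulated
subjects, 4 observations each) checks mean ≈ 0 and variance ≈ 1 within 3 SE
and a non-significant KS test against N(0,1) at α = 0.01.

## pcVPC

Observations and replicate simulations are corrected by
pcY = Y · median(PRED_bin)/PRED; bins default to the nominal sampling
offsets (0, 2, 4, 6 h), the natural choice for a sparse nominal-time
design, with quantile binning as an alternative. Records with PRED = 0 are
excluded (logged); bins under 3 observations merge into their nearest
neighbour (logged). Per bin, the observed 5th/50th/95th percentiles are
compared with nonparametric 95 % CIs formed from the per-replicate
percentile estimates (2.5th/97.5th percentiles across replicates); a
coverage summary counts observed percentile points inside their CI. The
true-model calibration test uses 200 replicates per seed, pooled over eight
seeds — a deliberate scale-down from the 1000-replicate production default,
which the acceptance script uses.

## Synthetic cohort: what it emulates, and what it cannot show

The generator reproduces the validation study's design: n = 14, 30 mg once
daily with food for 14 days (steady state by protocol), one
inhibitor-negative subject on 60 mg (mirroring the policy that a strong
CYP3A4 inhibitor forces the 30 mg dose), sampling the next morning at
predose/+2/+4/+6 h with uniform ±15 min jitter (predose drawn in
[−15 min, 0] so it remains a trough), covariate frequencies 64 % female /
79 % inhibitor / 100 % fed, and optionally one subject reduced to the +6 h
sample only, giving the cohort's 53 observations. Sampling offsets are
taken from that day's dose; nominal and actual times are both stored.

The published typical values imply a steady-state average concentration
(F1·Dose/(CL·τ) ≈ 530 ng/mL) several-fold above the concentrations the
validation cohort actually showed (timepoint means 82/129/141/120 ng/mL) —
presumably because unreported covariate scalings intervene. The generator
therefore uses the same typical values with an effective bioavailability
calibrated once (F1 = 0.213) so that simulated day-14 timepoint means land
near the observed means; a seeded 200-subject structural-plausibility test
holds them within ±40 %. This is a repository calibration that makes the
synthetic data resemble the study's concentration scale; it is not a
literature value. A consequence worth stating plainly: synthetic data are
generated by the same model family that predicts them, so passing
validation metrics here demonstrate the machinery (and the self-consistency
of the pipeline), not the clinical model's field performance — the
published cohort's population-level gate failures arose from real model–
patient mismatch that no self-consistent simulation can reproduce.

Bioanalytical batches follow the assay design: the 10-level 6–200 ng/mL
calibration ladder, QC levels 20/80/140 ng/mL with 6 replicates × 3 days,
response ratio = slope·conc + intercept around the published line
(0.0116, 0.1429), multiplicative within-day noise (5 % CV), a log-scale
between-day effect (6 % SD, so inter-day RSD exceeds intra-day) and a fixed
−6 % analyte loss placing accuracy in the high-80s-to-90s range typical of
liquid–liquid extraction. The loss acts on the analyte amount, not the
whole response, so accuracy shifts uniformly across levels.

## Bioanalytical statistics

Calibration is weighted least squares with weights 1, 1/x or 1/x² on
nominal concentration (1/x² default — the convention for wide ranges);
back-calculation is the algebraic inverse, with below-zero results flagged
but retained. Intra-day precision pools within-day variances (mean of day
means, pooled within-day SD); inter-day uses the grand mean and total SD; a
one-way ANOVA variance-component estimator is available by flag since the
source does not state which convention its table used. Accuracy is
100·mean/nominal. LLOQ passes on S/N ≥ 10, accuracy ∈ [80, 120] % and
RSD < 20 % (strict); carryover requires blank/LLOQ < 0.20 and selectivity
< 0.02, both strict. Matrix effect is mean(post-spiked/neat), recovery
mean(pre/post); IS-normalized versions divide the analyte ratio by the IS
ratio pairwise, so proportional suppression of analyte and internal
standard normalizes to exactly 1.

## Numerical choices and degenerate inputs

- Eigendecomposition path switches to `expm` stepping when the eigenvector
  condition number exceeds 1e10.
- Steady-state fallback tolerance 1e−8 relative, with the achieved
  tolerance attached to the convergence error.
- MAP residual variances are floored at 1e−12 to keep the objective finite
  when a profile touches zero.
- Zero doses contribute nothing; zero observations, empty metric inputs,
  degenerate calibration (identical responses at distinct levels) and
  unpopulated reports raise typed errors rather than returning silence.
- Thresholds, band edges and weighting schemes are configuration, with the
  published acceptance values as defaults.

## Problem sizes

Default test-suite scales: 1000 simulated subjects × K = 1000 for NPDE null
calibration; 8 seeds × 200 replicates for pcVPC coverage; 10⁵ draws for the
IIV law-of-large-numbers check; 10⁴ draws for the residual-CV check. The
acceptance script uses the 14-subject study design with K = 1000
replicates throughout.

## Known limitations

- No absorption lag, no enterohepatic or time-dependent clearance terms;
  the consolidation-phase concentration drift reported elsewhere for
  quizartinib is out of scope.
- The active metabolite (AC886) is not modelled, mirroring the validation
  study's own exclusion.
- Covariates travel with the dataset but only the inhibitor→dose policy is
  active by default; a multiplicative-on-CL covariate hook exists and is
  off.
- BLQ observations carry a flag but no imputation policy; the study
  reports none was needed above its 6 ng/mL LLOQ.
- MdAPE ≥ |MdPE| is not asserted globally — medians of |x| and |median x|
  are only ordered when all errors share a sign.
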