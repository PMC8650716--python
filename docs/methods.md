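# Methods

`neuroqol` implements a complete analysis chain for a longitudinal
observational design in multiple sclerosis (MS): regional cerebral blood
flow (CBF) measured with arterial-spin-labeling fMRI during a three-stage
stress paradigm (baseline 1, stress, baseline 2) at a baseline visit T0, and
health-related quality of life (HRQoL) measured with the HAQUAMS
questionnaire at T0 and a follow-up visit T1 several hundred days later.
The scientific question is whether the activity of latent neural networks
triggered by stress exposure or by stress cessation (relaxation) at T0
carries prognostic information about the change in HRQoL between T0 and T1.
Because no individual-level cohort data are distributed with the package,
every statistical guarantee is demonstrated on synthetic cohorts with
planted ground truth.

## HAQUAMS scoring (`haquams`)

Five subscales — fatigue (4 items), lower limb mobility (5), upper limb
mobility (5), social functions (6), mood (8) — are each scored as the
unweighted mean of their ordinal 1–5 items; the total score is the mean of
the five subscale scores; higher scores mean worse HRQoL.  The longitudinal
change score is T1 − T0, so positive change is worsening.  Two assumptions
are made explicit: the item→subscale rule is the instrument-standard
unweighted mean (only the subscale→total rule is externally fixed), and
items are taken to be pre-oriented (no reverse coding).  Missing items are
not imputed; a subscale with a missing item is missing, and a missing
timepoint makes the change score missing.

## Gray-matter group mask (`gm_mask`)

The voxel-level analysis mask is the intersection of three constraints:
(1) voxels whose across-participant mean gray-matter probability exceeds the
white-matter and CSF means (ties broken GM > WM > CSF, because the analysis
targets GM); (2) exclusion of every voxel lesioned in at least one patient
*plus its six face-adjacent neighbors* — the neighborhood is 6-connected in
voxel index units, so diagonal neighbors at index distance √2 or √3 are
retained even when anisotropic voxel sizes would change metric distances;
(3) coverage by every fMRI scan of every participant.  The dilation uses
`scipy.ndimage.binary_dilation` with the 6-connectivity structuring
element; each step's removal counts are logged as provenance.  Interpreting
the one-voxel neighborhood in index space rather than millimeters is a
documented choice; with strongly anisotropic slices a metric rule would
exclude fewer through-plane neighbors.

## Network extraction (`networks`)

Regional mean CBF (ml/100 g/min) per participant and stage is assembled
into participants × regions matrices.  Each participant's row is centered
by their global GM mean for that stage (`gm_center`), which removes
participant-level perfusion offsets.  The latent networks are the right
singular vectors of the centered *stress* matrix.  Deliberately, **no
region-wise (column) centering** is applied: the decomposition therefore
has exactly n_participants components for a full-rank wide matrix (28 in
the reference design), rather than the n−1 that a column-centered PCA would
leave.  Component signs are fixed by orienting each loading vector so its
largest-magnitude entry is positive.  Baseline stages are projected onto
the stress loadings to obtain stage scores; differential activity is
exposure = stress − baseline 1 and cessation = baseline 2 − stress, which
telescope to baseline 2 − baseline 1.  Winner-takes-all assigns each region
to the network with the maximal *absolute* loading (ties to the lower
component index); the absolute-value criterion is a documented choice since
loadings are signed.  A participant lacking the baseline-2 scan keeps their
exposure scores and carries NaN cessation scores, which downstream analyses
delete listwise for cessation only.

## Robust permutation inference (`robust`)

Each analysis regresses a HAQUAMS change score on one predictor of interest
plus fixed nuisance covariates.  The fit is a Huber M-estimate via
iteratively reweighted least squares: tuning constant c = 1.345 (the
standard 95%-efficiency default, exposed as a parameter), residual scale
re-estimated each iteration as the MAD about zero standardized by 0.6745,
convergence when the maximum coefficient change falls below 1e-8 (cap 200
iterations).  After 30 iterations the scale is frozen, which removes the
rare scale/coefficient oscillation of joint updates while leaving ordinary
convergence untouched.  The test statistic is the Wald statistic
W = β̂²/Var̂(β̂) with a sandwich variance (bread (XᵀWX)⁻¹, meat
Σ(wᵢrᵢ)²xᵢxᵢᵀ), which reduces to the HC0 heteroskedasticity-consistent
covariance of OLS in the equal-weights limit.  Significance comes from
permuting the predictor-of-interest column across participants with the
response and nuisance columns fixed — the studentized-statistic
construction of the robust permutation approach this follows — with the
add-one estimator p = (1 + #{W_perm ≥ W_obs})/(1 + n_perm), valid at any
finite permutation count.  A Freedman–Lane residual-permutation scheme
(permute the residuals of the nuisance-only robust fit, add them back to
its fitted values, refit the full model) is available as a configuration
alternative; both schemes are size-calibrated in the tests.  A signed `t_equivalent = sign(β̂)·√W` is reported
so that directions read like t statistics.  Exhaustive enumeration replaces
sampling for n ≤ 8.  Permuted designs differ from the observed one only in
the interest column, so the batched IRLS assembles normal equations from
precomputed nuisance cross-products; calibration studies with ~10⁷ refits
run in minutes on one core.

Two analysis frontends share this engine.  `screen_markers` tests nine
clinico-demographic/radiographic markers one at a time (nuisance: T0 total
score, follow-up days, intercept) at uncorrected two-sided α = 0.05 — a
screening step whose hits enter the key analysis as covariates.
`predict_hrql_from_networks` tests every process (exposure, cessation) ×
network × scale cell (nuisance: the scale's T0 score, follow-up days,
cognitive task load, disease type, intercept), Bonferroni-corrected within
each process × scale family with m = number of networks: per-test α =
α_FWE/m (0.05/28 → 0.0018 for the total score; 0.1/28 → 0.0036 for
subscales).  Defining the family per process × scale (rather than pooling
scales) is a documented choice.  Zero-variance predictors are reported as
non-testable without affecting the rest of the family.

## Mixed-model permutation tests (`lmm`)

Psychophysiological contrasts (perceived stress: stages V vs III and VII vs
V; pulse: IV vs II and VI vs IV) and longitudinal HRQoL change share a
balanced two-occasion design: fixed effect of interest = stage code (0/1)
or time-in-days (0 at T0, follow-up delay at T1), participant-level
nuisance covariates, and a per-participant random intercept.  Fitting is by
full maximum likelihood (not REML) so likelihoods are comparable across
permutations.  The public `fit_lmm` uses statsmodels `MixedLM`; permutation
loops use a profile-ML fitter specialized to the balanced paired case: the
2n observations rotate into n within-pair differences (variance σ²) and n
pair means (variance σ² + 2τ²), two independent Gaussian blocks solved by a
small coordinate-ascent iteration with τ² truncated at zero; the two
fitters agree to optimizer precision and are cross-checked in the tests.
The null distribution flips the earlier/later labels of the interest
regressor independently within each participant (2ⁿ relabelings, exhaustive
for small n, sampled otherwise), which is exchangeable under the null of no
occasion effect; a participant-level permutation of the interest-regressor
pairs is available as a configuration alternative.  One-sided p-values implement the directional claims
(increase under exposure, decrease after cessation, worsening over time);
two-sided inference is available.  When no within-pair variation exists the
occasion effect is exactly zero and p = 1 by construction.

## Synthetic cohorts (`synthetic`)

The generator plants every piece of structure the pipeline is designed to
detect, with defaults mirroring the reference design: 28 participants
(≈23 RRMS / 5 SPMS, ≈64% women), 100 atlas regions, follow-up uniform on
363–1169 days, baseline-2 fMRI missing for 1 participant (27 of 28), pulse
available for 21 of 28 (missing completely at random).

* **CBF**: X_stage = 50 + 10·S_stage·Lᵀ + g·1ᵀ + E (ml/100 g/min).  Loading
  columns L are orthonormal with zero region mean, so planted structure is
  invariant under row centering; random-orthonormal and block patterns are
  available.  Latent scores are i.i.d. normal per stage with per-network
  scales decaying geometrically (1.5·0.85ʲ) — distinct scales make the
  latent rotation identifiable — and the designated network's stress score
  is mean-shifted by +2.  Global offsets g ~ N(0, 5²) per participant and
  stage; noise E i.i.d. N(0, 1²) per region.
* **Outcomes**: each subscale's change is covariate terms (worsening
  2e-4/day of follow-up, +0.3 for SPMS by default) + the planted signal +
  N(0, 0.1²) noise, where the signal is the standardized designated-network
  differential times the configured effect size (planted into all subscales
  for a "total" target, or one subscale).  T1 item vectors are constructed
  to hit the target subscale mean on the 1/k grid of the k-item mean, so
  scores are quantized exactly as real item data would be; scores are
  clipped to [1, 5].  An outlier-fraction knob (default 0) contaminates
  change scores for robustness studies.
* **Psychophysiology**: ratings at stages I/III/V/VII from a latent normal
  rounded and clipped to the nine-point scale (stress stage +2 by default);
  pulse at II/IV/VI around 70 bpm with +10 under stress, participant random
  intercepts and Gaussian noise.
* The cognitive task-load covariate is standard normal — its real
  distribution is unreported, and this is the documented assumption.

What the generator does **not** emulate: voxel-level hemodynamics, spatial
autocorrelation between regions beyond the factor structure, systematic
(non-MCAR) missingness, item-level response styles, or floor/ceiling
pile-ups beyond clipping.  Passing recovery tests therefore show the
pipeline is correct and calibrated under the assumed factor-model
conditions, not that real cohorts satisfy those conditions.

## Calibration and recovery studies

The acceptance suite runs: (1) the analytic Bonferroni thresholds (0.0018,
0.0036); (2) the 28-component count; (3) permutation-test size at α = 0.05
over 1000 null datasets × 999 permutations, with Gaussian and t₃ outcome
noise, asserted inside the 99% binomial band [0.033, 0.069]; (4) exact
agreement of the sampled machinery with full enumeration at n = 5 (120
arrangements; 32 sign flips); (5) end-to-end recovery of a planted
cessation-network effect on the total score (effect size and seed panel
fixed by a pre-build oracle run) plus family-wise error control under the
global null over 500 seeds with 599 permutations per test (1/600 resolves
the 0.0018 threshold at half the cost of a longer run); (6) brute-force
oracle equivalence of the mask pipeline and the OLS/HC0 limit of the robust
fit; (7) the HAQUAMS scoring identities.  `scripts/acceptance.py` recomputes
scaled versions of the same quantities (400 null datasets, 30 recovery
seeds, 200 null-FWE seeds, 20 psychophysiology seeds) so the whole script
completes in a few minutes on one core; the panel sizes are the package's
reporting choice and are recorded in the output alongside each value.

## Numerical choices and limitations

Tolerances: IRLS 1e-8 on coefficients; PCA reconstruction asserted at 1e-8
relative; paired-ML variance iteration 1e-12 relative.  Ties: WTA → lower
component index; tissue argmax → GM > WM > CSF; permutation counting uses
weak inequality (≥), which is conservative.  Degenerate inputs: perfect
fits freeze at the OLS solution; zero within-pair variation short-circuits
to t = 0, p = 1; empty masks are returned with a warning.  The Wald
statistic's χ²(1) reference is asymptotic and is never used directly —
inference is always by permutation.  Known limitations: the sandwich
variance at n = 28 is noisy (the permutation calibration is what controls
size); Bonferroni is conservative under correlated networks; the
profile-ML fitter assumes exactly two occasions per participant and a
random intercept only.
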