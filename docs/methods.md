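# Methods

`lfconn` implements the connectivity analysis chain for staged
stimulus–response learning fMRI: stage-wise first-level GLMs, a global
phase-synchrony statistic regressed on the task model, psychophysiological
interactions (PPI), and bilinear dynamic causal modelling (DCM) with
fixed-effects Bayesian model selection — together with a synthetic-data
generator that makes the whole chain testable end to end against a known
ground truth.

## Task model

Two session types are constructed by `task_design`:

* **Instruction task** — four blocks; each opens with a 4-s rule-definition
  slide followed by 180 s of discrimination trials, partitioned into six
  contiguous 30-s learning stages.
* **Feedback task** — four blocks of 150 s (five stages); no rule slides;
  a random 50 % of trials are followed by correct/incorrect feedback and
  the rule must be found by trial and error.

Trials occupy 1.7-s slots; one third of the slots, drawn uniformly without
replacement per block (seeded), show fixation and enter no regressor.
Correct/incorrect labels come from a pluggable behaviour model; the default
stage-wise error probability decays geometrically (`p0 = 0.5`,
`decay = 0.3` per stage), which concentrates negative feedback in the first
stage and produces roughly 15–20 negative feedback events in a four-block
session.  Feedback events are modelled with a 1.5-s duration: the screen
event itself is brief, but its neural processing plausibly persists into
the inter-trial interval, and a sub-second boxcar leaves almost no trace at
a 2-s TR.

Regressors convolve event boxcars with the canonical double-gamma HRF
(response gamma peaking at 6 s, undershoot gamma at 16 s, ratio 1/6,
unit-peak normalised) on a microtime grid of TR/16 before down-sampling at
scan onsets; 1.7-s events against TR = 2 s alias badly at any coarser
resolution.  Trials belong to the stage containing their onset and never
split across stages.  The Novelty contrast weights stages
(3, 2, 1, −1, −2, −3) for the six-stage task and (2, 1, 0, −1, −2) for the
five-stage task; Task contrasts are all ones.

## Synthetic data generator

Each subject is generated by integrating the bilinear neural model

    dz/dt = (A + Σⱼ uⱼ(t) Bⱼ) z + C u(t)

through a balloon/windkessel haemodynamic model per region (the same code
path the DCM module uses), sampling at TR = 2 s, and adding (i) AR(1)
noise (innovation SD `white_sd`, coefficient 0.3), (ii) a slow cosine
drift (period 128 s, amplitude 0.6 % signal change, random phase) and
(iii) six smoothed random-walk motion traces used only as nuisance
regressors.

The default ground truths mirror the architectures the model comparisons
select.  The instruction-task truth has three cortical nodes (AIFO, IFS,
LFPC) with heterogeneous reciprocal coupling (0.05–0.18 s⁻¹), self
connections of −0.5 s⁻¹, Task driving all three nodes (0.022–0.035 s⁻¹)
and Novelty modulating LFPC→IFS and IFS→AIFO at +0.1 s⁻¹ per unit input —
the coupling asymmetry is deliberate, since a perfectly symmetric network
makes alternative modulation hypotheses artificially degenerate.  The
feedback-task truth adds a caudate node coupled bidirectionally to all
three cortical nodes (0.08 s⁻¹) with negative feedback as a driving input
to the caudate (0.6 s⁻¹); a variant replaces the drive with
feedback-*modulated* IFS↔caudate coupling (0.25 s⁻¹ each way) and can
append an IPC node (coupled to IFS, feedback-blind) as the control target
for the PPI double dissociation.  Inputs enter the neural model
unconvolved: Task as trial boxcars, Novelty as stage-long boxcars carrying
the contrast weights (mean-centred over the session), feedback as 1.5-s
boxcars at negative feedback events.

With these values the noiseless BOLD has an SD close to 1 % signal change,
and the default `white_sd = 0.95` puts the measurement noise SD at the
signal SD (SNR ≈ 1).  Cohorts draw each subject's free A/B/C entries from
Gaussians centred on the truth (SD 0.02 by default), redrawing on the rare
unstable sample, with per-subject event schedules and child seeds derived
deterministically from the cohort seed.

What the generator does **not** emulate: voxel-level structure (regions are
single timecourses), physiological (cardiac/respiratory) noise,
scanner-specific artefacts, haemodynamic variability across regions and
subjects (the truth uses canonical balloon parameters everywhere), and any
feedback of behaviour on neural dynamics.  Passing recovery tests therefore
show that the estimators are correct and informative under the assumed
generative family at realistic noise — not that real scans would yield the
same decisions.

Response times are Gaussian around stage means chosen to reproduce the
non-monotonic learning curves (early minimum at stage 3 for instruction,
stage 2 for feedback), with optional injected outliers for winsorisation
tests.

## First-level GLM and behavioural statistics

OLS with explicit rank checking; contrast t statistics use the textbook
`wᵀβ / √(σ̂² wᵀ(XᵀX)⁻¹w)`.  ROI summaries offer the arithmetic mean and
the first-eigenvariate timecourse (SVD of the centred voxel matrix,
sign-aligned to the ROI mean, scaled to the mean voxel SD).  Winsorisation
clips at mean ± 2.5 sample SD of the input vector in a single pass —
boundary replacement, the standard reading.  One-way repeated-measures
ANOVA reports uncorrected (k−1, (k−1)(n−1)) degrees of freedom by default,
with Greenhouse–Geisser available behind `greenhouse_geisser`; paired
t-tests take the tail as an explicit argument and never default silently
to one-tailed.

## Phase synchrony

Each region timecourse is high-pass filtered at a 60-s cutoff with a
zero-phase 2nd-order Butterworth (forward–backward), the instantaneous
phase Θ taken from the analytic signal, and the Kuramoto order parameter
R(t) = |mean exp(iΘ)| computed with chunked accumulation of the complex
mean, so voxel-scale N needs one pass and no N×N matrix.  One cutoff
period is discarded at each end before R(t) is regressed on the subject's
full first-level design (filter and Hilbert edge artefacts live there).

## PPI

The seed's neural signal is estimated by ridge-regularised inversion of
the canonical-HRF Toeplitz operator on an orthonormal DCT basis, with the
ridge weight chosen by generalised cross-validation and recorded in the
output.  The psychological boxcar is mean-centred over the session (so the
interaction cannot alias the main effects), multiplied with the neural
seed at microtime, and all three terms are re-convolved with the HRF and
sampled at scan onsets before the target GLM (physiological +
psychological + interaction + motion + constant).

## DCM

**Forward model.**  Fixed-step classical RK4 for the neural ODE with
inputs held constant per microtime step; balloon states (vasodilatory
signal, log flow, log volume, log deoxyhaemoglobin) also integrated by
RK4.  Log-state integration enforces positivity; because the
`v^(1/α)` outflow makes the volume equation stiff, the balloon takes
internal substeps of at most 0.25 s whatever the neural grid.  Balloon
constants are the canonical values (κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
τ = 2.0 s, α = 0.32, ρ = 0.32, V₀ = 0.04); BOLD output is percent signal
change via the classic (k₁, k₂, k₃) observation equation.

**Inversion.**  MAP estimation of the free parameters — A off-diagonals
declared by the model mask, self connections as −0.5·exp(θ), masked B and
C entries, and one log transit time per region — under shrinkage priors
(A: N(0, 0.5²); B, C: N(0, 1); log self and log τ: N(0, 0.5²) and
N(0, 0.2²)), by L-BFGS-B with finite-difference gradients on a TR/8
microtime grid.  Observation noise is one profiled variance per region.
Data and prediction are first residualised against a low-frequency DCT
confound basis (100-s cutoff plus constant), the standard fMRI confound
treatment; without it, scanner drift biases every fit.  Divergent or
unstable parameter proposals receive a large smooth penalty; degenerate
optima trigger up to three jittered restarts, after which the fit is
flagged non-converged and excluded listwise from model selection.

**Evidence.**  Laplace approximation at the MAP with a Gauss–Newton
likelihood Hessian (finite-difference Jacobian of the predicted
timecourses) plus the prior precision.  This reproduces the
decision-relevant quantity — complexity-penalised evidence ranking — at a
fraction of the cost of the full variational scheme it simplifies; the
trade-off is that hyperparameter (noise) uncertainty is not propagated
into the evidence.  Fixed-effects BMS sums log evidence over subjects and
softmaxes over models; family posteriors sum member posteriors.

**Fitting a model space.**  All models of a space share A, C and the
haemodynamics and differ in a few modulatory entries, so `fit_space`
inverts the richest model thoroughly (200 iterations) and warm-starts
every model from it (60 refinement iterations each, identical budget and
starting point across models).  Empirically this removes the largest
source of spurious ranking noise: with cold starts and small budgets,
nested and overlapping models land in different optimisation basins and
the evidence differences reflect optimiser luck rather than the data.

## Problem sizes and noise levels of the recovery suites

The acceptance suite runs on one CPU at desk scale; the sizes below are
the package's standing choices, recorded here so results are
interpretable:

* **Sign recovery** (anterior-to-posterior self-fits): 20 subjects at the
  generator default SNR ≈ 1, full four-block sessions.
* **Instruction-task model recovery** (8 models): 10 cohort seeds ×
  4 subjects, two-block sessions, `white_sd = 0.5` ("moderate SNR",
  ≈ 2).  The generating model is decisively identifiable on noiseless
  data, but at SNR ≈ 1 the per-subject evidence gap between the closest
  competing modulation hypotheses falls below the between-model
  optimisation noise at any desk-scale cohort — model *identity* recovery
  is therefore validated in the moderate-SNR regime, parameter-sign
  recovery at SNR ≈ 1.
* **Feedback-task model recovery** (17 models, 5 families): one cohort of
  4 subjects at moderate SNR, two-block sessions.
* **PPI double dissociation**: 10 seeds × 14 subjects, four-block
  sessions, moderate SNR.
* **Synchrony sign recovery**: 10 seeds × 12 subjects, two-block
  sessions, moderate SNR.
* **Null calibration**: 1000 simulated null tables (14 × 5).

## Numerical choices and degenerate inputs

* Microtime: TR/16 for regressor construction and data generation; TR/8
  for inversion (the fidelity loss against the generation grid is a
  correlation of ~0.9995, far below the measurement noise).
* RK4 neural integration verified against 10×-finer steps (≤1e−6 max
  error) and for 4th-order error scaling.
* Eigenvariate sign: aligned to positive correlation with the ROI mean.
* Kuramoto R is clipped into [0, 1] against floating-point excursions.
* Empty event trains produce zero regressors; all-zero series are
  rejected where a phase is undefined; designs are rejected when rank
  deficient rather than silently pseudo-inverted.
* The winsorisation bound uses the sample SD (ddof = 1) of the input
  vector; note that for n ≤ 6 no value can exceed 2.5 SD, so small
  samples pass through unchanged by arithmetic necessity.

## Known limitations

* The inversion is MAP + Gauss–Newton Laplace, not full variational
  Bayes: posterior covariances are approximate and noise uncertainty is
  not marginalised.  Evidence *differences* — the quantity model selection
  consumes — are the validated output.
* Model recovery at SNR ≲ 1 is statistically out of reach at desk-scale
  cohorts (see above); this mirrors the general observation that DCM
  model selection needs either strong effects or many subjects.
* The generator and the inversion share the forward-model family; recovery
  results do not probe robustness to haemodynamic model misspecification.
* Hemispheric pooling questions (pooled voxels vs per-hemisphere
  summaries) do not arise for the single-timecourse regions simulated
  here; the voxel-level operations implement pooled-voxels-first.
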