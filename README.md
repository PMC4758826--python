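# lfconn

Connectivity analysis of stage-wise intentional-learning fMRI: how lateral
frontal cortex (LFC) networks and the ventral striatum activate and
interact as new stimulus–response rules move from novel to routine.

`lfconn` is a library for analysts working with multi-region BOLD
timecourses from staged learning tasks — rules learnt either from explicit
instruction or by trial and error with feedback.  It implements the full
analysis chain on plain tabular data, plus a synthetic-data generator with
a known ground-truth network so that every stage can be validated end to
end without scans:

* **Task model** (`lfconn.task_design`) — event trains for the two task
  variants (1.7-s trial slots, 1/3 fixation, 4-s rule slides or 50 %
  random feedback), contiguous 30-s *learning stages*, canonical
  double-gamma HRF convolution on a TR/16 microtime grid, zero-sum Novelty
  contrasts ((3, 2, 1, −1, −2, −3) or (2, 1, 0, −1, −2)) and first-level
  design matrices with motion nuisance columns.
* **GLM & behaviour** (`lfconn.glm`) — OLS fits, contrast t statistics,
  ROI mean and first-eigenvariate timecourses, 2.5-SD winsorisation,
  one-way repeated-measures ANOVA and paired t-tests.
* **Phase synchrony** (`lfconn.synchrony`) — 60-s high-pass, Hilbert
  phases and the Kuramoto order parameter

      R(t) = | (1/N) Σₙ exp(i Θₙ(t)) |,

  a single global connectivity timecourse over N regions (or voxels),
  regressed on the subject's first-level model to test task-related
  synchrony changes.
* **PPI** (`lfconn.ppi`) — seed deconvolution (ridge on a cosine basis,
  GCV-chosen weight), neural-level interaction with a mean-centred
  psychological timecourse, HRF re-convolution and target GLM.
* **DCM** (`lfconn.dcm`) — bilinear deterministic dynamic causal models
  dz/dt = (A + Σⱼ uⱼBⱼ) z + C u with a balloon haemodynamic forward model,
  MAP inversion with Laplace evidence, the two standing model-comparison
  spaces (8 models over the 3-node LFC network; 17 models in 5 families
  over the 4-node network with caudate), and fixed-effects Bayesian model
  selection.
* **Synthetic cohorts** (`lfconn.synthetic`) — subjects generated from the
  selected network architectures with AR(1) noise, slow drift and motion
  traces, truth stored alongside the data.

## Worked example

Simulate one subject performing the instruction task (4 blocks of
6 × 30-s learning stages), fit the stage-wise GLM and estimate the Novelty
contrast per region, then test whether network phase synchrony tracks rule
novelty:

```python
import numpy as np
from lfconn import (build_study_design, novelty_contrast, fit_glm,
                    contrast_estimate, simulate_subject, study1_truth,
                    synchrony_timecourse, synchrony_regression)
from lfconn.task_design import first_level_design

trains, partition = build_study_design("instruction", n_blocks=4, seed=7)
subject = simulate_subject(study1_truth(), trains, partition,
                           "instruction", seed=7)
design = first_level_design(trains, partition, subject.motion,
                            subject.TR, subject.n_scans)

nov = novelty_contrast("instruction")
for i, node in enumerate(subject.nodes):
    fit = fit_glm(subject.region_timecourses[:, i], design)
    est, t = contrast_estimate(fit, nov)
    print(f"{node}: novelty contrast = {est:+.2f} (t = {t:+.2f})")

R = synchrony_timecourse(subject.region_timecourses, subject.TR)
sfit = synchrony_regression(R, design)
betas = np.array([sfit.betas[f"stage_{k+1}"] for k in range(6)])
print("synchrony novelty effect:", round(float(nov.weights @ betas), 4))
```

Output:

```
AIFO: novelty contrast = +0.42 (t = +11.54)
IFS: novelty contrast = +0.38 (t = +9.98)
LFPC: novelty contrast = +0.20 (t = +5.64)
synchrony novelty effect: 0.0262
```

All three regions respond more while the rules are novel (positive
declining-stage contrast), and the global phase synchrony of the network
is itself higher in the early learning stages — the generator's
ground-truth coupling is modulated by novelty, and both analyses recover
it.

Model comparison works the same way at cohort level: fit each model of
`build_space_study1()` to every subject with `fit_space`, then rank them
with `bms_fixed_effects`, which sums log evidence over subjects and
returns model (and family) posteriors.

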