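"""Synthetic multi-region BOLD cohorts with a known ground-truth network.

Subjects are generated by integrating the bilinear neural model through the
balloon haemodynamic forward model (the same code path as the DCM module),
sampling at TR = 2 s, and adding AR(1)-plus-white measurement noise, slow
scanner drift and smoothed random-walk motion traces.  The ground truth is
stored alongside the data so every downstream stage — GLM contrasts, phase
synchrony, PPI, DCM model recovery — is testable without scans.

The default ground truths mirror the network architectures selected by the
model comparisons: three cortical nodes (AIFO, IFS, LFPC) fully reciprocally
connected with Task driving all three and Novelty modulating the
anterior-to-posterior connections LFPC→IFS and IFS→AIFO; for the feedback
task, a caudate node bidirectionally coupled to all three, with negative
feedback driving the caudate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dcm.forward import simulate_bold
from .dcm.model import DCMModel, HemodynamicParams, build_inputs, stable
from .task_design import (
    EventTrain,
    StagePartition,
    TR_DEFAULT,
    build_study_design,
    stage_regressors,
)

# ---------------------------------------------------------------------------
# ground-truth networks
#
# Couplings are deliberately heterogeneous: real cortical networks are not
# symmetric, and a perfectly symmetric truth would make alternative
# modulation hypotheses artificially degenerate.

#: intrinsic cortical coupling matrix (s⁻¹), rows = target (AIFO, IFS, LFPC)
A_CORTICAL_MATRIX = np.array(
    [
        [0.0, 0.16, 0.06],
        [0.10, 0.0, 0.18],
        [0.05, 0.12, 0.0],
    ]
)
#: intrinsic coupling between caudate and cortical nodes (s⁻¹)
A_STRIATAL = 0.08
#: self-inhibition baseline (s⁻¹)
A_SELF = -0.5
#: Novelty modulation of LFPC→IFS and IFS→AIFO (s⁻¹ per unit input)
B_NOVELTY = 0.1
#: Task driving weights (s⁻¹ per unit input) for AIFO, IFS, LFPC
C_TASK = np.array([0.035, 0.03, 0.022])
#: negative-feedback driving weight onto the caudate
C_FEEDBACK = 0.6
#: feedback-gated caudate–IFS coupling, used for the PPI generative variant
B_FEEDBACK_GATE = 0.25


def study1_truth() -> DCMModel:
    """3-node instruction-task truth: Task drives all, Novelty modulates
    LFPC→IFS and IFS→AIFO (anterior-to-posterior)."""
    nodes, inputs = ("AIFO", "IFS", "LFPC"), ("task", "novelty")
    n, m = 3, 2
    A = A_CORTICAL_MATRIX.copy()
    np.fill_diagonal(A, A_SELF)
    B = np.zeros((m, n, n))
    B[1, 1, 2] = B_NOVELTY  # LFPC → IFS
    B[1, 0, 1] = B_NOVELTY  # IFS → AIFO
    C = np.zeros((n, m))
    C[:, 0] = C_TASK
    mask = ~np.eye(n, dtype=bool)
    return DCMModel("study1_truth", nodes, inputs, A, B, C,
                    mask, B != 0, C != 0)


def study2_truth(
    feedback_gates_ifs_caudate: bool = False, include_ipc: bool = False
) -> DCMModel:
    """4-node feedback-task truth (optionally 5 nodes including the IPC).

    By default negative feedback is a *driving* input to the caudate.  With
    ``feedback_gates_ifs_caudate`` the feedback instead *modulates* the
    bidirectional IFS–caudate connections, the generative condition for the
    PPI double-dissociation analyses.  ``include_ipc`` appends an inferior
    parietal node reciprocally coupled to the IFS with no feedback
    sensitivity, serving as the control target.
    """
    nodes = ["AIFO", "IFS", "LFPC", "CAUDATE"]
    if include_ipc:
        nodes.append("IPC")
    inputs = ("task", "novelty", "feedback")
    n, m = len(nodes), 3
    A = np.zeros((n, n))
    A[:3, :3] = A_CORTICAL_MATRIX
    for i in range(3):
        A[3, i] = A_STRIATAL
        A[i, 3] = A_STRIATAL
    if include_ipc:
        A[4, 1] = 0.15
        A[1, 4] = 0.12
    np.fill_diagonal(A, A_SELF)

    B = np.zeros((m, n, n))
    B[1, 1, 2] = B_NOVELTY
    B[1, 0, 1] = B_NOVELTY
    C = np.zeros((n, m))
    C[:3, 0] = C_TASK
    if include_ipc:
        C[4, 0] = 0.028
    if feedback_gates_ifs_caudate:
        B[2, 3, 1] = B_FEEDBACK_GATE  # IFS → caudate
        B[2, 1, 3] = B_FEEDBACK_GATE  # caudate → IFS
    else:
        C[3, 2] = C_FEEDBACK
    mask = A != 0
    np.fill_diagonal(mask, False)
    name = "study2_truth" + ("_gated" if feedback_gates_ifs_caudate else "")
    return DCMModel(name, tuple(nodes), inputs, A, B, C, mask, B != 0, C != 0)


# ---------------------------------------------------------------------------
# noise model


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement noise: AR(1) innovations, slow drift, motion amplitude.

    ``white_sd`` is the AR(1) innovation SD in percent-signal-change units;
    the default gives a noise SD comparable to the noiseless signal SD of the
    default truths (peak-to-noise ≈ 1).  Drift period exceeds the 60-s
    high-pass cutoff so the filter interacts with it meaningfully.
    """

    white_sd: float = 0.95
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.6
    drift_period: float = 128.0
    motion_sd: float = 0.05

    def __post_init__(self):
        if not -1.0 < self.ar1_coef < 1.0:
            raise ValueError("ar1_coef must be in (-1, 1) for stationarity")
        if min(self.white_sd, self.drift_amplitude, self.motion_sd) < 0:
            raise ValueError("noise SDs must be non-negative")


#: stage-wise mean response times (s) emulating the non-monotonic learning
#: curves: early minimum at stage 3 (instruction) or stage 2 (feedback).
RT_STAGE_MEANS = {
    "instruction": np.array([0.9, 0.7, 0.6, 0.65, 0.62, 0.6]),
    "feedback": np.array([0.95, 0.65, 0.7, 0.68, 0.66]),
}


@dataclass
class SyntheticSubject:
    """One simulated participant: data, nuisance traces and the truth."""

    region_timecourses: np.ndarray
    motion: np.ndarray
    truth: DCMModel
    seed: int
    rt_by_stage: np.ndarray
    noiseless: np.ndarray
    trains: dict[str, EventTrain]
    partition: StagePartition
    study: str
    TR: float
    U: np.ndarray
    input_names: tuple[str, ...]

    @property
    def n_scans(self) -> int:
        return self.region_timecourses.shape[0]

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.truth.nodes


def _session_scans(partition: StagePartition, TR: float) -> int:
    end = partition.block_starts[-1] + partition.n_stages * partition.stage_length
    return int(np.ceil(end / TR - 1e-9))


def simulate_subject(
    truth: DCMModel,
    trains: dict[str, EventTrain],
    partition: StagePartition,
    study: str,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    TR: float = TR_DEFAULT,
    oversample: int = 16,
    hparams: HemodynamicParams = HemodynamicParams(),
) -> SyntheticSubject:
    """Forward-simulate one subject from a valued ground-truth model.

    Refuses unstable truths.  Identical arguments and seed reproduce the
    subject bit-for-bit.
    """
    if not stable(truth.A):
        raise ValueError(
            f"ground-truth model {truth.name!r} is unstable "
            "(A has an eigenvalue with positive real part)"
        )
    n_scans = _session_scans(partition, TR)
    U, names = build_inputs(trains, partition, study, TR, n_scans, oversample)
    if len(names) != truth.n_inputs:
        raise ValueError(
            f"truth expects {truth.n_inputs} inputs, design provides {len(names)}"
        )
    clean = simulate_bold(truth, U, TR, n_scans, oversample, hparams)

    rng = np.random.default_rng(seed)
    n = truth.n_nodes
    y = clean.copy()
    if noise.white_sd > 0:
        e = np.zeros((n_scans, n))
        e[0] = rng.normal(0.0, noise.white_sd / np.sqrt(1 - noise.ar1_coef**2), n)
        innov = rng.normal(0.0, noise.white_sd, (n_scans, n))
        for t in range(1, n_scans):
            e[t] = noise.ar1_coef * e[t - 1] + innov[t]
        y = y + e
    if noise.drift_amplitude > 0:
        t_sec = np.arange(n_scans) * TR
        phase = rng.uniform(0, 2 * np.pi, n)
        y = y + noise.drift_amplitude * np.cos(
            2 * np.pi * t_sec[:, None] / noise.drift_period + phase[None, :]
        )
    motion = gaussian_filter1d(
        np.cumsum(rng.normal(0.0, noise.motion_sd, (n_scans, 6)), axis=0),
        sigma=3.0, axis=0,
    )
    rt_means = RT_STAGE_MEANS[study][: partition.n_stages]
    return SyntheticSubject(
        region_timecourses=y,
        motion=motion,
        truth=truth,
        seed=seed,
        rt_by_stage=rt_means,
        noiseless=clean,
        trains=trains,
        partition=partition,
        study=study,
        TR=TR,
        U=U,
        input_names=names,
    )


def _jitter_truth(truth: DCMModel, sd: float, rng: np.random.Generator,
                  max_tries: int = 50) -> DCMModel:
    """Draw subject-level parameters around the truth; keep a stable draw."""
    if sd == 0:
        return truth
    for _ in range(max_tries):
        A = truth.A.copy()
        off = ~np.eye(truth.n_nodes, dtype=bool)
        free_a = off & (truth.A != 0)
        A[free_a] += rng.normal(0.0, sd, int(free_a.sum()))
        B = truth.B.copy()
        B[truth.B != 0] += rng.normal(0.0, sd, int((truth.B != 0).sum()))
        C = truth.C.copy()
        C[truth.C != 0] += rng.normal(0.0, sd, int((truth.C != 0).sum()))
        if stable(A):
            return truth.with_values(A=A, B=B, C=C)
    raise RuntimeError("could not draw a stable subject-level model")


def simulate_cohort(
    truth: DCMModel,
    study: str,
    n_blocks: int = 4,
    n_subjects: int = 17,
    between_subject_sd: float = 0.02,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> list[SyntheticSubject]:
    """Simulate a cohort with subject-level parameter variability.

    Each subject receives a distinct child seed (for the event schedule,
    parameter jitter and measurement noise) derived deterministically from
    ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be non-negative")
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    subjects = []
    for child in children:
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        trains, partition = build_study_design(study, n_blocks, seed=sub_seed)
        sub_truth = _jitter_truth(truth, between_subject_sd, rng)
        subjects.append(
            simulate_subject(sub_truth, trains, partition, study, noise, seed=sub_seed)
        )
    return subjects


def simulate_rts(
    stage_means: np.ndarray,
    stage_trains: list[EventTrain],
    sd: float = 0.1,
    seed: int = 0,
    outliers: list[tuple[int, float]] | None = None,
) -> pd.DataFrame:
    """Per-trial response times, Gaussian around each stage mean.

    ``outliers`` optionally injects (stage_index, value) pairs replacing the
    first trial of that stage, for winsorisation screening tests.
    Returns a long-format table (stage, onset, rt).
    """
    stage_means = np.asarray(stage_means, dtype=float)
    if len(stage_trains) != stage_means.size:
        raise ValueError("need one mean per stage train")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for k, train in enumerate(stage_trains):
        rts = stage_means[k] + rng.normal(0.0, sd, len(train))
        for onset, rt in zip(train.onsets, rts):
            rows.append({"stage": k + 1, "onset": onset, "rt": rt})
    df = pd.DataFrame(rows, columns=["stage", "onset", "rt"])
    if outliers:
        for stage_idx, value in outliers:
            hit = df.index[df["stage"] == stage_idx + 1]
            if hit.empty:
                raise ValueError(f"no trials in stage {stage_idx + 1}")
            df.loc[hit[0], "rt"] = value
    return df


# ---------------------------------------------------------------------------
# plain-text export


def write_dataset(subject: SyntheticSubject, directory) -> None:
    """Write timecourses and motion as TSV plus a JSON truth sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(subject.region_timecourses, columns=list(subject.nodes)).to_csv(
        d / "timecourses.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        subject.motion, columns=[f"motion_{i + 1}" for i in range(6)]
    ).to_csv(d / "motion.tsv", sep="\t", index=False)
    sidecar = {
        "seed": subject.seed,
        "study": subject.study,
        "TR": subject.TR,
        "nodes": list(subject.nodes),
        "inputs": list(subject.truth.inputs),
        "A": subject.truth.A.tolist(),
        "B": subject.truth.B.tolist(),
        "C": subject.truth.C.tolist(),
        "rt_by_stage": subject.rt_by_stage.tolist(),
    }
    (d / "truth.json").write_text(json.dumps(sidecar, indent=1))
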