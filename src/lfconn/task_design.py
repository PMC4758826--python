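"""Event structure, learning-stage partitions, contrasts and design matrices.

Two stimulus–response learning tasks are supported:

* ``"instruction"`` — each block opens with a 4-s rule-definition slide
  followed by 180 s of discrimination trials; rules are applied from explicit
  instruction and no feedback is given.
* ``"feedback"`` — blocks are 150 s of trials with no rule slide; a random
  50 % of trials are followed by feedback (correct/incorrect) and the rule
  must be derived by trial and error.

In both tasks stimuli appear at a rate of one per 1.7 s with one third of
the slots showing fixation instead of a stimulus.  Trials are partitioned
into contiguous 30-s *learning stages* within each block (6 stages for the
instruction task, 5 for the feedback task), which index the transition of a
rule from novel to familiar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .hrf import MICROTIME_RES, convolve_microtime, event_boxcar, sample_at_scans

TRIAL_RATE_S = 1.7
FIXATION_FRACTION = 1.0 / 3.0
STAGE_LENGTH_S = 30.0
RULE_SLIDE_S = 4.0
FEEDBACK_DURATION_S = 1.5
BLOCK_LENGTH_S = {"instruction": 180.0, "feedback": 150.0}
N_STAGES = {"instruction": 6, "feedback": 5}
TR_DEFAULT = 2.0


@dataclass(frozen=True)
class EventTrain:
    """Timed psychological events of one condition.

    onsets are seconds from session start, strictly ascending; durations and
    weights align element-wise with onsets.
    """

    name: str
    onsets: np.ndarray
    durations: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if not (onsets.size == durations.size == weights.size):
            raise ValueError("onsets, durations and weights must align")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly ascending")
        if np.any(onsets < 0) or np.any(durations < 0):
            raise ValueError("onsets and durations must be non-negative")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def end(self) -> float:
        """Time at which the last event finishes (0 for an empty train)."""
        if not len(self):
            return 0.0
        return float(np.max(self.onsets + self.durations))

    def subset(self, mask: np.ndarray, name: str | None = None) -> "EventTrain":
        return EventTrain(
            name or self.name, self.onsets[mask], self.durations[mask], self.weights[mask]
        )


@dataclass(frozen=True)
class StagePartition:
    """Contiguous learning-stage windows within each task block."""

    stage_length: float
    n_stages: int
    block_starts: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "block_starts", np.asarray(self.block_starts, dtype=float)
        )
        if self.stage_length <= 0 or self.n_stages < 1:
            raise ValueError("stage_length and n_stages must be positive")

    def stage_of(self, onsets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (block index, stage index) for each onset.

        A trial belongs to the stage containing its onset; trials never split
        across stage boundaries.
        """
        onsets = np.asarray(onsets, dtype=float)
        block = np.searchsorted(self.block_starts, onsets, side="right") - 1
        if np.any(block < 0):
            raise ValueError("trial onset precedes the first block")
        rel = onsets - self.block_starts[block]
        stage = np.floor(rel / self.stage_length).astype(int)
        if np.any(stage >= self.n_stages):
            raise ValueError("trial onset lies beyond the staged part of its block")
        return block, stage


@dataclass(frozen=True)
class Contrast:
    """Named linear weighting over stage regressors."""

    name: str
    weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))


@dataclass
class DesignMatrix:
    """Named regressors sampled every TR, including nuisance and constant."""

    frame: pd.DataFrame
    TR: float

    @property
    def n_scans(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


# ---------------------------------------------------------------------------
# behaviour model for the feedback task


def geometric_error_model(p0: float = 0.5, decay: float = 0.3) -> Callable[[int], float]:
    """Stage-wise error probability p0 * decay**stage.

    Errors concentrate in the earliest stages, as observed when rules are
    derived by trial and error; with the defaults a 4-block feedback session
    produces on the order of 15–20 negative feedback events.
    """
    if not (0.0 <= p0 <= 1.0) or not (0.0 <= decay < 1.0):
        raise ValueError("p0 in [0,1] and decay in [0,1) required")
    return lambda stage: p0 * decay**stage


# ---------------------------------------------------------------------------
# study construction


def build_study_design(
    study: str,
    n_blocks: int,
    seed: int,
    block_length: float | None = None,
    error_model: Callable[[int], float] | None = None,
) -> tuple[dict[str, EventTrain], StagePartition]:
    """Construct the event trains and stage partition for one session.

    Returns a dict with keys ``trial``, ``fixation`` and, depending on the
    study, ``rule`` (4-s rule-definition slides) or ``feedback_pos`` /
    ``feedback_neg``.  Fixation slots never enter any regressor downstream;
    only stimuli with responses are modelled.
    """
    if study not in BLOCK_LENGTH_S:
        raise ValueError(f"unknown study label {study!r}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    blen = BLOCK_LENGTH_S[study] if block_length is None else float(block_length)
    rule_dur = RULE_SLIDE_S if study == "instruction" else 0.0
    rng = np.random.default_rng(seed)

    trial_on, fix_on = [], []
    fb_on, fb_correct = [], []
    rule_on = []
    block_starts = []
    err = error_model or geometric_error_model()
    n_stages = N_STAGES[study] if block_length is None else max(
        1, int(blen // STAGE_LENGTH_S) or 1
    )

    t = 0.0
    for _ in range(n_blocks):
        if study == "instruction":
            rule_on.append(t)
            t += rule_dur
        block_starts.append(t)
        n_slots = int(np.floor(blen / TRIAL_RATE_S))
        n_fix = int(round(n_slots * FIXATION_FRACTION))
        fix_slots = set(rng.choice(n_slots, size=n_fix, replace=False)) if n_slots else set()
        for s in range(n_slots):
            onset = t + s * TRIAL_RATE_S
            if s in fix_slots:
                fix_on.append(onset)
                continue
            trial_on.append(onset)
            if study == "feedback" and rng.random() < 0.5:
                stage = min(int((onset - t) / STAGE_LENGTH_S), n_stages - 1)
                fb_on.append(onset + TRIAL_RATE_S)
                fb_correct.append(rng.random() >= err(stage))
        t += blen

    def _train(name, onsets, dur, weight=1.0):
        onsets = np.asarray(onsets, float)
        return EventTrain(
            name, onsets, np.full(onsets.size, dur), np.full(onsets.size, weight)
        )

    trains = {
        "trial": _train("trial", trial_on, TRIAL_RATE_S),
        "fixation": _train("fixation", fix_on, TRIAL_RATE_S),
    }
    if study == "instruction":
        trains["rule"] = _train("rule", rule_on, RULE_SLIDE_S)
    else:
        fb_on = np.asarray(fb_on, float)
        fb_correct = np.asarray(fb_correct, bool)
        trains["feedback_pos"] = _train("feedback_pos", fb_on[fb_correct], FEEDBACK_DURATION_S)
        trains["feedback_neg"] = _train("feedback_neg", fb_on[~fb_correct], FEEDBACK_DURATION_S)

    partition = StagePartition(STAGE_LENGTH_S, n_stages, np.asarray(block_starts))
    return trains, partition


def session_length(study: str, n_blocks: int) -> float:
    """Total session duration in seconds."""
    per_block = BLOCK_LENGTH_S[study] + (RULE_SLIDE_S if study == "instruction" else 0.0)
    return n_blocks * per_block


def stage_regressors(trials: EventTrain, partition: StagePartition) -> list[EventTrain]:
    """Split a trial train into one train per learning stage.

    Stage k of every block is pooled into the k-th output train; the outputs
    partition the input exactly (no trial lost or duplicated).
    """
    trains = []
    if len(trials):
        _, stage = partition.stage_of(trials.onsets)
    else:
        stage = np.zeros(0, dtype=int)
    for k in range(partition.n_stages):
        trains.append(trials.subset(stage == k, name=f"stage_{k + 1}"))
    return trains


# ---------------------------------------------------------------------------
# regressor construction


def canonical_hrf_convolve(
    train: EventTrain, TR: float, n_scans: int, oversample: int = MICROTIME_RES
) -> np.ndarray:
    """HRF-convolved regressor for an event train, sampled at scan onsets.

    The weighted boxcar is built on a microtime grid of TR/oversample,
    convolved with the canonical double-gamma HRF and down-sampled at
    t = 0, TR, 2·TR, …  The operation is linear in the event train.
    """
    if TR <= 0:
        raise ValueError("TR must be positive")
    n_micro = n_scans * oversample
    dt = TR / oversample
    if len(train) and train.end > n_scans * TR + 1e-9:
        raise ValueError("events extend beyond the sampled session")
    u = event_boxcar(train.onsets, train.durations, train.weights, dt, n_micro)
    return sample_at_scans(convolve_microtime(u, dt), oversample, n_scans)


def novelty_contrast(study: str) -> Contrast:
    """Zero-sum declining weights over stage regressors indexing rule novelty."""
    if study == "instruction":
        return Contrast("novelty", np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]))
    if study == "feedback":
        return Contrast("novelty", np.array([2.0, 1.0, 0.0, -1.0, -2.0]))
    raise ValueError(f"unknown study label {study!r}")


def task_contrast(study: str) -> Contrast:
    """All-ones weighting over stage regressors (task vs implicit baseline)."""
    if study not in N_STAGES:
        raise ValueError(f"unknown study label {study!r}")
    return Contrast("task", np.ones(N_STAGES[study]))


def assemble_design(
    regressors: Mapping[str, np.ndarray],
    nuisance: np.ndarray | None,
    TR: float,
    n_scans: int,
) -> DesignMatrix:
    """Stack condition regressors, motion nuisance columns and a constant."""
    cols: dict[str, np.ndarray] = {}
    for name, vec in regressors.items():
        vec = np.asarray(vec, dtype=float)
        if vec.size != n_scans:
            raise ValueError(f"regressor {name!r} has length {vec.size}, expected {n_scans}")
        if name in cols:
            raise ValueError(f"duplicate regressor name {name!r}")
        cols[name] = vec
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_scans:
            raise ValueError("nuisance rows must equal n_scans")
        for j in range(nuisance.shape[1]):
            name = f"motion_{j + 1}"
            if name in cols:
                raise ValueError(f"duplicate regressor name {name!r}")
            cols[name] = nuisance[:, j]
    if "constant" in cols:
        raise ValueError("duplicate regressor name 'constant'")
    cols["constant"] = np.ones(n_scans)
    return DesignMatrix(pd.DataFrame(cols), TR)


def first_level_design(
    trains: Mapping[str, EventTrain],
    partition: StagePartition,
    motion: np.ndarray | None,
    TR: float,
    n_scans: int,
) -> DesignMatrix:
    """Full first-level design for one subject.

    Stage-wise trial regressors plus the rule-definition regressor
    (instruction task) or the two feedback regressors (feedback task), six
    motion nuisance columns and the constant.
    """
    regs: dict[str, np.ndarray] = {}
    for tr in stage_regressors(trains["trial"], partition):
        regs[tr.name] = canonical_hrf_convolve(tr, TR, n_scans)
    for extra in ("rule", "feedback_pos", "feedback_neg"):
        if extra in trains:
            regs[extra] = canonical_hrf_convolve(trains[extra], TR, n_scans)
    return assemble_design(regs, motion, TR, n_scans)


def design_from_config(path) -> tuple[dict[str, EventTrain], StagePartition, dict]:
    """Build a session from a YAML (or flat key: value) config file.

    Recognised keys: ``study`` (required), ``n_blocks`` (default 4),
    ``seed`` (default 0), ``block_length`` (optional override), ``TR``
    (returned in the config dict for downstream sampling).  Returns
    (trains, partition, config-with-defaults).
    """
    import yaml

    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "study" not in cfg:
        raise ValueError("config must be a mapping with at least a 'study' key")
    full = {
        "study": cfg["study"],
        "n_blocks": int(cfg.get("n_blocks", 4)),
        "seed": int(cfg.get("seed", 0)),
        "block_length": cfg.get("block_length"),
        "TR": float(cfg.get("TR", TR_DEFAULT)),
        "stage_length": float(cfg.get("stage_length", STAGE_LENGTH_S)),
    }
    if full["stage_length"] != STAGE_LENGTH_S:
        raise NotImplementedError("non-default stage lengths are not supported")
    trains, partition = build_study_design(
        full["study"], full["n_blocks"], full["seed"],
        block_length=full["block_length"],
    )
    return trains, partition, full


# ---------------------------------------------------------------------------
# plain-text interchange (BIDS-events-style TSV)


def write_events(trains: Mapping[str, EventTrain], path) -> None:
    rows = []
    for train in trains.values():
        for o, d, w in zip(train.onsets, train.durations, train.weights):
            rows.append({"onset": o, "duration": d, "weight": w, "condition": train.name})
    pd.DataFrame(rows, columns=["onset", "duration", "weight", "condition"]).sort_values(
        "onset"
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> dict[str, EventTrain]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for name, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("onset")
        out[name] = EventTrain(
            str(name),
            grp["onset"].to_numpy(),
            grp["duration"].to_numpy(),
            grp["weight"].to_numpy(),
        )
    return out


def write_design(design: DesignMatrix, path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def read_design(path, TR: float = TR_DEFAULT) -> DesignMatrix:
    return DesignMatrix(pd.read_csv(path, sep="\t"), TR)
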