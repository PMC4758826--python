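"""DCM model container, input construction and stability checks."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ..hrf import event_boxcar
from ..task_design import EventTrain, StagePartition, novelty_contrast


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon/windkessel parameters (canonical values).

    kappa: vasodilatory signal decay rate (s⁻¹); gamma: flow-dependent
    feedback rate (s⁻¹); tau: mean transit time (s); alpha: vessel stiffness
    exponent; rho: resting oxygen extraction fraction; V0: resting venous
    blood volume fraction.  BOLD output is in percent signal change.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    rho: float = 0.32
    V0: float = 0.04


@dataclass(frozen=True)
class DCMModel:
    """Bilinear DCM: structure masks plus (optionally) parameter values.

    Matrix convention: entry (i, j) is the influence of node j on node i,
    so the connection "LFPC → IFS" lives at row IFS, column LFPC.

    For a ground-truth (generative) model A/B/C carry values; for a
    hypothesis model in a comparison space they are zero and the boolean
    masks declare which entries are free parameters during inversion.
    The diagonal of A holds the (negative) self-connections and is always
    free in inversion via the −0.5·exp(θ) parameterisation.
    """

    name: str
    nodes: tuple[str, ...]
    inputs: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    a_mask: np.ndarray
    b_mask: np.ndarray
    c_mask: np.ndarray

    def __post_init__(self):
        n, m = len(self.nodes), len(self.inputs)
        A = np.asarray(self.A, dtype=float).reshape(n, n)
        B = np.asarray(self.B, dtype=float).reshape(m, n, n)
        C = np.asarray(self.C, dtype=float).reshape(n, m)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "a_mask", np.asarray(self.a_mask, bool).reshape(n, n))
        object.__setattr__(self, "b_mask", np.asarray(self.b_mask, bool).reshape(m, n, n))
        object.__setattr__(self, "c_mask", np.asarray(self.c_mask, bool).reshape(n, m))
        if np.any(np.diag(A) > 0):
            raise ValueError("self-connections (diagonal of A) must be non-positive")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    def with_values(self, A=None, B=None, C=None, name=None) -> "DCMModel":
        return replace(
            self,
            A=self.A if A is None else A,
            B=self.B if B is None else B,
            C=self.C if C is None else C,
            name=self.name if name is None else name,
        )


    def to_dict(self) -> dict:
        """JSON/YAML-serialisable description (values, masks, bindings)."""
        return {
            "name": self.name,
            "nodes": list(self.nodes),
            "inputs": list(self.inputs),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "C": self.C.tolist(),
            "a_mask": self.a_mask.astype(int).tolist(),
            "b_mask": self.b_mask.astype(int).tolist(),
            "c_mask": self.c_mask.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCMModel":
        return cls(
            name=d["name"],
            nodes=tuple(d["nodes"]),
            inputs=tuple(d["inputs"]),
            A=np.asarray(d["A"], float),
            B=np.asarray(d["B"], float),
            C=np.asarray(d["C"], float),
            a_mask=np.asarray(d["a_mask"], bool),
            b_mask=np.asarray(d["b_mask"], bool),
            c_mask=np.asarray(d["c_mask"], bool),
        )

    def save(self, path) -> None:
        """Write the model spec as JSON or YAML (by file suffix)."""
        import json
        from pathlib import Path

        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "DCMModel":
        import json
        from pathlib import Path

        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(path.read_text()))
        return cls.from_dict(json.loads(path.read_text()))


def stable(A: np.ndarray) -> bool:
    """True when every eigenvalue of A has negative real part."""
    return bool(np.all(np.linalg.eigvals(A).real < 0))


def build_inputs(
    trains: Mapping[str, EventTrain],
    partition: StagePartition,
    study: str,
    TR: float,
    n_scans: int,
    oversample: int = 16,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Experimental inputs u(t) on the microtime grid, unconvolved.

    * ``task`` — unit boxcars over the durations of all discrimination
      trials at all learning stages.
    * ``novelty`` — boxcars over the *entire duration* of each learning
      stage, weighted by the study's novelty contrast (declining, zero-sum),
      then mean-centred over the session.
    * ``feedback`` — boxcars over negative feedback events (feedback study
      only).

    Returns (U, names) with U of shape (n_scans·oversample, m).
    """
    dt = TR / oversample
    K = n_scans * oversample
    cols, names = [], []

    trials = trains["trial"]
    cols.append(event_boxcar(trials.onsets, trials.durations, trials.weights, dt, K))
    names.append("task")

    w = novelty_contrast(study).weights
    nov = np.zeros(K)
    for b0 in partition.block_starts:
        for k in range(partition.n_stages):
            i0 = int(round((b0 + k * partition.stage_length) / dt))
            i1 = int(round((b0 + (k + 1) * partition.stage_length) / dt))
            nov[i0:min(i1, K)] = w[k]
    nov -= nov.mean()
    cols.append(nov)
    names.append("novelty")

    if "feedback_neg" in trains:
        fb = trains["feedback_neg"]
        cols.append(event_boxcar(fb.onsets, fb.durations, fb.weights, dt, K))
        names.append("feedback")

    return np.column_stack(cols), tuple(names)
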