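"""The two model-comparison spaces over the lateral-frontal network.

Study 1 (learning from instruction): three nodes — AIFO (anterior
insula/frontal operculum), IFS (inferior frontal sulcus), LFPC (lateral
frontopolar cortex) — fully reciprocally and self connected, Task driving
all three, and eight alternative patterns of Novelty modulation.

Study 2 (learning from feedback): a caudate node is added, bidirectionally
connected to all three cortical nodes; the anterior-to-posterior Novelty
modulation that won the Study 1 comparison is retained; 17 models in five
families differ in how negative feedback enters the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DCMModel

STUDY1_NODES = ("AIFO", "IFS", "LFPC")
STUDY2_NODES = ("AIFO", "IFS", "LFPC", "CAUDATE")


@dataclass(frozen=True)
class ModelSpace:
    """A list of hypothesis models, optionally partitioned into families."""

    models: tuple[DCMModel, ...]
    families: dict[str, tuple[int, ...]] | None = None

    def __post_init__(self):
        if self.families is not None:
            idx = sorted(i for members in self.families.values() for i in members)
            if idx != list(range(len(self.models))):
                raise ValueError("families must partition the model list")

    def __len__(self) -> int:
        return len(self.models)

    def names(self) -> list[str]:
        return [m.name for m in self.models]


def _hypothesis(name, nodes, inputs, a_mask, b_mask, c_mask) -> DCMModel:
    n, m = len(nodes), len(inputs)
    return DCMModel(
        name=name,
        nodes=nodes,
        inputs=inputs,
        A=np.zeros((n, n)),
        B=np.zeros((m, n, n)),
        C=np.zeros((n, m)),
        a_mask=a_mask,
        b_mask=b_mask,
        c_mask=c_mask,
    )


def _bmask(n_inputs, n, input_idx, connections) -> np.ndarray:
    b = np.zeros((n_inputs, n, n), dtype=bool)
    for tgt, src in connections:
        b[input_idx, tgt, src] = True
    return b


def build_space_study1() -> ModelSpace:
    """Eight models varying the target of the Novelty modulation.

    Node indices: AIFO=0, IFS=1, LFPC=2; connection (target, source).
    """
    nodes, inputs = STUDY1_NODES, ("task", "novelty")
    n = 3
    a_mask = ~np.eye(n, dtype=bool)  # full reciprocal between-node coupling
    c_mask = np.zeros((n, 2), dtype=bool)
    c_mask[:, 0] = True  # Task drives all three nodes

    all_between = [(i, j) for i in range(n) for j in range(n) if i != j]
    patterns = {
        # one LFC sub-region drives the connectivity change (both efferents)
        "source_AIFO": [(1, 0), (2, 0)],
        "source_IFS": [(0, 1), (2, 1)],
        "source_LFPC": [(0, 2), (1, 2)],
        # general effect with no specific source
        "all_connections": all_between,
        "no_modulation": [],
        # hierarchical propagation
        "posterior_to_anterior": [(1, 0), (2, 1)],  # AIFO→IFS, IFS→LFPC
        "anterior_to_posterior": [(1, 2), (0, 1)],  # LFPC→IFS, IFS→AIFO
        "both_hierarchies": [(1, 0), (2, 1), (1, 2), (0, 1)],
    }
    models = tuple(
        _hypothesis(name, nodes, inputs, a_mask, _bmask(2, n, 1, conns), c_mask)
        for name, conns in patterns.items()
    )
    return ModelSpace(models)


ANTERIOR_POSTERIOR_B = ((1, 2), (0, 1))  # LFPC→IFS, IFS→AIFO


def build_space_study2() -> ModelSpace:
    """Seventeen models in five families varying the target of feedback.

    Node indices: AIFO=0, IFS=1, LFPC=2, CAUDATE=3.  All models retain the
    anterior-to-posterior Novelty modulation from Study 1 and bidirectional
    caudate–cortical connections; they differ in whether negative feedback
    is a driving (C) or modulatory (B) input and in its target.
    """
    nodes, inputs = STUDY2_NODES, ("task", "novelty", "feedback")
    n, m = 4, 3
    a_mask = np.zeros((n, n), dtype=bool)
    for i in range(3):
        for j in range(3):
            if i != j:
                a_mask[i, j] = True
    for i in range(3):  # caudate bidirectionally connected to each LFC node
        a_mask[3, i] = True
        a_mask[i, 3] = True

    c_task = np.zeros((n, m), dtype=bool)
    c_task[:3, 0] = True  # Task drives the three cortical nodes
    b_nov = _bmask(m, n, 1, ANTERIOR_POSTERIOR_B)

    cau_afferent = [(3, i) for i in range(3)]   # LFC → caudate
    cau_efferent = [(i, 3) for i in range(3)]   # caudate → LFC

    models: list[DCMModel] = []
    families: dict[str, tuple[int, ...]] = {}

    def add(name, b_fb=(), c_fb_node=None):
        b = b_nov | _bmask(m, n, 2, b_fb)
        c = c_task.copy()
        if c_fb_node is not None:
            c[c_fb_node, 2] = True
        models.append(_hypothesis(name, nodes, inputs, a_mask, b, c))

    # family 1: feedback as a driving input to one node (caudate first)
    start = len(models)
    for node_idx, node in ((3, "caudate"), (0, "AIFO"), (1, "IFS"), (2, "LFPC")):
        add(f"drive_{node}", c_fb_node=node_idx)
    families["driving_input"] = tuple(range(start, len(models)))

    # family 2: null — feedback has no target
    start = len(models)
    add("feedback_null")
    families["null"] = tuple(range(start, len(models)))

    # family 3: feedback modulates the bidirectional pathway with one LFC node
    start = len(models)
    for i, node in enumerate(("AIFO", "IFS", "LFPC")):
        add(f"pathway_{node}", b_fb=[(3, i), (i, 3)])
    families["single_pathway"] = tuple(range(start, len(models)))

    # family 4: feedback modulates parallel pathways (to/from/both with caudate)
    start = len(models)
    add("parallel_to_caudate", b_fb=cau_afferent)
    add("parallel_from_caudate", b_fb=cau_efferent)
    add("parallel_bidirectional", b_fb=cau_afferent + cau_efferent)
    families["parallel_pathways"] = tuple(range(start, len(models)))

    # family 5: feedback modulates one directed caudate connection
    start = len(models)
    for i, node in enumerate(("AIFO", "IFS", "LFPC")):
        add(f"single_{node}_to_caudate", b_fb=[(3, i)])
        add(f"single_caudate_to_{node}", b_fb=[(i, 3)])
    families["single_connection"] = tuple(range(start, len(models)))

    return ModelSpace(tuple(models), families)
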