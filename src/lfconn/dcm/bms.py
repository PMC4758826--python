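"""Fixed-effects Bayesian model selection over a fitted model space."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .invert import DCMFit
from .spaces import ModelSpace


@dataclass
class BMSResult:
    model_names: list[str]
    group_log_evidence: np.ndarray
    posterior: np.ndarray
    family_posterior: dict[str, float] | None
    n_subjects: int

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.posterior))

    @property
    def best_model(self) -> str:
        return self.model_names[self.best_index]

    @property
    def best_family(self) -> str | None:
        if self.family_posterior is None:
            return None
        return max(self.family_posterior, key=self.family_posterior.get)


def bms_fixed_effects(
    fits: list[list[DCMFit]], space: ModelSpace | None = None
) -> BMSResult:
    """Fixed-effects BMS: sum log evidences over subjects, softmax over models.

    ``fits`` is indexed [subject][model]; every subject must provide an
    evidence for every model.  Subjects with any non-converged fit are
    excluded listwise (with a warning) under the assumption of a common
    network architecture across healthy participants.  Family posteriors sum
    the member model posteriors when ``space`` defines families.
    """
    if not fits or not fits[0]:
        raise ValueError("empty fit set")
    n_models = len(fits[0])
    if any(len(row) != n_models for row in fits):
        raise ValueError("every subject needs a fit for every model")

    kept = [row for row in fits if all(f.converged for f in row)]
    if len(kept) < len(fits):
        import warnings

        warnings.warn(
            f"excluding {len(fits) - len(kept)} subject(s) with non-converged fits",
            RuntimeWarning,
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no subject has a converged fit for every model")

    group_le = np.array(
        [sum(row[m].log_evidence for row in kept) for m in range(n_models)]
    )
    posterior = np.exp(group_le - logsumexp(group_le))
    names = [f.model.name for f in kept[0]]

    fam = None
    if space is not None and space.families is not None:
        fam = {
            name: float(posterior[list(members)].sum())
            for name, members in space.families.items()
        }
    return BMSResult(
        model_names=names,
        group_log_evidence=group_le,
        posterior=posterior,
        family_posterior=fam,
        n_subjects=len(kept),
    )
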