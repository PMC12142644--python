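"""Self-conditioned training-set construction.

Patients with a real follow-up contribute the genuine progression task
(target = i2, conditioning = i1). Patients without one are still used:
their baseline becomes its own target, conditioned on either the exact
baseline or a lightly noised copy of it — the coin flip is a fair
Bernoulli draw, and the perturbation adds Gaussian noise equivalent to k
forward diffusion steps. Both the coin and the perturbation noise are
redrawn on every call, so each epoch sees a fresh augmentation of the
unpaired pool (D15).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Cohort
from .diffusion import NoiseSchedule

__all__ = ["TrainingSample", "perturb_self", "build_training_set"]


@dataclass
class TrainingSample:
    """(target, conditioning, labels) triple with provenance flags."""

    target: np.ndarray          # i_t
    cond_features: np.ndarray   # i_s
    labels: np.ndarray          # l
    is_self_conditioned: bool
    was_perturbed: bool = False

    def __post_init__(self) -> None:
        if self.was_perturbed and not self.is_self_conditioned:
            raise ValueError("was_perturbed implies is_self_conditioned")


def perturb_self(i1: np.ndarray, schedule: NoiseSchedule, k: int = 5,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Noise a baseline vector by k forward diffusion steps:
    sqrt(alpha_bar_k) * i1 + sqrt(1 - alpha_bar_k) * eps."""
    if not (1 <= k <= schedule.T):
        raise ValueError(f"k={k} out of range 1..{schedule.T}")
    rng = rng if rng is not None else np.random.default_rng()
    i1 = np.asarray(i1, dtype=float)
    _, _, ab = schedule.at(k)
    return np.sqrt(ab) * i1 + np.sqrt(1.0 - ab) * rng.standard_normal(i1.shape)


def build_training_set(cohort: Cohort, schedule: NoiseSchedule, k: int = 5,
                       epoch_rng: np.random.Generator | None = None) -> list[TrainingSample]:
    """One TrainingSample per record, mixing paired and self-conditioned.

    Paired records: (target=i2, cond=i1). Unpaired records: target=i1,
    conditioning is i1 itself or its k-step perturbation with equal
    probability.
    """
    if not (1 <= k <= schedule.T):
        raise ValueError(f"k={k} out of range 1..{schedule.T}")
    rng = epoch_rng if epoch_rng is not None else np.random.default_rng()
    samples = []
    for rec in cohort:
        if rec.has_followup:
            samples.append(TrainingSample(
                target=rec.i2.copy(), cond_features=rec.i1.copy(),
                labels=rec.labels.copy(), is_self_conditioned=False,
            ))
        else:
            delta = rng.integers(0, 2)  # fair coin
            if delta == 1:
                cond = perturb_self(rec.i1, schedule, k, rng)
            else:
                cond = rec.i1.copy()
            samples.append(TrainingSample(
                target=rec.i1.copy(), cond_features=cond,
                labels=rec.labels.copy(), is_self_conditioned=True,
                was_perturbed=bool(delta == 1),
            ))
    return samples
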