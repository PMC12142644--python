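"""Follow-up generation for single patients and cohort enrichment.

Enrichment completes a cohort: every record that lacks a follow-up
receives a generated one (flagged synthetic); records with a real
follow-up are untouched. Per-record seeds are derived by a stable hash of
(master seed, patient id), so enrichment is independent of record order.
"""

from __future__ import annotations

import numpy as np

from .data import Cohort, stable_record_seed
from .diffusion import NoiseSchedule, sample, sample_batch
from .network import UNet1D

__all__ = ["generate_followup", "enrich_cohort"]


def generate_followup(net: UNet1D, i1: np.ndarray, l: np.ndarray,
                      schedule: NoiseSchedule, seed: int,
                      clamp: bool = True) -> np.ndarray:
    """Sample one follow-up feature vector conditioned on (i1, l)."""
    i1 = np.asarray(i1, dtype=float)
    l = np.asarray(l, dtype=float)
    if i1.shape != (net.config.d,):
        raise ValueError(
            f"i1 has length {i1.shape}, checkpoint expects {net.config.d}"
        )
    if l.shape != (net.config.n_labels,):
        raise ValueError(
            f"labels have length {l.shape}, checkpoint expects {net.config.n_labels}"
        )
    net.T = schedule.T
    return sample(lambda x, t, c, lab: net.predict(x, t, c, lab),
                  (i1, l), schedule, seed, clamp=clamp)


def enrich_cohort(net: UNet1D, cohort: Cohort, schedule: NoiseSchedule,
                  seed: int) -> Cohort:
    """Impute follow-ups for every record lacking one.

    The conditioning label vector includes the task labels exactly as in
    training (the deliberate training-set-only leak, D23); callers must
    never enrich evaluation test sets.
    """
    out = cohort.copy()
    missing = [r for r in out if not r.has_followup]
    if not missing:
        return out
    I1 = np.stack([r.i1 for r in missing])
    L = np.stack([r.labels for r in missing])
    seeds = [stable_record_seed(seed, r.patient_id) for r in missing]
    gen = sample_batch(net.predictor(schedule.T), I1, L, schedule, seeds,
                       clamp=True)
    for rec, row in zip(missing, gen):
        rec.i2 = row.copy()
        rec.i2_is_synthetic = True
    return out
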