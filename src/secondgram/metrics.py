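"""Generative-evaluation metrics.

Three families of checks mirror how follow-up generation quality is
judged: (1) paired similarity — per-patient Pearson correlation,
Euclidean distance and cosine distance between real and generated
follow-up vectors, averaged over patients; (2) distributional similarity
— the Frechet distance between Gaussians fitted to the two feature sets,
the Pearson correlation of per-feature means, and the closeness of the
two feature-correlation matrices; (3) downstream utility — AUROC of a
small neural classifier trained on (baseline, follow-up, labels) feature
sets assembled from enriched or restricted cohorts.

Degenerate vectors (zero variance for Pearson, zero norm for cosine) are
skipped and tallied rather than silently scored 0 (D24).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .data import Cohort, denormalize_matrix

__all__ = [
    "MetricsReport",
    "PairedSimilarity",
    "paired_similarity",
    "frechet_distance",
    "mean_correlation",
    "covariate_similarity",
    "downstream_auroc",
    "subgroup_volume_change",
    "VolumeChangeReport",
]


@dataclass
class PairedSimilarity:
    mean_pearson: float
    mean_euclidean: float
    mean_cosine_distance: float
    n_excluded: int = 0

    def __iter__(self):  # allow tuple-style unpacking of the three metrics
        return iter((self.mean_pearson, self.mean_euclidean,
                     self.mean_cosine_distance))


@dataclass
class MetricsReport:
    """Bundle of similarity / distributional / downstream metrics."""

    mean_pearson: float | None = None
    mean_euclidean: float | None = None
    mean_cosine_distance: float | None = None
    frechet: float | None = None
    mean_correlation: float | None = None
    covariate_similarity: float | None = None
    auroc_by_task: dict[str, float] | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.mean_cosine_distance is not None and not (
                -1e-9 <= self.mean_cosine_distance <= 2 + 1e-9):
            raise ValueError("mean cosine distance out of [0, 2]")
        if self.frechet is not None and self.frechet < -1e-9:
            raise ValueError("Frechet distance must be nonnegative")
        if self.auroc_by_task:
            for task, v in self.auroc_by_task.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"AUROC for {task!r} out of [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def paired_similarity(real_set: np.ndarray, gen_set: np.ndarray) -> PairedSimilarity:
    """Per-patient Pearson / Euclidean / cosine-distance, averaged."""
    R = np.atleast_2d(np.asarray(real_set, dtype=float))
    G = np.atleast_2d(np.asarray(gen_set, dtype=float))
    if R.shape != G.shape:
        raise ValueError(f"shape mismatch: {R.shape} vs {G.shape}")
    n, d = R.shape
    if n < 1 or d < 2:
        raise ValueError("need n >= 1 patients and d >= 2 features")

    eucl = np.linalg.norm(R - G, axis=1)

    Rc = R - R.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=1, keepdims=True)
    sr = np.linalg.norm(Rc, axis=1)
    sg = np.linalg.norm(Gc, axis=1)
    nr = np.linalg.norm(R, axis=1)
    ng = np.linalg.norm(G, axis=1)

    ok_p = (sr > 0) & (sg > 0)
    ok_c = (nr > 0) & (ng > 0)
    pear = np.full(n, np.nan)
    pear[ok_p] = np.sum(Rc[ok_p] * Gc[ok_p], axis=1) / (sr[ok_p] * sg[ok_p])
    cosd = np.full(n, np.nan)
    cosd[ok_c] = 1.0 - np.sum(R[ok_c] * G[ok_c], axis=1) / (nr[ok_c] * ng[ok_c])

    n_excluded = int(np.sum(~ok_p) + np.sum(~ok_c))
    return PairedSimilarity(
        mean_pearson=float(np.nanmean(pear)) if ok_p.any() else float("nan"),
        mean_euclidean=float(np.mean(eucl)),
        mean_cosine_distance=float(np.nanmean(cosd)) if ok_c.any() else float("nan"),
        n_excluded=n_excluded,
    )


def frechet_distance(set_a: np.ndarray, set_b: np.ndarray,
                     jitter: float = 1e-6) -> float:
    """2-Wasserstein distance between Gaussians fitted to the two sets:
    ||mu_a - mu_b||^2 + tr(S_a + S_b - 2 (S_a S_b)^{1/2}).

    The cross term is computed via the symmetric form
    tr((S_a^{1/2} S_b S_a^{1/2})^{1/2}) with a small diagonal jitter; tiny
    negative eigenvalues from finite precision are clipped (D25).
    """
    A = np.atleast_2d(np.asarray(set_a, dtype=float))
    B = np.atleast_2d(np.asarray(set_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 vectors per set")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Sa = np.cov(A, rowvar=False) + jitter * np.eye(A.shape[1])
    Sb = np.cov(B, rowvar=False) + jitter * np.eye(B.shape[1])

    wa, Va = np.linalg.eigh(Sa)
    wa = np.clip(wa, 0.0, None)
    Sa_half = (Va * np.sqrt(wa)) @ Va.T
    M = Sa_half @ Sb @ Sa_half
    wm = np.linalg.eigvalsh(M)
    wm = np.clip(wm, 0.0, None)
    cross = np.sum(np.sqrt(wm))

    diff = mu_a - mu_b
    fd = float(diff @ diff + np.trace(Sa) + np.trace(Sb) - 2.0 * cross)
    return max(fd, 0.0)


def mean_correlation(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Pearson correlation between the two vectors of per-feature means."""
    A = np.atleast_2d(np.asarray(set_a, dtype=float))
    B = np.atleast_2d(np.asarray(set_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    if A.shape[1] < 3:
        raise ValueError("need at least 3 features")
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    if np.std(ma) == 0 or np.std(mb) == 0:
        raise ValueError("per-feature means have zero variance")
    return float(np.corrcoef(ma, mb)[0, 1])


def covariate_similarity(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """Mean absolute off-diagonal difference between the two d x d feature
    correlation matrices; 0 means identical correlation structure (D26).
    Constant features (zero variance in either set) are excluded."""
    A = np.atleast_2d(np.asarray(set_a, dtype=float))
    B = np.atleast_2d(np.asarray(set_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    if len(A) < 3 or len(B) < 3:
        raise ValueError("need at least 3 vectors per set")
    ok = (A.std(axis=0) > 0) & (B.std(axis=0) > 0)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 non-constant shared features")
    Ca = np.corrcoef(A[:, ok], rowvar=False)
    Cb = np.corrcoef(B[:, ok], rowvar=False)
    mask = ~np.eye(Ca.shape[0], dtype=bool)
    return float(np.mean(np.abs(Ca - Cb)[mask]))


def _downstream_features(cohort: Cohort, task_label: str, mode: str):
    ti = cohort.label_index(task_label)
    keep = [j for j in range(cohort.n_labels) if j != ti]
    X1 = cohort.baseline_matrix()
    L = cohort.labels_matrix()
    y = L[:, ti]
    if mode == "all_first":
        X = np.hstack([X1, L[:, keep]])
        return X, y
    recs = [r for r in cohort if r.has_followup]
    if mode == "limited_paired":
        recs = [r for r in recs if r.has_real_followup]
    if len(recs) != len(cohort) and mode == "enriched":
        raise ValueError("enriched mode requires every record to carry i2")
    if not recs:
        raise ValueError("no records with follow-up for downstream features")
    X1 = np.stack([r.i1 for r in recs])
    X2 = np.stack([r.i2 for r in recs])
    L = np.stack([r.labels for r in recs])
    y = L[:, ti]
    X = np.hstack([X1, X2, L[:, keep]])
    return X, y


def downstream_auroc(train: Cohort, test: Cohort, task_label: str,
                     seed: int = 0, mode: str = "enriched") -> float:
    """AUROC of a three-layer neural classifier on a binary label task.

    Feature vector is [i1; i2; labels minus the task label] — the task
    label is never an input (D27); in ``all_first`` mode only [i1; other
    labels] for all patients; ``limited_paired`` restricts to patients
    with a real follow-up. The test cohort always uses real follow-ups.
    """
    from sklearn.metrics import roc_auc_score
    from sklearn.neural_network import MLPClassifier

    if mode not in ("enriched", "all_first", "limited_paired"):
        raise ValueError(f"unknown downstream mode {mode!r}")
    for rec in test:
        if mode != "all_first" and not rec.has_real_followup:
            raise ValueError("test records must carry real follow-ups")
    Xtr, ytr = _downstream_features(train, task_label, mode)
    Xte, yte = _downstream_features(test, task_label,
                                    "all_first" if mode == "all_first" else "limited_paired")
    for name, y in (("train", ytr), ("test", yte)):
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(f"{name} labels contain a single class")
        if not set(classes).issubset({0.0, 1.0}):
            raise ValueError(f"task label {task_label!r} is not binary")
    clf = MLPClassifier(
        hidden_layer_sizes=(256, 256), batch_size=128,
        learning_rate_init=0.001, solver="adam",
        early_stopping=True, n_iter_no_change=5, validation_fraction=0.1,
        max_iter=200, random_state=seed,
    )
    clf.fit(Xtr, ytr)
    scores = clf.predict_proba(Xte)[:, 1]
    return float(roc_auc_score(yte, scores))


@dataclass
class VolumeChangeReport:
    """Mean within-group change of an averaged regional volume, on the raw
    scale, for real vs generated follow-ups."""

    real_group: float
    real_rest: float
    gen_group: float
    gen_rest: float

    @property
    def real_ratio(self) -> float:
        return self.real_group / self.real_rest if self.real_rest != 0 else float("nan")

    @property
    def gen_ratio(self) -> float:
        return self.gen_group / self.gen_rest if self.gen_rest != 0 else float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["real_ratio"] = self.real_ratio
        d["gen_ratio"] = self.gen_ratio
        return d


def subgroup_volume_change(cohort_real_pairs: Cohort,
                           generated_i2: np.ndarray,
                           feature_subset, group_label: str) -> VolumeChangeReport:
    """Case-study statistic: denormalize baseline, real follow-up and
    generated follow-up; average the subset features into one volume per
    patient; report the mean volume change (follow-up minus baseline) for
    the labelled group vs the rest, for real and generated follow-ups."""
    cohort = cohort_real_pairs
    if cohort.feature_ranges is None:
        raise ValueError("cohort carries no feature_ranges")
    if len(list(feature_subset)) == 0:
        raise ValueError("feature_subset is empty")
    recs = [r for r in cohort if r.has_real_followup]
    if len(recs) != len(generated_i2):
        raise ValueError("generated_i2 must align with real-pair records")
    idx = cohort.feature_indices(list(feature_subset))
    gi = cohort.label_index(group_label)

    I1 = denormalize_matrix(np.stack([r.i1 for r in recs]), cohort.feature_ranges)
    I2 = denormalize_matrix(np.stack([r.i2 for r in recs]), cohort.feature_ranges)
    Gen = denormalize_matrix(np.asarray(generated_i2, dtype=float), cohort.feature_ranges)
    group = np.array([r.labels[gi] for r in recs]) == 1.0
    if group.all() or not group.any():
        raise ValueError(f"group label {group_label!r} has an empty group")

    v1 = I1[:, idx].mean(axis=1)
    v2 = I2[:, idx].mean(axis=1)
    vg = Gen[:, idx].mean(axis=1)
    real_change = v2 - v1
    gen_change = vg - v1
    return VolumeChangeReport(
        real_group=float(real_change[group].mean()),
        real_rest=float(real_change[~group].mean()),
        gen_group=float(gen_change[group].mean()),
        gen_rest=float(gen_change[~group].mean()),
    )
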