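"""Cohort containers, file IO, normalization, imputation, and splitting.

A cohort is a collection of patients, each carrying a baseline imaging
feature vector ``i1`` (d continuous anatomical measurements), an optional
follow-up vector ``i2`` from a second scan, and a label vector ``l`` of
demographic/outcome covariates. Features are min-max normalized to [-1, 1]
before modelling; the raw per-feature ranges are kept on the cohort so
generated vectors can be mapped back to physical units (mm^3 etc.).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "Cohort",
    "SplitCohorts",
    "CohortSchema",
    "load_cohort",
    "write_cohort",
    "normalize",
    "denormalize",
    "impute_within_vector",
    "split_cohort",
    "stable_record_seed",
]


@dataclass
class PatientRecord:
    """One patient: baseline features, optional follow-up, labels."""

    patient_id: str
    i1: np.ndarray
    i2: np.ndarray | None
    labels: np.ndarray
    i2_is_synthetic: bool = False

    def __post_init__(self) -> None:
        self.i1 = np.asarray(self.i1, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        if self.i2 is not None:
            self.i2 = np.asarray(self.i2, dtype=float)
            if self.i2.shape != self.i1.shape:
                raise ValueError(
                    f"record {self.patient_id!r}: i2 length {self.i2.shape} "
                    f"!= i1 length {self.i1.shape}"
                )
        if self.i2_is_synthetic and self.i2 is None:
            raise ValueError(
                f"record {self.patient_id!r}: i2_is_synthetic without i2"
            )

    @property
    def has_followup(self) -> bool:
        return self.i2 is not None

    @property
    def has_real_followup(self) -> bool:
        return self.i2 is not None and not self.i2_is_synthetic

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            self.patient_id,
            self.i1.copy(),
            None if self.i2 is None else self.i2.copy(),
            self.labels.copy(),
            self.i2_is_synthetic,
        )


@dataclass
class Cohort:
    """Ordered collection of patient records with shared feature metadata.

    ``feature_ranges`` holds the raw-scale (min, max) per feature once the
    cohort has been normalized (or when ranges were supplied externally);
    it is ``None`` for raw cohorts that have never seen ``normalize``.
    """

    records: list[PatientRecord]
    feature_names: list[str]
    label_names: list[str]
    feature_ranges: np.ndarray | None = None  # (d, 2) raw-scale min/max
    is_normalized: bool = False

    def __post_init__(self) -> None:
        d = len(self.feature_names)
        n_l = len(self.label_names)
        for rec in self.records:
            if rec.i1.shape != (d,):
                raise ValueError(
                    f"record {rec.patient_id!r}: expected {d} features, "
                    f"got {rec.i1.shape}"
                )
            if rec.labels.shape != (n_l,):
                raise ValueError(
                    f"record {rec.patient_id!r}: expected {n_l} labels, "
                    f"got {rec.labels.shape}"
                )
        if self.feature_ranges is not None:
            self.feature_ranges = np.asarray(self.feature_ranges, dtype=float)
            if self.feature_ranges.shape != (d, 2):
                raise ValueError("feature_ranges must have shape (d, 2)")
            if np.any(self.feature_ranges[:, 0] > self.feature_ranges[:, 1]):
                raise ValueError("feature_ranges must satisfy min <= max")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def baseline_matrix(self) -> np.ndarray:
        return np.stack([r.i1 for r in self.records]) if self.records else np.empty((0, self.n_features))

    def labels_matrix(self) -> np.ndarray:
        return np.stack([r.labels for r in self.records]) if self.records else np.empty((0, self.n_labels))

    def followup_matrix(self) -> np.ndarray:
        """Follow-up vectors of the paired subset, in record order."""
        rows = [r.i2 for r in self.records if r.i2 is not None]
        return np.stack(rows) if rows else np.empty((0, self.n_features))

    def paired(self) -> "Cohort":
        return self.subset([r.patient_id for r in self.records if r.has_followup])

    def unpaired(self) -> "Cohort":
        return self.subset([r.patient_id for r in self.records if not r.has_followup])

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        wanted = set(patient_ids)
        recs = [r for r in self.records if r.patient_id in wanted]
        return Cohort(recs, list(self.feature_names), list(self.label_names),
                      None if self.feature_ranges is None else self.feature_ranges.copy(),
                      self.is_normalized)

    def copy(self) -> "Cohort":
        return Cohort(
            [r.copy() for r in self.records],
            list(self.feature_names),
            list(self.label_names),
            None if self.feature_ranges is None else self.feature_ranges.copy(),
            self.is_normalized,
        )

    def label_index(self, name: str) -> int:
        try:
            return self.label_names.index(name)
        except ValueError:
            raise KeyError(f"unknown label {name!r}") from None

    def feature_indices(self, names: Sequence[str]) -> np.ndarray:
        idx = []
        for name in names:
            try:
                idx.append(self.feature_names.index(name))
            except ValueError:
                raise KeyError(f"unknown feature {name!r}") from None
        return np.asarray(idx, dtype=int)


@dataclass
class SplitCohorts:
    """Train / validation / test partition of a cohort.

    Test records always carry a real (non-synthetic) follow-up so the
    held-out comparison is against genuine second-visit imaging.
    """

    train: Cohort
    validation: Cohort
    test: Cohort

    def __post_init__(self) -> None:
        ids_train = {r.patient_id for r in self.train}
        ids_val = {r.patient_id for r in self.validation}
        ids_test = {r.patient_id for r in self.test}
        if ids_train & ids_val or ids_train & ids_test or ids_val & ids_test:
            raise ValueError("patient ids overlap across splits")
        for rec in self.test:
            if not rec.has_real_followup:
                raise ValueError(
                    f"test record {rec.patient_id!r} lacks a real follow-up"
                )


@dataclass
class CohortSchema:
    """Column-role mapping for delimited cohort files.

    Follow-up feature columns share the baseline column's name plus
    ``followup_suffix``; missing cells are empty.
    """

    id_col: str = "patient_id"
    feature_cols: list[str] | None = None
    label_cols: list[str] | None = None
    followup_suffix: str = "__followup"
    synthetic_col: str = "i2_is_synthetic"

    def to_dict(self) -> dict:
        return {
            "id_col": self.id_col,
            "feature_cols": self.feature_cols,
            "label_cols": self.label_cols,
            "followup_suffix": self.followup_suffix,
            "synthetic_col": self.synthetic_col,
        }


def _numeric_block(df: pd.DataFrame, cols: list[str], what: str) -> np.ndarray:
    """Convert columns to float, raising a parse error naming row/column."""
    out = np.empty((len(df), len(cols)))
    for j, col in enumerate(cols):
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric {what} cell at row {row}, column {col!r}: "
                f"{raw.iloc[row]!r}"
            )
        out[:, j] = vals.to_numpy(dtype=float)
    return out


def load_cohort(path: str | Path, schema: CohortSchema | None = None) -> Cohort:
    """Read a cohort CSV on the raw (unnormalized) scale.

    Rows whose follow-up columns are entirely empty yield records with
    ``i2`` absent; partially empty baseline/follow-up cells become NaN
    (to be filled by :func:`impute_within_vector`).
    """
    schema = schema or CohortSchema()
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    if schema.id_col not in df.columns:
        raise ValueError(f"missing id column {schema.id_col!r}")
    ids = df[schema.id_col].astype(str)
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate patient_id {dup.iloc[0]!r}")

    suffix = schema.followup_suffix
    if schema.feature_cols is None:
        feature_cols = [
            c for c in df.columns
            if c not in (schema.id_col, schema.synthetic_col)
            and not c.endswith(suffix)
            and (schema.label_cols is None or c not in schema.label_cols)
            and c + suffix in df.columns
        ]
        if not feature_cols:  # no follow-up columns at all: everything but labels
            feature_cols = [
                c for c in df.columns
                if c not in (schema.id_col, schema.synthetic_col)
                and (schema.label_cols is None or c not in schema.label_cols)
                and not c.endswith(suffix)
            ]
    else:
        feature_cols = list(schema.feature_cols)
    followup_cols = [c + suffix for c in feature_cols if c + suffix in df.columns]
    has_followup_cols = len(followup_cols) == len(feature_cols) and len(followup_cols) > 0
    if schema.label_cols is None:
        claimed = {schema.id_col, schema.synthetic_col, *feature_cols, *followup_cols}
        label_cols = [c for c in df.columns if c not in claimed and not c.endswith(suffix)]
    else:
        label_cols = list(schema.label_cols)

    X1 = _numeric_block(df, feature_cols, "feature")
    L = _numeric_block(df, label_cols, "label") if label_cols else np.empty((len(df), 0))
    X2 = _numeric_block(df, followup_cols, "follow-up feature") if has_followup_cols else None
    if schema.synthetic_col in df.columns:
        synth = df[schema.synthetic_col].fillna("0").astype(str).str.strip().isin(
            {"1", "1.0", "true", "True"}
        ).to_numpy()
    else:
        synth = np.zeros(len(df), dtype=bool)

    records = []
    for i in range(len(df)):
        i2 = None
        if X2 is not None and not np.all(np.isnan(X2[i])):
            i2 = X2[i]
        records.append(
            PatientRecord(str(ids.iloc[i]), X1[i], i2, L[i],
                          bool(synth[i]) and i2 is not None)
        )
    return Cohort(records, feature_cols, label_cols)


def write_cohort(cohort: Cohort, path: str | Path,
                 schema: CohortSchema | None = None,
                 sidecar: bool = True) -> None:
    """Write a cohort CSV (D4 dialect) plus a JSON sidecar with the raw
    feature ranges and schema needed for exact denormalization."""
    schema = schema or CohortSchema()
    path = Path(path)
    cols: dict[str, object] = {schema.id_col: [r.patient_id for r in cohort]}
    X1 = cohort.baseline_matrix()
    for j, name in enumerate(cohort.feature_names):
        cols[name] = X1[:, j]
    d = cohort.n_features
    any_followup = any(r.has_followup for r in cohort)
    if any_followup:
        for j, name in enumerate(cohort.feature_names):
            col = np.full(len(cohort), np.nan)
            for i, rec in enumerate(cohort):
                if rec.i2 is not None:
                    col[i] = rec.i2[j]
            cols[name + schema.followup_suffix] = col
    L = cohort.labels_matrix()
    for j, name in enumerate(cohort.label_names):
        cols[name] = L[:, j]
    cols[schema.synthetic_col] = [int(r.i2_is_synthetic) for r in cohort]
    pd.DataFrame(cols).to_csv(path, index=False)
    if sidecar:
        meta = {
            "schema": schema.to_dict() | {
                "feature_cols": cohort.feature_names,
                "label_cols": cohort.label_names,
            },
            "is_normalized": cohort.is_normalized,
            "feature_ranges": None if cohort.feature_ranges is None
            else cohort.feature_ranges.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2)
        )


def load_ranges(path: str | Path) -> np.ndarray | None:
    meta = json.loads(Path(path).read_text())
    rng = meta.get("feature_ranges")
    return None if rng is None else np.asarray(rng, dtype=float)


def _apply_ranges(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    out = np.zeros_like(x)
    ok = span > 0
    out[..., ok] = 2.0 * (x[..., ok] - lo[ok]) / span[ok] - 1.0
    # constant features (min == max) map to 0 (D1)
    return np.clip(out, -1.0, 1.0)


def normalize(cohort: Cohort, ranges: np.ndarray | None = None) -> Cohort:
    """Min-max normalize every feature to [-1, 1].

    If ``ranges`` is not given, per-feature min/max are computed over all
    available i1 and i2 vectors of this cohort (NaNs ignored). Values
    outside supplied ranges are clipped. Constant features map to 0.
    """
    if cohort.is_normalized:
        raise ValueError("cohort is already normalized")
    if ranges is None:
        rows = [cohort.baseline_matrix()]
        fu = cohort.followup_matrix()
        if len(fu):
            rows.append(fu)
        stacked = np.vstack(rows)
        with np.errstate(all="ignore"):
            lo = np.nanmin(stacked, axis=0)
            hi = np.nanmax(stacked, axis=0)
        ranges = np.column_stack([lo, hi])
    else:
        ranges = np.asarray(ranges, dtype=float)
        if ranges.shape != (cohort.n_features, 2):
            raise ValueError("ranges must have shape (d, 2)")
    lo, hi = ranges[:, 0], ranges[:, 1]
    out = cohort.copy()
    for rec in out:
        rec.i1 = _apply_ranges(rec.i1, lo, hi)
        if rec.i2 is not None:
            rec.i2 = _apply_ranges(rec.i2, lo, hi)
    out.feature_ranges = ranges.copy()
    out.is_normalized = True
    return out


def denormalize(cohort: Cohort) -> Cohort:
    """Exact inverse of :func:`normalize` (up to clipping at normalize time)."""
    if cohort.feature_ranges is None:
        raise ValueError("cohort carries no feature_ranges; cannot denormalize")
    if not cohort.is_normalized:
        raise ValueError("cohort is not normalized")
    lo, hi = cohort.feature_ranges[:, 0], cohort.feature_ranges[:, 1]
    span = hi - lo

    def inv(x: np.ndarray) -> np.ndarray:
        out = (x + 1.0) / 2.0 * span + lo
        out[..., span == 0] = lo[span == 0]
        return out

    out = cohort.copy()
    for rec in out:
        rec.i1 = inv(rec.i1)
        if rec.i2 is not None:
            rec.i2 = inv(rec.i2)
    out.is_normalized = False
    return out


def denormalize_matrix(X: np.ndarray, feature_ranges: np.ndarray) -> np.ndarray:
    """Map normalized vectors (rows) back to the raw scale."""
    lo, hi = feature_ranges[:, 0], feature_ranges[:, 1]
    span = hi - lo
    out = (np.asarray(X, dtype=float) + 1.0) / 2.0 * span + lo
    out[..., span == 0] = lo[span == 0]
    return out


def impute_within_vector(cohort: Cohort, max_rounds: int = 10,
                         seed: int = 0) -> Cohort:
    """Fill rare within-vector missingness by chained regression.

    All available imaging vectors (i1 and i2 alike — they share the same
    feature space) are stacked and each incomplete feature is iteratively
    regressed on all the others, starting from per-feature means, until
    ``max_rounds`` or convergence. Observed entries are preserved exactly.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer
    from sklearn.linear_model import LinearRegression

    mats = [cohort.baseline_matrix()]
    n1 = len(cohort)
    fu = cohort.followup_matrix()
    if len(fu):
        mats.append(fu)
    X = np.vstack(mats)
    missing = np.isnan(X)
    if not missing.any():
        return cohort
    fully_missing = np.flatnonzero(missing.all(axis=0))
    if len(fully_missing):
        name = cohort.feature_names[int(fully_missing[0])]
        raise ValueError(f"feature {name!r} is entirely missing; cannot impute")
    imputer = IterativeImputer(
        estimator=LinearRegression(),
        max_iter=max_rounds,
        tol=1e-3,
        initial_strategy="mean",
        imputation_order="roman",  # input column order
        sample_posterior=False,
        random_state=seed,
    )
    filled = imputer.fit_transform(X)
    # fit_transform may drop columns only if fully missing (excluded above)
    filled[~missing] = X[~missing]
    out = cohort.copy()
    for i, rec in enumerate(out):
        rec.i1 = filled[i]
    k = n1
    for rec in out:
        if rec.i2 is not None:
            rec.i2 = filled[k]
            k += 1
    return out


def split_cohort(cohort: Cohort, test_frac: float = 0.2,
                 val_frac: float = 0.1, seed: int = 0) -> SplitCohorts:
    """Partition a cohort into train/validation/test.

    The test set is ``ceil(test_frac * n_longitudinal)`` records drawn
    uniformly from the patients with a real follow-up; everyone else
    (remaining longitudinal plus all non-longitudinal patients) forms a
    combined pool, from which ``ceil(val_frac * stratum)`` are drawn per
    stratum for validation; the rest is training. Sizes are deterministic
    given the counts; membership is random given the seed.
    """
    longi = [r for r in cohort if r.has_real_followup]
    nonlong = [r for r in cohort if not r.has_real_followup]
    if len(longi) < 2:
        raise ValueError("need at least 2 longitudinal records to split")
    rng = np.random.default_rng(seed)

    n_test = math.ceil(test_frac * len(longi))
    order = rng.permutation(len(longi))
    test = [longi[i] for i in order[:n_test]]
    rest_long = [longi[i] for i in order[n_test:]]

    def draw(pool: list[PatientRecord], frac: float):
        n = math.ceil(frac * len(pool)) if pool else 0
        order = rng.permutation(len(pool))
        return [pool[i] for i in order[:n]], [pool[i] for i in order[n:]]

    val_long, train_long = draw(rest_long, val_frac)
    val_non, train_non = draw(nonlong, val_frac)

    def mk(recs: list[PatientRecord]) -> Cohort:
        return Cohort([r.copy() for r in recs], list(cohort.feature_names),
                      list(cohort.label_names),
                      None if cohort.feature_ranges is None else cohort.feature_ranges.copy(),
                      cohort.is_normalized)

    return SplitCohorts(
        train=mk(train_long + train_non),
        validation=mk(val_long + val_non),
        test=mk(test),
    )


def stable_record_seed(master_seed: int, patient_id: str) -> int:
    """Deterministic, order-independent per-record seed below 2**31 (D22)."""
    h = hashlib.sha256(f"{master_seed}:{patient_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
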