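"""Trained single/double-cropping classifiers on smoothed NDVI vectors.

Three model families are supported, mirroring the usual remote-sensing
toolbox for time-series classification: an RBF support vector machine, a
random forest, and a k-nearest-neighbour classifier under dynamic time
warping (DTW) distance, which aligns greenness curves whose planting dates
are shifted.

The training protocol is: crop-stratified 80/20 train/test splits; within
the training set, hyperparameters are chosen by 5-fold stratified
cross-validation on overall accuracy, with the minority (double-cropped)
class oversampled with replacement to 50% of the majority size *inside
each CV training fold only* — never into a validation fold, where the
duplicated records would inflate the score. The final model is refit on
the full oversampled training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from math import ceil
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .preprocess import N_WINDOWS, SmoothSeries

logger = logging.getLogger(__name__)

SINGLE = "single"
DOUBLE = "double"
MODEL_KINDS = ("svm", "rf", "knn_dtw")
_MODEL_FILE_VERSION = 1

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "svm": [
        {"C": C, "gamma": g}
        for C, g in product([0.1, 1.0, 10.0, 100.0], ["scale", 0.01, 0.1])
    ],
    "rf": [
        {"n_estimators": n, "max_depth": d}
        for n, d in product([100, 300], [None, 10])
    ],
    "knn_dtw": [{"n_neighbors": k} for k in [1, 3, 5, 7]],
}


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-length (36) smoothed NDVI vector for one field-year."""

    values: np.ndarray
    field_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_WINDOWS,):
            raise ValueError(f"expected length-{N_WINDOWS} vector, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature values")


@dataclass
class LabeledDataset:
    """Feature vectors with truth labels and a crop stratum per record."""

    records: list[FeatureVector]
    strata: list[str]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.strata):
            raise ValueError("records and strata length mismatch")
        for r in self.records:
            if r.label not in (SINGLE, DOUBLE):
                raise ValueError(f"record {r.field_id} has label {r.label!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def X(self) -> np.ndarray:
        return np.array([r.values for r in self.records])

    @property
    def y(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in idx],
            strata=[self.strata[i] for i in idx],
        )


def to_feature_vector(smooth: SmoothSeries, label: str | None = None) -> FeatureVector:
    """Copy a smoothed series into a classifier input vector, window order."""
    return FeatureVector(
        values=smooth.values.copy(), field_id=smooth.meta.field_id, label=label
    )


# --------------------------------------------------------------------------
# Dynamic time warping

def _dtw_numpy(a: np.ndarray, b: np.ndarray, band: int) -> float:
    n, m = len(a), len(b)
    inf = np.inf
    D = np.full((n + 1, m + 1), inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        lo = 1 if band < 0 else max(1, i - band)
        hi = m if band < 0 else min(m, i + band)
        for j in range(lo, hi + 1):
            cost = abs(a[i - 1] - b[j - 1])
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


try:  # optional numba acceleration; semantics identical to _dtw_numpy
    from numba import njit, prange

    _dtw_core = njit(cache=False)(_dtw_numpy)

    @njit(parallel=False, cache=False)
    def _cross_dtw_core(A, B, band):  # pragma: no cover - thin jit wrapper
        out = np.empty((A.shape[0], B.shape[0]))
        for i in prange(A.shape[0]):
            for j in range(B.shape[0]):
                out[i, j] = _dtw_core(A[i], B[j], band)
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _dtw_core = _dtw_numpy
    _cross_dtw_core = None
    _HAVE_NUMBA = False


def dtw_distance(
    a: Sequence[float], b: Sequence[float], window: int | None = None
) -> float:
    """Classic DTW distance with absolute-difference local cost.

    Unit steps (match / insert / delete), unconstrained by default;
    ``window`` adds a Sakoe–Chiba band of that half-width.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    band = -1 if window is None else int(window)
    if band >= 0 and abs(len(a) - len(b)) > band:
        raise ValueError("band narrower than the length difference")
    return float(_dtw_core(a, b, band))


def dtw_matrix(
    A: np.ndarray, B: np.ndarray, window: int | None = None
) -> np.ndarray:
    """Pairwise DTW distances between the rows of A and the rows of B."""
    A = np.ascontiguousarray(A, dtype=float)
    B = np.ascontiguousarray(B, dtype=float)
    band = -1 if window is None else int(window)
    if _HAVE_NUMBA:
        return np.asarray(_cross_dtw_core(A, B, band))
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = _dtw_numpy(A[i], B[j], band)
    return out


# --------------------------------------------------------------------------
# Sampling protocol

def stratified_split(
    dataset: LabeledDataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Crop-stratified train/test split.

    Within each crop stratum, ``round(test_fraction * n)`` records go to
    test; strata of size 1 go entirely to train. Deterministic per seed.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    strata = np.asarray(dataset.strata)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for s in sorted(set(strata)):
        idx = np.flatnonzero(strata == s)
        if idx.size == 1:
            train_idx.extend(idx)
            continue
        n_test = int(round(test_fraction * idx.size))
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


def _oversample_indices(
    labels: np.ndarray, target_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of the original records plus resampled minority duplicates."""
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires both classes present")
    minority = classes[np.argmin(counts)]
    majority_n = int(counts.max())
    minority_idx = np.flatnonzero(labels == minority)
    target = ceil(target_ratio * majority_n)
    n_extra = target - minority_idx.size
    base = np.arange(len(labels))
    if n_extra <= 0:
        return base
    extra = rng.choice(minority_idx, size=n_extra, replace=True)
    return np.concatenate([base, extra])


def oversample_minority(
    train: LabeledDataset, target_ratio: float = 0.5, seed: int = 0
) -> LabeledDataset:
    """Resample the minority class with replacement to ``target_ratio`` of
    the majority size; the majority and all original records are untouched."""
    rng = np.random.default_rng(seed)
    idx = _oversample_indices(train.y, target_ratio, rng)
    return train.subset(list(idx))


# --------------------------------------------------------------------------
# Training

@dataclass
class TrainedModel:
    """A fitted classifier plus its training configuration and CV table."""

    kind: str
    estimator: object
    config: dict
    seed: int
    cv_table: list[dict] = field(default_factory=list)
    train_X: np.ndarray | None = None  # reference set for knn_dtw

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": _MODEL_FILE_VERSION,
                "kind": self.kind,
                "estimator": self.estimator,
                "config": self.config,
                "seed": self.seed,
                "cv_table": self.cv_table,
                "train_X": self.train_X,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format_version") != _MODEL_FILE_VERSION:
            raise ValueError(f"unsupported model file version: {blob.get('format_version')}")
        return cls(
            kind=blob["kind"],
            estimator=blob["estimator"],
            config=blob["config"],
            seed=blob["seed"],
            cv_table=blob["cv_table"],
            train_X=blob["train_X"],
        )


def _make_estimator(kind: str, params: Mapping, seed: int):
    if kind == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "knn_dtw":
        return KNeighborsClassifier(metric="precomputed", **params)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Class-stratified fold assignment so every fold sees both classes."""
    fold_of = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold_of[idx] = np.arange(idx.size) % n_folds
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


def train_classifier(
    kind: str,
    train: LabeledDataset,
    cv_folds: int = 5,
    grid: Sequence[Mapping] | None = None,
    seed: int = 0,
    oversample_ratio: float = 0.5,
) -> TrainedModel:
    """Grid-search ``kind`` by stratified CV and refit on the training set.

    Oversampling of the minority class happens inside each CV training
    fold only; validation folds keep the native class balance. The winning
    configuration (ties broken toward the first grid entry) is refit on the
    full, oversampled training set.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    grid = list(grid) if grid is not None else DEFAULT_GRIDS[kind]
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    X, y = train.X, train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, cv_folds, rng)
    fold_seeds = rng.integers(0, 2**31 - 1, size=cv_folds)

    D_full = dtw_matrix(X, X) if kind == "knn_dtw" else None

    cv_table: list[dict] = []
    mean_scores = np.empty(len(grid))
    for gi, params in enumerate(grid):
        scores = []
        for f, val_idx in enumerate(folds):
            tr_idx = np.concatenate([folds[g] for g in range(cv_folds) if g != f])
            os_rng = np.random.default_rng(fold_seeds[f])
            os_idx = tr_idx[_oversample_indices(y[tr_idx], oversample_ratio, os_rng)]
            est = _make_estimator(kind, params, seed)
            if kind == "knn_dtw":
                est.fit(D_full[np.ix_(os_idx, os_idx)], y[os_idx])
                pred = est.predict(D_full[np.ix_(val_idx, os_idx)])
            else:
                est.fit(X[os_idx], y[os_idx])
                pred = est.predict(X[val_idx])
            scores.append(float(np.mean(pred == y[val_idx])))
        mean_scores[gi] = np.mean(scores)
        cv_table.append(
            {"params": dict(params), "fold_scores": scores, "mean_oa": mean_scores[gi]}
        )
    best = int(np.argmax(mean_scores))
    best_params = dict(grid[best])
    logger.info("%s: best params %s (CV OA %.3f)", kind, best_params, mean_scores[best])

    final_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    final_idx = _oversample_indices(y, oversample_ratio, final_rng)
    est = _make_estimator(kind, best_params, seed)
    if kind == "knn_dtw":
        est.fit(D_full[np.ix_(final_idx, final_idx)], y[final_idx])
        train_X = X[final_idx]
    else:
        est.fit(X[final_idx], y[final_idx])
        train_X = None
    return TrainedModel(
        kind=kind,
        estimator=est,
        config={
            "params": best_params,
            "cv_folds": cv_folds,
            "oversample_ratio": oversample_ratio,
        },
        seed=seed,
        cv_table=cv_table,
        train_X=train_X,
    )


def predict(model: TrainedModel, vectors: np.ndarray | Sequence[FeatureVector]) -> np.ndarray:
    """Predict a single/double label for each length-36 vector."""
    if isinstance(vectors, (list, tuple)) and vectors and isinstance(vectors[0], FeatureVector):
        X = np.array([v.values for v in vectors])
    else:
        X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_WINDOWS:
        raise ValueError(f"expected (n, {N_WINDOWS}) inputs, got {X.shape}")
    if model.kind == "knn_dtw":
        if model.train_X is None:
            raise ValueError("knn_dtw model lacks its reference set")
        D = dtw_matrix(X, model.train_X)
        return model.estimator.predict(D)
    return model.estimator.predict(X)


# --------------------------------------------------------------------------
# Image adapter (input hook for external image classifiers)

def render_series_image(
    smooth: SmoothSeries, width: int = 224, height: int = 224
) -> np.ndarray:
    """Deterministic grayscale line plot of a series on a [0, 1] × year canvas.

    Returns a (height, width) uint8 matrix, 0 = background, 255 = line;
    row 0 is the top, so higher NDVI means a smaller row index. This is a
    plain rasterization (no axes, no antialiasing) intended as the input
    adapter for an external image classifier.
    """
    if width <= 0 or height <= 0:
        raise ValueError("dimensions must be positive")
    img = np.zeros((height, width), dtype=np.uint8)
    v = np.clip(smooth.values, 0.0, 1.0)
    # x positions of the 36 samples spread across the canvas
    xs = np.round(np.linspace(0, width - 1, len(v))).astype(int)
    ys = np.round((1.0 - v) * (height - 1)).astype(int)
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        span = max(x1 - x0, 1)
        for x in range(x0, x1 + 1):
            t = (x - x0) / span
            y = int(round(y0 + t * (y1 - y0)))
            img[y, x] = 255
    return img
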