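"""Nearest shrunken centroid classification of copy-number (LRR) features.

The classifier compares each sample to per-class centroids whose
standardized offsets from the overall centroid have been soft-thresholded
("shrunken") by an amount Delta.  For feature i and class k with n_k of n
samples,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),

where xbar_ik is the class mean, xbar_i the overall mean, s_i the pooled
within-class standard deviation (n - K denominator), s0 a positive guard
(a quantile, by default the median, of the s_i) that keeps low-variance
features from producing huge d, and m_k = sqrt(1/n_k + 1/n) makes
m_k * s_i an estimated standard error of the numerator.  Soft thresholding

    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0)

zeroes uninformative features; the shrunken centroids are recovered as
xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik.  A test sample t is assigned
to the class minimizing the discriminant score

    delta_k(t) = sum_i (t_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 log pi_k,

with pi_k the class prior.  Delta is tuned by stratified cross-validation;
a feature with d'_ik = 0 for every k drops out of the model entirely, so
the surviving feature set at the tuned Delta is the classifier's selection
of disease-relevant copy-number features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import DataError
from .lrr import LRRMatrix

__all__ = [
    "CentroidFit",
    "ShrunkenFit",
    "CVCurve",
    "fit_centroids",
    "shrink",
    "predict",
    "predict_matrix",
    "cross_validate",
    "rank_features",
]


@dataclass(frozen=True)
class CentroidFit:
    """Unshrunken centroid statistics for one training matrix."""

    class_labels: np.ndarray        # (K,) sorted class codes
    class_centroids: np.ndarray     # (K, p) xbar_ik
    overall_centroid: np.ndarray    # (p,)  xbar_i
    pooled_sd: np.ndarray           # (p,)  s_i
    s0: float
    mk: np.ndarray                  # (K,)  m_k
    d: np.ndarray                   # (K, p) d_ik
    priors: np.ndarray              # (K,)  pi_k
    feature_ids: list[str]
    scale: np.ndarray = None        # (p,) effective s_i + s0 used in d

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class ShrunkenFit:
    """Soft-thresholded fit at a given Delta."""

    base: CentroidFit
    delta: float
    d_shrunk: np.ndarray            # (K, p)
    shrunken_centroids: np.ndarray  # (K, p)

    @property
    def selected_mask(self) -> np.ndarray:
        """Features with a nonzero shrunken offset for at least one class."""
        return (self.d_shrunk != 0).any(axis=0)

    @property
    def selected_features(self) -> list[str]:
        mask = self.selected_mask
        return [f for f, m in zip(self.base.feature_ids, mask) if m]


@dataclass(frozen=True)
class CVCurve:
    """Cross-validation profile of accuracy and model size along a Delta grid."""

    delta_grid: np.ndarray
    accuracy: np.ndarray
    n_selected: np.ndarray
    best_delta: float


def fit_centroids(
    matrix: LRRMatrix,
    s0_quantile: float = 0.5,
    mk_variant: str = "plus",
    priors: str = "empirical",
) -> CentroidFit:
    """Compute class/overall centroids, pooled SDs and the d statistics.

    ``mk_variant`` selects m_k = sqrt(1/n_k + 1/n) (``"plus"``, default) or
    sqrt(1/n_k - 1/n) (``"minus"``).  ``priors`` is ``"empirical"`` (n_k/n)
    or ``"uniform"``.
    """
    matrix.validate_for_fit()
    if not 0.0 <= s0_quantile <= 1.0:
        raise DataError("s0_quantile must lie in [0, 1]")
    if mk_variant not in ("plus", "minus"):
        raise DataError("mk_variant must be 'plus' or 'minus'")
    if priors not in ("empirical", "uniform"):
        raise DataError("priors must be 'empirical' or 'uniform'")

    x = matrix.values
    labels = matrix.labels
    classes, counts = np.unique(labels, return_counts=True)
    n, p = x.shape
    k = len(classes)
    if k < 2:
        raise DataError("at least two classes required")

    class_centroids = np.empty((k, p))
    ss_within = np.zeros(p)
    for idx, c in enumerate(classes):
        xc = x[labels == c]
        class_centroids[idx] = xc.mean(axis=0)
        ss_within += ((xc - class_centroids[idx]) ** 2).sum(axis=0)
    overall = x.mean(axis=0)
    pooled_sd = np.sqrt(ss_within / (n - k))
    s0 = float(np.quantile(pooled_sd, s0_quantile))

    if mk_variant == "plus":
        mk = np.sqrt(1.0 / counts + 1.0 / n)
    else:
        mk = np.sqrt(np.maximum(1.0 / counts - 1.0 / n, 0.0))

    # s0 guards zero-variance features, but if at least half the features
    # are constant within every class s0 itself is 0; keep d finite by
    # borrowing the smallest positive scale (constant features with equal
    # centroids simply get d = 0).
    scale = pooled_sd + s0
    if (scale == 0).any():
        zero_cols = scale == 0
        num_zero = class_centroids[:, zero_cols] - overall[zero_cols][None, :]
        if np.any(num_zero != 0):
            if (~zero_cols).any():
                scale = np.where(zero_cols, scale[~zero_cols].min(), scale)
            else:
                raise DataError(
                    "every feature has zero within-class variance; the "
                    "standardized d statistic is undefined")
        else:
            scale = np.where(zero_cols, 1.0, scale)
    denom = mk[:, None] * scale[None, :]
    d = (class_centroids - overall[None, :]) / denom

    pri = counts / n if priors == "empirical" else np.full(k, 1.0 / k)
    return CentroidFit(
        class_labels=classes,
        class_centroids=class_centroids,
        overall_centroid=overall,
        pooled_sd=pooled_sd,
        s0=s0,
        mk=mk,
        d=d,
        priors=pri,
        feature_ids=list(matrix.feature_ids),
        scale=scale,
    )


def shrink(fit: CentroidFit, delta: float) -> ShrunkenFit:
    """Soft-threshold the d statistics by Delta and rebuild the centroids."""
    if delta < 0:
        raise DataError("delta must be non-negative")
    d_shrunk = np.sign(fit.d) * np.maximum(np.abs(fit.d) - delta, 0.0)
    scale = fit.mk[:, None] * fit.scale[None, :]
    shrunken = fit.overall_centroid[None, :] + scale * d_shrunk
    return ShrunkenFit(base=fit, delta=float(delta), d_shrunk=d_shrunk,
                       shrunken_centroids=shrunken)


def _scores(sfit: ShrunkenFit, x: np.ndarray) -> np.ndarray:
    """Discriminant scores delta_k for rows of x; shape (n, K)."""
    base = sfit.base
    denom = base.scale ** 2
    diff = x[:, None, :] - sfit.shrunken_centroids[None, :, :]
    dist = (diff ** 2 / denom[None, None, :]).sum(axis=2)
    return dist - 2.0 * np.log(base.priors)[None, :]


def predict(sfit: ShrunkenFit, sample: np.ndarray) -> tuple[int, np.ndarray]:
    """Class label of one sample and its per-class discriminant scores.

    Ties break toward the lower class code.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (sfit.base.n_features,):
        raise DataError(
            f"sample has {sample.shape} values, expected ({sfit.base.n_features},)"
        )
    if not np.isfinite(sample).all():
        raise DataError("sample contains non-finite values")
    scores = _scores(sfit, sample[None, :])[0]
    return int(sfit.base.class_labels[int(np.argmin(scores))]), scores


def predict_matrix(sfit: ShrunkenFit, x: np.ndarray) -> np.ndarray:
    """Vectorized prediction for an (n, p) matrix of samples."""
    x = np.asarray(x, dtype=float)
    scores = _scores(sfit, x)
    return sfit.base.class_labels[np.argmin(scores, axis=1)]


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified fold assignment; every class spread across folds."""
    classes, counts = np.unique(labels, return_counts=True)
    for c, cnt in zip(classes, counts):
        if cnt < n_folds:
            raise DataError(
                f"class {c} has only {cnt} samples; cannot stratify into "
                f"{n_folds} folds"
            )
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    matrix: LRRMatrix,
    n_folds: int = 10,
    delta_grid: np.ndarray | None = None,
    seed: int = 0,
    n_grid: int = 30,
    s0_quantile: float = 0.5,
    mk_variant: str = "plus",
    priors: str = "empirical",
) -> CVCurve:
    """Tune Delta by stratified cross-validation.

    The default grid spans 0 to max|d_ik| of the full-data fit in ``n_grid``
    steps, guaranteeing the fully shrunken (empty) model at the far end.
    Accuracy per Delta is the pooled fraction of correctly classified
    held-out samples.  ``best_delta`` is the *largest* grid value attaining
    the maximal accuracy: on an accuracy plateau the sparsest model wins.
    """
    if n_folds < 2:
        raise DataError("n_folds must be at least 2")
    matrix.validate_for_fit()

    full_fit = fit_centroids(matrix, s0_quantile=s0_quantile,
                             mk_variant=mk_variant, priors=priors)
    if delta_grid is None:
        delta_grid = np.linspace(0.0, float(np.abs(full_fit.d).max()), n_grid)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if (np.diff(delta_grid) < 0).any() or (delta_grid < 0).any():
        raise DataError("delta_grid must be ascending and non-negative")

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(matrix.labels, n_folds, rng)
    n = matrix.n_samples
    correct = np.zeros(len(delta_grid), dtype=int)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train = LRRMatrix(
            values=matrix.values[train_mask],
            labels=matrix.labels[train_mask],
            sample_ids=[matrix.sample_ids[i] for i in np.flatnonzero(train_mask)],
            feature_ids=matrix.feature_ids,
        )
        fit = fit_centroids(train, s0_quantile=s0_quantile,
                            mk_variant=mk_variant, priors=priors)
        x_test = matrix.values[test_idx]
        y_test = matrix.labels[test_idx]
        for g, delta in enumerate(delta_grid):
            pred = predict_matrix(shrink(fit, delta), x_test)
            correct[g] += int((pred == y_test).sum())

    accuracy = correct / n
    n_selected = np.array(
        [int(shrink(full_fit, d).selected_mask.sum()) for d in delta_grid]
    )
    best_mask = accuracy == accuracy.max()
    best_delta = float(delta_grid[np.flatnonzero(best_mask)[-1]])
    return CVCurve(delta_grid=delta_grid, accuracy=accuracy,
                   n_selected=n_selected, best_delta=best_delta)


def rank_features(sfit: ShrunkenFit) -> list[tuple[str, float]]:
    """Selected features ranked by max_k |d'_ik|, descending.

    Only features surviving shrinkage appear; ties keep input order.
    """
    scores = np.abs(sfit.d_shrunk).max(axis=0)
    order = np.argsort(-scores, kind="stable")
    return [
        (sfit.base.feature_ids[i], float(scores[i]))
        for i in order
        if scores[i] > 0
    ]
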