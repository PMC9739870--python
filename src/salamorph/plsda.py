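"""Partial Least Squares Discriminant Analysis on the pixel matrix.

PLS-DA regresses a one-hot class indicator matrix on the (column-centered)
binary pixel matrix with NIPALS PLS2 and classifies by nearest class mean in
X-score space.  The per-pixel VIP (variable importance in projection) score
summarizes how much each pixel contributes to the discriminating components;
squared VIPs average to 1 over pixels, so VIP > 1 marks above-average
importance.  Painting VIP back into the consensus frame shows *where* on the
head the best partition differs.

Columns are centered but not scaled: all pixels share the same 0/1 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .morphometrics import ConsensusFrame, PixelMatrix

__all__ = ["PlsdaModel", "fit_plsda", "predict_plsda", "vip_map", "cross_validated_accuracy"]


@dataclass
class PlsdaModel:
    A: int                      # number of components
    x_weights: np.ndarray       # (J, A)
    x_loadings: np.ndarray      # (J, A)
    x_scores: np.ndarray        # (n, A), mutually orthogonal
    y_loadings: np.ndarray      # (C, A)
    x_mean: np.ndarray          # (J,)
    classes: np.ndarray         # sorted class levels
    class_score_means: np.ndarray  # (C, A) training class centroids in score space
    vip: np.ndarray             # (J,) VIP scores, mean(vip^2) = 1
    cv_accuracy: float | None = None


def _as_matrix(data) -> np.ndarray:
    return (data.values if isinstance(data, PixelMatrix) else np.asarray(data)).astype(float)


def _one_hot(enc: np.ndarray, C: int) -> np.ndarray:
    return np.eye(C)[enc]


def _vip(pls: PLSRegression) -> np.ndarray:
    """VIP_j = sqrt( J * sum_a ss_a (w_ja/||w_a||)^2 / sum_a ss_a ), with
    ss_a the Y variance explained by component a."""
    W = pls.x_weights_
    T = pls.x_scores_
    Q = pls.y_loadings_
    J, A = W.shape
    ss = np.array([(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(A)])
    wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(J * (wn2 @ ss) / ss.sum())


def _fit_raw(X: np.ndarray, enc: np.ndarray, C: int, A: int) -> tuple[PLSRegression, np.ndarray]:
    pls = PLSRegression(n_components=A, scale=False)
    pls.fit(X, _one_hot(enc, C))
    scores = pls.x_scores_
    means = np.vstack([scores[enc == c].mean(axis=0) for c in range(C)])
    return pls, means


def _predict_raw(pls: PLSRegression, means: np.ndarray, X: np.ndarray) -> np.ndarray:
    scores = pls.transform(X)
    d2 = ((scores[:, None, :] - means[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def cross_validated_accuracy(
    data, labels: np.ndarray, A: int, folds: int = 5, seed: int = 0
) -> float:
    """Stratified k-fold cross-validated classification accuracy at A components."""
    X = _as_matrix(data)
    labels = np.asarray(labels)
    classes, enc = np.unique(labels, return_inverse=True)
    C = len(classes)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    hits = 0
    for train, test in skf.split(X, enc):
        a = min(A, len(train) - 1)
        pls, means = _fit_raw(X[train], enc[train], C, a)
        hits += int((_predict_raw(pls, means, X[test]) == enc[test]).sum())
    return hits / len(labels)


def fit_plsda(
    data,
    labels: np.ndarray,
    A: int | None = None,
    max_components: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> PlsdaModel:
    """Fit PLS-DA on the pixel matrix against a class labelling.

    With ``A`` unspecified, the component count is chosen in 1..max_components
    by stratified ``folds``-fold cross-validated accuracy (ties go to the
    smaller A).  The fit itself is deterministic given data and A.
    """
    X = _as_matrix(data)
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("labels length must match the number of rows")
    classes, enc = np.unique(labels, return_inverse=True)
    C = len(classes)
    if C < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    n, J = X.shape

    if A is None:
        best_a, best_acc = 1, -1.0
        for a in range(1, min(max_components, n - 1, J) + 1):
            acc = cross_validated_accuracy(X, labels, a, folds=folds, seed=seed)
            if acc > best_acc + 1e-12:
                best_a, best_acc = a, acc
        A = best_a
        cv_acc = best_acc
    else:
        if not 1 <= A < min(n, J):
            raise ValueError(f"A must lie in [1, min(n, J)), got {A}")
        cv_acc = cross_validated_accuracy(X, labels, A, folds=folds, seed=seed)

    pls, means = _fit_raw(X, enc, C, A)
    return PlsdaModel(
        A=A,
        x_weights=pls.x_weights_,
        x_loadings=pls.x_loadings_,
        x_scores=pls.x_scores_,
        y_loadings=pls.y_loadings_,
        x_mean=X.mean(axis=0),
        classes=classes,
        class_score_means=means,
        vip=_vip(pls),
        cv_accuracy=cv_acc,
    )


def predict_plsda(model: PlsdaModel, data) -> np.ndarray:
    """Class labels by nearest class mean in score space."""
    X = _as_matrix(data) - model.x_mean
    scores = X @ model.x_weights @ np.linalg.pinv(model.x_loadings.T @ model.x_weights)
    d2 = ((scores[:, None, :] - model.class_score_means[None, :, :]) ** 2).sum(-1)
    return model.classes[d2.argmin(axis=1)]


def vip_map(model: PlsdaModel, mask_index: np.ndarray, frame: ConsensusFrame) -> np.ndarray:
    """Paint per-pixel VIP scores back into the consensus frame (background 0)."""
    if len(model.vip) != len(mask_index):
        raise ValueError(
            f"mask has {len(mask_index)} pixels but the model was fitted on {len(model.vip)}"
        )
    out = np.zeros((frame.rows, frame.cols))
    out[mask_index[:, 0], mask_index[:, 1]] = model.vip
    return out
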