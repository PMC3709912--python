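"""PCA + linear-SVM pattern classification with leave-one-out CV.

Subjects' normalized ReHo maps are flattened over a common voxel mask into
an N x D feature matrix (N subjects, D voxels, N << D).  Because the
centered training data span at most N-1 dimensions, projecting onto the
N-1 leading principal components is a lossless change of coordinates; a
soft-margin linear SVM (C = 1) is then trained in the reduced space.
Generalization is assessed by leave-one-out cross-validation in which PCA
and SVM are refit on each fold's training subjects only, so the held-out
subject never leaks into the model.

Labels: patient = +1, control = -1.  A decision value of exactly 0 is
classified as control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ConfigurationError, DegenerateInputError
from .reho import ReHoMap

__all__ = [
    "FeatureMatrix",
    "PCAModel",
    "SVMModel",
    "ConfusionCounts",
    "build_feature_matrix",
    "fit_pca",
    "train_svm",
    "loocv",
    "metrics",
]

PATIENT, CONTROL = 1, -1


@dataclass
class FeatureMatrix:
    """N x D matrix of normalized ReHo features on a common voxel mask."""

    X: np.ndarray  # (N, D)
    labels: np.ndarray  # (N,) in {+1, -1}
    voxel_index: np.ndarray  # (D, 3) grid coordinates of each column
    mask: np.ndarray  # 3D bool, the common computable mask

    def __post_init__(self):
        if self.X.shape[0] != self.labels.shape[0]:
            raise ConfigurationError("X rows and labels length differ")
        if self.X.shape[1] != self.voxel_index.shape[0]:
            raise ConfigurationError("X columns and voxel_index length differ")

    def to_map(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a D-vector back onto the 3D grid."""
        out = np.full(self.mask.shape, fill)
        out[tuple(self.voxel_index.T)] = values
        return out


@dataclass
class PCAModel:
    """Training mean and orthonormal D x d eigenvector matrix, d = N-1."""

    mean: np.ndarray  # (D,)
    U: np.ndarray  # (D, d), columns orthonormal

    @property
    def n_components(self) -> int:
        return self.U.shape[1]

    def project(self, X: np.ndarray) -> np.ndarray:
        """y = U^T (x - mean), rows of X projected to the reduced space."""
        return (np.atleast_2d(X) - self.mean) @ self.U

    def back_project(self, w_reduced: np.ndarray) -> np.ndarray:
        """Map a reduced-space vector back to voxel space: U w."""
        return self.U @ np.asarray(w_reduced)


@dataclass
class SVMModel:
    """Soft-margin linear SVM in the reduced space."""

    w: np.ndarray  # (d,)
    b: float
    alpha: np.ndarray  # (N,) dual coefficients, 0 <= alpha_i <= C
    C: float = 1.0
    meta: dict = field(default_factory=dict)

    def decision(self, Y: np.ndarray) -> np.ndarray:
        return np.atleast_2d(Y) @ self.w + self.b

    def predict(self, Y: np.ndarray) -> np.ndarray:
        # tie at exactly 0 -> control
        return np.where(self.decision(Y) > 0, PATIENT, CONTROL)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def build_feature_matrix(
    reho_maps: list[ReHoMap], labels
) -> FeatureMatrix:
    """Stack normalized ReHo maps over the intersection of computable masks."""
    labels = np.asarray(labels, dtype=int)
    if len(reho_maps) != len(labels):
        raise ConfigurationError("one label per ReHo map required")
    for lab in (PATIENT, CONTROL):
        if (labels == lab).sum() < 2:
            raise ConfigurationError("need at least 2 subjects per class")
    common = np.logical_and.reduce([m.computable_mask for m in reho_maps])
    if not common.any():
        raise ConfigurationError(
            "intersection of computable masks across subjects is empty"
        )
    voxel_index = np.argwhere(common)
    X = np.stack([m.normalized[common] for m in reho_maps])
    if np.isnan(X).any():
        raise DegenerateInputError("NaN feature values inside the common mask")
    return FeatureMatrix(X=X, labels=labels, voxel_index=voxel_index, mask=common)


def fit_pca(X_train: np.ndarray) -> PCAModel:
    """Nondestructive PCA: all d = N-1 components of the training rows.

    Computed from the thin SVD of the centered data, so U is exactly
    orthonormal and spans the full centered training subspace (any
    direction of zero variance contributes a zero singular value but is
    still a valid basis vector of the span's complement; retaining N-1
    columns keeps every nonzero-variance direction).
    """
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[0]
    if n < 2:
        raise ConfigurationError("PCA needs at least 2 training rows")
    mean = X_train.mean(axis=0)
    _, _, vt = np.linalg.svd(X_train - mean, full_matrices=False)
    return PCAModel(mean=mean, U=vt[: n - 1].T)


def train_svm(Y_train: np.ndarray, labels, C: float = 1.0) -> SVMModel:
    """Soft-margin linear SVM at box constraint C (default 1)."""
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ConfigurationError("both classes must be present to train the SVM")
    clf = SVC(kernel="linear", C=C, tol=1e-7)
    clf.fit(Y_train, labels)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    alpha = np.zeros(len(labels))
    # dual_coef_ holds alpha_i * y_i for support vectors
    alpha[clf.support_] = np.abs(clf.dual_coef_.ravel())
    return SVMModel(w=w, b=b, alpha=alpha, C=C)


def loocv(
    fm: FeatureMatrix, C: float = 1.0
) -> tuple[ConfusionCounts, np.ndarray, list[tuple[PCAModel, SVMModel]]]:
    """Leave-one-out cross-validation of the PCA + linear-SVM classifier.

    In each of the N folds, PCA (d = N-2 components) and the SVM are fit on
    the N-1 training subjects only; the held-out subject is projected with
    the fold's PCA and classified.  Returns aggregated confusion counts,
    the N held-out predictions, and the per-fold models.
    """
    X, labels = fm.X, fm.labels
    n = X.shape[0]
    if n < 4:
        raise ConfigurationError("LOOCV needs at least 4 subjects")
    preds = np.zeros(n, dtype=int)
    models = []
    for i in range(n):
        keep = np.arange(n) != i
        train_labels = labels[keep]
        if np.unique(train_labels).size < 2:
            raise ConfigurationError(
                f"training fold {i} lost one class entirely"
            )
        pca = fit_pca(X[keep])
        svm = train_svm(pca.project(X[keep]), train_labels, C=C)
        preds[i] = svm.predict(pca.project(X[i]))[0]
        models.append((pca, svm))
    tp = int(((preds == PATIENT) & (labels == PATIENT)).sum())
    tn = int(((preds == CONTROL) & (labels == CONTROL)).sum())
    fp = int(((preds == PATIENT) & (labels == CONTROL)).sum())
    fn = int(((preds == CONTROL) & (labels == PATIENT)).sum())
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn), preds, models


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Generalization rate, sensitivity and specificity, as percentages.

    GR = (TP + TN) / N, SS = TP / (TP + FN), SC = TN / (TN + FP).
    """
    if counts.n == 0:
        raise DegenerateInputError("no predictions to score")
    n_pat = counts.tp + counts.fn
    n_con = counts.tn + counts.fp
    if n_pat == 0 or n_con == 0:
        raise DegenerateInputError(
            "sensitivity/specificity undefined: a class has no members"
        )
    return {
        "GR": 100.0 * (counts.tp + counts.tn) / counts.n,
        "SS": 100.0 * counts.tp / n_pat,
        "SC": 100.0 * counts.tn / n_con,
    }
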