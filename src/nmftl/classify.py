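"""Large-margin classification on the augmented feature space.

Each sample x is extended with its shared-subspace coordinates, [x; Hx],
and a soft-margin linear SVM is trained on the augmented vectors using
labeled source data.  The learned (d+r)-dimensional weight vector splits
into w (original space) and v (subspace), so the decision function reads

    f(x) = w'x + v'(Hx) + b

Although [x; Hx] is a linear image of x (the hypothesis class is unchanged),
the L2 penalty on (w, v) prices directions inside the shared subspace more
cheaply, biasing the classifier toward domain-invariant structure — the
source of the transfer benefit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC

from .nmf import FitConfig, SharedSubspaceNMF, project_shared

__all__ = [
    "AugmentedLinearModel",
    "NMFTransferSVC",
    "augment_features",
    "train_augmented_classifier",
    "predict",
]


def augment_features(X: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Concatenate each row x with its subspace projection Hx.

    Returns an n x (d + r) matrix whose row i is ``[x_i ; H @ x_i]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    proj = project_shared(H, X)
    return np.hstack([X, proj])


@dataclass
class AugmentedLinearModel:
    """Linear decision rule over the augmented space.

    For binary problems there is a single (w, v, b) triple and the positive
    class is predicted iff ``w'x + v'Hx + b >= 0`` (ties go to the positive
    class).  Multiclass uses one-vs-rest with one triple per class and
    argmax over decision values.
    """

    w: np.ndarray  # (n_triples, d)
    v: np.ndarray  # (n_triples, r)
    b: np.ndarray  # (n_triples,)
    H_ref: np.ndarray  # (r, d)
    classes: np.ndarray  # ordered label set; binary: [negative, positive]

    def __post_init__(self) -> None:
        self.w = np.atleast_2d(np.asarray(self.w, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        self.H_ref = np.asarray(self.H_ref, dtype=float)
        self.classes = np.asarray(self.classes)
        r, d = self.H_ref.shape
        if self.w.shape[1] != d or self.v.shape[1] != r:
            raise ValueError("w/v lengths must match H_ref dimensions")
        n_binary = 1 if len(self.classes) == 2 else len(self.classes)
        if self.w.shape[0] != n_binary:
            raise ValueError(
                f"expected {n_binary} weight triple(s), got {self.w.shape[0]}"
            )

    @property
    def is_binary(self) -> bool:
        return len(self.classes) == 2

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.H_ref.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects "
                f"{self.H_ref.shape[1]}"
            )
        proj = project_shared(self.H_ref, X)
        scores = X @ self.w.T + proj @ self.v.T + self.b
        return scores[:, 0] if self.is_binary else scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        if self.is_binary:
            return np.where(scores >= 0, self.classes[1], self.classes[0])
        return self.classes[np.argmax(scores, axis=1)]


def train_augmented_classifier(
    Xs: np.ndarray,
    ys: np.ndarray,
    H: np.ndarray,
    C: float = 1.0,
    max_iter: int = 20000,
    random_state: int = 0,
) -> AugmentedLinearModel:
    """Train the augmented-space linear SVM on labeled source data.

    A soft-margin linear SVM (hinge loss, L2 regularization, cost ``C``) is
    fitted on ``augment_features(Xs, H)``; the learned weights split into
    the original-space and subspace parts.  Multiclass problems are handled
    one-vs-rest.
    """
    Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
    ys = np.asarray(ys)
    if np.any(~np.isfinite(Xs)):
        raise ValueError("Xs contains NaN or infinite entries")
    classes = np.unique(ys)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train a classifier")
    H = np.asarray(H, dtype=float)
    d = Xs.shape[1]
    r = H.shape[0]
    A = augment_features(Xs, H)
    svc = LinearSVC(
        C=C, loss="hinge", max_iter=max_iter, random_state=random_state
    )
    svc.fit(A, ys)
    coef = np.atleast_2d(svc.coef_)
    intercept = np.atleast_1d(svc.intercept_)
    return AugmentedLinearModel(
        w=coef[:, :d], v=coef[:, d:], b=intercept, H_ref=H, classes=classes
    )


def predict(
    model: AugmentedLinearModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels plus raw decision values for a trained model."""
    return model.predict(X), model.decision_function(X)


class NMFTransferSVC(ClassifierMixin, BaseEstimator):
    """End-to-end transfer classifier: joint subspace + augmented linear SVM.

    ``fit(X, y, X_target=...)`` first learns the shared non-negative basis
    from the labeled source matrix and the (unlabeled) target matrix, then
    trains the augmented-space SVM on source data only.  ``predict`` scores
    any matrix over the same feature space, typically the target domain.

    Parameters
    ----------
    r : int
        Shared-subspace dimension; capped at the feature count during fit.
    alpha_s : float
        Source weight in the joint factorization objective.
    C : float
        SVM margin-cost parameter.
    max_iter, eps : optimizer controls for the factorization.
    random_state : int
        Seeds both the factorization init and the SVM solver.

    Attributes
    ----------
    subspace_ : SharedSubspaceNMF
        The fitted joint factorization.
    model_ : AugmentedLinearModel
        The fitted decision rule (w, v, b, H).
    classes_ : ndarray
    """

    def __init__(
        self,
        r: int = 10,
        alpha_s: float = 0.5,
        C: float = 1.0,
        max_iter: int = 1000,
        eps: float = 1e-6,
        random_state: int = 0,
    ):
        self.r = r
        self.alpha_s = alpha_s
        self.C = C
        self.max_iter = max_iter
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y, *, X_target=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X_target is None:
            # degenerate but permitted: learn the basis from the source alone
            X_target = X
        r = min(self.r, X.shape[1])
        self.subspace_ = SharedSubspaceNMF(
            r=r,
            alpha_s=self.alpha_s,
            max_iter=self.max_iter,
            eps=self.eps,
            random_state=self.random_state,
        ).fit(X, X_target=X_target)
        self.model_ = train_augmented_classifier(
            X, y, self.subspace_.H_, C=self.C, random_state=self.random_state
        )
        self.classes_ = self.model_.classes
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        return self.model_.decision_function(X)

    def predict(self, X):
        return self.model_.predict(X)


def save_augmented_model(model: AugmentedLinearModel, directory: str | Path) -> None:
    """JSON manifest + delimited-text parameter files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "classes": [str(c) for c in model.classes],
        "shapes": {"w": list(model.w.shape), "v": list(model.v.shape)},
        "b": [float(x) for x in model.b],
    }
    (directory / "classifier.json").write_text(json.dumps(manifest, indent=2))
    np.savetxt(directory / "w.csv", model.w, delimiter=",", fmt="%.17g")
    np.savetxt(directory / "v.csv", model.v, delimiter=",", fmt="%.17g")
    np.savetxt(directory / "H.csv", model.H_ref, delimiter=",", fmt="%.17g")


def load_augmented_model(directory: str | Path) -> AugmentedLinearModel:
    directory = Path(directory)
    manifest = json.loads((directory / "classifier.json").read_text())
    return AugmentedLinearModel(
        w=np.loadtxt(directory / "w.csv", delimiter=",", ndmin=2),
        v=np.loadtxt(directory / "v.csv", delimiter=",", ndmin=2),
        b=np.array(manifest["b"]),
        H_ref=np.loadtxt(directory / "H.csv", delimiter=",", ndmin=2),
        classes=np.array(manifest["classes"]),
    )
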