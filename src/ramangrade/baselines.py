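"""Shallow comparison methods: PCA reduction, SVM (RBF), LDA and an MLP.

Each method runs either directly on the three-category task
(``three_class`` mode) or as a stage replacement inside the cascade
(``pipeline`` mode, handled by the cascade module through the same
fit/predict surface).  Settings follow the conventional choices for
spectral discrimination: LDA with the SVD solver (tolerance 1e-4, no
shrinkage); SVM with an RBF kernel, C = 1 and the 'scale' gamma heuristic
1 / (n_features * Var(X)); one-vs-one multi-class; PCA to 30 components
fit on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = ["BaselineSpec", "pca_fit_transform", "fit_predict_baseline"]

METHODS = ("pca_svm", "pca_lda", "lda", "ann", "cnn1d")


@dataclass(frozen=True)
class BaselineSpec:
    method: str = "pca_svm"
    mode: str = "three_class"
    pca_components: int = 30
    svm_c: float = 1.0
    lda_tol: float = 1e-4
    ann_hidden: tuple = (256, 64)
    ann_max_iter: int = 500
    seed: int = 0
    cnn_epochs: int = 30

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        if self.mode not in ("three_class", "pipeline"):
            raise ValueError("mode must be 'three_class' or 'pipeline'")


def pca_fit_transform(train_X, test_X, k: int = 30):
    """Fit PCA on the training matrix only and project both splits.

    Returns (reduced train, reduced test, explained-variance ratios);
    ratios are non-increasing and sum to <= 1.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    if k > min(train_X.shape):
        raise ValueError(
            f"k={k} exceeds min(n_samples, n_features) = {min(train_X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    red_train = pca.fit_transform(train_X)
    red_test = pca.transform(test_X)
    return red_train, red_test, pca.explained_variance_ratio_


def _majority(train_y):
    vals, counts = np.unique(train_y, return_counts=True)
    return vals[np.argmax(counts)]


def fit_predict_baseline(spec: BaselineSpec, train_X, train_y, test_X) -> np.ndarray:
    """Fit the named baseline on (train_X, train_y) and predict test_X.

    Degenerate training features (all columns constant) predict the
    majority class.  Deterministic under a fixed ``spec.seed``.
    """
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("need at least two classes to fit a baseline")
    if np.all(train_X.std(axis=0) == 0):
        return np.full(len(test_X), _majority(train_y))
    method = spec.method
    if method in ("pca_svm", "pca_lda"):
        k = min(spec.pca_components, min(train_X.shape))
        train_X, test_X, _ = pca_fit_transform(train_X, test_X, k)
    if method == "pca_svm":
        clf = SVC(kernel="rbf", C=spec.svm_c, gamma="scale",
                  decision_function_shape="ovo", random_state=spec.seed)
    elif method in ("pca_lda", "lda"):
        clf = LinearDiscriminantAnalysis(solver="svd", tol=spec.lda_tol,
                                         shrinkage=None)
    elif method == "ann":
        clf = MLPClassifier(hidden_layer_sizes=spec.ann_hidden, activation="relu",
                            solver="adam", max_iter=spec.ann_max_iter,
                            random_state=spec.seed)
    elif method == "cnn1d":
        return _cnn1d_baseline(spec, train_X, train_y, test_X)
    clf.fit(train_X, train_y)
    return clf.predict(test_X)


def _cnn1d_baseline(spec, train_X, train_y, test_X):
    """The stage-1 CNN architecture run as a direct multi-class baseline."""
    from . import nn
    from .cascade import weighted_sampler_weights
    from .stage1 import build_cnn1d

    classes = np.unique(train_y)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[c] for c in train_y])
    model = build_cnn1d(train_X.shape[1], seed=spec.seed, n_out=len(classes))
    rng = np.random.default_rng(spec.seed)
    probs = weighted_sampler_weights(y)
    probs = probs / probs.sum()
    opt = nn.Adam(model.parameters(), lr=1e-4, weight_decay=0.01)
    n = len(train_X)
    for _ in range(spec.cnn_epochs):
        for _ in range(max(1, n // 32)):
            idx = rng.choice(n, size=32, replace=True, p=probs)
            logits = model.forward(train_X[idx][:, None, :], training=True)
            _, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
    pred_idx = model.predict_proba(test_X).argmax(axis=1)
    return classes[pred_idx]
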