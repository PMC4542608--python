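"""Partial least squares discriminant analysis via the NIPALS recursion.

PLS-DA regresses spectra against one-hot class responses and classifies
by argmax of the predicted responses. Components are extracted with the
iterative NIPALS PLS2 algorithm: alternating weight/score/loading updates
until the X-score converges, then rank-one deflation of both blocks. The
X-score vectors are mutually orthogonal by construction, and the fitted
linear map is condensed into a coefficient matrix
``B = W (P'W)^(-1) Q`` so that prediction is a single matrix product.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """NIPALS PLS2 discriminant classifier.

    Parameters
    ----------
    n_components : int
        Number of latent variables to extract.
    max_iter, tol : NIPALS inner-loop controls (convergence of the
        X-score vector between iterations, relative L2).

    Attributes (after ``fit``)
    --------------------------
    classes_ : class labels in response-column order (sorted); argmax ties
        resolve to the earlier class.
    x_mean_, y_mean_ : centering vectors.
    x_weights_, x_loadings_ : (n_channels, A)
    y_loadings_ : (n_classes, A)
    x_scores_ : (n_samples, A), mutually orthogonal columns.
    coef_ : (n_channels, n_classes) regression coefficients on centered data.
    """

    def __init__(self, n_components: int = 3, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("PLS-DA needs at least two classes")
        n, p = X.shape
        a = self.n_components
        if a < 1:
            raise ValueError("n_components must be >= 1")
        if a > min(n - 1, p):
            raise ValueError(
                f"n_components={a} exceeds the rank bound min(n-1, p)={min(n - 1, p)}"
            )
        Y = (y[:, None] == self.classes_[None, :]).astype(float)

        self.n_features_in_ = p
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xr = X - self.x_mean_
        Yr = Y - self.y_mean_

        W = np.empty((p, a))
        P = np.empty((p, a))
        Q = np.empty((self.classes_.size, a))
        T = np.empty((n, a))
        n_extracted = 0
        for comp in range(a):
            if np.linalg.norm(Yr) < 1e-12 or np.linalg.norm(Xr) < 1e-12:
                break
            u = Yr[:, int(np.argmax(Yr.var(axis=0)))].copy()
            t_old = None
            for _ in range(self.max_iter):
                w = Xr.T @ u
                wn = np.linalg.norm(w)
                if wn < 1e-300:
                    break
                w /= wn
                t = Xr @ w
                tt = float(t @ t)
                if tt < 1e-300:
                    break
                q = Yr.T @ t / tt
                qq = float(q @ q)
                if qq < 1e-300:
                    break
                u = Yr @ q / qq
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * max(
                    np.linalg.norm(t), 1e-300
                ):
                    t_old = t
                    break
                t_old = t
            t = t_old if t_old is not None else Xr @ w
            tt = float(t @ t)
            if tt < 1e-300:
                break
            p_load = Xr.T @ t / tt
            q = Yr.T @ t / tt
            Xr = Xr - np.outer(t, p_load)
            Yr = Yr - np.outer(t, q)
            W[:, comp], P[:, comp], Q[:, comp], T[:, comp] = w, p_load, q, t
            n_extracted += 1

        if n_extracted == 0:
            raise ValueError("no PLS component could be extracted (degenerate data)")
        self.n_components_ = n_extracted
        self.x_weights_ = W[:, :n_extracted]
        self.x_loadings_ = P[:, :n_extracted]
        self.y_loadings_ = Q[:, :n_extracted]
        self.x_scores_ = T[:, :n_extracted]
        # B = W (P'W)^-1 Q'
        pw = self.x_loadings_.T @ self.x_weights_
        self.coef_ = self.x_weights_ @ np.linalg.solve(pw, self.y_loadings_.T)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Continuous one-hot response predictions, (n_samples, n_classes)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} channels; model was fit with "
                f"{self.n_features_in_}"
            )
        return (X - self.x_mean_) @ self.coef_ + self.y_mean_

    def predict(self, X) -> np.ndarray:
        """Hard labels by argmax; ties resolve to the earlier class in
        ``classes_`` order."""
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def positive_scores(self, X, positive_class) -> np.ndarray:
        """Continuous score of one class, for ROC thresholding in binary tasks."""
        j = int(np.flatnonzero(self.classes_ == positive_class)[0])
        return self.decision_function(X)[:, j]


def plsda_fit(X, labels, n_components: int = 3) -> PLSDAClassifier:
    return PLSDAClassifier(n_components).fit(X, labels)


def plsda_predict(model: PLSDAClassifier, X):
    """Hard labels plus the continuous per-class responses."""
    scores = model.decision_function(X)
    return model.classes_[np.argmax(scores, axis=1)], scores


def select_n_components_cv(
    X,
    y,
    candidates=range(1, 11),
    n_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> int:
    """Pick the latent-variable count by k-fold cross-validated accuracy.

    Folds are a random partition of the samples; ties in mean accuracy go
    to the smaller model. Candidates exceeding the fold-wise rank bound
    are skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng() if rng is None else rng
    n = X.shape[0]
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    best_a, best_acc = None, -1.0
    for a in candidates:
        accs = []
        ok = True
        for f in range(len(folds)):
            test = folds[f]
            train = np.concatenate([folds[g] for g in range(len(folds)) if g != f])
            if np.unique(y[train]).size < 2 or a > min(train.size - 1, X.shape[1]):
                ok = False
                break
            model = PLSDAClassifier(a).fit(X[train], y[train])
            accs.append(float(np.mean(model.predict(X[test]) == y[test])))
        if not ok:
            continue
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_a, best_acc = a, acc
    if best_a is None:
        raise ValueError("no candidate latent-variable count was feasible")
    return best_a
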