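"""Latent-variable exploration: PCA, PLS-DA and OPLS-DA with CV'd Q2."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PCAModel:
    mean_: np.ndarray
    loadings: np.ndarray        # (p, A), orthonormal columns
    scores: np.ndarray          # (n, A)
    eigenvalues: np.ndarray     # score variances, non-increasing
    explained_variance_ratio: np.ndarray
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) @ self.loadings

    def reconstruct(self, X) -> np.ndarray:
        return self.mean_ + self.transform(X) @ self.loadings.T


def pca_fit(X, n_components: int | None = None, center: bool = True) -> PCAModel:
    """Mean-centered SVD principal component analysis."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_a = min(n - 1 if center else n, p)
    A = max_a if n_components is None else int(n_components)
    if not 1 <= A <= max_a:
        raise ValueError(f"n_components must be in [1, {max_a}], got {A}")
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    denom = n - 1 if center else n
    eig = s**2 / denom
    total = float(eig.sum())
    return PCAModel(mean, Vt[:A].T, U[:, :A] * s[:A], eig[:A],
                    eig[:A] / total, total)


def _one_hot(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _pls2_nipals(Xc: np.ndarray, Yc: np.ndarray, A: int,
                 tol: float = 1e-12, max_iter: int = 500):
    """NIPALS PLS2; returns weights W, loadings P, Y-loadings Q, scores T."""
    X, Y = Xc.copy(), Yc.copy()
    p, m = X.shape[1], Y.shape[1]
    W, P = np.zeros((p, A)), np.zeros((p, A))
    Q, T = np.zeros((m, A)), np.zeros((X.shape[0], A))
    for a in range(A):
        u = Y[:, int(np.argmax((Y**2).sum(axis=0)))].copy()
        t_old = None
        for _ in range(max_iter):
            w = X.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("PLS component collapsed: no X-Y covariance left")
            w /= nw
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q) if (q @ q) > 0 else t
            if t_old is not None and np.linalg.norm(t - t_old) <= tol * np.linalg.norm(t):
                break
            t_old = t
        pl = X.T @ t / (t @ t)
        X -= np.outer(t, pl)
        Y -= np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pl, q, t
    return W, P, Q, T


def _pls_coef(W, P, Q) -> np.ndarray:
    return W @ np.linalg.solve(P.T @ W, Q.T)


def _osc_filter(Xc: np.ndarray, Yc: np.ndarray, n_orthogonal: int):
    """Remove Y-orthogonal structured variation; returns (Xf, Wo, Po)."""
    Xf = Xc.copy()
    p = Xc.shape[1]
    Wo, Po = np.zeros((p, n_orthogonal)), np.zeros((p, n_orthogonal))
    for a in range(n_orthogonal):
        # predictive weight direction: first singular direction of X'Y
        w = np.linalg.svd(Xf.T @ Yc, full_matrices=False)[0][:, 0]
        t = Xf @ w
        pl = Xf.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ValueError(f"no orthogonal variation left at component {a + 1}")
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf -= np.outer(t_o, p_o)
        Wo[:, a], Po[:, a] = w_o, p_o
    return Xf, Wo, Po


def _osc_apply(Xc: np.ndarray, Wo: np.ndarray, Po: np.ndarray) -> np.ndarray:
    X = Xc.copy()
    for a in range(Wo.shape[1]):
        t_o = X @ Wo[:, a]
        X -= np.outer(t_o, Po[:, a])
    return X


@dataclass
class DiscriminantModel:
    kind: str                 # "PLSDA" | "OPLSDA"
    classes_: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    coef_: np.ndarray
    n_components: int
    r2x: float
    r2y: float
    q2: float | None = None
    n_orthogonal: int = 0
    orth_weights: np.ndarray | None = field(default=None, repr=False)
    orth_loadings: np.ndarray | None = field(default=None, repr=False)

    def decision_values(self, X) -> np.ndarray:
        Xc = np.asarray(X, dtype=float) - self.x_mean
        if self.n_orthogonal:
            Xc = _osc_apply(Xc, self.orth_weights, self.orth_loadings)
        return self.y_mean + Xc @ self.coef_

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_values(X), axis=1)]


def _cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(order, folds)]


def _fit_core(X, Y, n_components: int, n_orthogonal: int):
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    Wo = Po = None
    Xf = Xc
    if n_orthogonal:
        Xf, Wo, Po = _osc_filter(Xc, Yc, n_orthogonal)
    W, P, Q, T = _pls2_nipals(Xf, Yc, n_components)
    coef = _pls_coef(W, P, Q)
    r2x = float(((T @ P.T) ** 2).sum() / (Xc**2).sum())
    r2y = float(1.0 - ((Yc - T @ Q.T) ** 2).sum() / (Yc**2).sum())
    return x_mean, y_mean, coef, Wo, Po, r2x, r2y


def _fit_discriminant(X, labels, kind: str, n_components: int,
                      n_orthogonal: int, cv_folds: int, seed: int) -> DiscriminantModel:
    X = np.asarray(X, dtype=float)
    Y, classes = _one_hot(labels)
    if classes.size < 2:
        raise ValueError(f"{kind} needs at least two classes")
    if n_orthogonal >= min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_orthogonal must be smaller than the rank of X")
    x_mean, y_mean, coef, Wo, Po, r2x, r2y = _fit_core(X, Y, n_components, n_orthogonal)
    model = DiscriminantModel(kind, classes, x_mean, y_mean, coef, n_components,
                              r2x, r2y, None, n_orthogonal, Wo, Po)

    press = 0.0
    ssy = ((Y - Y.mean(axis=0)) ** 2).sum()
    for fold in _cv_folds(X.shape[0], cv_folds, seed):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[fold] = False
        try:
            xm, ym, cf, Wof, Pof, _, _ = _fit_core(X[mask], Y[mask],
                                                   n_components, n_orthogonal)
        except ValueError:
            press += ((Y[fold] - Y[mask].mean(axis=0)) ** 2).sum()
            continue
        Xt = X[fold] - xm
        if n_orthogonal:
            Xt = _osc_apply(Xt, Wof, Pof)
        press += ((Y[fold] - (ym + Xt @ cf)) ** 2).sum()
    model.q2 = float(1.0 - press / ssy)
    return model


def plsda_fit(X, labels, n_components: int, cv_folds: int = 7,
              seed: int = 0) -> DiscriminantModel:
    """PLS2 discriminant analysis on one-hot labels with K-fold Q2."""
    return _fit_discriminant(X, labels, "PLSDA", n_components, 0, cv_folds, seed)


def oplsda_fit(X, labels, n_orthogonal: int, n_components: int = 1,
               cv_folds: int = 7, seed: int = 0) -> DiscriminantModel:
    """Orthogonal-signal-corrected PLS-DA.

    Repeatedly removes structured variation in X that is orthogonal to
    the class indicators, then fits the predictive component(s) on the
    filtered matrix.  With ``n_orthogonal=0`` it coincides with PLS-DA.
    """
    return _fit_discriminant(X, labels, "OPLSDA", n_components, n_orthogonal,
                             cv_folds, seed)
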