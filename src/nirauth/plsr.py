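"""PLS1 regression of adulterant fraction on spectra, latent-variable
selection by 10-fold RMSECV, and the preprocessing screening harness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import preprocess, sampling
from .synthetic import GENUINE_CLASS, SpectraSet


@dataclass
class PLSRModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # W (p, A)
    x_loadings: np.ndarray  # P (p, A)
    y_loadings: np.ndarray  # q (A,)
    coef_: np.ndarray      # regression vector b
    n_lv: int

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean + (X - self.x_mean) @ self.coef_

    def to_dict(self) -> dict:
        return {"x_mean": self.x_mean.tolist(), "y_mean": self.y_mean,
                "coef": self.coef_.tolist(), "n_lv": self.n_lv}


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    X, y = Xc.copy(), yc.copy()
    p = X.shape[1]
    W, P = np.zeros((p, n_lv)), np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"PLS1 collapsed at component {a + 1}: "
                             "no covariance left")
        w /= norm
        t = X @ w
        tt = float(t @ t)
        P[:, a] = X.T @ t / tt
        q[a] = float(y @ t) / tt
        X -= np.outer(t, P[:, a])
        y = y - q[a] * t
        W[:, a] = w
    return W, P, q


def _coefs_per_lv(W, P, q) -> list[np.ndarray]:
    """Regression vector b for every truncation 1..A (for cheap RMSECV)."""
    A = W.shape[1]
    return [W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            for a in range(1, A + 1)]


def pls1_fit(X, y, n_lv: int) -> PLSRModel:
    """Mean-centered NIPALS PLS1 with ``b = W (P'W)^-1 q``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X")
    if np.ptp(y) == 0:
        raise ValueError("y is constant: nothing to regress")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv must be in [1, {min(n - 1, p)}], got {n_lv}")
    x_mean, y_mean = X.mean(axis=0), float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_lv)
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSRModel(x_mean, y_mean, W, P, q, b, n_lv)


def select_lv(X, y, max_lv: int = 12, folds: int = 10,
              seed: int = 0) -> tuple[int, np.ndarray]:
    """Latent-variable count minimizing 10-fold RMSECV (ties: fewest)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if folds > n:
        raise ValueError(f"{folds} folds but only {n} samples")
    max_lv = min(max_lv, n - 1 - int(np.ceil(n / folds)), X.shape[1])
    if max_lv < 1:
        raise ValueError("too few samples for even one latent variable")
    sse = np.zeros(max_lv)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in kf.split(X):
        xm, ym = X[train].mean(axis=0), y[train].mean()
        W, P, q = _nipals_pls1(X[train] - xm, y[train] - ym, max_lv)
        Xt = X[test] - xm
        for a, b in enumerate(_coefs_per_lv(W, P, q)):
            sse[a] += ((y[test] - (ym + Xt @ b)) ** 2).sum()
    rmsecv = np.sqrt(sse / n)
    return int(np.argmin(rmsecv)) + 1, rmsecv


@dataclass(frozen=True)
class RegressionMetrics:
    rmse: float
    r2: float
    mae: float
    rpd: float
    n: int


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """RMSE, R2 (about the evaluated set's own mean), MAE and RPD."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between reference and prediction")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least two samples for regression metrics")
    if np.ptp(y_true) == 0:
        raise ValueError("constant reference values: R2 and RPD undefined")
    err = y_true - y_pred
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = float(1.0 - (err**2).sum() / sst)
    sd = float(y_true.std(ddof=1))
    rpd = float(np.inf) if rmse == 0 else sd / rmse
    return RegressionMetrics(rmse, r2, mae, rpd, n)


REQUIRED_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def screen(dataset: SpectraSet, adulterant: str, window: int = 15,
           polyorder: int = 2, max_lv: int = 12, folds: int = 10,
           seed: int = 0, required_fractions=REQUIRED_FRACTIONS) -> pd.DataFrame:
    """Run every registry pipeline on one genuine-adulterant mixture series.

    The 7:3 Kennard-Stone split is computed once on the raw series; each
    pipeline is then fitted on the calibration rows only, the LV count
    picked by RMSECV, and calibration/prediction metrics reported.  The
    best row (highest prediction R2, RMSEP tie-break) is flagged.
    """
    series = dataset.pair_series(adulterant)
    present = set(np.round(np.unique(series.fraction), 6))
    missing = [f for f in required_fractions if round(f, 6) not in present]
    if missing:
        raise ValueError(f"series {GENUINE_CLASS}-{adulterant} lacks "
                         f"fraction levels {missing}")
    X_raw, y = series.absorbance, series.fraction
    split = sampling.split_73(X_raw)
    cal, pred = split.train_idx, split.test_idx
    delta = series.grid.step

    rows = []
    for name, pipe in preprocess.registry(window, polyorder).items():
        Xc_t, (Xp_t,) = preprocess.apply_pipeline(pipe, X_raw[cal],
                                                  [X_raw[pred]], delta=delta)
        n_lv, _ = select_lv(Xc_t, y[cal], max_lv=max_lv, folds=folds, seed=seed)
        model = pls1_fit(Xc_t, y[cal], n_lv)
        m_cal = regression_metrics(y[cal], model.predict(Xc_t))
        m_pred = regression_metrics(y[pred], model.predict(Xp_t))
        rows.append({"pair": f"{GENUINE_CLASS}-{adulterant}", "pipeline": name,
                     "n_lv": n_lv,
                     "rmse_pred": m_pred.rmse, "r2_pred": m_pred.r2,
                     "mae_pred": m_pred.mae, "rpd_pred": m_pred.rpd,
                     "rmse_cal": m_cal.rmse, "r2_cal": m_cal.r2,
                     "mae_cal": m_cal.mae, "rpd_cal": m_cal.rpd})
    grid = pd.DataFrame(rows)
    order = grid.sort_values(["r2_pred", "rmse_pred"],
                             ascending=[False, True], kind="mergesort")
    grid["best"] = False
    grid.loc[order.index[0], "best"] = True
    return grid
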