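"""Data-driven SIMCA one-class classification.

A PCA model is fitted on genuine spectra only.  For each sample the
score distance ``h = sum_a t_a^2 / lambda_a`` and orthogonal distance
``v = ||x - x_hat||^2`` are combined into a total distance

    c = N_h * h / h0 + N_v * v / v0

whose null distribution is approximately chi-squared with N_h + N_v
degrees of freedom; h0, v0 and the integer DoF are estimated from the
calibration distances by the method of moments.  A sample is accepted
as genuine when c does not exceed the chi-squared quantile at 1 - alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .latent import PCAModel, pca_fit

DOF_MAX = 250


def distances(pca: PCAModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Score distance h and orthogonal distance v for each row of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != pca.mean_.shape[0]:
        raise ValueError(f"grid mismatch: model has {pca.mean_.shape[0]} "
                         f"points, spectra have {X.shape[1]}")
    if np.any(pca.eigenvalues <= 0):
        raise ValueError("zero eigenvalue among retained components")
    T = pca.transform(X)
    h = (T**2 / pca.eigenvalues).sum(axis=1)
    resid = (X - pca.mean_) - T @ pca.loadings.T
    v = (resid**2).sum(axis=1)
    return h, v


def estimate_dof(d) -> tuple[float, int]:
    """Moment estimate (d0, N) of a scaled chi-squared distance sample."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance sample")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    d0 = float(d.mean())
    if d0 == 0:
        raise ValueError("all distances are zero: degenerate class model")
    var = float(d.var(ddof=1)) if d.size > 1 else 0.0
    if var == 0:
        return d0, DOF_MAX
    n = int(round(2.0 * d0 * d0 / var))
    return d0, int(np.clip(n, 1, DOF_MAX))


@dataclass
class DDSimcaModel:
    pca: PCAModel
    n_pc: int
    h0: float
    v0: float
    dof_h: int
    dof_v: int
    alpha: float
    gamma: float
    c_crit: float
    c_out: float
    n_train: int

    def total_distance(self, X) -> np.ndarray:
        h, v = distances(self.pca, X)
        return self.dof_h * h / self.h0 + self.dof_v * v / self.v0

    def to_dict(self) -> dict:
        return {
            "n_pc": self.n_pc, "h0": self.h0, "v0": self.v0,
            "dof_h": self.dof_h, "dof_v": self.dof_v,
            "alpha": self.alpha, "gamma": self.gamma,
            "c_crit": self.c_crit, "c_out": self.c_out,
            "n_train": self.n_train,
            "mean": self.pca.mean_.tolist(),
            "loadings": self.pca.loadings.tolist(),
            "eigenvalues": self.pca.eigenvalues.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DDSimcaModel":
        eig = np.asarray(d["eigenvalues"], dtype=float)
        pca = PCAModel(np.asarray(d["mean"], dtype=float),
                       np.asarray(d["loadings"], dtype=float),
                       np.zeros((0, len(eig))), eig,
                       eig / eig.sum(), float(eig.sum()))
        return cls(pca, d["n_pc"], d["h0"], d["v0"], d["dof_h"], d["dof_v"],
                   d["alpha"], d["gamma"], d["c_crit"], d["c_out"], d["n_train"])


def fit(genuine_train, n_pc: int, alpha: float = 0.01, gamma: float = 0.01,
        labels=None) -> DDSimcaModel:
    """Fit the one-class model on genuine calibration spectra only.

    ``labels`` (optional) is checked against the one-class contract: any
    non-genuine entry is an error.
    """
    X = np.asarray(genuine_train, dtype=float)
    if labels is not None and len(np.unique(np.asarray(labels))) > 1:
        raise ValueError("one-class contract violated: training labels "
                         f"contain {list(np.unique(np.asarray(labels)))}")
    n = X.shape[0]
    if not 1 <= n_pc < n:
        raise ValueError(f"n_pc must be in [1, {n - 1}], got {n_pc}")
    if not 0 < alpha < 1 or not 0 < gamma < 1:
        raise ValueError("alpha and gamma must lie in (0, 1)")
    pca = pca_fit(X, n_pc)
    h, v = distances(pca, X)
    h0, dof_h = estimate_dof(h)
    v0, dof_v = estimate_dof(v)
    dof = dof_h + dof_v
    c_crit = float(chi2.ppf(1.0 - alpha, dof))
    c_out = float(chi2.ppf((1.0 - gamma) ** (1.0 / n), dof))
    return DDSimcaModel(pca, n_pc, h0, v0, dof_h, dof_v, alpha, gamma,
                        c_crit, max(c_out, c_crit), n)


def predict(model: DDSimcaModel, X) -> pd.DataFrame:
    """Per-sample distances, acceptance-plot coordinates and verdicts."""
    h, v = distances(model.pca, X)
    c = model.dof_h * h / model.h0 + model.dof_v * v / model.v0
    verdict = np.where(c <= model.c_crit, "genuine",
                       np.where(c > model.c_out, "outlier", "adulterated"))
    return pd.DataFrame({
        "h": h, "v": v, "c": c,
        "log1p_h": np.log1p(h / model.h0),
        "log1p_v": np.log1p(v / model.v0),
        "verdict": verdict,
    })


@dataclass(frozen=True)
class OneClassReport:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fn + self.tn + self.fp)


def evaluate(decisions: pd.DataFrame, is_genuine) -> OneClassReport:
    """Confusion counts with genuine as the positive class."""
    is_genuine = np.asarray(is_genuine, dtype=bool)
    if is_genuine.size == 0:
        raise ValueError("empty evaluation set")
    if is_genuine.size != len(decisions):
        raise ValueError("labels and decisions differ in length")
    accepted = decisions["verdict"].to_numpy() == "genuine"
    return OneClassReport(
        tp=int(np.sum(accepted & is_genuine)),
        fn=int(np.sum(~accepted & is_genuine)),
        tn=int(np.sum(~accepted & ~is_genuine)),
        fp=int(np.sum(accepted & ~is_genuine)),
    )


def select_n_pc(genuine_train, X_val, val_is_genuine, candidates=range(1, 11),
                alpha: float = 0.01, gamma: float = 0.01) -> tuple[int, pd.DataFrame]:
    """Pick n_pc maximizing validation balanced accuracy (ties: smallest).

    Returns the winner and the per-candidate metric table.  The test set
    is never seen here by construction.
    """
    val_is_genuine = np.asarray(val_is_genuine, dtype=bool)
    if val_is_genuine.all() or not val_is_genuine.any():
        raise ValueError("validation set must contain both genuine and "
                         "adulterated samples")
    rows = []
    for n_pc in candidates:
        model = fit(genuine_train, n_pc, alpha, gamma)
        report = evaluate(predict(model, X_val), val_is_genuine)
        rows.append({"n_pc": int(n_pc), "sensitivity": report.sensitivity,
                     "specificity": report.specificity,
                     "balanced_accuracy": 0.5 * (report.sensitivity
                                                 + report.specificity)})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["balanced_accuracy"].idxmax(), "n_pc"])
    return best, table
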