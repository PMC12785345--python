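"""Spectral preprocessing operators and the named pipeline registry.

Conventions
-----------
* Spectra are rows of a 2-D array.
* ``delta`` is the signed physical step between adjacent columns
  (negative for a descending wavenumber grid); derivatives are returned
  per physical unit (AU per cm^-1, AU per cm^-2).
* Scatter correction (SNV/MSC) is applied before differentiation; a
  "+ SG" derivative is a fused Savitzky-Golay derivative filter, a bare
  derivative uses finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter


def _as_matrix(spectra) -> np.ndarray:
    X = np.asarray(spectra, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("spectra must be a vector or a 2-D matrix")
    return X


def snv(spectra) -> np.ndarray:
    """Standard normal variate: per-row centering and unit (n-1) scaling."""
    X = _as_matrix(spectra)
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum (row {bad[0]})")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def msc_fit(calibration) -> np.ndarray:
    """Reference spectrum for MSC: the column mean of the calibration set."""
    X = _as_matrix(calibration)
    if X.shape[0] == 0:
        raise ValueError("MSC reference requires a non-empty calibration set")
    return X.mean(axis=0)


def msc_apply(spectra, reference) -> np.ndarray:
    """Regress each row on the reference (x ~ a + b*ref) and invert."""
    X = _as_matrix(spectra)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("MSC reference length does not match spectra")
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    if denom == 0:
        raise ValueError("MSC reference is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
    small = np.flatnonzero(np.abs(b) < 1e-12)
    if small.size:
        raise ValueError(f"degenerate MSC scatter fit (|b| < 1e-12) in row {small[0]}")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None]


def savgol(spectra, window: int, polyorder: int, deriv: int = 0,
           delta: float = 1.0) -> np.ndarray:
    """Savitzky-Golay smoothing / differentiation (polynomial-fit edges)."""
    X = _as_matrix(spectra)
    if window % 2 == 0:
        raise ValueError(f"SG window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"SG window {window} must exceed polyorder {polyorder}")
    if window > X.shape[1]:
        raise ValueError(f"SG window {window} exceeds {X.shape[1]} points")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    out = savgol_filter(X, window, polyorder, deriv=deriv, delta=abs(delta),
                        axis=1, mode="interp")
    if delta < 0 and deriv % 2 == 1:
        out = -out
    return out


def derivative(spectra, order: int, delta: float = 1.0) -> np.ndarray:
    """Finite-difference derivative (central interior, one-sided edges)."""
    X = _as_matrix(spectra)
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if X.shape[1] < order + 1:
        raise ValueError(f"need at least {order + 1} points for order {order}")
    out = X
    for _ in range(order):
        out = np.gradient(out, delta, axis=1, edge_order=2 if out.shape[1] > 2 else 1)
    return out


@dataclass(frozen=True)
class PreprocessingStep:
    kind: str  # SNV | MSC | SG_SMOOTH | DERIV1 | DERIV2 | SG_DERIV1 | SG_DERIV2
    window: int = 15
    polyorder: int = 2

    def __post_init__(self) -> None:
        allowed = {"SNV", "MSC", "SG_SMOOTH", "DERIV1", "DERIV2",
                   "SG_DERIV1", "SG_DERIV2"}
        if self.kind not in allowed:
            raise ValueError(f"unknown step kind {self.kind!r}")


@dataclass
class PreprocessingPipeline:
    """Ordered preprocessing steps with train/test hygiene for MSC.

    ``fit`` learns the MSC reference from the calibration matrix only;
    ``transform`` then applies the frozen state to any matrix.
    """

    name: str
    steps: tuple = ()
    reference_: np.ndarray | None = field(default=None, repr=False)
    delta_: float = 1.0

    @property
    def needs_fit(self) -> bool:
        return any(s.kind == "MSC" for s in self.steps)

    def fit(self, calibration, delta: float = 1.0) -> "PreprocessingPipeline":
        self.delta_ = float(delta)
        X = _as_matrix(calibration)
        for step in self.steps:
            if step.kind == "MSC":
                self.reference_ = msc_fit(X)
            X = self._apply_step(step, X)
        return self

    def transform(self, spectra) -> np.ndarray:
        if self.needs_fit and self.reference_ is None:
            raise RuntimeError(
                f"pipeline {self.name!r} contains MSC and must be fitted "
                "on calibration data before transform")
        X = _as_matrix(spectra)
        for step in self.steps:
            X = self._apply_step(step, X)
        return X

    def fit_transform(self, calibration, delta: float = 1.0) -> np.ndarray:
        self.fit(calibration, delta=delta)
        return self.transform(calibration)

    def _apply_step(self, step: PreprocessingStep, X: np.ndarray) -> np.ndarray:
        if step.kind == "SNV":
            return snv(X)
        if step.kind == "MSC":
            return msc_apply(X, self.reference_)
        if step.kind == "SG_SMOOTH":
            return savgol(X, step.window, step.polyorder, 0, self.delta_)
        if step.kind == "SG_DERIV1":
            return savgol(X, step.window, step.polyorder, 1, self.delta_)
        if step.kind == "SG_DERIV2":
            return savgol(X, step.window, step.polyorder, 2, self.delta_)
        if step.kind == "DERIV1":
            return derivative(X, 1, self.delta_)
        if step.kind == "DERIV2":
            return derivative(X, 2, self.delta_)
        raise AssertionError(step.kind)


def apply_pipeline(pipeline: PreprocessingPipeline, calibration,
                   others=(), delta: float = 1.0):
    """Fit on calibration only, then transform calibration and the others."""
    cal_t = pipeline.fit_transform(calibration, delta=delta)
    return cal_t, [pipeline.transform(X) for X in others]


#: Row labels of the screening table, in presentation order.
REGISTRY_NAMES = (
    "RAW",
    "1st Der + SG", "1st Der",
    "2nd Der + SG", "2nd Der",
    "MSC + 1st Der + SG", "MSC + 1st Der",
    "MSC + 2nd Der + SG", "MSC + 2nd Der",
    "MSC",
    "SNV + 1st Der + SG", "SNV + 1st Der",
    "SNV + 2nd Der + SG", "SNV + 2nd Der",
    "SNV",
)


def _steps_for(name: str, window: int, polyorder: int) -> tuple:
    sg = dict(window=window, polyorder=polyorder)
    steps: list[PreprocessingStep] = []
    if name.startswith("SNV"):
        steps.append(PreprocessingStep("SNV"))
    elif name.startswith("MSC"):
        steps.append(PreprocessingStep("MSC"))
    if "1st Der" in name:
        steps.append(PreprocessingStep("SG_DERIV1" if "+ SG" in name else "DERIV1", **sg))
    elif "2nd Der" in name:
        steps.append(PreprocessingStep("SG_DERIV2" if "+ SG" in name else "DERIV2", **sg))
    return tuple(steps)


def registry(window: int = 15, polyorder: int = 2) -> dict:
    """Fresh instances of the 15 named screening pipelines."""
    return {name: PreprocessingPipeline(name, _steps_for(name, window, polyorder))
            for name in REGISTRY_NAMES}


def get_pipeline(name: str, window: int = 15, polyorder: int = 2) -> PreprocessingPipeline:
    """Pipeline by name; also accepts the standalone "SG" smoother."""
    if name == "SG":
        return PreprocessingPipeline(
            "SG", (PreprocessingStep("SG_SMOOTH", window, polyorder),))
    if name not in REGISTRY_NAMES:
        raise KeyError(f"unknown pipeline {name!r}; choose from "
                       f"{('SG',) + REGISTRY_NAMES}")
    return PreprocessingPipeline(name, _steps_for(name, window, polyorder))
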