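"""Synthetic NIR-like spectral datasets.

Generates absorbance matrices (log(1/R) units on a descending wavenumber
grid) for one genuine class and five adulterants, with binary mixtures at
fixed mass fractions, batch-to-batch amplitude variation, multiplicative
scatter, linear baseline drift, and additive noise.  All randomness flows
from a single root seed through ``numpy.random.SeedSequence`` children
(spawn keys: 0 = endmember construction, 1 = batch jitter, 2 = sample
assembly), so datasets are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENUINE_CLASS = "DKM"
ADULTERANT_CLASSES = ("DL", "DH", "DKML", "bamboo", "corn")
ALL_CLASSES = (GENUINE_CLASS,) + ADULTERANT_CLASSES

# Broad quasi-flat absorbance background shared by every class; its gain
# fluctuation dominates raw-spectrum variance the way scatter does in real
# diffuse-reflectance NIR.
_BACKGROUND_BAND = (7000.0, 9000.0, 12.0)

# Canonical overtone/combination band regions shared by all classes
# (center cm^-1, width cm^-1, base amplitude AU).
_CANONICAL_BANDS = (
    (6850.0, 130.0, 0.30),
    (5600.0, 70.0, 0.25),
    (5150.0, 45.0, 0.35),
    (4700.0, 60.0, 0.32),
)

# Per-class intensity factor applied to the canonical bands.  The
# Dendrobium congeners differ from the genuine class only moderately.
_CLASS_FACTORS = {
    "DKM": 1.00,
    "DL": 0.88,
    "DH": 1.12,
    "DKML": 0.92,
    "bamboo": 1.06,
    "corn": 0.95,
}

# Marker bands absent from the genuine class.  The congeners share one
# moderate marker region (differing in intensity) plus a small species-
# specific band — mimicking closely related chemistry — while the
# botanically unrelated adulterants carry two strong bands each.
_UNIQUE_BANDS = {
    "DKM": (),
    "DL": ((6250.0, 50.0, 0.80), (5900.0, 45.0, 0.12)),
    "DH": ((6250.0, 50.0, 0.70), (7600.0, 55.0, 0.12)),
    "DKML": ((6250.0, 50.0, 0.75), (6450.0, 50.0, 0.12)),
    "bamboo": ((8300.0, 80.0, 2.0), (4420.0, 70.0, 1.8)),
    "corn": ((9150.0, 90.0, 1.9), (4250.0, 75.0, 2.0)),
}

_DENDROBIUM_GROUP = frozenset({"DKM", "DL", "DH", "DKML"})


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly decreasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        d = np.diff(v)
        if not np.all(d < 0):
            raise ValueError("wavenumber grid must be strictly decreasing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-8):
            raise ValueError("wavenumber grid must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, high: float = 10_000.0, low: float = 4_000.0,
                n_points: int = 1557) -> "WavenumberGrid":
        return cls(np.linspace(high, low, n_points))

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def step(self) -> float:
        """Signed column-to-column step (negative for a descending grid)."""
        return float(self.values[1] - self.values[0])

    @property
    def spacing(self) -> float:
        return abs(self.step)

    def normalized(self) -> np.ndarray:
        """Grid rescaled to [0, 1] (used for baseline drift)."""
        v = self.values
        return (v - v.min()) / (v.max() - v.min())


@dataclass(frozen=True)
class EndmemberSpec:
    """Gaussian-band description of one pure-class spectrum."""

    class_name: str
    bands: tuple  # of (center, width, amplitude)
    similarity_group: str

    def __post_init__(self) -> None:
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError(f"{self.class_name}: band width must be > 0")
            if a < 0:
                raise ValueError(f"{self.class_name}: band amplitude must be >= 0")


def make_endmembers(seed: int) -> list[EndmemberSpec]:
    """Construct the six pure-class endmember specs.

    The band table is a fixed design; the seed adds small deterministic
    perturbations to class factors and unique-band centers so that
    different seeds give distinct (but equally separable) worlds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    # marker regions shared between classes must shift together, so center
    # perturbations are drawn once per distinct center
    shifts: dict[float, float] = {}
    specs = []
    for name in ALL_CLASSES:
        factor = _CLASS_FACTORS[name] + rng.uniform(-0.02, 0.02)
        bands = [_BACKGROUND_BAND]
        for c, w, a in _CANONICAL_BANDS:
            wiggle = rng.uniform(0.98, 1.02)
            bands.append((c, w, a * factor * wiggle))
        for c, w, a in _UNIQUE_BANDS[name]:
            if c not in shifts:
                shifts[c] = rng.uniform(-15.0, 15.0)
            bands.append((c + shifts[c], w, a))
        group = "dendrobium" if name in _DENDROBIUM_GROUP else "non-dendrobium"
        specs.append(EndmemberSpec(name, tuple(bands), group))
    return specs


def evaluate_endmember(spec: EndmemberSpec, grid: WavenumberGrid) -> np.ndarray:
    """Sum-of-Gaussians pure spectrum of ``spec`` on ``grid``."""
    if not spec.bands:
        raise ValueError(f"endmember {spec.class_name!r} has no bands")
    nu = grid.values
    out = np.zeros_like(nu)
    for c, w, a in spec.bands:
        out += a * np.exp(-((nu - c) ** 2) / (2.0 * w * w))
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset (defaults give 275 samples)."""

    seed: int = 42
    n_genuine_batches: int = 10
    genuine_replicates: int = 5
    mixture_replicates: int = 10
    pure_replicates: int = 5
    adulteration_fractions: tuple = (0.2, 0.4, 0.6, 0.8)
    noise_sd: float = 0.002
    scatter_sd: float = 0.05
    baseline_offset_range: tuple = (-0.02, 0.02)
    baseline_slope_range: tuple = (-0.05, 0.05)
    batch_jitter_sd: float = 0.03
    grid: WavenumberGrid = field(default_factory=WavenumberGrid.default)

    def __post_init__(self) -> None:
        for f in self.adulteration_fractions:
            if not 0.0 < f < 1.0:
                raise ValueError(f"adulteration fraction {f} outside (0, 1)")
        if self.n_genuine_batches < 1:
            raise ValueError("need at least one genuine batch")

    @property
    def n_samples(self) -> int:
        n_ad = len(ADULTERANT_CLASSES)
        return (self.n_genuine_batches * self.genuine_replicates
                + n_ad * len(self.adulteration_fractions) * self.mixture_replicates
                + n_ad * self.pure_replicates)

    def noiseless(self) -> "SimulationConfig":
        """Copy with every stochastic distortion switched off."""
        return replace(self, noise_sd=0.0, scatter_sd=0.0,
                       baseline_offset_range=(0.0, 0.0),
                       baseline_slope_range=(0.0, 0.0), batch_jitter_sd=0.0)


@dataclass
class SpectraSet:
    """Samples x wavenumbers absorbance matrix with per-sample metadata.

    ``label`` is the adulterant identity (the genuine class name for
    unadulterated samples); ``fraction`` is the adulterant mass fraction
    (0 genuine, 1 pure adulterant); ``batch`` an integer batch id.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    label: np.ndarray
    fraction: np.ndarray
    batch: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.label = np.asarray(self.label, dtype=object)
        self.fraction = np.asarray(self.fraction, dtype=float)
        self.batch = np.asarray(self.batch, dtype=int)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        n = self.absorbance.shape[0]
        if self.absorbance.ndim != 2 or self.absorbance.shape[1] != self.grid.n_points:
            raise ValueError("absorbance shape does not match grid")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        for name, arr in (("label", self.label), ("fraction", self.fraction),
                          ("batch", self.batch), ("sample_id", self.sample_id)):
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != {n} samples")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(self.absorbance.shape[0])

    @property
    def is_genuine(self) -> np.ndarray:
        return self.fraction == 0.0

    @property
    def is_pure(self) -> np.ndarray:
        return (self.fraction == 0.0) | (self.fraction == 1.0)

    def subset(self, idx) -> "SpectraSet":
        idx = np.asarray(idx)
        return SpectraSet(self.grid, self.absorbance[idx], self.label[idx],
                          self.fraction[idx], self.batch[idx], self.sample_id[idx])

    def pair_series(self, adulterant: str) -> "SpectraSet":
        """Genuine + all samples containing the given single adulterant."""
        if adulterant not in ADULTERANT_CLASSES:
            raise ValueError(f"unknown adulterant {adulterant!r}")
        mask = (self.label == GENUINE_CLASS) | (self.label == adulterant)
        return self.subset(np.flatnonzero(mask))


def generate(config: SimulationConfig) -> SpectraSet:
    """Simulate a full dataset under ``config``.

    Per sample: ``clean = (1-f) * dkm_batch + f * adulterant`` and
    ``observed = gain * clean + a0 + a1 * nu_tilde + eps`` with
    ``gain = exp(N(0, scatter_sd^2))``, uniform baseline coefficients, and
    iid Gaussian noise.
    """
    grid = config.grid
    specs = {s.class_name: s for s in make_endmembers(config.seed)}
    pure = {name: evaluate_endmember(spec, grid) for name, spec in specs.items()}

    # Batch-level amplitude jitter: one relative intensity factor per
    # genuine batch, applied to the canonical bands (the broad background
    # is a shared instrument response and is left alone).
    rng_batch = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1,)))
    dkm_bands = np.array(specs[GENUINE_CLASS].bands)  # (n_bands, 3)
    n_batches = config.n_genuine_batches
    jitter = rng_batch.normal(1.0, config.batch_jitter_sd, size=n_batches)
    nu = grid.values
    shapes = np.stack([np.exp(-((nu - c) ** 2) / (2.0 * w * w))
                       for c, w, _a in dkm_bands])  # (n_bands, p)
    background = dkm_bands[0, 2] * shapes[0]
    canonical = dkm_bands[1:, 2] @ shapes[1:]
    dkm_by_batch = background[None, :] + jitter[:, None] * canonical[None, :]

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    rows, labels, fractions, batches, ids = [], [], [], [], []

    def emit(clean: np.ndarray, label: str, f: float, batch: int, sid: str) -> None:
        gain = np.exp(rng.normal(0.0, config.scatter_sd)) if config.scatter_sd > 0 else 1.0
        a0 = rng.uniform(*config.baseline_offset_range)
        a1 = rng.uniform(*config.baseline_slope_range)
        eps = (rng.normal(0.0, config.noise_sd, size=grid.n_points)
               if config.noise_sd > 0 else 0.0)
        rows.append(gain * clean + a0 + a1 * grid.normalized() + eps)
        labels.append(label)
        fractions.append(f)
        batches.append(batch)
        ids.append(sid)

    for b in range(n_batches):
        for r in range(config.genuine_replicates):
            emit(dkm_by_batch[b], GENUINE_CLASS, 0.0, b + 1,
                 f"{GENUINE_CLASS}-b{b + 1:02d}-r{r + 1}")
    for name in ADULTERANT_CLASSES:
        for f in config.adulteration_fractions:
            for r in range(config.mixture_replicates):
                b = r % n_batches
                clean = (1.0 - f) * dkm_by_batch[b] + f * pure[name]
                emit(clean, name, f, b + 1, f"{name}-f{f:g}-r{r + 1:02d}")
        for r in range(config.pure_replicates):
            emit(pure[name], name, 1.0, 0, f"{name}-pure-r{r + 1}")

    return SpectraSet(grid, np.asarray(rows), np.asarray(labels, dtype=object),
                      np.asarray(fractions), np.asarray(batches),
                      np.asarray(ids, dtype=object))


_META_COLUMNS = ("sample_id", "label", "fraction", "batch")


def write_csv(spectra: SpectraSet, path) -> None:
    """Wide-format CSV: metadata columns then one column per wavenumber."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_META_COLUMNS)
                        + [format(v, ".12g") for v in spectra.grid.values])
        for i in range(spectra.n_samples):
            writer.writerow([spectra.sample_id[i], spectra.label[i],
                             format(spectra.fraction[i], ".17g"),
                             int(spectra.batch[i])]
                            + [format(v, ".17g") for v in spectra.absorbance[i]])


def read_csv(path) -> SpectraSet:
    """Inverse of :func:`write_csv`; validates the header and row shapes."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) <= len(_META_COLUMNS) or tuple(header[:4]) != _META_COLUMNS:
            raise ValueError(
                f"{path}: header must start with {','.join(_META_COLUMNS)}")
        try:
            wavenumbers = np.array([float(v) for v in header[4:]])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric wavenumber in header: {exc}") from None
        if np.any(np.diff(wavenumbers) >= 0):
            bad = int(np.flatnonzero(np.diff(wavenumbers) >= 0)[0]) + 5
            raise ValueError(f"{path}: wavenumber header not strictly "
                             f"decreasing at column {bad}")
        n_cols = len(header)
        ids, labels, fractions, batches, rows = [], [], [], [], []
        for i, row in enumerate(reader):
            if len(row) != n_cols:
                raise ValueError(f"{path}: row {i + 2} has {len(row)} fields, "
                                 f"expected {n_cols}")
            ids.append(row[0])
            labels.append(row[1])
            fractions.append(float(row[2]))
            batches.append(int(row[3]))
            rows.append([float(v) for v in row[4:]])
    if not rows:
        raise ValueError(f"{path}: no samples")
    return SpectraSet(WavenumberGrid(wavenumbers), np.asarray(rows),
                      np.asarray(labels, dtype=object), np.asarray(fractions),
                      np.asarray(batches), np.asarray(ids, dtype=object))
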