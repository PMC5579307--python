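"""Inverse composition identification: PLS1 calibration of FTIR spectra.

The liquid composition of a binary mixture is estimated from its mid-IR
spectrum by partial least squares regression with a scalar response
(PLS1), trained on a set of mixtures of known composition.  Spectra are
mean-centred but not variance-scaled (absorbance units are homogeneous
across wavenumbers); the number of latent directions is chosen by
leave-one-out cross-validation, minimising the mean absolute prediction
error with ties broken toward fewer directions.

All composition errors are reported in mol%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, DomainError, FormatError, GridMismatchError
from .spectra import Spectrum

__all__ = [
    "CalibrationSet",
    "PLSModel",
    "CVReport",
    "Prediction",
    "fit_pls1",
    "loo_cv_select",
    "predict_composition",
    "error_metrics",
    "save_pls_model",
    "load_pls_model",
]


@dataclass(frozen=True)
class CalibrationSet:
    """Known compositions (mol% of component A) paired with spectra.

    ``spectra_matrix`` has one row per mixture on the shared grid.
    """

    compositions_molpct: np.ndarray
    spectra_matrix: np.ndarray
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.compositions_molpct, dtype=float)
        x = np.asarray(self.spectra_matrix, dtype=float)
        nu = np.asarray(self.wavenumbers, dtype=float)
        object.__setattr__(self, "compositions_molpct", y)
        object.__setattr__(self, "spectra_matrix", x)
        object.__setattr__(self, "wavenumbers", nu)
        if y.ndim != 1 or y.size < 2:
            raise DomainError("calibration set needs at least two entries")
        if x.shape != (y.size, nu.size):
            raise DomainError("spectra matrix shape does not match set size/grid")
        if np.any(y < 0) or np.any(y > 100):
            raise DomainError("compositions must lie within [0, 100] mol%")

    @classmethod
    def from_entries(cls, entries) -> "CalibrationSet":
        """Build from an iterable of ``(x_a_fraction, Spectrum)`` pairs."""
        entries = list(entries)
        if len(entries) < 2:
            raise DomainError("calibration set needs at least two entries")
        first = entries[0][1]
        for _, spec in entries:
            if not first.same_grid(spec):
                raise GridMismatchError("calibration spectra are on different grids")
        y = np.array([100.0 * x for x, _ in entries])
        x = np.vstack([spec.absorbance for _, spec in entries])
        return cls(y, x, first.wavenumbers)

    def __len__(self) -> int:
        return self.compositions_molpct.size

    def subset(self, idx) -> "CalibrationSet":
        idx = np.asarray(idx)
        return CalibrationSet(
            self.compositions_molpct[idx], self.spectra_matrix[idx], self.wavenumbers
        )


def _nipals_pls1(x0: np.ndarray, y0: np.ndarray, n_components: int):
    """NIPALS PLS1 on centred data; returns (W, P, q) truncated on degeneracy."""
    x = x0.copy()
    y = y0.copy()
    scale = float(np.linalg.norm(x0)) or 1.0
    ws, ps, qs = [], [], []
    for _ in range(n_components):
        w = x.T @ y
        nw = float(np.linalg.norm(w))
        if nw <= 1e-14 * scale:
            warnings.warn(
                "PLS1 deflation became degenerate; returning "
                f"{len(ws)} of {n_components} requested components",
                stacklevel=3,
            )
            break
        w /= nw
        t = x @ w
        tt = float(t @ t)
        if tt <= 1e-28 * scale**2:
            warnings.warn(
                "PLS1 score collapsed; returning "
                f"{len(ws)} of {n_components} requested components",
                stacklevel=3,
            )
            break
        p = x.T @ t / tt
        q = float(y @ t) / tt
        x = x - np.outer(t, p)
        y = y - q * t
        ws.append(w)
        ps.append(p)
        qs.append(q)
    if not ws:
        return (
            np.zeros((x0.shape[1], 0)),
            np.zeros((x0.shape[1], 0)),
            np.zeros(0),
        )
    return np.column_stack(ws), np.column_stack(ps), np.array(qs)


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS1 inverse map from spectrum to composition (mol%)."""

    wavenumbers: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # p x A
    loadings: np.ndarray  # p x A
    q: np.ndarray  # A
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_components", int(self.weights.shape[1]))

    def regression_vector(self, n_components: int | None = None) -> np.ndarray:
        """``b_k`` such that ``y_hat = y_mean + (x - x_mean) @ b_k``."""
        k = self.n_components if n_components is None else int(n_components)
        if not 0 <= k <= self.n_components:
            raise DomainError(
                f"n_components {k} outside [0, {self.n_components}]"
            )
        if k == 0:
            return np.zeros(self.x_mean.size)
        w = self.weights[:, :k]
        p = self.loadings[:, :k]
        return w @ np.linalg.solve(p.T @ w, self.q[:k])

    def predict_matrix(self, x: np.ndarray, n_components: int | None = None):
        """Predict compositions (mol%) for rows of a spectra matrix."""
        b = self.regression_vector(n_components)
        return self.y_mean + (np.asarray(x, dtype=float) - self.x_mean) @ b


@dataclass(frozen=True)
class Prediction:
    """A composition estimate in mol%, flagged when clipped to [0, 100]."""

    molpct: float
    clipped: bool
    raw_molpct: float


def fit_pls1(cal: CalibrationSet, n_components: int) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent directions.

    The rank bound ``n_components <= min(n_samples - 1, n_wavenumbers)``
    is enforced; degenerate deflation stops early with a warning.  With
    zero components the model predicts the training mean.
    """
    n, p = cal.spectra_matrix.shape
    bound = min(n - 1, p)
    if not 0 <= n_components <= bound:
        raise DomainError(
            f"n_components must lie in [0, {bound}] for {n} samples x {p} channels"
        )
    x_mean = cal.spectra_matrix.mean(axis=0)
    y_mean = float(cal.compositions_molpct.mean())
    w, pl, q = _nipals_pls1(
        cal.spectra_matrix - x_mean, cal.compositions_molpct - y_mean, n_components
    )
    return PLSModel(cal.wavenumbers, x_mean, y_mean, w, pl, q)


def predict_composition(model: PLSModel, spec: Spectrum) -> Prediction:
    """Predict the composition (mol% A) of one spectrum.

    The spectrum grid must match the training grid; the estimate is
    clipped to [0, 100] mol% with the clipping flagged.
    """
    if spec.wavenumbers.shape != model.wavenumbers.shape or not np.allclose(
        spec.wavenumbers, model.wavenumbers, rtol=0, atol=1e-9
    ):
        raise GridMismatchError("spectrum grid differs from the training grid")
    raw = float(model.y_mean + (spec.absorbance - model.x_mean) @ model.regression_vector())
    value = min(max(raw, 0.0), 100.0)
    return Prediction(molpct=value, clipped=value != raw, raw_molpct=raw)


@dataclass(frozen=True)
class CVReport:
    """Leave-one-out errors per direction count, and the chosen count."""

    table: pd.DataFrame  # columns: n_components, mean_abs_error_molpct, max_abs_error_molpct
    chosen: int

    @property
    def mean_error_at_chosen(self) -> float:
        row = self.table[self.table["n_components"] == self.chosen]
        return float(row["mean_abs_error_molpct"].iloc[0])

    @property
    def max_error_at_chosen(self) -> float:
        row = self.table[self.table["n_components"] == self.chosen]
        return float(row["max_abs_error_molpct"].iloc[0])


def loo_cv_select(cal: CalibrationSet, max_components: int) -> CVReport:
    """Choose the PLS direction count by leave-one-out cross-validation.

    Each training point is held out in turn; models with 1 to
    ``max_components`` directions (capped at the fold rank bound) are fit
    on the rest and predict the held-out composition.  The chosen count
    minimises the mean absolute error, ties going to the smaller count.
    """
    if max_components < 1:
        raise DomainError("max_components must be at least 1")
    n = len(cal)
    bound = min(n - 2, cal.wavenumbers.size)
    k_max = min(max_components, bound)
    errors = np.empty((n, k_max))
    for i in range(n):
        rest = np.r_[0:i, i + 1 : n]
        model = fit_pls1(cal.subset(rest), k_max)
        held = cal.spectra_matrix[i]
        truth = cal.compositions_molpct[i]
        for k in range(1, k_max + 1):
            kk = min(k, model.n_components)
            pred = model.y_mean + (held - model.x_mean) @ model.regression_vector(kk)
            errors[i, k - 1] = abs(pred - truth)
    table = pd.DataFrame(
        {
            "n_components": np.arange(1, max_components + 1),
            "mean_abs_error_molpct": [
                errors[:, min(k, k_max) - 1].mean() for k in range(1, max_components + 1)
            ],
            "max_abs_error_molpct": [
                errors[:, min(k, k_max) - 1].max() for k in range(1, max_components + 1)
            ],
        }
    )
    means = table["mean_abs_error_molpct"].to_numpy()
    chosen = int(table["n_components"].iloc[int(np.argmin(means))])  # argmin -> first, i.e. fewest
    return CVReport(table=table, chosen=chosen)


def error_metrics(predicted, truth) -> tuple[float, float]:
    """``(max_abs, mean_abs)`` prediction errors in mol%."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size < 1:
        raise DataIntegrityError("predicted and truth sequences differ in length")
    err = np.abs(p - t)
    return float(err.max()), float(err.mean())


MODEL_FORMAT_VERSION = 1


def save_pls_model(model: PLSModel, path) -> None:
    """Serialise a model to a columnar text file.

    Header comments carry scalars (format version, component count,
    ``y_mean``); columns carry the grid, spectral mean and the regression
    vector at the model's full component count.
    """
    b = model.regression_vector()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# azeoblend-pls1-model version={MODEL_FORMAT_VERSION}\n")
        fh.write(f"# n_components={model.n_components}\n")
        fh.write(f"# y_mean_molpct={model.y_mean!r}\n")
        fh.write("wavenumber_cm-1,x_mean,regression_vector\n")
        for nu, xm, bv in zip(model.wavenumbers, model.x_mean, b):
            fh.write(f"{float(nu)!r},{float(xm)!r},{float(bv)!r}\n")


@dataclass(frozen=True)
class SerializedPLSModel:
    """A deserialised inverse map: enough to predict, not to refit."""

    wavenumbers: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    regression: np.ndarray
    n_components: int

    def regression_vector(self, n_components=None) -> np.ndarray:
        return self.regression

    def predict_matrix(self, x: np.ndarray, n_components=None):
        return self.y_mean + (np.asarray(x, dtype=float) - self.x_mean) @ self.regression


def load_pls_model(path) -> SerializedPLSModel:
    """Read a model written by :func:`save_pls_model`."""
    header: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    header[k] = v
        else:
            body_start = i
            break
    if "n_components" not in header or "y_mean_molpct" not in header:
        raise FormatError("PLS model file missing n_components/y_mean_molpct header")
    data = np.loadtxt(lines[body_start + 1 :], delimiter=",")
    return SerializedPLSModel(
        wavenumbers=data[:, 0],
        x_mean=data[:, 1],
        y_mean=float(header["y_mean_molpct"]),
        regression=data[:, 2],
        n_components=int(header["n_components"]),
    )
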