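"""Empirical orthogonal function (EOF) decomposition of movie data.

Treating a movie as a ``T x N`` matrix ``A`` (columns = pixel time courses,
detrended and column-centered), the EOFs are the eigenvectors ``e_i`` of the
pixel covariance matrix ``R = A^T A``.  The eigenvalue share
``100 * Omega_i / sum_j Omega_j`` [%] quantifies the variance carried by each
spatial pattern, and the projection ``c_i(t) = (A e_i)(t)`` is the i-th
empirical (temporal) mode.  For a synchronized oscillator network almost all
variance falls on the first mode; desynchronized tissue spreads it thinly
over many modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .movie import Movie

__all__ = [
    "Detrender",
    "preprocess",
    "EOF",
    "EOFResult",
    "compute_eof",
    "PixelClassification",
    "classify_pixels",
]


class Detrender(BaseEstimator, TransformerMixin):
    """Moving-window detrending and variance normalization.

    Each column first has a smooth baseline (least-squares quadratic in
    time) removed — this captures the slow culture decay so that the
    shrinking edge windows of the moving statistics are not biased by a
    monotone trend — then its centered moving average is subtracted and the
    result is divided by the centered moving standard deviation.  The window
    should span at least one expected period (default 24 h) so the circadian
    component survives.  Constant columns are zero-filled with a warning.
    """

    def __init__(self, window: float = 24.0, dt: float = 1.0,
                 baseline_degree: int = 2):
        self.window = window
        self.dt = dt
        self.baseline_degree = baseline_degree

    def fit(self, X, y=None):
        if self.window < 24.0 - 1e-9:
            raise ValueError("window must span at least one expected period (24 h)")
        return self

    def transform(self, X):
        self.fit(X)
        X = np.asarray(X, dtype=float)
        if self.baseline_degree > 0:
            t = np.arange(X.shape[0], dtype=float)
            design = np.vander(t, self.baseline_degree + 1)
            coef, *_ = np.linalg.lstsq(design, X, rcond=None)
            X = X - design @ coef
        w = int(round(self.window / self.dt))
        w = max(w + (w + 1) % 2, 3)  # odd, >= 3
        df = pd.DataFrame(X)
        roll = df.rolling(window=w, center=True, min_periods=1)
        mean = roll.mean().to_numpy()
        sd = roll.std(ddof=0).to_numpy()
        out = X - mean
        flat = sd <= 1e-12
        const_cols = flat.all(axis=0)
        if const_cols.any():
            warnings.warn(
                f"{int(const_cols.sum())} constant column(s) zero-filled",
                RuntimeWarning,
            )
        sd[flat] = 1.0
        out = out / sd
        out[:, const_cols] = 0.0
        # remove the small residual temporal mean left by edge effects
        out -= out.mean(axis=0, keepdims=True)
        return out


def preprocess(movie: Movie, window: float = 24.0) -> Movie:
    """Detrend and normalize each pixel of a movie (see :class:`Detrender`)."""
    out = Detrender(window=window, dt=movie.dt).transform(movie.samples)
    return Movie(samples=out, coords=movie.coords, dt=movie.dt)


@dataclass
class EOFResult:
    """Spectrum of an EOF decomposition.

    ``eigenvalues`` are the Omega_i in descending order (length min(T, N),
    covering the full rank), ``normalized`` their percentage shares summing
    to 100, ``eigenvectors`` the orthonormal spatial loadings (one row per
    mode, length N) and ``modes`` the temporal sequences c_i(t) (T x m).
    """

    eigenvalues: np.ndarray
    normalized: np.ndarray
    eigenvectors: np.ndarray
    modes: np.ndarray
    mean: np.ndarray = field(default=None, repr=False)

    @property
    def eig12_sum(self) -> float:
        """Normalized first + second eigenvalue [%]."""
        return float(self.normalized[:2].sum())


class EOF(BaseEstimator, TransformerMixin):
    """EOF/eigen-mode decomposition, sklearn transformer style.

    Fitted attributes: ``eigenvalues_``, ``normalized_eigenvalues_`` (%),
    ``components_`` (m x N orthonormal loadings), ``modes_`` (T x m),
    ``mean_``.  When ``N > T`` the dual T x T problem is solved; the spectrum
    always covers the full rank so the normalized shares sum to 100%.
    """

    def __init__(self, n_components: int | None = None, center: bool = True):
        self.n_components = n_components
        self.center = center

    def fit(self, X, y=None):
        A = np.asarray(X, dtype=float)
        if A.ndim != 2:
            raise ValueError("expected a 2-D (T, N) matrix")
        t, n = A.shape
        self.mean_ = A.mean(axis=0) if self.center else np.zeros(n)
        A = A - self.mean_
        total = float(np.sum(A * A))
        if total <= 0:
            raise ValueError("degenerate all-zero movie: no variance to decompose")
        if n <= t:
            R = A.T @ A
            evals, evecs = np.linalg.eigh(R)
            order = np.argsort(evals)[::-1]
            evals = np.clip(evals[order], 0.0, None)
            components = evecs[:, order].T
        else:
            C = A @ A.T  # dual problem
            evals, u = np.linalg.eigh(C)
            order = np.argsort(evals)[::-1]
            evals = np.clip(evals[order], 0.0, None)
            u = u[:, order]
            scale = np.sqrt(np.where(evals > 1e-12 * evals[0], evals, np.inf))
            components = (A.T @ u / scale).T
            # zero-variance directions have no defined loading; drop them
            keep = np.isfinite(scale)
            components = components[keep]
            evals = evals[: components.shape[0]]
        self.eigenvalues_ = evals
        self.components_ = components
        self.normalized_eigenvalues_ = 100.0 * self.eigenvalues_ / self.eigenvalues_.sum()
        self.modes_ = A @ self.components_.T
        if self.n_components is not None:
            k = self.n_components
            self.components_ = self.components_[:k]
            self.modes_ = self.modes_[:, :k]
        return self

    def transform(self, X):
        A = np.asarray(X, dtype=float) - self.mean_
        return A @ self.components_.T

    def inverse_transform(self, C):
        return np.asarray(C) @ self.components_ + self.mean_


def compute_eof(movie: Movie, center: bool = True) -> EOFResult:
    """Decompose a (preprocessed) movie into empirical orthogonal functions."""
    est = EOF(center=center).fit(movie.samples)
    return EOFResult(
        eigenvalues=est.eigenvalues_,
        normalized=est.normalized_eigenvalues_,
        eigenvectors=est.components_,
        modes=est.modes_,
        mean=est.mean_,
    )


@dataclass
class PixelClassification:
    """Per-pixel component labels (1-based; 0 = unclassified)."""

    labels: np.ndarray
    n_components: int
    threshold: float

    def pixels_of(self, component: int) -> np.ndarray:
        return np.flatnonzero(self.labels == component)


def classify_pixels(
    eof: EOFResult, n_components: int = 2, threshold: float = 0.5
) -> PixelClassification:
    """Assign each pixel to the component with the largest absolute loading.

    Pixel ``k`` gets label ``i`` (1-based) maximizing ``|e_i(k)|`` over the
    first ``n_components`` modes, provided ``|e_i(k)| >= threshold/sqrt(N)``
    (``threshold`` is the cut in units of the r.m.s. loading of a fully
    delocalized mode; the default keeps pixels with at least half that
    loading); otherwise it stays unclassified (label 0).
    """
    if n_components > eof.eigenvectors.shape[0]:
        raise ValueError("n_components exceeds the number of computed modes")
    loadings = np.abs(eof.eigenvectors[:n_components])
    n = loadings.shape[1]
    best = np.argmax(loadings, axis=0)
    best_val = loadings[best, np.arange(n)]
    labels = np.where(best_val >= threshold / np.sqrt(n), best + 1, 0)
    return PixelClassification(labels=labels, n_components=n_components,
                               threshold=threshold)
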