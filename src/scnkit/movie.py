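"""Pixel-level bioluminescence movie container.

A movie is the common currency between the network simulator, the
synthetic renderer and the EOF analyzer: a ``T x N`` sample matrix
(rows = time points, columns = pixels/ROIs) together with pixel
coordinates and the sampling interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Movie"]


@dataclass
class Movie:
    """A ``T x N`` bioluminescence recording.

    Parameters
    ----------
    samples : ndarray of shape (T, N)
        Bioluminescence intensity, one column per pixel/ROI.
    coords : ndarray of shape (N, 2)
        Pixel positions (arbitrary spatial units).
    dt : float, default 1.0
        Sampling interval in hours.
    """

    samples: np.ndarray
    coords: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (T, N) array")
        t, n = self.samples.shape
        if t < 48:
            raise ValueError(f"movie too short: T={t} < 48 samples")
        if n < 2:
            raise ValueError(f"movie needs at least 2 pixels, got N={n}")
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match N={n}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("movie contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in hours, starting at 0."""
        return np.arange(self.n_times) * self.dt

    @property
    def duration(self) -> float:
        return (self.n_times - 1) * self.dt
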