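"""Synthetic PER2::LUC-like movies, dispersed-cell traces and test fixtures.

The imaging model turns dimensionless oscillator states into photon-count
movies with the hallmarks of real slice recordings: a slow exponential decay
of the culture baseline, a multiplicative reporter modulation, several
adjacent pixels per cell, and shot noise whose variance grows with the mean
("poisson-like") or stays constant ("gaussian-scaled").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .movie import Movie
from .network import NetworkRun
from .oscillator import CellTrace, OscillatorParams, simulate_cell

__all__ = ["ImagingModel", "render_movie", "render_dispersed", "fixture",
           "FIXTURE_NAMES"]


@dataclass(frozen=True)
class ImagingModel:
    """How oscillator states map to camera counts.

    ``pixel(t) = baseline * exp(-t/decay_tau) * max(1 + gain * x(t), 0)``
    plus noise.  ``pixels_per_cell`` adjacent pixels share a cell's trace but
    receive independent noise (emulating ROI-scale sampling of ~100 um^2
    cells with ~2 um pixels).  Counts are clipped at zero after adding noise
    (bioluminescence is non-negative), which slightly biases very dim pixels.
    """

    baseline: float = 40_000.0
    decay_tau: float = 150.0
    gain: float = 0.6
    noise_model: str = "poisson-like"
    gaussian_sd: float = 50.0
    pixels_per_cell: int = 4

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.noise_model not in ("poisson-like", "gaussian-scaled", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.pixels_per_cell < 1:
            raise ValueError("pixels_per_cell must be >= 1")

    def render(self, times: np.ndarray, x: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """Counts for signal matrix ``x`` of shape (T, n_traces)."""
        decay = np.exp(-times / self.decay_tau)[:, None]
        mean = self.baseline * decay * np.clip(1.0 + self.gain * x, 0.0, None)
        if self.noise_model == "poisson-like":
            noisy = mean + rng.standard_normal(mean.shape) * np.sqrt(mean)
        elif self.noise_model == "gaussian-scaled":
            noisy = mean + rng.standard_normal(mean.shape) * self.gaussian_sd
        else:
            noisy = mean
        return np.clip(noisy, 0.0, None)


def render_movie(run: NetworkRun, imaging: ImagingModel | None = None,
                 seed: int = 0) -> Movie:
    """Render a network run into a pixel-level movie.

    Each cell maps to ``pixels_per_cell`` pixels laid out in a small block at
    twice the lattice scale, so the pixel map preserves the two-lobed
    geometry.
    """
    imaging = imaging or ImagingModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ppc = imaging.pixels_per_cell
    x = np.repeat(run.traces, ppc, axis=1)
    side = int(np.ceil(np.sqrt(ppc)))
    offsets = np.array([(k % side, k // side) for k in range(ppc)], dtype=float)
    coords = (run.geometry.coords[:, None, :] * side + offsets[None, :, :])
    coords = coords.reshape(-1, 2)
    samples = imaging.render(run.times, x, rng)
    return Movie(samples=samples, coords=coords, dt=run.scenario.sample_interval)


def render_dispersed(
    params_list: list[OscillatorParams],
    duration: float,
    imaging: ImagingModel | None = None,
    seed: int = 0,
    dt: float = 0.05,
    sample_interval: float = 1.0,
) -> list[CellTrace]:
    """Independent single-cell traces rendered through the imaging model.

    One trace per parameter set, no coupling — the in-silico counterpart of
    a dispersed-cell culture.  The default imaging baseline is much dimmer
    than the slice default: a single dispersed cell emits far fewer photons
    than a pixel of stacked tissue.  ``duration = 0`` returns an empty list.
    """
    if not params_list:
        raise ValueError("need at least one parameter set")
    if duration <= 0:
        return []
    imaging = imaging or ImagingModel(baseline=5000.0)
    ss = np.random.SeedSequence(seed)
    traces = []
    for params, child in zip(params_list, ss.spawn(len(params_list))):
        rng = np.random.default_rng(child)
        tr = simulate_cell(params, duration, dt=dt,
                           sample_interval=sample_interval, seed=rng)
        counts = imaging.render(tr.times, tr.x[:, None], rng)[:, 0]
        traces.append(CellTrace(times=tr.times, x=counts))
    return traces


FIXTURE_NAMES = ("rank1", "sincos-50-50", "two-cluster-periods", "white-noise")


def _grid_coords(n: int) -> np.ndarray:
    side = int(np.ceil(np.sqrt(n)))
    return np.array([(k % side, k // side) for k in range(n)], dtype=float)


def fixture(name: str) -> Movie:
    """Small deterministic movies with analytically known EOF spectra.

    * ``rank1`` — one 24-h cosine times fixed positive loadings: the first
      normalized eigenvalue is exactly 100%.
    * ``sincos-50-50`` — half the pixels carry sin, half cos of a 24-h cycle
      over an integer number of periods: two eigenvalues of 50% each.
    * ``two-cluster-periods`` — a 32-h group (larger amplitude) and a 21-h
      group: the two leading modes segregate the groups and carry the two
      imposed periods (the splitting construction).
    * ``white-noise`` — seeded i.i.d. Gaussian pixels, no rhythm.
    """
    if name == "rank1":
        t = np.arange(96.0)
        c = np.cos(2 * np.pi * t / 24.0)
        w = np.linspace(0.7, 1.3, 12)
        return Movie(samples=np.outer(c, w), coords=_grid_coords(12))
    if name == "sincos-50-50":
        t = np.arange(192.0)
        w = 2 * np.pi / 24.0
        half = np.ones(20)
        samples = np.concatenate(
            [np.outer(np.sin(w * t), half), np.outer(np.cos(w * t), half)],
            axis=1,
        )
        coords = _grid_coords(40)
        coords[20:, 0] += 10.0  # separate the two groups spatially
        return Movie(samples=samples, coords=coords)
    if name == "two-cluster-periods":
        t = np.arange(168.0)
        slow = 1.2 * np.cos(2 * np.pi * t / 32.0)
        fast = 1.0 * np.cos(2 * np.pi * t / 21.0)
        samples = np.concatenate(
            [np.outer(slow, np.ones(20)), np.outer(fast, np.ones(20))], axis=1
        )
        coords = _grid_coords(40)
        coords[20:, 0] += 10.0
        return Movie(samples=samples, coords=coords)
    if name == "white-noise":
        rng = np.random.default_rng(20181210)
        return Movie(samples=rng.standard_normal((144, 30)),
                     coords=_grid_coords(30))
    raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
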