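"""Readers and writers for the plain-text formats used across the pipeline.

Movies travel as a wide CSV (first column ``time`` in hours, one column per
pixel) with a companion coordinates CSV (``pixel,x,y``); single-cell traces
as two-column ``time,value`` CSVs; parameter sets as flat JSON/YAML with keys
``alpha, omega, damping, d_r, d_phi``; scenarios as YAML/JSON mirroring the
:class:`~scnkit.network.NetworkScenario` fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .movie import Movie
from .network import NetworkRun, NetworkScenario, PeriodField, scenario_preset
from .oscillator import CellTrace, OscillatorParams

__all__ = [
    "save_movie", "load_movie", "read_movie_tiff",
    "save_trace", "load_trace",
    "save_params", "load_params",
    "save_run", "scenario_from_config", "scenario_to_dict", "config_hash",
]


# -- movies ----------------------------------------------------------------

def save_movie(movie: Movie, movie_path, coords_path=None) -> None:
    movie_path = Path(movie_path)
    df = pd.DataFrame(movie.samples,
                      columns=[f"px{i}" for i in range(movie.n_pixels)])
    df.insert(0, "time", movie.times)
    df.to_csv(movie_path, index=False, float_format="%.6g")
    if coords_path is not None:
        cdf = pd.DataFrame(movie.coords, columns=["x", "y"])
        cdf.insert(0, "pixel", [f"px{i}" for i in range(movie.n_pixels)])
        cdf.to_csv(coords_path, index=False)


def load_movie(movie_path, coords_path=None) -> Movie:
    df = pd.read_csv(movie_path)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    samples = df.iloc[:, 1:].to_numpy(dtype=float)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    if coords_path is not None:
        coords = pd.read_csv(coords_path)[["x", "y"]].to_numpy(dtype=float)
    else:
        coords = np.column_stack([np.arange(samples.shape[1]),
                                  np.zeros(samples.shape[1])])
    return Movie(samples=samples, coords=coords, dt=dt)


def read_movie_tiff(tiff_path, mask_csv=None, dt: float = 1.0) -> Movie:
    """Read a multi-page TIFF stack (one page per frame) as a movie.

    ``mask_csv`` (columns ``x,y``) restricts the pixels; otherwise every
    pixel of the frame enters the matrix.
    """
    import tifffile

    stack = tifffile.imread(tiff_path)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, rows, cols) TIFF stack")
    if mask_csv is not None:
        mask = pd.read_csv(mask_csv)[["x", "y"]].to_numpy(dtype=int)
        samples = stack[:, mask[:, 1], mask[:, 0]].astype(float)
        coords = mask.astype(float)
    else:
        t, rows, cols = stack.shape
        samples = stack.reshape(t, rows * cols).astype(float)
        yy, xx = np.mgrid[0:rows, 0:cols]
        coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    return Movie(samples=samples, coords=coords, dt=dt)


# -- traces and parameters ---------------------------------------------------

def save_trace(trace: CellTrace, path) -> None:
    pd.DataFrame({"time": trace.times, "value": trace.x}).to_csv(
        path, index=False, float_format="%.6g")


def load_trace(path) -> CellTrace:
    df = pd.read_csv(path)
    return CellTrace(times=df.iloc[:, 0].to_numpy(dtype=float),
                     x=df.iloc[:, 1].to_numpy(dtype=float))


_PARAM_KEYS = ("alpha", "omega", "damping", "d_r", "d_phi")


def save_params(params: OscillatorParams, path) -> None:
    path = Path(path)
    payload = {k: getattr(params, k) for k in _PARAM_KEYS}
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_params(path) -> OscillatorParams:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return OscillatorParams(**{k: float(data[k]) for k in _PARAM_KEYS})


# -- runs and scenarios ------------------------------------------------------

def scenario_to_dict(scenario: NetworkScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["base_params"] = {k: getattr(scenario.base_params, k) for k in _PARAM_KEYS}
    d["period_field"] = dataclasses.asdict(scenario.period_field)
    return d


def scenario_from_config(config: dict) -> NetworkScenario:
    """Build a scenario from a config dict (e.g. parsed YAML).

    A ``preset`` key selects defaults; any other key overrides the
    corresponding scenario field.
    """
    cfg = dict(config)
    preset = cfg.pop("preset", None)
    if "base_params" in cfg:
        cfg["base_params"] = OscillatorParams(**cfg["base_params"])
    if "period_field" in cfg:
        cfg["period_field"] = PeriodField(**cfg["period_field"])
    if preset is not None:
        seed = cfg.pop("seed", 0)
        return scenario_preset(preset, seed=seed, **cfg)
    return NetworkScenario(**cfg)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def save_run(run: NetworkRun, csv_path, sidecar_path=None) -> None:
    """Wide CSV (time + one column per cell) plus a JSON scenario sidecar."""
    df = pd.DataFrame(run.traces,
                      columns=[f"cell{i}" for i in range(run.traces.shape[1])])
    df.insert(0, "time", run.times)
    df.to_csv(csv_path, index=False, float_format="%.6g")
    if sidecar_path is not None:
        sidecar = {
            "scenario": scenario_to_dict(run.scenario),
            "periods": run.periods.tolist(),
            "lobe": run.geometry.lobe.tolist(),
            "coords": run.geometry.coords.tolist(),
            "config_hash": config_hash(scenario_to_dict(run.scenario)),
        }
        Path(sidecar_path).write_text(json.dumps(sidecar))
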