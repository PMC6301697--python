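"""SCN network model: two-lobed lattice of coupled amplitude-phase oscillators.

Each cell follows the stochastic limit-cycle model of :mod:`.oscillator`,
extended by diffusive nearest-neighbor coupling and an optional sinusoidal
paracrine forcing that represents a co-cultured wild-type graft::

    dx_i/dt = -lambda_i x_i r_i (r_i - alpha_i) - omega_i y_i
              + sum_{j in N_i} K (x_j - x_i)
              + I_avp sin(2 pi t / 24) + I_vip sin(2 pi (t + phi) / 24)
              + xi_{x,i}
    dy_i/dt = -lambda_i y_i r_i (r_i - alpha_i) + omega_i x_i + xi_{y,i}

The coupling strength is decomposed into the two neuropeptide channels,
``K = a_avp * K_avp + a_vip * K_vip`` with attenuation factors
``a_vip, a_avp`` in [0, 1] encoding genotype and age:

* through development VIP coupling is attenuated (adult slices),
* Cry1/2 double knockout attenuates AVP coupling,
* the additional Vipr2 knockout inactivates VIP coupling entirely and makes
  external VIP forcing ineffective (the receptor is gone, even though the
  graft still secretes VIP).

The VIP/AVP forcing phase delay ``phi`` decides whether the two channels act
synergistically (phi = 0 h) or antagonistically (phi near 12 h); the
antagonistic regime used throughout is phi = 11 h.  AVP receptor antagonist
treatment is abstracted as ``I_avp = 0`` (and, by default, ``a_avp = 0``
inside the slice, since the blockade also acts on recipient cells).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .movie import Movie
from .oscillator import OscillatorParams, simulate_ensemble

__all__ = [
    "NetworkGeometry",
    "PeriodField",
    "NetworkScenario",
    "NetworkRun",
    "build_geometry",
    "assign_periods",
    "simulate_network",
    "scenario_preset",
    "sweep_synchronization",
    "WT_FIT",
    "DKO_FIT",
    "SPLIT_FIT",
    "PRESET_NAMES",
]

#: Single-cell parameters fitted to neonatal wild-type dispersed cells:
#: a sturdy self-sustained oscillator (CV = 0.3) with slow phase diffusion.
WT_FIT = OscillatorParams(alpha=1.0, omega=2 * np.pi / 24.0, damping=0.05,
                          d_r=0.0045, d_phi=0.005)

#: Parameters fitted to Cry1/2 double-knockout cells: a weak, noise-dominated
#: oscillator (CV = 1.4 by the linearized criterion) whose amplitude
#: fluctuations turn over fast (relaxation 0.6/h) while the phase diffuses
#: with a ~17 h coherence time.
DKO_FIT = OscillatorParams(alpha=0.01, omega=2 * np.pi / 24.0, damping=60.0,
                           d_r=1.2e-4, d_phi=0.06)

#: The rhythmic tail of the knockout CV distribution (CV = 0.5): used for the
#: minority of neonatal double-knockout slices that retain enough cellular
#: rhythmicity for the two lobes to lock internally and split.
SPLIT_FIT = OscillatorParams(alpha=0.5, omega=2 * np.pi / 24.0, damping=0.1,
                             d_r=3.125e-3, d_phi=0.005)


@dataclass
class NetworkGeometry:
    """Two disc-shaped 4-neighbor lattices joined by a few bridge edges."""

    coords: np.ndarray          # (n, 2) grid positions
    lobe: np.ndarray            # (n,) 0 = left, 1 = right
    dorsomedial: np.ndarray     # (n,) bool
    edges: np.ndarray           # (m, 2) int, i < j, each undirected edge once
    bridge: np.ndarray          # (m,) bool, True for inter-lobe edges

    @property
    def n_cells(self) -> int:
        return len(self.coords)

    def adjacency(self, bridge_factor: float = 1.0) -> sparse.csr_matrix:
        """Symmetric weighted adjacency; bridge edges get ``bridge_factor``."""
        w = np.where(self.bridge, bridge_factor, 1.0)
        i, j = self.edges.T if len(self.edges) else (np.array([], int),) * 2
        n = self.n_cells
        a = sparse.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]),
                                      np.concatenate([j, i]))),
            shape=(n, n),
        )
        return a.tocsr()

    def n_components(self) -> int:
        return connected_components(self.adjacency(), directed=False)[0]


def _disc_lattice(n: int) -> np.ndarray:
    """First n integer grid points by distance from the origin (a disc)."""
    radius = int(np.ceil(np.sqrt(n / np.pi))) + 2
    pts = np.array(list(itertools.product(range(-radius, radius + 1), repeat=2)))
    d2 = (pts**2).sum(axis=1)
    order = np.lexsort((pts[:, 1], pts[:, 0], d2))
    return pts[order[:n]]


def build_geometry(
    cells_per_lobe: int,
    bridge_count: int = 4,
    dorsomedial_fraction: float = 0.1,
    seed: int = 0,
) -> NetworkGeometry:
    """Construct the two-lobed SCN lattice.

    Each lobe is a disc-shaped 4-neighbor lattice; the innermost-dorsal
    ``dorsomedial_fraction`` of each lobe is labelled dorsomedial; exactly
    ``bridge_count`` symmetric edges connect medial cells of the two lobes.
    """
    if cells_per_lobe < 9:
        raise ValueError("cells_per_lobe must be at least 9")
    if bridge_count < 0:
        raise ValueError("bridge_count must be non-negative")
    if not 0.0 <= dorsomedial_fraction <= 1.0:
        raise ValueError("dorsomedial_fraction must lie in [0, 1]")

    pts = _disc_lattice(cells_per_lobe)
    span = pts[:, 0].max() - pts[:, 0].min() + 3
    left = pts.copy()
    right = pts.copy()
    right[:, 0] = -right[:, 0] + span  # mirrored, shifted to the right
    coords = np.vstack([left, right]).astype(float)
    lobe = np.repeat([0, 1], cells_per_lobe)

    # intra-lobe 4-neighbor edges
    index = {(lb, x, y): i for i, (lb, (x, y)) in
             enumerate(zip(lobe, coords.astype(int)))}
    edges, bridge = [], []
    for i, ((x, y), lb) in enumerate(zip(coords.astype(int), lobe)):
        for dx, dy in ((1, 0), (0, 1)):
            j = index.get((lb, x + dx, y + dy))
            if j is not None:
                edges.append((min(i, j), max(i, j)))
                bridge.append(False)

    # dorsomedial label: dorsal (high y) and medial (toward the midline)
    midline = span / 2.0
    n_dm = int(np.ceil(dorsomedial_fraction * cells_per_lobe))
    dorsomedial = np.zeros(2 * cells_per_lobe, dtype=bool)
    for lb in (0, 1):
        sel = np.flatnonzero(lobe == lb)
        score = coords[sel, 1] - 0.5 * np.abs(coords[sel, 0] - midline)
        dorsomedial[sel[np.argsort(score)[::-1][:n_dm]]] = True

    # bridges: pair medial-most left cells with their mirror images
    if bridge_count > 0:
        rng = np.random.default_rng(seed)
        left_ids = np.flatnonzero(lobe == 0)
        medial_rank = np.argsort(-coords[left_ids, 0] +
                                 1e-3 * np.abs(coords[left_ids, 1]))
        candidates = left_ids[medial_rank]
        if bridge_count > len(candidates):
            raise ValueError("bridge_count exceeds available medial cells")
        pick = candidates[:max(bridge_count * 2, bridge_count)]
        chosen = rng.choice(pick, size=bridge_count, replace=False)
        mirror = {tuple(c): i for i, c in enumerate(coords.astype(int))
                  if lobe[i] == 1}
        for i in chosen:
            x, y = coords[i].astype(int)
            j = mirror[(int(-x + span), int(y))]
            edges.append((min(i, int(j)), max(i, int(j))))
            bridge.append(True)

    return NetworkGeometry(
        coords=coords, lobe=lobe, dorsomedial=dorsomedial,
        edges=np.array(edges, dtype=int).reshape(-1, 2),
        bridge=np.array(bridge, dtype=bool),
    )


@dataclass(frozen=True)
class PeriodField:
    """Per-cell intrinsic period assignment (hours).

    ``dorsomedial_offset`` shifts the mean period of dorsomedial cells
    (negative = shorter, as reported for the innermost dorsomedial SCN);
    ``right_lobe_offset`` shifts the right lobe (the splitting regime).
    """

    mean: float = 24.0
    sd: float = 1.5
    dorsomedial_offset: float = 0.0
    right_lobe_offset: float = 0.0


def assign_periods(
    geometry: NetworkGeometry,
    mean_period: float = 24.0,
    sd_period: float = 1.5,
    dorsomedial_offset: float = 0.0,
    right_lobe_offset: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw per-cell intrinsic periods (h) with regional mean offsets."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.full(geometry.n_cells, mean_period, dtype=float)
    means[geometry.dorsomedial] += dorsomedial_offset
    means[geometry.lobe == 1] += right_lobe_offset
    if np.any(means <= 0):
        raise ValueError("offsets produce a non-positive mean period")
    periods = rng.normal(means, sd_period)
    if np.any(periods <= 0):
        raise ValueError("drawn periods include non-positive values; reduce sd")
    return periods


@dataclass
class NetworkScenario:
    """Full specification of one in-silico slice experiment."""

    base_params: OscillatorParams = WT_FIT
    period_field: PeriodField = field(default_factory=PeriodField)
    cells_per_lobe: int = 120
    bridge_count: int = 4
    bridge_factor: float = 0.1
    dorsomedial_fraction: float = 0.1
    a_vip: float = 1.0
    a_avp: float = 1.0
    k_vip: float = 0.05
    k_avp: float = 0.05
    i_vip: float = 0.0
    i_avp: float = 0.0
    phi: float = 11.0
    vip_receptor: bool = True
    antagonist: bool = False
    initial_phase_sd: float = 0.5
    duration: float = 144.0
    transient: float = 48.0
    dt: float = 0.05
    sample_interval: float = 1.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.antagonist:
            # receptor blockade: no AVP forcing, no intra-slice AVP coupling
            self.i_avp = 0.0
            self.a_avp = 0.0
        if not (0 <= self.a_vip <= 1 and 0 <= self.a_avp <= 1):
            raise ValueError("attenuation factors must lie in [0, 1]")
        if self.i_vip < 0 or self.i_avp < 0:
            raise ValueError("forcing intensities must be non-negative")
        if not 0 <= self.phi < 24:
            raise ValueError("phi must lie in [0, 24) hours")

    @property
    def coupling_strength(self) -> float:
        """K = a_avp * K_avp + a_vip * K_vip."""
        return self.a_avp * self.k_avp + self.a_vip * self.k_vip

    @property
    def effective_i_vip(self) -> float:
        """VIP forcing is ineffective when the receptor is knocked out."""
        return self.i_vip if self.vip_receptor else 0.0


@dataclass
class NetworkRun:
    """Sampled output of one network simulation."""

    scenario: NetworkScenario
    geometry: NetworkGeometry
    periods: np.ndarray
    times: np.ndarray
    traces: np.ndarray      # (T, n) x_i samples
    traces_y: np.ndarray    # (T, n) conjugate coordinate

    def as_movie(self) -> Movie:
        """View the raw cell traces as a movie (one pixel per cell)."""
        return Movie(samples=self.traces, coords=self.geometry.coords,
                     dt=self.scenario.sample_interval)


def simulate_network(scenario: NetworkScenario) -> NetworkRun:
    """Integrate the coupled network (Euler-Maruyama) and sample hourly."""
    ss = np.random.SeedSequence(scenario.seed)
    s_geom, s_period, s_phase, s_noise = ss.spawn(4)
    geometry = build_geometry(
        scenario.cells_per_lobe, scenario.bridge_count,
        scenario.dorsomedial_fraction,
        seed=int(s_geom.generate_state(1)[0] % (2**31)),
    )
    pf = scenario.period_field
    periods = assign_periods(
        geometry, pf.mean, pf.sd, pf.dorsomedial_offset, pf.right_lobe_offset,
        seed=np.random.default_rng(s_period),
    )
    omega = 2 * np.pi / periods

    p = scenario.base_params
    n = geometry.n_cells
    rng_phase = np.random.default_rng(s_phase)
    # slices come out of an LD-entrained animal: cells start phase-ordered
    # (spread initial_phase_sd rad); weakly coupled scenarios disperse
    # during the transient through phase noise and period heterogeneity
    theta0 = rng_phase.normal(0.0, scenario.initial_phase_sd, size=n)
    x0 = p.alpha * np.cos(theta0)
    y0 = p.alpha * np.sin(theta0)

    k = scenario.coupling_strength
    adj = geometry.adjacency(scenario.bridge_factor)
    degree = np.asarray(adj.sum(axis=1)).ravel()

    def coupling(x):
        return k * (adj @ x - degree * x)

    i_avp = scenario.i_avp
    i_vip = scenario.effective_i_vip
    phi = scenario.phi
    w24 = 2 * np.pi / 24.0

    forcing = None
    if i_avp > 0 or i_vip > 0:
        def forcing(t):
            return i_avp * np.sin(w24 * t) + i_vip * np.sin(w24 * (t + phi))

    times, xs, ys = simulate_ensemble(
        p.alpha, omega, p.damping, p.d_r, p.d_phi,
        x0, y0, scenario.duration, scenario.dt, scenario.sample_interval,
        np.random.default_rng(s_noise),
        coupling=coupling if k > 0 else None,
        forcing=forcing,
        transient=scenario.transient,
    )
    return NetworkRun(scenario=scenario, geometry=geometry, periods=periods,
                      times=times, traces=xs, traces_y=ys)


def _preset_table() -> dict[str, dict]:
    wt_periods = PeriodField(mean=24.0, sd=1.5, dorsomedial_offset=-1.0)
    # knockout cells show very broad intrinsic periods (rescued slices span
    # roughly 15-37 h), hence the wide spread
    ko_periods = PeriodField(mean=24.0, sd=5.0)
    force = dict(i_vip=0.01, i_avp=0.01, phi=11.0)
    return {
        # neonatal slices
        "neonate-wt": dict(base_params=WT_FIT, a_vip=1.0, a_avp=1.0,
                           period_field=wt_periods),
        "neonate-dko": dict(base_params=DKO_FIT, a_vip=0.1, a_avp=0.1,
                            period_field=ko_periods),
        # the minority splitting regime: each lobe locks internally but the
        # lobes run at the observed distinct periods (~21 h vs ~32 h); a
        # smaller lobe-period difference cannot decorrelate the lobes within
        # a 6-day record
        "neonate-dko-split": dict(
            base_params=SPLIT_FIT, a_vip=1.0, a_avp=1.0,
            period_field=PeriodField(mean=21.0, sd=0.5, right_lobe_offset=11.0),
            bridge_count=2,
        ),
        "neonate-tko": dict(base_params=DKO_FIT, a_vip=0.0, a_avp=0.1,
                            vip_receptor=False, period_field=ko_periods),
        # adult slices: VIP coupling attenuated through development
        "adult-wt": dict(base_params=WT_FIT, a_vip=0.3, a_avp=1.0,
                         period_field=PeriodField(mean=24.0, sd=1.5)),
        "adult-dko": dict(base_params=DKO_FIT, a_vip=0.1, a_avp=0.1,
                          period_field=ko_periods),
        "adult-tko": dict(base_params=DKO_FIT, a_vip=0.0, a_avp=0.1,
                          vip_receptor=False, period_field=ko_periods),
        # co-culture with a neonatal wild-type graft (24-h forcing)
        "coculture-dko": dict(base_params=DKO_FIT, a_vip=0.1, a_avp=0.1,
                              period_field=ko_periods, **force),
        "coculture-dko-antagonist": dict(
            base_params=DKO_FIT, a_vip=0.1, a_avp=0.1,
            period_field=ko_periods, antagonist=True, **force),
        "coculture-tko": dict(base_params=DKO_FIT, a_vip=0.0, a_avp=0.1,
                              vip_receptor=False, period_field=ko_periods,
                              **force),
        "coculture-tko-antagonist": dict(
            base_params=DKO_FIT, a_vip=0.0, a_avp=0.1, vip_receptor=False,
            period_field=ko_periods, antagonist=True, **force),
    }


PRESET_NAMES = tuple(_preset_table())


def scenario_preset(name: str, seed: int = 0, **overrides) -> NetworkScenario:
    """A fully populated scenario for a named experimental condition.

    ``overrides`` replace any :class:`NetworkScenario` field (e.g. a smaller
    ``cells_per_lobe`` for quick runs).
    """
    table = _preset_table()
    if name not in table:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(table)}"
        )
    cfg = {**table[name], "seed": seed, "name": name, **overrides}
    return NetworkScenario(**cfg)


def sweep_synchronization(
    scenario: NetworkScenario,
    grid: list[tuple[str, list]],
    replicates: int = 1,
) -> pd.DataFrame:
    """Synchronization index over a cartesian parameter grid.

    Each row is one grid point: the named scenario fields are replaced by the
    grid values, the run repeated ``replicates`` times with distinct seeds,
    and the sync index computed on the final 24 h of the detrended traces.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    for name, _ in grid:
        if not hasattr(scenario, name):
            raise ValueError(f"scenario has no parameter {name!r}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    names = [name for name, _ in grid]
    rows = []
    for values in itertools.product(*(vals for _, vals in grid)):
        r_means = []
        for rep in range(replicates):
            sc = replace(scenario, seed=scenario.seed + 10_000 * rep,
                         **dict(zip(names, values)))
            run = simulate_network(sc)
            from .eof import preprocess  # local import avoids a cycle
            from .rhythm import sync_index
            movie = preprocess(run.as_movie())
            r_mean, _, _ = sync_index(movie)
            r_means.append(r_mean)
        rows.append({**dict(zip(names, values)),
                     "mean_sync": float(np.mean(r_means)),
                     "sd_sync": float(np.std(r_means, ddof=0))})
    return pd.DataFrame(rows)
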