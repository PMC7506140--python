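"""Stochastic simulation, mean residence times and quasi-potential landscapes.

The reduced (ZEB protein, miR-200) system is driven with additive Gaussian
white noise (Euler-Maruyama, reflecting boundary at zero).  Trajectories
are coarse-grained into an itinerary of attractor basins — each sampled
point is assigned to the basin a short noise-free relaxation from its grid
cell converges to — from which mean residence times and occupancy
fractions follow.  The quasi-potential is U = -ln P of the smoothed
stationary histogram on a log-log grid, with barrier heights measured at
the minimax saddle between adjacent minima (union-find flood by ascending
potential).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import _kernels
from ._kernels import DRIFT_DOUBLE_WELL, DRIFT_EMT
from .reduction import ReducedSystem, pack_reduced


class StochasticConfigError(ValueError):
    pass


@dataclass
class DriftSpec:
    """A packed drift usable by the numba kernels."""

    kind: int
    theta: np.ndarray

    def __call__(self, x: float, y: float) -> tuple[float, float]:
        return _kernels._drift(self.kind, self.theta, x, y)


def emt_drift(system: ReducedSystem) -> DriftSpec:
    return DriftSpec(DRIFT_EMT, pack_reduced(system))


def double_well_drift(center: float = 2.0, half_width: float = 1.0,
                      stiffness: float = 4.0, y_center: float = 1.0,
                      y_rate: float = 1.0) -> DriftSpec:
    """Symmetric double-well toy: wells at center +/- half_width, saddle at
    the center; the second coordinate relaxes linearly.  Used as an
    analytically known fixture for basin and barrier estimators."""
    return DriftSpec(DRIFT_DOUBLE_WELL,
                     np.array([center, half_width, stiffness, y_center, y_rate]))


@dataclass
class StochasticRun:
    """A recorded Euler-Maruyama path (thinned to every ``record_every``-th
    step; ``dt_record = dt * record_every``)."""

    drift: DriftSpec
    dt: float
    record_every: int
    sigma: tuple[float, float]
    seed: int
    path: np.ndarray  # (n_rec, 2): columns (Z, mu) / (x, y)

    @property
    def dt_record(self) -> float:
        return self.dt * self.record_every

    @property
    def n_steps(self) -> int:
        return (self.path.shape[0] - 1) * self.record_every


def euler_maruyama(drift: DriftSpec, x0: tuple[float, float], *,
                   dt: float = 0.01, n_steps: int = 1_000_000,
                   sigma: tuple[float, float], seed: int,
                   record_every: int = 10) -> StochasticRun:
    """Simulate ``x_{t+dt} = x_t + f(x) dt + sigma sqrt(dt) xi`` with
    reflection of negative proposals; bit-reproducible for a given seed."""
    if dt <= 0:
        raise StochasticConfigError("dt must be positive")
    if sigma[0] < 0 or sigma[1] < 0:
        raise StochasticConfigError("noise amplitudes must be non-negative")
    path = _kernels.em_path(drift.kind, drift.theta, float(x0[0]), float(x0[1]),
                            float(dt), int(n_steps), float(sigma[0]),
                            float(sigma[1]), int(seed) % 2**31,
                            int(record_every))
    return StochasticRun(drift=drift, dt=dt, record_every=record_every,
                         sigma=(float(sigma[0]), float(sigma[1])),
                         seed=int(seed), path=path)


DEFAULT_NOISE_FRACTIONS = (0.05, 0.12)  # (ZEB protein, miR-200)


def default_sigma(attractors: np.ndarray,
                  fractions: tuple[float, float] = DEFAULT_NOISE_FRACTIONS,
                  labels: list[str] | None = None) -> tuple[float, float]:
    """Noise amplitude per variable: a fraction of the geometric mean of
    the attractor levels.  Attractor levels span orders of magnitude, so a
    fraction of the absolute range would swamp the low-level states; the
    geometric scale perturbs every well at a comparable relative depth.

    When ``labels`` are given and a hybrid/mesenchymal pair is present,
    only those two states set the scale: the pair exists across the whole
    SNAIL window the landscapes probe, so the amplitude varies smoothly
    across the epithelial fold instead of jumping when the E state
    appears.  The default fractions (5% ZEB, 12% miR-200) are calibrated
    so both basins exchange within accessible horizons (see methods)."""
    attractors = np.atleast_2d(attractors)
    if labels is not None and {"H", "M"} <= set(labels):
        keep = [i for i, l in enumerate(labels) if l in ("H", "M")]
        attractors = attractors[keep]
    gmean = np.exp(np.mean(np.log(np.maximum(attractors, 1e-12)), axis=0))
    return (float(fractions[0] * gmean[0]), float(fractions[1] * gmean[1]))


# ---------------------------------------------------------------------------
# Basin coarse-graining
# ---------------------------------------------------------------------------

@dataclass
class BasinGrid:
    """Cached basin labels on a log-log grid."""

    log_x_edges: np.ndarray
    log_y_edges: np.ndarray
    labels: np.ndarray  # (nx, ny) attractor index, -1 unresolved
    attractors: np.ndarray  # (k, 2)
    unresolved: int = 0

    def assign(self, path: np.ndarray) -> np.ndarray:
        ix = np.clip(np.searchsorted(self.log_x_edges,
                                     np.log(np.maximum(path[:, 0], 1e-12))) - 1,
                     0, self.labels.shape[0] - 1)
        iy = np.clip(np.searchsorted(self.log_y_edges,
                                     np.log(np.maximum(path[:, 1], 1e-12))) - 1,
                     0, self.labels.shape[1] - 1)
        return self.labels[ix, iy]


def _log_grid(attractors: np.ndarray, path: np.ndarray | None, n_cells: int,
              margin: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    pts = attractors if path is None else np.vstack([attractors, path])
    lo = np.log(np.maximum(pts.min(axis=0), 1e-9)) - margin
    hi = np.log(np.maximum(pts.max(axis=0), 1e-9)) + margin
    return (np.linspace(lo[0], hi[0], n_cells + 1),
            np.linspace(lo[1], hi[1], n_cells + 1))


def build_basin_grid(drift: DriftSpec, attractors: np.ndarray, *,
                     path: np.ndarray | None = None, n_cells: int = 80,
                     dt: float = 0.05, max_steps: int = 400_000,
                     log_radius: float = 0.1) -> BasinGrid:
    """Relax every cell centre with the noise-free drift and record which
    attractor it converges to (basins are non-convex near the separatrix,
    so nearest-attractor assignment would mislabel)."""
    attractors = np.atleast_2d(np.asarray(attractors, dtype=float))
    ex, ey = _log_grid(attractors, path, n_cells)
    cx = np.exp(0.5 * (ex[:-1] + ex[1:]))
    cy = np.exp(0.5 * (ey[:-1] + ey[1:]))
    labels = _kernels.basin_grid(drift.kind, drift.theta, cx, cy, dt,
                                 max_steps, attractors[:, 0].copy(),
                                 attractors[:, 1].copy(), log_radius)
    unresolved = int(np.sum(labels < 0))
    if unresolved:
        # fall back to nearest attractor in log space for stragglers
        la = np.log(np.maximum(attractors, 1e-12))
        for i, j in zip(*np.where(labels < 0)):
            p = np.array([np.log(cx[i]), np.log(cy[j])])
            labels[i, j] = int(np.argmin(np.sum((la - p) ** 2, axis=1)))
    return BasinGrid(log_x_edges=ex, log_y_edges=ey, labels=labels,
                     attractors=attractors, unresolved=unresolved)


@dataclass
class Itinerary:
    """Basin index per recorded time step."""

    labels: np.ndarray  # int per recorded point
    dt: float  # recording interval, h
    state_names: list[str]

    def __len__(self) -> int:
        return self.labels.size


def coarse_grain(run: StochasticRun, basin: BasinGrid,
                 state_names: list[str] | None = None) -> Itinerary:
    names = state_names or [f"A{i}" for i in range(len(basin.attractors))]
    return Itinerary(labels=basin.assign(run.path), dt=run.dt_record,
                     state_names=names)


# ---------------------------------------------------------------------------
# Mean residence time
# ---------------------------------------------------------------------------

def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """(label, length) for each maximal run."""
    if labels.size == 0:
        return []
    change = np.where(np.diff(labels) != 0)[0]
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [labels.size]])
    return [(int(labels[s]), int(e - s)) for s, e in zip(starts, ends)]


def mean_residence_time(itinerary: Itinerary) -> dict[str, dict[str, float]]:
    """Per-state mean residence time (mean contiguous-run length x dt) and
    occupancy fraction.  States never visited are absent from the result
    (not reported as zero)."""
    if len(itinerary) == 0:
        raise ValueError("empty itinerary")
    by_state: dict[int, list[int]] = {}
    for lab, length in _runs(itinerary.labels):
        by_state.setdefault(lab, []).append(length)
    total = itinerary.labels.size
    out: dict[str, dict[str, float]] = {}
    for lab, lengths in sorted(by_state.items()):
        name = itinerary.state_names[lab] if lab >= 0 else "unresolved"
        out[name] = {
            "mrt": float(np.mean(lengths) * itinerary.dt),
            "fraction": float(sum(lengths) / total),
            "n_visits": float(len(lengths)),
        }
    return out


# ---------------------------------------------------------------------------
# Quasi-potential landscape
# ---------------------------------------------------------------------------

@dataclass
class PotentialField:
    log_x_edges: np.ndarray
    log_y_edges: np.ndarray
    U: np.ndarray  # (nx, ny); np.inf where unvisited
    minima: list[tuple[int, int]]
    minima_states: list[str]
    saddle_levels: dict[str, float]  # per state: U at first connection
    barriers: dict[str, float]  # saddle - minimum
    coverage: float  # fraction of attractor-region cells visited


def quasi_potential(runs: list[StochasticRun], attractors: np.ndarray,
                    state_names: list[str], *, n_cells: int = 120,
                    smooth_sigma: float = 1.5,
                    coverage_radius: float = 0.5) -> PotentialField:
    """U = -ln(P) of the pooled, kernel-smoothed 2-D histogram in log
    coordinates; barriers from a union-find flood by ascending U.

    ``coverage`` reports the fraction of cells within ``coverage_radius``
    (log units) of any attractor that were visited.
    """
    attractors = np.atleast_2d(np.asarray(attractors, dtype=float))
    pooled = np.vstack([r.path for r in runs])
    ex, ey = _log_grid(attractors, pooled, n_cells, margin=0.3)
    lx = np.log(np.maximum(pooled[:, 0], 1e-12))
    ly = np.log(np.maximum(pooled[:, 1], 1e-12))
    H, _, _ = np.histogram2d(lx, ly, bins=[ex, ey])
    Hs = gaussian_filter(H, smooth_sigma)
    visited = Hs > 0
    U = np.full_like(Hs, np.inf)
    U[visited] = -np.log(Hs[visited] / Hs.sum())
    U[visited] -= U[visited].min()

    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    # coverage near the attractors
    la = np.log(np.maximum(attractors, 1e-12))
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    near = np.zeros_like(visited)
    for a in la:
        near |= (CX - a[0]) ** 2 + (CY - a[1]) ** 2 < coverage_radius**2
    coverage = float(visited[near].mean()) if near.any() else 0.0

    # minima: one per attractor, the lowest-U visited cell near it; an
    # attractor whose neighbourhood was never visited has no minimum and
    # the barriers toward it are reported infinite
    minima: list[tuple[int, int]] = []
    valid: list[bool] = []
    for a in la:
        d2 = (CX - a[0]) ** 2 + (CY - a[1]) ** 2
        mask = visited & (d2 < coverage_radius**2)
        valid.append(bool(mask.any()))
        if not mask.any():
            import logging

            logging.getLogger(__name__).warning(
                "no sampled density near attractor %s", np.exp(a))
            mask = visited
        Um = np.where(mask, U, np.inf)
        minima.append(tuple(int(v) for v in
                            np.unravel_index(np.argmin(Um), Um.shape)))

    if sum(valid) < 2:
        barriers = [np.inf] * len(minima)
        saddles = [np.inf] * len(minima)
    else:
        flood_minima = [m for m, v in zip(minima, valid) if v]
        fb, fs = _barriers_by_flood(U, flood_minima)
        barriers, saddles = [], []
        j = 0
        for v in valid:
            if v:
                barriers.append(fb[j])
                saddles.append(fs[j])
                j += 1
            else:
                barriers.append(np.inf)
                saddles.append(np.inf)
    return PotentialField(log_x_edges=ex, log_y_edges=ey, U=U, minima=minima,
                          minima_states=list(state_names),
                          saddle_levels={state_names[i]: saddles[i]
                                         for i in range(len(minima))},
                          barriers={state_names[i]: barriers[i]
                                    for i in range(len(minima))},
                          coverage=coverage)


def _barriers_by_flood(U: np.ndarray, minima: list[tuple[int, int]]
                       ) -> tuple[list[float], list[float]]:
    """Activate cells by ascending U, union-find with 8-neighbours; a
    minimum's saddle level is the U at which its component first touches a
    component holding another minimum."""
    nx, ny = U.shape
    order = np.argsort(U, axis=None, kind="stable")
    parent = np.full(nx * ny, -1, dtype=np.int64)
    min_id = {m[0] * ny + m[1]: i for i, m in enumerate(minima)}
    comp_minima: dict[int, set[int]] = {}
    saddle = [np.inf] * len(minima)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    active = np.zeros(nx * ny, dtype=bool)
    k = len(minima)
    resolved = 0
    for flat in order:
        u = U.flat[flat]
        if not np.isfinite(u):
            break
        parent[flat] = flat
        active[flat] = True
        if flat in min_id:
            comp_minima[flat] = {min_id[flat]}
        i, j = divmod(int(flat), ny)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                i2, j2 = i + di, j + dj
                if not (0 <= i2 < nx and 0 <= j2 < ny):
                    continue
                nflat = i2 * ny + j2
                if not active[nflat]:
                    continue
                ra, rb = find(flat), find(nflat)
                if ra == rb:
                    continue
                ma = comp_minima.get(ra, set())
                mb = comp_minima.get(rb, set())
                if ma and mb:
                    for m in ma | mb:
                        if saddle[m] == np.inf:
                            saddle[m] = float(u)
                            resolved += 1
                parent[rb] = ra
                comp_minima[ra] = ma | mb
                comp_minima.pop(rb, None)
        if resolved >= k and k > 1:
            pass  # keep flooding only until all resolved
        if resolved >= k:
            break
    barriers = [float(saddle[i] - U[minima[i]]) if np.isfinite(saddle[i])
                else np.inf for i in range(len(minima))]
    if len(minima) == 1:
        barriers = [np.inf]
    return barriers, saddle
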