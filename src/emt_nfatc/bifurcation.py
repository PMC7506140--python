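"""Bifurcation analysis against the SNAIL input.

A sweep runs multi-start root finding at each SNAIL value (warm-started
from the neighbouring value), links the resulting equilibria into branches
by nearest-neighbour continuation in ZEB mRNA, and labels stable branches
by identity: the lowest-ZEB-mRNA stable branch is epithelial (E), the
highest mesenchymal (M), anything between hybrid (H).  The hybrid-enabling
SNAIL interval and the +/-10% single-parameter sensitivity analysis are
built on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SteadyState, find_steady_states
from .params import MechanisticParameters

logger = logging.getLogger(__name__)

_LINK_LOG_TOL = 0.8  # max |log mz ratio| for continuing a branch between grid points


@dataclass
class BifurcationBranch:
    """One solution branch: aligned SNAIL values and steady states."""

    branch_id: int
    S_values: list[float] = field(default_factory=list)
    states: list[SteadyState] = field(default_factory=list)
    label: str | None = None  # E / H / M for stable branches

    @property
    def stable(self) -> bool:
        return all(s.stable for s in self.states)

    def mz_at(self, S: float) -> float:
        i = int(np.argmin(np.abs(np.asarray(self.S_values) - S)))
        return self.states[i].mz

    def mean_log_mz(self) -> float:
        return float(np.mean([np.log(max(s.mz, 1e-9)) for s in self.states]))


@dataclass
class PhaseDiagram:
    """Phases (sets of coexisting stable phenotypes) along the SNAIL grid."""

    S_grid: np.ndarray
    phases: list[frozenset[str]]
    fold_points: list[float]
    branches: list[BifurcationBranch]
    stable_counts: np.ndarray

    def phase_at(self, S: float) -> frozenset[str]:
        i = int(np.argmin(np.abs(self.S_grid - S)))
        return self.phases[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"S": self.S_grid,
             "phase": ["".join(sorted(p)) for p in self.phases],
             "n_stable": self.stable_counts}
        )

    def branches_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            for S, st in zip(b.S_values, b.states):
                rows.append({"branch": b.branch_id, "label": b.label or "",
                             "S": S, "mz": st.mz, "mu": st.mu,
                             "stable": st.stable})
        return pd.DataFrame(rows)


def _link(branches_open: list[BifurcationBranch], found: list[SteadyState],
          S: float, all_branches: list[BifurcationBranch]) -> list[BifurcationBranch]:
    """Greedy nearest-neighbour continuation in log ZEB mRNA, stability-aware."""
    pairs = []
    for bi, b in enumerate(branches_open):
        last = b.states[-1]
        for si, s in enumerate(found):
            if s.stable != last.stable:
                continue
            d = abs(np.log(max(s.mz, 1e-9)) - np.log(max(last.mz, 1e-9)))
            pairs.append((d, abs(s.mz - last.mz), bi, si))
    pairs.sort()
    used_b: set[int] = set()
    used_s: set[int] = set()
    for d, _dabs, bi, si in pairs:
        if d > _LINK_LOG_TOL or bi in used_b or si in used_s:
            continue
        branches_open[bi].S_values.append(S)
        branches_open[bi].states.append(found[si])
        used_b.add(bi)
        used_s.add(si)
    nxt = [b for i, b in enumerate(branches_open) if i in used_b]
    for si, s in enumerate(found):
        if si not in used_s:
            nb = BifurcationBranch(branch_id=len(all_branches),
                                   S_values=[S], states=[s])
            all_branches.append(nb)
            nxt.append(nb)
    return nxt


def _label_branches(branches: list[BifurcationBranch]) -> None:
    stable = [b for b in branches if b.states and b.states[0].stable]
    stable.sort(key=lambda b: b.mean_log_mz())
    for b in branches:
        b.label = None
    if not stable:
        return
    if len(stable) == 1:
        stable[0].label = "E"
        return
    stable[0].label = "E"
    stable[-1].label = "M"
    for b in stable[1:-1]:
        b.label = "H"


def sweep(params: MechanisticParameters, S_grid: np.ndarray,
          n_starts: int = 16, seed: int = 0) -> PhaseDiagram:
    """Grid sweep with warm starts; returns the labelled phase diagram."""
    S_grid = np.asarray(S_grid, dtype=float)
    if S_grid.size < 2 or np.any(np.diff(S_grid) <= 0):
        raise ValueError("S_grid must be increasing with >= 2 points")
    all_branches: list[BifurcationBranch] = []
    open_branches: list[BifurcationBranch] = []
    per_S_states: list[list[SteadyState]] = []
    prev: list[SteadyState] = []
    for S in S_grid:
        ps = params.with_snail(S)
        extra = np.array([s.state for s in prev]) if prev else None
        found = find_steady_states(ps, n_starts=n_starts, seed=seed,
                                   extra_starts=extra)
        per_S_states.append(found)
        prev = found
        if not open_branches:
            for s in found:
                nb = BifurcationBranch(branch_id=len(all_branches),
                                       S_values=[S], states=[s])
                all_branches.append(nb)
                open_branches.append(nb)
        else:
            open_branches = _link(open_branches, found, S, all_branches)

    _label_branches(all_branches)

    label_of: dict[tuple[int, int], str] = {}
    for b in all_branches:
        for S_val, st in zip(b.S_values, b.states):
            if b.label and st.stable:
                i = int(np.argmin(np.abs(S_grid - S_val)))
                label_of[(i, id(st))] = b.label
    phases: list[frozenset[str]] = []
    counts = np.zeros(S_grid.size, dtype=int)
    for i, found in enumerate(per_S_states):
        labs = {label_of.get((i, id(s))) for s in found if s.stable}
        labs.discard(None)
        phases.append(frozenset(labs))
        counts[i] = sum(1 for s in found if s.stable)
    fold_points = [float(0.5 * (S_grid[i] + S_grid[i + 1]))
                   for i in range(S_grid.size - 1) if counts[i] != counts[i + 1]]
    return PhaseDiagram(S_grid=S_grid, phases=phases, fold_points=fold_points,
                        branches=all_branches, stable_counts=counts)


# ---------------------------------------------------------------------------
# Hybrid interval
# ---------------------------------------------------------------------------

def _h_state_near(params: MechanisticParameters, S: float,
                  warm: np.ndarray, seed: int = 0) -> bool:
    """Does a stable state continue from the warm start at this S?"""
    ss = find_steady_states(params.with_snail(S), n_starts=6, seed=seed,
                            extra_starts=np.atleast_2d(warm))
    warm_mz = max(warm[1], 1e-9)
    for s in ss:
        if s.stable and abs(np.log(max(s.mz, 1e-9)) - np.log(warm_mz)) < _LINK_LOG_TOL:
            return True
    return False


def hybrid_interval(diagram: PhaseDiagram,
                    params: MechanisticParameters | None = None,
                    refine_frac: float = 1e-3) -> tuple[float, float]:
    """SNAIL interval over which a stable hybrid state exists.

    Endpoints are taken from the grid and, when ``params`` is given,
    refined by bisection (continuation of the hybrid branch) to
    ``refine_frac`` of the grid span.  Returns (lo, hi); (0, 0)-length
    interval when no hybrid state exists anywhere.
    """
    S = diagram.S_grid
    has_h = np.array(["H" in p for p in diagram.phases])
    if not has_h.any():
        return (0.0, 0.0)
    idx = np.where(has_h)[0]
    lo_i, hi_i = int(idx[0]), int(idx[-1])
    lo, hi = float(S[lo_i]), float(S[hi_i])
    if params is None:
        return (lo, hi)

    span = float(S[-1] - S[0])
    tol = refine_frac * span
    h_branches = [b for b in diagram.branches if b.label == "H"]

    def warm_state(S_val: float) -> np.ndarray:
        best, bd = None, np.inf
        for b in h_branches:
            i = int(np.argmin(np.abs(np.asarray(b.S_values) - S_val)))
            d = abs(b.S_values[i] - S_val)
            if d < bd:
                bd, best = d, b.states[i].state
        return best

    # refine lower endpoint into [S[lo_i-1], S[lo_i]]
    if lo_i > 0:
        a, b_ = float(S[lo_i - 1]), lo
        w = warm_state(lo)
        while b_ - a > tol:
            mid = 0.5 * (a + b_)
            if _h_state_near(params, mid, w):
                b_ = mid
            else:
                a = mid
        lo = b_
    if hi_i < S.size - 1:
        a, b_ = hi, float(S[hi_i + 1])
        w = warm_state(hi)
        while b_ - a > tol:
            mid = 0.5 * (a + b_)
            if _h_state_near(params, mid, w):
                a = mid
            else:
                b_ = mid
        hi = a
    return (lo, hi)


def hybrid_interval_length(params: MechanisticParameters, S_grid: np.ndarray,
                           n_starts: int = 16, seed: int = 0,
                           refine: bool = True) -> float:
    d = sweep(params, S_grid, n_starts=n_starts, seed=seed)
    lo, hi = hybrid_interval(d, params if refine else None)
    return hi - lo


def _root_near(params: MechanisticParameters, S: float, warm: np.ndarray,
               log_tol: float = 0.5) -> SteadyState | None:
    """Stable root continuing the warm start (log-ZEB-mRNA continuity)."""
    ss = find_steady_states(params.with_snail(S), n_starts=0, seed=0,
                            extra_starts=np.atleast_2d(warm),
                            include_corners=False)
    warm_mz = max(warm[1], 1e-9)
    for s in ss:
        if s.stable and abs(np.log(max(s.mz, 1e-9)) - np.log(warm_mz)) < log_tol:
            return s
    return None


def hybrid_interval_continuation(params: MechanisticParameters,
                                 seed_state: np.ndarray, S_seed: float,
                                 S_min: float = 0.0, S_max: float = 500e3,
                                 dS: float = 5e3, refine_frac: float = 1e-3
                                 ) -> tuple[float, float]:
    """Hybrid interval by direct fold tracking of the hybrid branch.

    Marches the branch from ``(S_seed, seed_state)`` in both directions
    with warm-started root finding until the root is lost or jumps
    branches, then refines each fold by bisection.  Used by the
    sensitivity batch; a full grid sweep gives the same interval (tested)
    at many times the cost.
    """
    start = _root_near(params, S_seed, seed_state, log_tol=0.8)
    if start is None:
        return (0.0, 0.0)
    tol = refine_frac * (S_max - S_min)

    def march(direction: int) -> float:
        S, state = S_seed, start.state
        while True:
            S_next = S + direction * dS
            if not S_min <= S_next <= S_max:
                return float(np.clip(S_next, S_min, S_max))
            nxt = _root_near(params, S_next, state)
            if nxt is None:
                lo_, hi_ = (S, S_next) if direction > 0 else (S_next, S)
                good = state
                while hi_ - lo_ > tol:
                    mid = 0.5 * (lo_ + hi_)
                    cand = _root_near(params, mid, good)
                    if cand is not None:
                        good = cand.state
                        if direction > 0:
                            lo_ = mid
                        else:
                            hi_ = mid
                    else:
                        if direction > 0:
                            hi_ = mid
                        else:
                            lo_ = mid
                return lo_ if direction > 0 else hi_
            S, state = S_next, nxt.state

    return (march(-1), march(+1))


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class SensitivityReport:
    parameter: str
    direction: str  # "+10%" / "-10%"
    percent_change: float


def sensitivity(params: MechanisticParameters,
                core_params: MechanisticParameters | None = None,
                delta: float = 0.10,
                S_grid: np.ndarray | None = None,
                n_starts: int = 12, seed: int = 0) -> pd.DataFrame:
    """Percent change of the hybrid SNAIL interval under +/-delta on every
    continuous scalar parameter (Hill cooperativities excluded).

    The baseline interval comes from a full sweep; each perturbed interval
    is recomputed by fold continuation of the hybrid branch seeded from
    the baseline branch (a full sweep gives the same answer, tested, at
    many times the cost).  The returned frame carries one row per
    (parameter, direction); ``attrs['reference_percent']`` holds the
    core-vs-coupled reference change when ``core_params`` is given, and
    ``attrs['baseline_interval']`` the unperturbed interval.
    """
    if S_grid is None:
        S_grid = np.linspace(0.0, 500e3, 251)
    base_diag = sweep(params, S_grid, n_starts=n_starts, seed=seed)
    lo, hi = hybrid_interval(base_diag, params)
    if hi - lo <= 0:
        raise ValueError("baseline hybrid interval is empty")
    S_seed = 0.5 * (lo + hi)
    h_branches = [b for b in base_diag.branches if b.label == "H"]
    i_near = int(np.argmin(np.abs(np.asarray(h_branches[0].S_values) - S_seed)))
    seed_state = h_branches[0].states[i_near].state
    S_span = float(S_grid[-1] - S_grid[0])
    # measure the baseline with the same continuation estimator used for
    # the perturbations, so the 0% anchor is exact
    lo, hi = hybrid_interval_continuation(
        params, seed_state, S_seed, S_min=float(S_grid[0]),
        S_max=float(S_grid[0]) + 1.5 * S_span)
    base_len = hi - lo

    rows: list[SensitivityReport] = []
    directions = ((1.0, "0%"),) if delta == 0 else (
        (1 + delta, f"+{delta:.0%}"), (1 - delta, f"-{delta:.0%}"))
    for name in params.scalar_names():
        for sgn, tag in directions:
            p = params.copy()
            p.set_scalar(name, params.get_scalar(name) * sgn)
            try:
                plo, phi = hybrid_interval_continuation(
                    p, seed_state, S_seed, S_min=float(S_grid[0]),
                    S_max=float(S_grid[0]) + 1.5 * S_span)
                new_len = phi - plo
            except Exception:  # pathological perturbation
                logger.warning("perturbation %s %s failed", name, tag)
                new_len = 0.0
            if new_len <= 0:
                logger.warning("perturbation %s %s lost the hybrid branch",
                               name, tag)
            rows.append(SensitivityReport(
                parameter=name, direction=tag,
                percent_change=100.0 * (new_len - base_len) / base_len))

    out = pd.DataFrame([r.__dict__ for r in rows])
    out.attrs["baseline_interval"] = (lo, hi)
    if core_params is not None:
        core_len = hybrid_interval_length(core_params, S_grid,
                                          n_starts=n_starts, seed=seed)
        out.attrs["reference_percent"] = 100.0 * (core_len - base_len) / base_len
    return out
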