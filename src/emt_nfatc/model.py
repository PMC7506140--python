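"""Mechanistic ODE model of the coupled EMT-NFATc circuit.

State vector (molecules): miR-200 ``mu``, ZEB mRNA ``mz``, ZEB protein
``Z``, plus E-cadherin ``E`` and NFATc ``N`` in the coupled model.  SNAIL
is a clamped external input S.  Transcriptional and indirect edges act as
shifted Hill factors on production; the miR-200 -> ZEB-mRNA edge uses the
binding-site formalism: with ``M_i(mu)`` the probability of ``i`` occupied
sites, translation is scaled by ``L(mu) = sum_i l_i M_i``, mRNA active
degradation is ``Ym(mu) = sum_i gamma_m_i M_i`` and microRNA loss through
duplex formation is ``Ymu(mu) = sum_i i gamma_mu_i M_i``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from .params import (
    MechanisticParameters,
    MicroRnaCoupling,
    ParameterError,
    ShiftedHillBlock,
)

logger = logging.getLogger(__name__)

#: eigenvalue tolerance separating stable from unstable fixed points (1/h)
EPS_EIG = 1e-6
#: relative tolerance under which two roots are considered the same state
DEDUP_RTOL = 1e-2
#: molecule floor used in relative comparisons
LEVEL_FLOOR = 1.0


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last valid time point."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


# ---------------------------------------------------------------------------
# Regulation primitives
# ---------------------------------------------------------------------------

def shifted_hill(level: float | np.ndarray, block: ShiftedHillBlock
                 ) -> float | np.ndarray:
    """Shifted Hill factor ``H- + lam * H+``: 1 at zero regulator,
    ``(1+lam)/2`` at the threshold, ``lam`` at saturation."""
    if not (block.threshold > 0 and block.cooperativity >= 1):
        raise ParameterError("invalid Hill block")
    x = np.asarray(level, dtype=float)
    if np.any(x < 0):
        raise ValueError("regulator level must be non-negative")
    p = (x / block.threshold) ** block.cooperativity
    out = (1.0 + block.fold_change * p) / (1.0 + p)
    return float(out) if np.isscalar(level) else out


def mirna_site_occupancy(mu: float, coupling: MicroRnaCoupling, i: int) -> float:
    """Probability ``M_i(mu)`` that exactly ``i`` of the binding sites are
    occupied (binomial occupancy with per-site ratio mu/mu0)."""
    n = coupling.n_sites
    if not 0 <= i <= n:
        raise IndexError(f"site count {i} out of range 0..{n}")
    return float(_occupancies(mu, coupling)[i])


def _occupancies(mu: float, c: MicroRnaCoupling) -> np.ndarray:
    # binomial in q = r/(1+r) with r = mu/mu0; stable for arbitrarily large mu
    n = c.n_sites
    r = mu / c.mu0
    q = r / (1.0 + r)
    return np.array([comb(n, i) * q**i * (1.0 - q) ** (n - i)
                     for i in range(n + 1)])


def mirna_translation_factor(mu: float, c: MicroRnaCoupling) -> float:
    """L(mu): fraction of full translation rate retained."""
    return float(np.dot(np.asarray(c.l), _occupancies(mu, c)))


def mirna_mrna_degradation(mu: float, c: MicroRnaCoupling) -> float:
    """Ym(mu): microRNA-dependent active mRNA degradation rate (1/h)."""
    return float(np.dot(np.asarray(c.gamma_m), _occupancies(mu, c)))


def mirna_mirna_loss(mu: float, c: MicroRnaCoupling) -> float:
    """Ymu(mu): per-mRNA microRNA consumption rate through duplexes (1/h)."""
    i = np.arange(c.n_sites + 1)
    return float(np.dot(i * np.asarray(c.gamma_mu), _occupancies(mu, c)))


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _hill_or_inert(params: MechanisticParameters, key: tuple[str, str],
                   level: float) -> float:
    block = params.hill.get(key)
    return 1.0 if block is None else shifted_hill(level, block)


def rhs(state: np.ndarray, params: MechanisticParameters) -> np.ndarray:
    """Time derivatives (molecules/h) of the mechanistic state vector."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(params.species),):
        raise ParameterError(
            f"state must have {len(params.species)} components {params.species}"
        )
    g, k = params.production, params.degradation
    S = params.snail
    coupled = params.is_coupled
    mu, mz, Z = state[0], state[1], state[2]
    E = state[3] if coupled else 0.0
    N = state[4] if coupled else 0.0

    h_mu = (shifted_hill(S, params.hill[("SNAIL", "miR200")])
            * shifted_hill(Z, params.hill[("ZEB", "miR200")]))
    h_mz = (shifted_hill(S, params.hill[("SNAIL", "ZEB")])
            * shifted_hill(Z, params.hill[("ZEB", "ZEB")]))
    if coupled:
        h_mu *= _hill_or_inert(params, ("NFATc", "miR200"), N)
        h_mz *= (_hill_or_inert(params, ("NFATc", "ZEB"), N)
                 * _hill_or_inert(params, ("Ecad", "ZEB"), E))

    if params.mirna_mode == "binding_site":
        c = params.mirna
        L = mirna_translation_factor(mu, c)
        Ym = mirna_mrna_degradation(mu, c)
        Ymu = mirna_mirna_loss(mu, c)
        d_mu = g["mu"] * h_mu - mz * Ymu - k["mu"] * mu
        d_mz = g["mz"] * h_mz - mz * Ym - k["mz"] * mz
        d_Z = g["Z"] * mz * L - k["Z"] * Z
    else:  # plain shifted-Hill silencing through the mirna edge's block
        h_sil = shifted_hill(mu, params.hill[("miR200", "ZEB")])
        d_mu = g["mu"] * h_mu - k["mu"] * mu
        d_mz = g["mz"] * h_mz * h_sil - k["mz"] * mz
        d_Z = g["Z"] * mz - k["Z"] * Z

    if not coupled:
        return np.array([d_mu, d_mz, d_Z])

    h_E = (_hill_or_inert(params, ("ZEB", "Ecad"), Z)
           * _hill_or_inert(params, ("NFATc", "Ecad"), N))
    d_E = g["E"] * h_E - k["E"] * E
    d_N = g["N"] - k["N"] * N  # constitutive
    return np.array([d_mu, d_mz, d_Z, d_E, d_N])


def jacobian(state: np.ndarray, params: MechanisticParameters,
             rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`rhs`."""
    state = np.asarray(state, dtype=float)
    n = state.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(state[j]), LEVEL_FLOOR)
        xp, xm = state.copy(), state.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (rhs(xp, params) - rhs(xm, params)) / (xp[j] - xm[j])
    return J


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Deterministic trajectory; ``states`` rows align with ``times``."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species: tuple[str, ...]
    snail: float

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def component(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]


def simulate(initial: np.ndarray, params: MechanisticParameters, t_max: float,
             n_points: int = 500, rtol: float = 1e-8, atol: float = 1e-6
             ) -> Trajectory:
    """Integrate the model with a stiff-capable adaptive solver (LSODA)."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    initial = np.asarray(initial, dtype=float)
    t_eval = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(lambda t, y: rhs(np.maximum(y, 0.0), params),
                    (0.0, t_max), initial, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}",
                               t_last=sol.t[-1] if sol.t.size else 0.0,
                               state_last=sol.y[:, -1] if sol.t.size else initial)
    return Trajectory(times=sol.t, states=np.maximum(sol.y.T, 0.0),
                      species=params.species, snail=params.snail)


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyState:
    """Equilibrium with a linear-stability tag."""

    state: np.ndarray
    stable: bool
    leading_eigenvalue: float  # largest real part, 1/h
    species: tuple[str, ...]

    @property
    def mz(self) -> float:
        return float(self.state[self.species.index("mz")])

    @property
    def mu(self) -> float:
        return float(self.state[self.species.index("mu")])


def state_scales(params: MechanisticParameters) -> np.ndarray:
    """Upper-bound level per species: g/k times the maximal Hill boost
    (ZEB protein scales with the maximal mRNA level times translation)."""
    g, k = params.production, params.degradation

    def boost(target: str) -> float:
        b = 1.0
        for (src, tgt), block in params.hill.items():
            if tgt == target:
                b *= max(1.0, block.fold_change)
        return b

    mu_max = g["mu"] / k["mu"] * boost("miR200")
    mz_max = g["mz"] / k["mz"] * boost("ZEB")
    z_max = g["Z"] * mz_max / k["Z"]
    scales = [mu_max, mz_max, z_max]
    if params.is_coupled:
        scales.append(g["E"] / k["E"] * boost("Ecad"))
        scales.append(g["N"] / k["N"])
    return np.array(scales)


def _is_duplicate(a: np.ndarray, b: np.ndarray, rtol: float = DEDUP_RTOL) -> bool:
    ref = np.maximum(np.maximum(np.abs(a), np.abs(b)), LEVEL_FLOOR)
    return bool(np.max(np.abs(a - b) / ref) < rtol)


def classify_stability(state: np.ndarray, params: MechanisticParameters
                       ) -> SteadyState:
    lead = float(np.max(np.real(np.linalg.eigvals(jacobian(state, params)))))
    return SteadyState(state=np.asarray(state, float), stable=lead < -EPS_EIG,
                       leading_eigenvalue=lead, species=params.species)


def find_steady_states(params: MechanisticParameters, n_starts: int = 24,
                       seed: int | None = 0,
                       extra_starts: np.ndarray | None = None,
                       residual_tol: float = 1e-6,
                       include_corners: bool = True) -> list[SteadyState]:
    """Multi-start root finding on :func:`rhs`.

    Starts are log-uniform over ``[1e-2, 1.2]`` times each species' scale;
    ``extra_starts`` (e.g. warm starts from a neighbouring SNAIL value) are
    tried first.  Roots are deduplicated at 1% relative tolerance, tagged
    by the Jacobian's leading eigenvalue and returned sorted by ZEB mRNA.
    """
    if n_starts < 1 and (extra_starts is None or not len(extra_starts)):
        raise ValueError("n_starts must be >= 1 without extra starts")
    scales = state_scales(params)
    rng = np.random.default_rng(seed)
    lo, hi = np.log(1e-2 * scales), np.log(1.2 * scales)
    starts = np.exp(rng.uniform(lo, hi, size=(max(n_starts, 0), scales.size)))
    if include_corners:
        # deterministic archetype starts: epithelial-like (miR-200 high,
        # rest low), mesenchymal-like, plus a mid-level point
        corners = np.array([
            np.where(np.arange(scales.size) == 0, scales, 1e-2 * scales),
            np.where(np.arange(scales.size) == 0, 1e-2 * scales, scales),
            0.1 * scales,
        ])
        starts = np.vstack([corners, starts])
    if extra_starts is not None and len(extra_starts):
        starts = np.vstack([np.atleast_2d(extra_starts), starts])

    # root finding in log coordinates with degradation-normalised residuals:
    # well-scaled across species spanning several decades, positivity free
    k_rate = params_rate_scale(params)

    def g(u: np.ndarray) -> np.ndarray:
        x = np.exp(np.clip(u, -60.0, 60.0))
        return rhs(x, params) / (k_rate * x)

    roots: list[np.ndarray] = []
    for x0 in starts:
        u0 = np.log(np.maximum(x0, 1e-12))
        sol = _scipy_root(g, u0, method="hybr", options={"xtol": 1e-12})
        if not sol.success:
            continue
        x = np.exp(np.clip(sol.x, -60.0, 60.0))
        if np.max(np.abs(g(sol.x))) > residual_tol:
            continue
        if not any(_is_duplicate(x, r) for r in roots):
            roots.append(x)
    if not roots:
        logger.warning("no steady state found from any start (S=%g)", params.snail)
        return []
    out = [classify_stability(x, params) for x in roots]
    out.sort(key=lambda ss: ss.mz)
    return out


def params_rate_scale(params: MechanisticParameters) -> np.ndarray:
    """Per-species degradation rates, used to normalise rhs residuals."""
    k = params.degradation
    return np.array([k[sp] for sp in params.species])
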