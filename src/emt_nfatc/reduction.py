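"""Quasi-steady-state reduction to two variables (ZEB protein, miR-200).

ZEB mRNA turns over much faster than ZEB protein and miR-200, and
E-cadherin and NFATc relax quickly to levels slaved to ZEB; setting their
time derivatives to zero closes the system to two coupled ODEs:

    N* = g_N / k_N
    E*(Z) = g_E H(Z) H(N*) / k_E
    m_Z*(Z, mu) = g_mz H(Z) H(S) H(N*) H(E*(Z)) / (k_mz + Ym(mu))
    dZ/dt  = g_Z m_Z* L(mu) - k_Z Z
    dmu/dt = g_mu H(Z) H(S) H(N*) - m_Z* Ymu(mu) - k_mu mu

Fixed points of the reduced drift, lifted through the closures, are fixed
points of the full model exactly (the closures are the equilibrium
conditions of the eliminated variables).

The drift is also exported as a packed parameter vector consumed by the
numba kernels in :mod:`emt_nfatc.stochastic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root as _scipy_root

from .model import (
    DEDUP_RTOL,
    classify_stability,
    mirna_mirna_loss,
    mirna_mrna_degradation,
    mirna_translation_factor,
    shifted_hill,
    state_scales,
)
from .params import MechanisticParameters, ParameterError


@dataclass
class ReducedSystem:
    """2-D drift in (Z, mu) plus the algebraic closures."""

    params: MechanisticParameters

    def __post_init__(self) -> None:
        p = self.params
        if p.mirna_mode != "binding_site":
            raise ParameterError("QSS reduction requires the binding-site "
                                 "microRNA formalism")
        g, k = p.production, p.degradation
        self.N_star = g["N"] / k["N"] if p.is_coupled else 0.0
        S = p.snail
        # constant SNAIL/NFATc factors
        self._a_mu = g["mu"] * shifted_hill(S, p.hill[("SNAIL", "miR200")])
        self._a_mz = g["mz"] * shifted_hill(S, p.hill[("SNAIL", "ZEB")])
        if p.is_coupled:
            self._a_mu *= shifted_hill(self.N_star, p.hill[("NFATc", "miR200")])
            self._a_mz *= shifted_hill(self.N_star, p.hill[("NFATc", "ZEB")])
            self._e_base = (g["E"] / k["E"]
                            * shifted_hill(self.N_star, p.hill[("NFATc", "Ecad")]))
        else:
            self._e_base = 0.0

    # ---- closures ------------------------------------------------------
    def E_star(self, Z: float) -> float:
        p = self.params
        if not p.is_coupled:
            return 0.0
        return self._e_base * shifted_hill(Z, p.hill[("ZEB", "Ecad")])

    def mz_star(self, Z: float, mu: float) -> float:
        p = self.params
        prod = self._a_mz * shifted_hill(Z, p.hill[("ZEB", "ZEB")])
        if p.is_coupled:
            prod *= shifted_hill(self.E_star(Z), p.hill[("Ecad", "ZEB")])
        return prod / (p.degradation["mz"] + mirna_mrna_degradation(mu, p.mirna))

    # ---- drift ---------------------------------------------------------
    def drift(self, Z: float, mu: float) -> tuple[float, float]:
        p = self.params
        g, k = p.production, p.degradation
        mz = self.mz_star(Z, mu)
        dZ = g["Z"] * mz * mirna_translation_factor(mu, p.mirna) - k["Z"] * Z
        dmu = (self._a_mu * shifted_hill(Z, p.hill[("ZEB", "miR200")])
               - mz * mirna_mirna_loss(mu, p.mirna) - k["mu"] * mu)
        return dZ, dmu

    def lift(self, Z: float, mu: float) -> np.ndarray:
        """Embed a reduced point into the full state space via the closures."""
        p = self.params
        mz = self.mz_star(Z, mu)
        if p.is_coupled:
            return np.array([mu, mz, Z, self.E_star(Z), self.N_star])
        return np.array([mu, mz, Z])

    # ---- fixed points --------------------------------------------------
    def fixed_points(self, n_starts: int = 40, seed: int = 0) -> list:
        """Multi-start root finding on the reduced drift; returns full-model
        :class:`~emt_nfatc.model.SteadyState` objects (lifted), sorted by
        ZEB protein level."""
        p = self.params
        scales = state_scales(p)
        z_scale, mu_scale = scales[2], scales[0]
        rng = np.random.default_rng(seed)
        lo = np.log([1e-2 * z_scale, 1e-2 * mu_scale])
        hi = np.log([1.2 * z_scale, 1.2 * mu_scale])
        starts = list(np.exp(rng.uniform(lo, hi, size=(n_starts, 2))))
        starts += [np.array([1e-2 * z_scale, mu_scale]),
                   np.array([z_scale, 1e-2 * mu_scale]),
                   np.array([0.1 * z_scale, 0.1 * mu_scale])]
        k_rate = np.array([p.degradation["Z"], p.degradation["mu"]])

        def g(u: np.ndarray) -> np.ndarray:
            x = np.exp(np.clip(u, -60.0, 60.0))
            return np.array(self.drift(x[0], x[1])) / (k_rate * x)

        pts: list[np.ndarray] = []
        for x0 in starts:
            sol = _scipy_root(g, np.log(np.maximum(x0, 1e-12)),
                              method="hybr", options={"xtol": 1e-12})
            if not sol.success:
                continue
            x = np.exp(np.clip(sol.x, -60.0, 60.0))
            if np.max(np.abs(g(sol.x))) > 1e-6:
                continue
            if not any(np.max(np.abs(x - q) / np.maximum(np.maximum(x, q), 1.0))
                       < DEDUP_RTOL for q in pts):
                pts.append(x)
        out = [classify_stability(self.lift(Z, mu), p) for Z, mu in pts]
        out.sort(key=lambda ss: float(ss.state[2]))
        return out


def qss_reduce(params: MechanisticParameters) -> ReducedSystem:
    """Build the 2-D reduced system for a parameter set (core or coupled)."""
    return ReducedSystem(params)


# ---------------------------------------------------------------------------
# Packed parameter vector for the numba kernels
# ---------------------------------------------------------------------------
# Layout (floats):
#  0 a_mu, 1 k_mu, 2 a_mz, 3 k_mz, 4 g_Z, 5 k_Z,
#  6 mu0, 7 n_sites,
#  8..8+n l, next n+1 gamma_m, next n+1 gamma_mu,
#  then 4 hill blocks (A0, n, lam) in order:
#    ZEB->ZEB, ZEB->miR200, ZEB->Ecad, Ecad->ZEB,
#  then e_base (g_E/k_E * NFATc factor; 0 disables the E-cad loop)

def pack_reduced(system: ReducedSystem) -> np.ndarray:
    p = system.params
    c = p.mirna
    n = c.n_sites
    vec = [system._a_mu, p.degradation["mu"], system._a_mz, p.degradation["mz"],
           p.production["Z"], p.degradation["Z"], c.mu0, float(n)]
    vec += list(c.l) + list(c.gamma_m) + list(c.gamma_mu)
    for key in (("ZEB", "ZEB"), ("ZEB", "miR200")):
        b = p.hill[key]
        vec += [b.threshold, float(b.cooperativity), b.fold_change]
    if p.is_coupled:
        for key in (("ZEB", "Ecad"), ("Ecad", "ZEB")):
            b = p.hill[key]
            vec += [b.threshold, float(b.cooperativity), b.fold_change]
        vec.append(system._e_base)
    else:
        vec += [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0]
    return np.asarray(vec, dtype=np.float64)
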