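"""Numba-compiled kernels: reduced-model drift, Euler-Maruyama paths,
deterministic basin relaxation, and the random-parameter ensemble solver.

All kernels consume flat float64 parameter vectors so they stay nopython-
compatible; packing lives in :mod:`emt_nfatc.reduction` and
:mod:`emt_nfatc.ensemble`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# drift selector codes
DRIFT_EMT = 0
DRIFT_DOUBLE_WELL = 1


@njit(cache=True, inline="always")
def _hill(x, A0, n, lam):
    r = x / A0
    p = 1.0
    for _ in range(n):
        p *= r
    return (1.0 + lam * p) / (1.0 + p)


@njit(cache=True)
def _drift_emt(th, Z, mu):
    """Reduced (Z, mu) drift; see reduction.pack_reduced for the layout."""
    a_mu = th[0]
    k_mu = th[1]
    a_mz = th[2]
    k_mz = th[3]
    g_Z = th[4]
    k_Z = th[5]
    mu0 = th[6]
    n = int(th[7])
    base = 8
    # binomial site occupancies, iterated to avoid large powers
    r = mu / mu0
    q = r / (1.0 + r)
    one_q = 1.0 - q
    M = one_q**n
    ratio = 0.0 if one_q == 0.0 else q / one_q
    L = 0.0
    Ym = 0.0
    Ymu = 0.0
    for i in range(n + 1):
        L += th[base + i] * M
        Ym += th[base + (n + 1) + i] * M
        Ymu += i * th[base + 2 * (n + 1) + i] * M
        M *= ratio * (n - i) / (i + 1.0)
    hb = base + 3 * (n + 1)
    h_zz = _hill(Z, th[hb], int(th[hb + 1]), th[hb + 2])
    h_zmu = _hill(Z, th[hb + 3], int(th[hb + 4]), th[hb + 5])
    e_base = th[hb + 12]
    fe = 1.0
    if e_base > 0.0:
        E = e_base * _hill(Z, th[hb + 6], int(th[hb + 7]), th[hb + 8])
        fe = _hill(E, th[hb + 9], int(th[hb + 10]), th[hb + 11])
    mzs = a_mz * h_zz * fe / (k_mz + Ym)
    dZ = g_Z * mzs * L - k_Z * Z
    dmu = a_mu * h_zmu - mzs * Ymu - k_mu * mu
    return dZ, dmu


@njit(cache=True)
def _drift_double_well(th, x, y):
    """Symmetric double well in x (wells th[0]+-th[1], quartic stiffness
    th[2]) with linear relaxation of y to th[3] at rate th[4]."""
    u = x - th[0]
    w2 = th[1] * th[1]
    dx = -th[2] * u * (u * u - w2)
    dy = -th[4] * (y - th[3])
    return dx, dy


@njit(cache=True)
def _drift(kind, th, x, y):
    if kind == 0:
        return _drift_emt(th, x, y)
    return _drift_double_well(th, x, y)


@njit(cache=True)
def em_path(kind, th, x0, y0, dt, n_steps, sig_x, sig_y, seed, record_every):
    """Euler-Maruyama path with reflection at 0; records every
    ``record_every`` steps (the initial point included)."""
    np.random.seed(seed)
    n_rec = n_steps // record_every + 1
    out = np.empty((n_rec, 2))
    x = x0
    y = y0
    out[0, 0] = x
    out[0, 1] = y
    sdt = np.sqrt(dt)
    idx = 1
    for t in range(1, n_steps + 1):
        dx, dy = _drift(kind, th, x, y)
        x = x + dx * dt + sig_x * sdt * np.random.normal()
        y = y + dy * dt + sig_y * sdt * np.random.normal()
        if x < 0.0:
            x = -x
        if y < 0.0:
            y = -y
        if t % record_every == 0:
            out[idx, 0] = x
            out[idx, 1] = y
            idx += 1
    return out


@njit(cache=True)
def relax_to_attractor(kind, th, x0, y0, dt, max_steps, attr_x, attr_y, log_radius):
    """Deterministic (sigma=0) relaxation; returns the index of the
    attractor whose log-space ball of ``log_radius`` is entered first,
    or -1 if none is reached within ``max_steps``."""
    x = x0
    y = y0
    n_attr = attr_x.size
    for t in range(max_steps):
        dx, dy = _drift(kind, th, x, y)
        # clamp the step to 20% of the level so stiff regions stay stable
        # (only the basin membership matters here, not the time course)
        fac = 1.0
        fx = abs(dx) * dt / (0.2 * (abs(x) + 1.0))
        fy = abs(dy) * dt / (0.2 * (abs(y) + 1.0))
        if fx > fac:
            fac = fx
        if fy > fac:
            fac = fy
        x += dx * dt / fac
        y += dy * dt / fac
        if x < 1e-12:
            x = 1e-12
        if y < 1e-12:
            y = 1e-12
        if t % 20 == 0 or t == max_steps - 1:
            for a in range(n_attr):
                dlx = np.log(x / attr_x[a])
                dly = np.log(y / attr_y[a])
                if dlx * dlx + dly * dly < log_radius * log_radius:
                    return a
    return -1


@njit(cache=True)
def basin_grid(kind, th, gx, gy, dt, max_steps, attr_x, attr_y, log_radius):
    """Basin label for every (gx[i], gy[j]) grid point."""
    nx = gx.size
    ny = gy.size
    lab = np.empty((nx, ny), dtype=np.int64)
    for i in range(nx):
        for j in range(ny):
            lab[i, j] = relax_to_attractor(kind, th, gx[i], gy[j], dt,
                                           max_steps, attr_x, attr_y,
                                           log_radius)
    return lab


# ---------------------------------------------------------------------------
# Random-parameter ensemble solver (all-Hill dynamics, any topology)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _ens_rhs(x, g, k, esrc, etgt, elam, en, ea0, out):
    n_nodes = g.size
    for j in range(n_nodes):
        out[j] = g[j]
    for e in range(esrc.size):
        out[etgt[e]] *= _hill(x[esrc[e]], ea0[e], en[e], elam[e])
    for j in range(n_nodes):
        out[j] -= k[j] * x[j]


@njit(cache=True)
def ensemble_relax(x0, g, k, esrc, etgt, elam, en, ea0,
                   dt, max_steps, check_every, rel_tol):
    """Euler relaxation to a fixed point; returns (state, converged)."""
    n = g.size
    x = x0.copy()
    f = np.empty(n)
    for t in range(max_steps):
        _ens_rhs(x, g, k, esrc, etgt, elam, en, ea0, f)
        for j in range(n):
            x[j] += dt * f[j]
            if x[j] < 0.0:
                x[j] = 0.0
        if (t + 1) % check_every == 0:
            ok = True
            for j in range(n):
                ref = k[j] * (x[j] if x[j] > 1.0 else 1.0)
                if abs(f[j]) > rel_tol * ref:
                    ok = False
                    break
            if ok:
                return x, True
    return x, False


@njit(cache=True)
def ensemble_solve_model(ics, g, k, esrc, etgt, elam, en, ea0,
                         dt, max_steps, check_every, rel_tol):
    """Relax every initial condition; returns (endpoints, converged flags)."""
    n_ic = ics.shape[0]
    n = g.size
    out = np.empty((n_ic, n))
    conv = np.zeros(n_ic, dtype=np.bool_)
    for i in range(n_ic):
        x, ok = ensemble_relax(ics[i], g, k, esrc, etgt, elam, en, ea0,
                               dt, max_steps, check_every, rel_tol)
        out[i] = x
        conv[i] = ok
    return out, conv
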