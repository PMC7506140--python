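"""End-to-end reproduction pipeline at configurable scale.

Runs the stages in dependency order (fixtures -> bifurcation ->
delayed-EMT comparison -> residence times / landscapes -> ensemble ->
randomization -> relative stability), writes each stage's outputs under
the run directory, and aggregates the headline qualitative comparisons
into ``summary.json``.  Identical seed and scale give identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import hybrid_interval, sweep
from .ensemble import (
    EnsembleConfig,
    phase_frequencies,
    relative_stability,
    run_ensemble,
    stability_frame,
)
from .fixtures import generate_fixtures
from .model import find_steady_states, simulate
from .params import default_core_parameters, default_coupled_parameters
from .randomization import compare_phase_fractions, enumerate_randomized
from .reduction import qss_reduce
from .stochastic import (
    build_basin_grid,
    coarse_grain,
    default_sigma,
    emt_drift,
    euler_maruyama,
    mean_residence_time,
    quasi_potential,
)
from .topology import core_emt, wildtype_coupled

logger = logging.getLogger(__name__)

SCALES = {
    # n_models, replicates, rand_subsample, rand_models, em_steps, seeds
    "desk": dict(n_models=1000, replicates=3, rand_subsample=12,
                 rand_models=800, em_steps=20_000_000, em_seeds=4,
                 s_points=151, stability_models=25),
    "full": dict(n_models=10_000, replicates=3, rand_subsample=None,
                 rand_models=10_000, em_steps=10_000_000, em_seeds=10,
                 s_points=251, stability_models=None),
    # smoke-test sizes: exercises every stage in about a minute
    "micro": dict(n_models=40, replicates=2, rand_subsample=2,
                  rand_models=40, em_steps=200_000, em_seeds=2,
                  s_points=60, stability_models=3),
}


def mz_band_threshold(diagram) -> float:
    """ZEB-mRNA level above which a state counts as mesenchymal: the top
    of the hybrid branch (its level at the fold where it disappears), the
    highest fold value of the diagram.  Falls back to the top of the
    epithelial branch when no hybrid branch exists."""
    for label in ("H", "E"):
        branches = [b for b in diagram.branches if b.label == label]
        if branches:
            return max(st.mz for b in branches for st in b.states)
    return np.inf


def time_to_band(params_factory, snail: float, threshold: float,
                 t_max: float = 3000.0) -> float:
    """Hours until ZEB mRNA first exceeds ``threshold`` from the model's
    own epithelial state; inf when the band is never entered."""
    p0 = params_factory(0.0)
    e0 = [s for s in find_steady_states(p0, seed=0) if s.stable][0].state
    tr = simulate(e0, params_factory(snail), t_max=t_max, n_points=2000)
    mz = tr.component("mz")
    hit = np.nonzero(mz >= threshold)[0]
    return float(tr.times[hit[0]]) if hit.size else float("inf")


def landscape_at(params, *, em_steps: int, em_seeds: int, seed: int,
                 labels_by_count={1: ["E"], 2: ["H", "M"], 3: ["E", "H", "M"]}):
    """Residence times and barriers at one SNAIL level.

    Runs start alternately in each basin.  Each state's barrier is
    estimated from the runs that started in its own basin (the escape
    barrier a la Kramers): pooling runs across basins would weight the
    wells by the arbitrary start allocation rather than by dynamics when
    transitions are rare.  Residence times pool all runs."""
    system = qss_reduce(params)
    fps = system.fixed_points(seed=1)
    att = np.array([[s.state[2], s.state[0]] for s in fps if s.stable])
    labels = labels_by_count[len(att)]
    drift = emt_drift(system)
    sig = default_sigma(att, labels=labels)
    runs_by_start: dict[int, list] = {}
    bg = None
    mrt_acc: dict[str, list[float]] = {}
    for i in range(em_seeds):
        start = i % len(att)
        run = euler_maruyama(drift, tuple(att[start]), dt=0.01,
                             n_steps=em_steps, sigma=sig, seed=seed + i,
                             record_every=50)
        runs_by_start.setdefault(start, []).append(run)
        if bg is None:
            bg = build_basin_grid(drift, att, path=run.path, n_cells=60)
        for state, vals in mean_residence_time(
                coarse_grain(run, bg, labels)).items():
            mrt_acc.setdefault(state, []).append(vals["mrt"])
    barriers = {}
    for start, runs in runs_by_start.items():
        field = quasi_potential(runs, att, labels, n_cells=100)
        barriers[labels[start]] = float(field.barriers[labels[start]])
    return ({k: float(np.mean(v)) for k, v in mrt_acc.items()}, barriers)


def run_pipeline(out_dir: str | Path, seed: int = 1729,
                 scale: str = "desk") -> dict:
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    cfg = SCALES[scale]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict = {"seed": seed, "scale": scale, "version": __version__,
                     "stages": {}, "headline": {}}

    def stage(name):
        logger.info("stage: %s", name)
        summary["stages"][name] = {"t": round(time.time() - t_start, 1)}
        d = out / name
        d.mkdir(exist_ok=True)
        return d

    # 1. fixtures ---------------------------------------------------------
    d = stage("fixtures")
    generate_fixtures(d, master_seed=seed, force=True)

    # 2. bifurcation ------------------------------------------------------
    d = stage("bifurcation")
    grid = np.linspace(0.0, 500e3, cfg["s_points"])
    coupled_p = default_coupled_parameters()
    core_p = default_core_parameters()
    diag_c = sweep(coupled_p, grid, seed=seed)
    diag_k = sweep(core_p, grid, seed=seed)
    int_c = hybrid_interval(diag_c, coupled_p)
    int_k = hybrid_interval(diag_k, core_p)
    for tag, diag in (("coupled", diag_c), ("core", diag_k)):
        diag.branches_frame().to_csv(d / f"branches_{tag}.csv", index=False)
        diag.to_frame().to_csv(d / f"phases_{tag}.csv", index=False)
    summary["headline"]["hybrid_interval_coupled"] = list(int_c)
    summary["headline"]["hybrid_interval_core"] = list(int_k)
    summary["headline"]["hybrid_interval_comparison"] = (
        "coupled > core" if int_c[1] - int_c[0] > int_k[1] - int_k[0]
        else "core >= coupled")

    # 3. delayed EMT ------------------------------------------------------
    stage("delayed_emt")
    thr_core = mz_band_threshold(diag_k)
    thr_coupled = mz_band_threshold(diag_c)
    t_core = time_to_band(default_core_parameters, 330e3, thr_core)
    t_coupled = time_to_band(default_coupled_parameters, 330e3, thr_coupled)
    summary["headline"]["time_to_M_core_h"] = t_core
    summary["headline"]["time_to_M_coupled_h"] = (
        "inf" if np.isinf(t_coupled) else t_coupled)
    summary["headline"]["emt_delayed_by_nfatc"] = bool(t_coupled > t_core)

    # 4. residence times and landscapes -----------------------------------
    d = stage("landscape")
    rows = []
    for tag, pf, s_values in (
            ("coupled", default_coupled_parameters, (323e3, 330e3, 380e3)),
            ("core", default_core_parameters, (230e3, 245e3, 260e3))):
        for S in s_values:
            mrt, barriers = landscape_at(pf(S), em_steps=cfg["em_steps"],
                                         em_seeds=cfg["em_seeds"], seed=seed)
            rows.append({"model": tag, "S": S, **{f"mrt_{k}": v for k, v in mrt.items()},
                         **{f"barrier_{k}": v for k, v in barriers.items()}})
    land = pd.DataFrame(rows)
    land.to_csv(d / "landscape.csv", index=False)
    cl = land[land.model == "coupled"].set_index("S")
    summary["headline"]["barrier_H_gt_M_at_323k"] = bool(
        cl.loc[323e3, "barrier_H"] > cl.loc[323e3, "barrier_M"])
    summary["headline"]["barrier_M_gt_H_at_380k"] = bool(
        cl.loc[380e3, "barrier_M"] > cl.loc[380e3, "barrier_H"])

    # 5. ensemble ---------------------------------------------------------
    d = stage("ensemble")
    config = EnsembleConfig(n_models=cfg["n_models"], replicates=cfg["replicates"],
                            seed=seed)
    table = phase_frequencies([core_emt(), wildtype_coupled()], config)
    table.to_csv(d / "phase_frequencies.csv", index=False)
    get = lambda name, ph: float(
        table[(table.topology == name) & (table.phase == ph)]["mean"].iloc[0])
    summary["headline"]["EH_coupled_minus_core"] = get("coupled", "EH") - get("core", "EH")
    summary["headline"]["EHM_coupled_minus_core"] = get("coupled", "EHM") - get("core", "EHM")

    # 6. randomization ----------------------------------------------------
    d = stage("randomization")
    rset = enumerate_randomized(wildtype_coupled())
    rcfg = EnsembleConfig(n_models=cfg["rand_models"], seed=seed)
    res = compare_phase_fractions(rset, "EHM", rcfg,
                                  subsample=cfg["rand_subsample"])
    res.fractions.to_csv(d / "fractions_EHM.csv", index=False)
    summary["headline"]["n_randomized_networks"] = len(rset)
    summary["headline"]["wildtype_EHM_percentile"] = res.percentile

    # 7. relative stability ----------------------------------------------
    d = stage("stability")
    models = run_ensemble(wildtype_coupled(), cfg["n_models"], 100, seed=seed)
    multis = [m for m in models if m.phase in ("EH", "HM", "EHM")]
    cap = cfg["stability_models"]
    if cap is not None:
        multis = multis[:cap]
    records = relative_stability(wildtype_coupled(), multis,
                                 n_initial_conditions=1000, seed=seed)
    sf = stability_frame(records)
    sf.to_csv(d / "stability.csv", index=False)
    hm = sf[sf.phase == "HM"].groupby("model_id")[["n_H", "n_M"]].mean()
    if len(hm):
        summary["headline"]["HM_models_H_wins"] = int((hm.n_H > hm.n_M).sum())
        summary["headline"]["HM_models_M_wins"] = int((hm.n_M > hm.n_H).sum())

    summary["runtime_s"] = round(time.time() - t_start, 1)
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
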