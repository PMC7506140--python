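"""Random-circuit-perturbation ensemble analysis.

For a fixed topology, an ensemble of ODE models is generated by sampling
kinetic parameters (production, degradation, and one shifted-Hill block
per edge); every species — including SNAIL and miR-200 — is an ordinary
dynamical node here, unlike the mechanistic model.  Each model is relaxed
from many log-uniform initial conditions to collect its stable states;
states are pooled per ensemble, z-scored on log2 levels, and labelled
epithelial / hybrid / mesenchymal from the ZEB and miR-200 z-scores:

    z_zeb > 0, z_mir200 < 0  ->  M
    z_zeb > 0, z_mir200 > 0  ->  H
    z_zeb < 0, z_mir200 > 0  ->  E
    z_zeb < 0, z_mir200 < 0  ->  unlabelled (reported separately)

A model's *phase* is the set of labels of its stable states ({E}, {E,H},
{E,H,M}, ...).  Phase frequencies over replicate ensembles, and the
relative-stability (basin size) analysis over random initial conditions,
reproduce the published ensemble statistics pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _kernels
from .topology import ACTIVATION, NetworkTopology

logger = logging.getLogger(__name__)

PHASES = ("E", "H", "M", "EM", "EH", "HM", "EHM")
ZEB_NODE = "ZEB"
MIR_NODE = "miR200"

# sampling ranges of the random-circuit-perturbation method
G_RANGE = (1.0, 100.0)
K_RANGE = (0.1, 1.0)
LAMBDA_RANGE = (1.0, 100.0)
N_CHOICES = (1, 2, 3, 4, 5, 6)
THRESHOLD_SPAN = (0.02, 1.98)  # times the regulator's median operating level


@dataclass
class EnsembleConfig:
    n_models: int = 10_000
    n_initial_conditions: int = 100
    replicates: int = 3
    seed: int = 0
    n_stability: int = 1000  # initial conditions for relative stability

    def __post_init__(self) -> None:
        for name in ("n_models", "n_initial_conditions", "replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SampledModel:
    """One ensemble member: kinetic parameters plus its solved states."""

    g: np.ndarray
    k: np.ndarray
    lam: np.ndarray
    n: np.ndarray
    threshold: np.ndarray
    states: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    labels: list[str] = field(default_factory=list)

    @property
    def phase(self) -> str:
        labs = sorted(set(l for l in self.labels if l in "EHM"),
                      key="EHM".index)
        return "".join(labs)


def _edge_arrays(topology: NetworkTopology
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = {n: i for i, n in enumerate(topology.nodes)}
    esrc = np.array([idx[e.source] for e in topology.edges], dtype=np.int64)
    etgt = np.array([idx[e.target] for e in topology.edges], dtype=np.int64)
    eact = np.array([e.is_activation for e in topology.edges])
    return esrc, etgt, eact


def _median_levels(topology: NetworkTopology, rng: np.random.Generator,
                   n_draws: int = 1000) -> np.ndarray:
    """Monte-Carlo median operating level per node for the half-functional
    threshold rule: g/k modulated by every incoming regulation at half
    effect, with the fold change drawn from that edge's own sampling
    distribution.  Ignoring the activatory inputs leaves thresholds far
    below the operating levels of strongly activated nodes, which
    saturates their downstream Hills and all but eliminates
    multistability from the ensemble."""
    medians = np.empty(len(topology.nodes))
    for i, node in enumerate(topology.nodes):
        g = rng.uniform(*G_RANGE, n_draws)
        k = rng.uniform(*K_RANGE, n_draws)
        level = g / k
        for e in topology.incoming(node):
            lam_raw = rng.uniform(*LAMBDA_RANGE, n_draws)
            lam = lam_raw if e.is_activation else 1.0 / lam_raw
            level = level * (1.0 + lam) / 2.0
        medians[i] = np.median(level)
    return medians


def sample_parameters(topology: NetworkTopology, rng: np.random.Generator
                      ) -> SampledModel:
    """Draw one random kinetic parameter set.

    Per node: g ~ U[1, 100], k ~ U[0.1, 1].  Per edge: integer Hill
    coefficient n ~ U{1..6}; fold change lam ~ U[1, 100] for activation,
    its reciprocal for inhibition; threshold uniform over [0.02, 1.98]
    times the source's median operating level (half-functional rule).
    """
    n_nodes = len(topology.nodes)
    g = rng.uniform(*G_RANGE, n_nodes)
    k = rng.uniform(*K_RANGE, n_nodes)
    esrc, _etgt, eact = _edge_arrays(topology)
    n_edges = len(topology.edges)
    n = rng.integers(N_CHOICES[0], N_CHOICES[-1] + 1, n_edges)
    lam_raw = rng.uniform(*LAMBDA_RANGE, n_edges)
    lam = np.where(eact, lam_raw, 1.0 / lam_raw)
    # medians from a fixed sub-stream so thresholds depend on the topology,
    # not on how many models were drawn before this one
    med_rng = np.random.default_rng(rng.integers(2**31))
    medians = _median_levels(topology, med_rng)
    threshold = rng.uniform(*THRESHOLD_SPAN, n_edges) * medians[esrc]
    return SampledModel(g=g, k=k, lam=lam, n=n.astype(np.int64),
                        threshold=threshold)


def _initial_conditions(model: SampledModel, n_ic: int,
                        rng: np.random.Generator) -> np.ndarray:
    scale = model.g / model.k
    lo = np.log(1e-2 * scale)
    hi = np.log(1.2 * scale * np.maximum(1.0, model.lam.max(initial=1.0)))
    return np.exp(rng.uniform(lo, hi, size=(n_ic, scale.size)))


def _ensemble_jacobian(x: np.ndarray, model: SampledModel, esrc, etgt,
                       rel_step: float = 1e-6) -> np.ndarray:
    def f(y):
        out = np.empty_like(y)
        _kernels._ens_rhs(y, model.g, model.k, esrc, etgt, model.lam,
                          model.n, model.threshold, out)
        return out

    m = x.size
    J = np.empty((m, m))
    for j in range(m):
        h = rel_step * max(x[j], 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] = max(xm[j] - h, 0.0)
        J[:, j] = (f(xp) - f(xm)) / (xp[j] - xm[j])
    return J


def solve_model(topology: NetworkTopology, model: SampledModel,
                n_initial_conditions: int, rng: np.random.Generator, *,
                dt: float = 0.1, t_max: float = 1000.0,
                rel_tol: float = 1e-6, dedup_log_tol: float = 1e-2,
                check_stability: bool = False) -> np.ndarray:
    """Relax every initial condition to a fixed point and deduplicate.

    Convergence requires the infinity-norm of the rhs, relative to k*x
    (floored at one molecule), below ``rel_tol``; endpoints identical
    within ``dedup_log_tol`` in log levels are merged.  Non-converged
    starts are dropped (and counted in the log).  With
    ``check_stability`` each retained state is also verified against the
    Jacobian's leading eigenvalue (Euler relaxation only reaches stable
    states, so this is off by default for speed).
    """
    esrc, etgt, _ = _edge_arrays(topology)
    ics = _initial_conditions(model, n_initial_conditions, rng)
    ends, conv = _kernels.ensemble_solve_model(
        ics, model.g, model.k, esrc, etgt, model.lam, model.n,
        model.threshold, dt, int(t_max / dt), 50, rel_tol)
    n_failed = int((~conv).sum())
    if n_failed:
        logger.debug("%d/%d initial conditions did not converge", n_failed,
                     len(ics))
    states: list[np.ndarray] = []
    for x in ends[conv]:
        lx = np.log(np.maximum(x, 1e-9))
        dup = any(np.max(np.abs(lx - np.log(np.maximum(s, 1e-9))))
                  < dedup_log_tol for s in states)
        if not dup:
            states.append(x)
    if check_stability:
        keep = []
        for x in states:
            J = _ensemble_jacobian(x, model, esrc, etgt)
            if np.max(np.real(np.linalg.eigvals(J))) < 0:
                keep.append(x)
        states = keep
    model.states = (np.vstack(states) if states
                    else np.empty((0, len(topology.nodes))))
    return model.states


def classify_states(models: list[SampledModel], topology: NetworkTopology
                    ) -> None:
    """Pool all stable states, z-score log2 levels per node, and attach
    E/H/M labels (in place) from the ZEB and miR-200 z-scores."""
    if not models:
        raise ValueError("empty ensemble")
    iz = topology.nodes.index(ZEB_NODE)
    im = topology.nodes.index(MIR_NODE)
    pool = np.vstack([m.states for m in models if len(m.states)])
    logpool = np.log2(np.maximum(pool, 1e-9))
    mean = logpool.mean(axis=0)
    sd = logpool.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("degenerate ensemble: zero variance in a node")
    offset = 0
    for m in models:
        m.labels = []
        for s in m.states:
            z = (np.log2(np.maximum(s, 1e-9)) - mean) / sd
            zz, zm = z[iz], z[im]
            if zz > 0 and zm < 0:
                m.labels.append("M")
            elif zz > 0 and zm > 0:
                m.labels.append("H")
            elif zz < 0 and zm > 0:
                m.labels.append("E")
            else:
                m.labels.append("unlabelled")
        offset += len(m.states)


def zscore_frame(models: list[SampledModel], topology: NetworkTopology
                 ) -> pd.DataFrame:
    """Pooled per-state z-scores with labels (diagnostic output)."""
    pool = np.vstack([m.states for m in models if len(m.states)])
    logpool = np.log2(np.maximum(pool, 1e-9))
    z = (logpool - logpool.mean(axis=0)) / logpool.std(axis=0)
    labels = [l for m in models for l in m.labels]
    df = pd.DataFrame(z, columns=[f"z_{n}" for n in topology.nodes])
    df["label"] = labels
    return df


def run_ensemble(topology: NetworkTopology, n_models: int,
                 n_initial_conditions: int, seed: int,
                 progress: bool = False) -> list[SampledModel]:
    """Sample, solve and classify one full ensemble."""
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n_models):
        m = sample_parameters(topology, rng)
        solve_model(topology, m, n_initial_conditions, rng)
        models.append(m)
    classify_states(models, topology)
    return models


def phase_counts(models: list[SampledModel]) -> dict[str, int]:
    """Model counts per phase, plus 'none' (no stable state found) and
    'unlabelled' (states exist but none earned an E/H/M label); the
    counts partition the ensemble."""
    counts = {ph: 0 for ph in PHASES}
    counts["none"] = 0
    counts["unlabelled"] = 0
    for m in models:
        if len(m.states) == 0:
            counts["none"] += 1
        elif m.phase == "":
            counts["unlabelled"] += 1
        else:
            counts[m.phase] += 1
    return counts


def phase_frequencies(topologies: list[NetworkTopology],
                      config: EnsembleConfig,
                      reference: int = 0) -> pd.DataFrame:
    """Replicated phase-frequency table for one or more topologies.

    Each replicate uses a fresh seed (config.seed + replicate index).
    Returns a tidy frame with mean and standard deviation per (topology,
    phase) over replicates, and — when at least two topologies and two
    replicates are given — the two-tailed equal-variance t-test p-value
    of each topology against the reference topology's frequencies.
    """
    if not topologies:
        raise ValueError("need at least one topology")
    rows = []
    per_rep: dict[tuple[str, str], list[int]] = {}
    for t_i, topo in enumerate(topologies):
        for rep in range(config.replicates):
            models = run_ensemble(topo, config.n_models,
                                  config.n_initial_conditions,
                                  seed=config.seed + 1000 * rep + t_i)
            counts = phase_counts(models)
            total = sum(counts.values())
            assert total == config.n_models
            for ph, c in counts.items():
                per_rep.setdefault((topo.name, ph), []).append(c)
    do_tests = len(topologies) > 1 and config.replicates > 1
    if len(topologies) > 1 and config.replicates < 2:
        logger.warning("fewer than 2 replicates: t-tests skipped")
    ref_name = topologies[reference].name
    for (name, ph), counts in per_rep.items():
        row = {"topology": name, "phase": ph,
               "mean": float(np.mean(counts)), "sd": float(np.std(counts, ddof=1))
               if len(counts) > 1 else 0.0,
               "counts": counts}
        if do_tests and name != ref_name:
            ref_counts = per_rep[(ref_name, ph)]
            if np.var(counts) + np.var(ref_counts) > 0:
                row["p_vs_reference"] = float(
                    sps.ttest_ind(counts, ref_counts, equal_var=True).pvalue)
            else:
                row["p_vs_reference"] = 1.0 if counts == ref_counts else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Relative stability
# ---------------------------------------------------------------------------

@dataclass
class RelativeStabilityRecord:
    model_id: int
    phase: str
    replicate: int
    arrivals: dict[str, int]  # per-label arrival counts
    overflow: int  # arrivals at no recorded state

    @property
    def total(self) -> int:
        return sum(self.arrivals.values()) + self.overflow


def relative_stability(topology: NetworkTopology,
                       models: list[SampledModel], *,
                       n_initial_conditions: int = 1000,
                       repeats: int = 3, seed: int = 0,
                       phases: tuple[str, ...] = ("EH", "HM", "EHM")
                       ) -> list[RelativeStabilityRecord]:
    """Basin-size analysis: relax ``n_initial_conditions`` random starts
    per multistable model and count arrivals at each labelled state
    (nearest recorded state in log space; unmatched arrivals go to an
    overflow bin).  ``repeats`` independent batches give error bars."""
    esrc, etgt, _ = _edge_arrays(topology)
    records: list[RelativeStabilityRecord] = []
    for mid, m in enumerate(models):
        if m.phase not in phases:
            continue
        ref_logs = np.log(np.maximum(m.states, 1e-9))
        for rep in range(repeats):
            rng = np.random.default_rng(seed + 7919 * rep + mid)
            ics = _initial_conditions(m, n_initial_conditions, rng)
            ends, conv = _kernels.ensemble_solve_model(
                ics, m.g, m.k, esrc, etgt, m.lam, m.n, m.threshold,
                0.1, 10_000, 50, 1e-6)
            arrivals = {lab: 0 for lab in m.labels}
            overflow = 0
            for x, ok in zip(ends, conv):
                if not ok:
                    overflow += 1
                    continue
                d = np.max(np.abs(ref_logs - np.log(np.maximum(x, 1e-9))),
                           axis=1)
                j = int(np.argmin(d))
                if d[j] < 0.3:
                    arrivals[m.labels[j]] = arrivals.get(m.labels[j], 0) + 1
                else:
                    overflow += 1
            records.append(RelativeStabilityRecord(
                model_id=mid, phase=m.phase, replicate=rep,
                arrivals=arrivals, overflow=overflow))
    return records


def stability_frame(records: list[RelativeStabilityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"model_id": r.model_id, "phase": r.phase,
               "replicate": r.replicate, "overflow": r.overflow,
               "total": r.total}
        for lab in "EHM":
            row[f"n_{lab}"] = r.arrivals.get(lab, 0)
        rows.append(row)
    return pd.DataFrame(rows)
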