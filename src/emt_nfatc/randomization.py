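"""Degree-preserving sign randomization of a topology.

The null model keeps every edge's endpoints (hence all in/out degrees)
and permutes only which edges are activating, under the global constraint
that the counts of activating and inhibiting edges match the wild type.
All C(E, A) assignments are enumerated in lexicographic edge order and
the wild-type assignment is excluded, giving C(E, A) - 1 networks (461
for the 11-edge, 6-activation wild type).  Edge rewiring (endpoint
shuffling) is deliberately not offered — it is a different null model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .ensemble import EnsembleConfig, phase_counts, run_ensemble
from .topology import NetworkTopology

logger = logging.getLogger(__name__)


@dataclass
class RandomizedNetworkSet:
    base: NetworkTopology
    sign_vectors: list[tuple[bool, ...]]  # activation flags per member

    def __len__(self) -> int:
        return len(self.sign_vectors)

    def member(self, i: int) -> NetworkTopology:
        return self.base.with_signs(self.sign_vectors[i],
                                    name=f"{self.base.name}-rand{i:04d}")

    def __iter__(self):
        return (self.member(i) for i in range(len(self)))


def enumerate_randomized(topology: NetworkTopology) -> RandomizedNetworkSet:
    """All sign assignments with the wild-type activation count, excluding
    the wild type itself; deterministic lexicographic order."""
    if not topology.edges:
        raise ValueError("topology has no edges")
    E = len(topology.edges)
    A = topology.n_activation
    wild = topology.sign_vector()
    vectors = []
    for combo in combinations(range(E), A):
        flags = tuple(i in set(combo) for i in range(E))
        if flags != wild:
            vectors.append(flags)
    assert len(vectors) == comb(E, A) - 1
    return RandomizedNetworkSet(base=topology, sign_vectors=vectors)


@dataclass
class RandomizationComparison:
    phase: str
    fractions: pd.DataFrame  # per randomized network
    wildtype_fraction: float
    percentile: float  # wild type within the randomized distribution


def _phase_fraction(topology: NetworkTopology, phase: str,
                    n_models: int, n_ic: int, seed: int) -> float:
    models = run_ensemble(topology, n_models, n_ic, seed=seed)
    counts = phase_counts(models)
    if counts.get(phase, 0) == 0 and sum(counts.values()) == 0:
        logger.warning("%s: no stable states anywhere", topology.name)
    return counts.get(phase, 0) / n_models


def compare_phase_fractions(rand_set: RandomizedNetworkSet, phase: str,
                            config: EnsembleConfig,
                            subsample: int | None = None) -> RandomizationComparison:
    """Phase fraction of every (sub)sampled randomized network vs the wild
    type, with the wild type's percentile in the randomized distribution.

    The subsample (when smaller than the full set) is drawn with the
    config seed, so repeated calls are reproducible.
    """
    idx = np.arange(len(rand_set))
    if subsample is not None and subsample < len(rand_set):
        rng = np.random.default_rng(config.seed)
        idx = np.sort(rng.choice(idx, size=subsample, replace=False))
    rows = []
    for i in idx:
        topo = rand_set.member(int(i))
        frac = _phase_fraction(topo, phase, config.n_models,
                               config.n_initial_conditions,
                               seed=config.seed + 17 + int(i))
        rows.append({"network": int(i), "fraction": frac})
    frame = pd.DataFrame(rows)
    wt_frac = _phase_fraction(rand_set.base, phase, config.n_models,
                              config.n_initial_conditions,
                              seed=config.seed + 13)
    fr = frame["fraction"].to_numpy()
    percentile = float(100.0 * ((fr < wt_frac).sum() + 0.5 * (fr == wt_frac).sum())
                       / len(fr))
    return RandomizationComparison(phase=phase, fractions=frame,
                                   wildtype_fraction=wt_frac,
                                   percentile=percentile)
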