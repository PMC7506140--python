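"""Random-parameter ensemble engine: sampling, solving, classification,
phase statistics and relative stability."""

import numpy as np
import pytest

from emt_nfatc.ensemble import (
    EnsembleConfig,
    SampledModel,
    classify_states,
    phase_counts,
    phase_frequencies,
    relative_stability,
    run_ensemble,
    sample_parameters,
    solve_model,
    stability_frame,
    zscore_frame,
)
from emt_nfatc.topology import (
    core_emt,
    single_node,
    toggle_switch,
    wildtype_coupled,
)


class TestSampling:
    def test_ranges_and_sign_conventions(self):
        rng = np.random.default_rng(0)
        topo = wildtype_coupled()
        act = np.array([e.is_activation for e in topo.edges])
        for _ in range(200):
            m = sample_parameters(topo, rng)
            assert np.all((m.g >= 1) & (m.g <= 100))
            assert np.all((m.k >= 0.1) & (m.k <= 1.0))
            assert np.all((m.n >= 1) & (m.n <= 6))
            assert np.all(m.lam[act] >= 1.0)
            assert np.all((m.lam[~act] > 0) & (m.lam[~act] <= 1.0))
            assert np.all(m.threshold > 0)

    def test_threshold_medians_track_the_sampling_rule(self):
        """Direct simulation of the half-functional rule: the sampled
        threshold median per edge matches the rule's own median (the
        regulator's g/k modulated by each input at half effect)."""
        from emt_nfatc.ensemble import _edge_arrays, _median_levels

        topo = core_emt()
        rng = np.random.default_rng(1)
        draws = np.array([sample_parameters(topo, rng).threshold
                          for _ in range(4000)])
        esrc, _, _ = _edge_arrays(topo)
        rule_med = _median_levels(topo, np.random.default_rng(2), 20_000)
        for e in range(draws.shape[1]):
            expected = rule_med[esrc[e]]  # span [0.02, 1.98] has median 1.0
            assert np.median(draws[:, e]) == pytest.approx(expected, rel=0.15)


class TestSolveModel:
    def test_single_unregulated_node_reaches_g_over_k(self):
        topo = single_node()
        rng = np.random.default_rng(3)
        m = sample_parameters(topo, rng)
        states = solve_model(topo, m, 10, rng)
        assert states.shape == (1, 1)
        assert states[0, 0] == pytest.approx(m.g[0] / m.k[0], rel=1e-4)

    def test_strong_toggle_matches_brute_force_grid(self):
        """A strongly mutually inhibitory toggle: states from the solver
        equal the attractors found by relaxing a deterministic grid."""
        topo = toggle_switch()
        m = SampledModel(g=np.array([50.0, 50.0]), k=np.array([0.5, 0.5]),
                         lam=np.array([0.02, 0.02]), n=np.array([4, 4]),
                         threshold=np.array([60.0, 60.0]))
        states = solve_model(topo, m, 60, np.random.default_rng(4))

        # independent oracle: dense grid of starts, plain Euler in numpy
        def rhs(x):
            h = lambda v, lam: (1 + lam * (v / 60.0) ** 4) / (1 + (v / 60.0) ** 4)
            return np.array([50 * h(x[1], 0.02) - 0.5 * x[0],
                             50 * h(x[0], 0.02) - 0.5 * x[1]])

        found = []
        # asymmetric grids keep starts off the invariant diagonal, whose
        # points would relax onto the saddle
        for a in np.geomspace(1, 120, 12):
            for b in np.geomspace(1.3, 117, 13):
                x = np.array([a, b])
                for _ in range(4000):
                    x = np.maximum(x + 0.1 * rhs(x), 0)
                if not any(np.allclose(x, f, rtol=1e-2) for f in found):
                    found.append(x)
        assert len(found) == len(states) == 2
        for f in found:
            assert any(np.allclose(f, s, rtol=1e-2) for s in states)

    def test_returned_states_are_fixed_points(self):
        topo = wildtype_coupled()
        rng = np.random.default_rng(5)
        from emt_nfatc.ensemble import _edge_arrays
        from emt_nfatc._kernels import _ens_rhs

        esrc, etgt, _ = _edge_arrays(topo)
        for _ in range(20):
            m = sample_parameters(topo, rng)
            states = solve_model(topo, m, 30, rng, check_stability=True)
            out = np.empty(len(topo.nodes))
            for s in states:
                _ens_rhs(s, m.g, m.k, esrc, etgt, m.lam, m.n, m.threshold, out)
                assert np.max(np.abs(out) / np.maximum(m.k * s, 1e-6)) < 1e-5


class TestClassification:
    def test_pooled_zscores_standardized(self, coupled_models):
        zf = zscore_frame(coupled_models, wildtype_coupled())
        for node in wildtype_coupled().nodes:
            col = zf[f"z_{node}"]
            assert col.mean() == pytest.approx(0.0, abs=1e-9)
            assert col.std(ddof=0) == pytest.approx(1.0, rel=1e-9)

    def test_quadrant_labels(self, coupled_models):
        zf = zscore_frame(coupled_models, wildtype_coupled())
        m = zf[zf.label == "M"]
        h = zf[zf.label == "H"]
        e = zf[zf.label == "E"]
        assert (m.z_ZEB > 0).all() and (m.z_miR200 < 0).all()
        assert (h.z_ZEB > 0).all() and (h.z_miR200 > 0).all()
        assert (e.z_ZEB < 0).all() and (e.z_miR200 > 0).all()

    def test_degenerate_ensemble_rejected(self):
        from emt_nfatc.topology import NetworkTopology

        topo = NetworkTopology(["ZEB", "miR200"], [], name="pair")
        m = SampledModel(g=np.array([10.0, 10.0]), k=np.array([1.0, 1.0]),
                         lam=np.empty(0), n=np.empty(0, dtype=np.int64),
                         threshold=np.empty(0))
        m.states = np.array([[10.0, 10.0]])
        with pytest.raises(ValueError, match="degenerate"):
            classify_states([m, m], topo)


class TestPhaseStatistics:
    def test_counts_partition_the_ensemble(self, coupled_models):
        counts = phase_counts(coupled_models)
        assert sum(counts.values()) == len(coupled_models)

    def test_frequencies_deterministic_in_config(self):
        cfg = EnsembleConfig(n_models=60, replicates=2, seed=77)
        a = phase_frequencies([core_emt()], cfg)
        b = phase_frequencies([core_emt()], cfg)
        assert a.drop(columns="counts").equals(b.drop(columns="counts"))

    def test_replicate_counts_sum_to_n_models(self, ensemble_table):
        from conftest import ENSEMBLE_MODELS

        for name in ensemble_table.topology.unique():
            sub = ensemble_table[ensemble_table.topology == name]
            per_rep = np.array([c for c in sub.counts])
            assert np.all(per_rep.sum(axis=0) == ENSEMBLE_MODELS)


class TestRelativeStability:
    def test_monostable_model_sends_every_start_to_its_state(self):
        topo = core_emt()
        models = run_ensemble(topo, 40, 50, seed=9)
        mono = next(m for m in models if len(m.states) == 1 and m.phase)
        recs = relative_stability(topo, [mono], n_initial_conditions=200,
                                  repeats=1, seed=1, phases=(mono.phase,))
        assert recs[0].arrivals[mono.labels[0]] == 200
        assert recs[0].overflow == 0

    def test_arrival_counts_partition_the_starts(self, coupled_models):
        topo = wildtype_coupled()
        multis = [m for m in coupled_models if m.phase in ("EH", "HM", "EHM")]
        recs = relative_stability(topo, multis[:6], n_initial_conditions=300,
                                  repeats=2, seed=2)
        assert recs
        for r in recs:
            assert r.total == 300
        sf = stability_frame(recs)
        assert (sf[["n_E", "n_H", "n_M"]].sum(axis=1) + sf.overflow == 300).all()
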