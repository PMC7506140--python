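"""SNAIL sweeps, phase classification, hybrid interval, sensitivity."""

import numpy as np
import pytest

from emt_nfatc.bifurcation import (
    hybrid_interval,
    hybrid_interval_continuation,
    sensitivity,
    sweep,
)
from emt_nfatc.model import find_steady_states


def phase_sequence(diagram):
    seq = []
    for ph in diagram.phases:
        lab = "".join(sorted(ph))
        if not seq or seq[-1] != lab:
            seq.append(lab)
    return seq


class TestSweep:
    def test_grid_must_be_increasing(self, coupled_params):
        with pytest.raises(ValueError):
            sweep(coupled_params, np.array([2.0, 1.0]))

    def test_coupled_phase_structure(self, coupled_diagram):
        seq = phase_sequence(coupled_diagram)
        assert seq[0] == "E"                      # monostable epithelial onset
        assert "H" not in seq                     # no monostable hybrid regime
        assert any("H" in s and len(s) > 1 for s in seq)
        assert seq[-1] == "M"                     # full EMT at high SNAIL

    def test_core_phase_structure(self, core_diagram):
        seq = phase_sequence(core_diagram)
        assert seq[0] == "E" and seq[-1] == "M"

    def test_phases_match_independent_multistart(self, coupled_diagram,
                                                 coupled_params):
        """Stable-state counts from the sweep equal counts from fresh
        multi-start root finding at random grid points."""
        rng = np.random.default_rng(7)
        for i in rng.choice(len(coupled_diagram.S_grid), 8, replace=False):
            S = coupled_diagram.S_grid[i]
            fresh = find_steady_states(coupled_params.with_snail(S),
                                       n_starts=40, seed=9)
            assert coupled_diagram.stable_counts[i] == sum(
                1 for s in fresh if s.stable)

    def test_fold_points_bracket_count_changes(self, coupled_diagram):
        c = coupled_diagram.stable_counts
        changes = np.nonzero(np.diff(c))[0]
        assert len(coupled_diagram.fold_points) == len(changes)
        for f, i in zip(coupled_diagram.fold_points, changes):
            assert coupled_diagram.S_grid[i] < f < coupled_diagram.S_grid[i + 1]


class TestHybridInterval:
    def test_interval_endpoints_bracket_brute_force_count_change(
            self, coupled_interval, coupled_params):
        lo, hi = coupled_interval

        def n_stable(S):
            return sum(1 for s in find_steady_states(
                coupled_params.with_snail(S), n_starts=40, seed=11) if s.stable)

        assert n_stable(hi - 2e3) > n_stable(hi + 2e3)

    def test_monostable_diagram_has_empty_interval(self, core_params):
        grid = np.linspace(0, 100e3, 60)
        d = sweep(core_params, grid, seed=0)
        assert hybrid_interval(d) == (0.0, 0.0)

    def test_continuation_matches_sweep_interval(self, coupled_diagram,
                                                 coupled_params,
                                                 coupled_interval):
        lo, hi = coupled_interval
        h_branch = [b for b in coupled_diagram.branches if b.label == "H"][0]
        mid = int(len(h_branch.states) // 2)
        clo, chi = hybrid_interval_continuation(
            coupled_params, h_branch.states[mid].state,
            h_branch.S_values[mid], S_max=600e3)
        assert clo == pytest.approx(lo, abs=4e3)
        assert chi == pytest.approx(hi, abs=4e3)


class TestSensitivity:
    def test_zero_delta_reports_zero_change(self, coupled_params):
        fr = sensitivity(coupled_params, delta=0.0,
                         S_grid=np.linspace(0, 500e3, 126), seed=0)
        assert np.allclose(fr.percent_change, 0.0, atol=0.5)

    def test_batch_value_matches_independent_full_sweep(self, coupled_params,
                                                        sensitivity_result):
        """One perturbed interval recomputed by an independent full sweep
        agrees with the continuation batch value."""
        name = "lam_ZEB_ZEB"
        p = coupled_params.copy()
        p.set_scalar(name, p.get_scalar(name) * 1.1)
        grid = np.linspace(0, 500e3, 126)
        d = sweep(p, grid, seed=0)
        lo, hi = hybrid_interval(d, p)

        fr = sensitivity_result
        row = fr[(fr.parameter == name) & (fr.direction == "+10%")].iloc[0]
        base_lo, base_hi = fr.attrs["baseline_interval"]
        expected = 100.0 * ((hi - lo) - (base_hi - base_lo)) / (base_hi - base_lo)
        assert row.percent_change == pytest.approx(expected, abs=1.5)
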