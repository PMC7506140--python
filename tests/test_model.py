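"""Mechanistic ODE model: rhs structure, simulation, steady states."""

import numpy as np
import pytest

from emt_nfatc.model import (
    find_steady_states,
    jacobian,
    rhs,
    simulate,
    state_scales,
)
from emt_nfatc.params import (
    CORE_SPECIES,
    default_core_parameters,
    default_coupled_parameters,
)


class TestRhs:
    def test_boundary_states_cannot_go_negative(self, coupled_params):
        """Non-negativity is forward-invariant: on each boundary face the
        normal component of the flow points inward."""
        p = coupled_params.with_snail(200e3)
        scales = state_scales(p)
        rng = np.random.default_rng(0)
        for j in range(len(p.species)):
            for _ in range(5):
                state = rng.uniform(0.1, 1.0) * scales
                state[j] = 0.0
                assert rhs(state, p)[j] >= 0.0

    def test_nfatc_neutralized_matches_core_derivatives(self, coupled_params,
                                                        core_params):
        """With every coupling edge inert the (mu, mz, Z) subsystem is the
        core model exactly."""
        p = coupled_params.nfatc_neutralized().with_snail(250e3)
        pc = core_params.with_snail(250e3)
        rng = np.random.default_rng(1)
        for _ in range(10):
            core_state = rng.uniform(0.01, 1.0, 3) * state_scales(pc)
            full_state = np.concatenate([core_state, [1e5, 1e3]])
            np.testing.assert_allclose(rhs(full_state, p)[:3],
                                       rhs(core_state, pc), rtol=1e-12)

    def test_snail_enters_only_as_clamped_input(self, coupled_params):
        state = 0.3 * state_scales(coupled_params)
        d1 = rhs(state, coupled_params.with_snail(100e3))
        d2 = rhs(state, coupled_params.with_snail(400e3))
        # NFATc and E-cadherin-from-NFATc terms unaffected; mu/mz terms move
        assert d1[4] == d2[4]
        assert d1[0] != d2[0] and d1[1] != d2[1]

    def test_steady_state_has_zero_rhs(self, coupled_params):
        p = coupled_params.with_snail(330e3)
        for ss in find_steady_states(p, seed=3):
            resid = rhs(ss.state, p)
            scale = np.maximum(np.abs(ss.state), 1.0) * 0.05
            assert np.max(np.abs(resid) / scale) < 1e-6


class TestSimulate:
    def test_equilibrium_is_invariant(self, core_params):
        p = core_params.with_snail(200e3)
        stable = [s for s in find_steady_states(p, seed=0) if s.stable][0]
        tr = simulate(stable.state, p, t_max=200.0)
        np.testing.assert_allclose(tr.final_state(), stable.state, rtol=1e-3)

    def test_nfatc_relaxes_to_production_over_degradation(self, coupled_params):
        p = coupled_params.with_snail(50e3)
        x0 = 0.5 * state_scales(p)
        x0[4] = 1.0
        tr = simulate(x0, p, t_max=200.0)
        expected = p.production["N"] / p.degradation["N"]
        assert tr.component("N")[-1] == pytest.approx(expected, rel=1e-4)

    def test_t_max_must_be_positive(self, core_params):
        with pytest.raises(ValueError):
            simulate(np.ones(3), core_params, t_max=0.0)


class TestFindSteadyStates:
    def test_low_snail_coupled_is_monostable_epithelial(self, coupled_params):
        """At vanishing SNAIL the only attractor is epithelial: miR-200
        high, ZEB mRNA low."""
        states = find_steady_states(coupled_params.with_snail(0.0), seed=2)
        stable = [s for s in states if s.stable]
        assert len(stable) == 1
        assert stable[0].mu > 10 * stable[0].mz

    def test_perturbed_stable_states_return_under_integration(self, core_params):
        p = core_params.with_snail(215e3)
        stable = [s for s in find_steady_states(p, seed=4) if s.stable]
        assert len(stable) >= 2  # multistable regime
        for ss in stable:
            tr = simulate(ss.state * 1.01, p, t_max=500.0)
            np.testing.assert_allclose(tr.final_state(), ss.state, rtol=1e-2)

    def test_stability_flag_matches_jacobian_sign(self, core_params):
        p = core_params.with_snail(215e3)
        for ss in find_steady_states(p, seed=5):
            lead = np.max(np.real(np.linalg.eigvals(jacobian(ss.state, p))))
            assert ss.stable == (lead < -1e-6)

    def test_core_state_vector_is_three_species(self, core_params):
        assert core_params.species == CORE_SPECIES
        ss = find_steady_states(core_params, seed=0)[0]
        assert ss.state.shape == (3,)


class TestBoundedness:
    def test_trajectories_enter_the_production_bound_box(self, coupled_params):
        p = coupled_params.with_snail(250e3)
        scales = state_scales(p)
        tr = simulate(2.0 * scales, p, t_max=2000.0)
        assert np.all(tr.final_state() <= scales * 1.01)
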