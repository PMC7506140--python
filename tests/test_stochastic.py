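"""Euler-Maruyama simulation, basin coarse-graining, residence times and
quasi-potential landscapes, checked on the analytically known double-well
toy and on the reduced EMT system."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from emt_nfatc.params import default_coupled_parameters
from emt_nfatc.reduction import qss_reduce
from emt_nfatc.stochastic import (
    Itinerary,
    StochasticConfigError,
    build_basin_grid,
    coarse_grain,
    default_sigma,
    double_well_drift,
    emt_drift,
    euler_maruyama,
    mean_residence_time,
    quasi_potential,
)

WELLS = np.array([[1.0, 1.0], [3.0, 1.0]])  # double-well attractors (x, y)


@pytest.fixture(scope="module")
def dw():
    return double_well_drift()


class TestEulerMaruyama:
    def test_config_validation(self, dw):
        with pytest.raises(StochasticConfigError):
            euler_maruyama(dw, (1, 1), dt=-0.01, sigma=(1, 1), seed=0)
        with pytest.raises(StochasticConfigError):
            euler_maruyama(dw, (1, 1), dt=0.01, sigma=(-1, 1), seed=0)

    def test_same_seed_is_bit_identical(self, dw):
        a = euler_maruyama(dw, (1, 1), dt=0.01, n_steps=20_000,
                           sigma=(0.3, 0.3), seed=99)
        b = euler_maruyama(dw, (1, 1), dt=0.01, n_steps=20_000,
                           sigma=(0.3, 0.3), seed=99)
        assert np.array_equal(a.path, b.path)

    def test_zero_noise_stays_at_fixed_point(self, dw):
        run = euler_maruyama(dw, (3.0, 1.0), dt=0.01, n_steps=10_000,
                             sigma=(0.0, 0.0), seed=0)
        assert np.allclose(run.path[-1], [3.0, 1.0], atol=1e-6)

    def test_zero_noise_matches_ode_integration(self):
        p = default_coupled_parameters(330e3)
        system = qss_reduce(p)
        drift = emt_drift(system)
        x0 = (2e5, 5e3)
        run = euler_maruyama(drift, x0, dt=0.005, n_steps=40_000,
                             sigma=(0.0, 0.0), seed=0)
        sol = solve_ivp(lambda t, y: system.drift(*np.maximum(y, 1e-12)),
                        (0, 200.0), x0, method="LSODA", rtol=1e-10)
        np.testing.assert_allclose(run.path[-1], sol.y[:, -1], rtol=1e-3)

    def test_reflection_keeps_path_non_negative(self, dw):
        run = euler_maruyama(dw, (1.0, 0.01), dt=0.01, n_steps=50_000,
                             sigma=(1.0, 1.0), seed=3)
        assert np.all(run.path >= 0)


class TestCoarseGraining:
    def test_basin_grid_splits_at_the_separatrix(self, dw):
        """The double well separates at x = 2: relaxation labels must
        agree with the sign of (x - 2) away from the boundary."""
        grid = build_basin_grid(dw, WELLS, n_cells=40)
        cx = np.exp(0.5 * (grid.log_x_edges[:-1] + grid.log_x_edges[1:]))
        for i, x in enumerate(cx):
            if abs(x - 2.0) < 0.1:
                continue
            expected = 0 if x < 2.0 else 1
            assert np.all(grid.labels[i] == expected)

    def test_pinned_trajectory_has_constant_itinerary(self, dw):
        run = euler_maruyama(dw, (3.0, 1.0), dt=0.01, n_steps=5_000,
                             sigma=(0.05, 0.05), seed=5)
        grid = build_basin_grid(dw, WELLS, path=run.path, n_cells=40)
        it = coarse_grain(run, grid, ["L", "R"])
        assert set(it.labels) == {1}

    def test_itinerary_switches_when_crossing(self, dw):
        run = euler_maruyama(dw, (1.0, 1.0), dt=0.01, n_steps=400_000,
                             sigma=(0.9, 0.3), seed=8, record_every=5)
        grid = build_basin_grid(dw, WELLS, path=run.path, n_cells=40)
        it = coarse_grain(run, grid, ["L", "R"])
        assert {0, 1} <= set(it.labels)  # both wells visited
        # label changes only when x crosses the separatrix region
        x = run.path[:, 0]
        changes = np.nonzero(np.diff(it.labels))[0]
        assert np.all(np.abs(x[changes] - 2.0) < 0.8)


class TestMeanResidenceTime:
    def test_single_label_run(self):
        it = Itinerary(labels=np.zeros(1000, dtype=int), dt=0.1,
                       state_names=["A"])
        res = mean_residence_time(it)
        assert res["A"]["mrt"] == pytest.approx(100.0)
        assert res["A"]["fraction"] == 1.0

    def test_alternating_runs(self):
        labels = np.repeat(np.tile([0, 1], 50), 5)
        it = Itinerary(labels=labels, dt=0.2, state_names=["A", "B"])
        res = mean_residence_time(it)
        assert res["A"]["mrt"] == pytest.approx(1.0)
        assert res["B"]["mrt"] == pytest.approx(1.0)
        assert res["A"]["fraction"] + res["B"]["fraction"] == pytest.approx(1.0)

    def test_never_visited_state_absent_not_zero(self):
        it = Itinerary(labels=np.zeros(10, dtype=int), dt=1.0,
                       state_names=["A", "B"])
        assert "B" not in mean_residence_time(it)

    def test_empty_itinerary_rejected(self):
        with pytest.raises(ValueError):
            mean_residence_time(Itinerary(labels=np.array([], dtype=int),
                                          dt=1.0, state_names=[]))


class TestQuasiPotential:
    def test_symmetric_double_well_has_equal_barriers(self, dw):
        runs = [euler_maruyama(dw, tuple(WELLS[i % 2]), dt=0.01,
                               n_steps=600_000, sigma=(0.8, 0.3),
                               seed=20 + i, record_every=5)
                for i in range(4)]
        field = quasi_potential(runs, WELLS, ["L", "R"], n_cells=80)
        assert field.coverage > 0.95
        bL, bR = field.barriers["L"], field.barriers["R"]
        assert np.isfinite(bL) and np.isfinite(bR)
        assert bL == pytest.approx(bR, rel=0.35)  # Monte-Carlo tolerance

    def test_occupancy_concentrates_at_low_noise(self, dw):
        run = euler_maruyama(dw, (1.0, 1.0), dt=0.01, n_steps=200_000,
                             sigma=(0.15, 0.1), seed=31)
        grid = build_basin_grid(dw, WELLS, path=run.path, n_cells=40)
        res = mean_residence_time(coarse_grain(run, grid, ["L", "R"]))
        assert res["L"]["fraction"] > 0.99


class TestDefaultSigma:
    def test_scales_with_geometric_mean(self):
        att = np.array([[10.0, 1000.0], [1000.0, 10.0]])
        sz, sm = default_sigma(att, fractions=(0.05, 0.05))
        assert sz == pytest.approx(0.05 * 100.0)
        assert sm == pytest.approx(0.05 * 100.0)
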