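"""Shifted Hill factors and the microRNA binding-site formalism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emt_nfatc.model import (
    mirna_mirna_loss,
    mirna_mrna_degradation,
    mirna_site_occupancy,
    mirna_translation_factor,
    shifted_hill,
)
from emt_nfatc.params import MicroRnaCoupling, ParameterError, ShiftedHillBlock


def block(A0=100.0, n=2, lam=3.0):
    return ShiftedHillBlock(A0, n, lam)


class TestShiftedHill:
    @pytest.mark.parametrize("lam", [0.1, 1.0, 7.5])
    @pytest.mark.parametrize("n", [1, 2, 4])
    def test_anchor_values(self, n, lam):
        b = block(n=n, lam=lam)
        assert shifted_hill(0.0, b) == pytest.approx(1.0)
        assert shifted_hill(b.threshold, b) == pytest.approx((1 + lam) / 2)
        saturating = (1e6 if n > 1 else 1e8) * b.threshold
        assert shifted_hill(saturating, b) == pytest.approx(lam, rel=1e-6)

    def test_invalid_block_rejected(self):
        with pytest.raises(ParameterError):
            ShiftedHillBlock(-1.0, 2, 3.0)
        with pytest.raises(ParameterError):
            ShiftedHillBlock(100.0, 0, 3.0)
        with pytest.raises(ValueError):
            shifted_hill(-1.0, block())

    @settings(max_examples=60, derandomize=True)
    @given(lam=st.floats(0.01, 100), n=st.integers(1, 6),
           x=st.floats(0, 1e7), y=st.floats(0, 1e7))
    def test_bounded_and_monotone(self, lam, n, x, y):
        b = block(n=n, lam=lam)
        hx, hy = shifted_hill(x, b), shifted_hill(y, b)
        lo, hi = min(1.0, lam), max(1.0, lam)
        assert lo - 1e-12 <= hx <= hi + 1e-12
        if x < y:  # increasing for activation, decreasing for inhibition
            assert (hx <= hy + 1e-12) if lam >= 1 else (hx >= hy - 1e-12)


@pytest.fixture(scope="module")
def coupling():
    return MicroRnaCoupling(mu0=10e3, n_sites=2,
                            l=(1.0, 0.5, 0.2),
                            gamma_m=(0.0, 0.1, 0.5),
                            gamma_mu=(0.0, 0.05, 0.2))


class TestSiteOccupancy:
    def test_zero_mirna_means_no_occupancy(self, coupling):
        assert mirna_site_occupancy(0.0, coupling, 0) == pytest.approx(1.0)
        assert mirna_site_occupancy(0.0, coupling, 1) == 0.0

    def test_at_threshold_two_sites_single_occupancy_is_half(self, coupling):
        assert mirna_site_occupancy(coupling.mu0, coupling, 1) == pytest.approx(0.5)

    @settings(max_examples=40, derandomize=True)
    @given(mu=st.floats(0, 1e9))
    def test_occupancies_sum_to_one(self, coupling, mu):
        total = sum(mirna_site_occupancy(mu, coupling, i)
                    for i in range(coupling.n_sites + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_site_index(self, coupling):
        with pytest.raises(IndexError):
            mirna_site_occupancy(1.0, coupling, 3)

    def test_silencing_functions_are_monotone(self, coupling):
        mus = np.linspace(0, 100e3, 50)
        L = [mirna_translation_factor(m, coupling) for m in mus]
        Ym = [mirna_mrna_degradation(m, coupling) for m in mus]
        assert all(np.diff(L) <= 1e-12)       # translation falls
        assert all(np.diff(Ym) >= -1e-12)     # active degradation rises
        assert mirna_mirna_loss(0.0, coupling) == 0.0


class TestCouplingValidation:
    def test_vector_length_must_match_sites(self):
        with pytest.raises(ParameterError):
            MicroRnaCoupling(mu0=1.0, n_sites=2, l=(1.0, 0.5),
                             gamma_m=(0.0, 0.1, 0.5),
                             gamma_mu=(0.0, 0.05, 0.2))

    def test_free_mrna_anchors_required(self):
        with pytest.raises(ParameterError):
            MicroRnaCoupling(mu0=1.0, n_sites=1, l=(0.9, 0.5),
                             gamma_m=(0.0, 0.1), gamma_mu=(0.0, 0.05))
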