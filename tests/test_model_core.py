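"""Unit tests of the per-hexamer rate laws and update rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kaiabc.model_core import (
    HexamerState,
    IntegrationError,
    ModelParameters,
    adp_lifetime,
    atpase_step,
    kaiA_cii_equilibrium,
    kaiA_on_kaiB_alpha,
    kaiA_rates,
    kaiB_rates,
    kaiB_ring_step,
    phospho_step,
    structure_drive,
    structure_update,
)

P = ModelParameters()


class TestModelParameters:
    def test_standard_values(self):
        assert P.hA0 == 0.5 and P.fA0 == 1e3
        assert P.hB0 == 5e-5 and P.fB0 == 2.0
        assert P.hAB == 0.6 and P.fAB == 1e2
        assert P.kp == P.kdp == 0.18
        assert P.f_hyd == 1.0 and P.inv_dADP0 == 1.0
        assert (P.d0, P.d1, P.d2, P.d3, P.d4) == (2.0, 5.0, 5.0, 3.0, 2.0)
        assert (P.A_X, P.B_X, P.C_X, P.P0) == (1.0, 1.0, 2.0, 0.1)
        assert P.AT == 2 * P.N and P.BT == 6 * P.N

    def test_volume_scales_with_ensemble_size(self):
        p = ModelParameters.standard(N=250)
        assert p.V == pytest.approx(0.25)
        # concentrations (counts per V) are N-independent
        assert p.AT == pytest.approx(2000.0) and p.BT == pytest.approx(6000.0)

    @pytest.mark.parametrize("bad", [
        {"hB0": -1.0}, {"P0": 0.0}, {"N": 0}, {"dt": 0.0}, {"C_X": -2.0},
    ])
    def test_validation_rejects(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)


class TestStructure:
    def test_drive_with_vanishing_couplings_returns_baseline(self):
        # D=0.5 and F=0 remove every coupling term
        r = structure_drive(0.0, np.eye(7)[0], 0.5, 0.5, 0.5, P)
        assert r == pytest.approx(P.d0)

    def test_drive_closed_forms(self):
        # fully phosphorylated, ADP-loaded, X=1 hexamer
        r = structure_drive(0.0, np.eye(7)[0], 1.0, 1.0, 1.0, P)
        assert r == pytest.approx(P.d0 - P.d3 - P.d4)  # = -3 kB T0
        # fully dephosphorylated, ATP-loaded, X=0 hexamer
        r = structure_drive(0.0, np.eye(7)[0], 0.0, 0.0, 0.0, P)
        assert r == pytest.approx(P.d0 + P.d3 + P.d4)  # = +7 kB T0

    def test_update_fixed_points(self):
        assert structure_update(0.0, 300.0, 300.0) == pytest.approx(0.5)
        assert structure_update(50.0, 300.0, 300.0) == pytest.approx(1.0)
        assert structure_update(-50.0, 300.0, 300.0) == pytest.approx(0.0)
        assert structure_update(2.0, 300.0, 300.0) == pytest.approx(
            0.5 * (1 + math.tanh(2.0)), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-30, 30), st.floats(270, 330))
    def test_update_antisymmetry(self, r, T):
        x1 = structure_update(r, T, 303.15)
        x2 = structure_update(-r, T, 303.15)
        assert x1 + x2 == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= x1 <= 1.0


class TestKaiABinding:
    def test_no_free_kaiA_means_no_binding(self):
        pA, _, _ = kaiA_cii_equilibrium(0.0, 0.7, 1.0, P)
        assert pA == 0.0

    def test_neutral_structure_rates(self):
        hA, fA = kaiA_rates(0.5, P)
        assert hA == pytest.approx(P.hA0) and fA == pytest.approx(P.fA0)
        assert hA / fA == pytest.approx(5e-4)

    def test_saturated_structure_rate(self):
        hA, _ = kaiA_rates(1.0, P)
        assert hA == pytest.approx(P.hA0 * (1 + math.tanh(1.0)), rel=1e-12)

    def test_alpha_saturation(self):
        assert kaiA_on_kaiB_alpha(0.0, P) == 0.0
        g = P.hAB / P.fAB
        assert kaiA_on_kaiB_alpha(1.0 / g, P) == pytest.approx(0.5)


class TestKaiBRing:
    def test_empty_ring_is_stationary_without_kaiB(self):
        pB = np.zeros(7)
        pB[0] = 1.0
        out = kaiB_ring_step(pB, 0.0, P.hB0, P.fB0, P.dt)
        assert np.array_equal(out, pB)

    def test_neutral_structure_rates(self):
        hB, fB = kaiB_rates(0.5, P)
        assert hB == pytest.approx(P.hB0) and fB == pytest.approx(P.fB0)

    def test_probability_conserved_per_step(self, rng):
        pB = rng.dirichlet(np.ones(7), size=10)
        out = kaiB_ring_step(pB, 500.0, 1e-4, 2.0, 1e-3)
        assert np.all(np.abs(out.sum(axis=-1) - 1.0) <= 1e-12)

    def test_stationary_law_is_binomial(self):
        # long-run Euler integration against the detailed-balance closed form
        hx, f = 0.8, 1.3  # hB*xB and fB, fixed
        pB = np.zeros(7)
        pB[0] = 1.0
        for _ in range(6000):
            pB = kaiB_ring_step(pB, 1.0, hx, f, 0.01)
        p_site = hx / (hx + f)
        k = np.arange(7)
        binom = (np.array([math.comb(6, int(i)) for i in k])
                 * p_site**k * (1 - p_site)**(6 - k))
        assert np.max(np.abs(pB - binom)) <= 1e-6

    def test_unstable_step_raises(self):
        pB = np.zeros(7)
        pB[6] = 1.0
        with pytest.raises(IntegrationError):
            kaiB_ring_step(pB, 0.0, 0.0, 50.0, 0.01)  # 6*f*dt = 3 > 1


class TestPhospho:
    def test_pure_dephosphorylation_without_kaiA(self):
        d = phospho_step(0.8, 0.0, P, P.dt)
        assert d == pytest.approx(0.8 - P.dt * P.kdp * 0.8)

    def test_balanced_steady_state(self):
        # z = 1 (pA = P0) with kp = kdp settles at D = 1/2
        d = 0.05
        for _ in range(30000):
            d = phospho_step(d, P.P0, P, 5e-3)
        assert d == pytest.approx(0.5, abs=1e-6)

    def test_stays_in_unit_interval(self):
        assert 0.0 <= phospho_step(0.0, 1.0, P, P.dt) <= 1.0
        assert 0.0 <= phospho_step(1.0, 0.0, P, P.dt) <= 1.0


class TestATPase:
    def test_lifetime_closed_forms(self):
        assert adp_lifetime(0.5, P) == pytest.approx(P.dADP0)
        assert adp_lifetime(1.0, P) == pytest.approx(
            P.dADP0 * (1 - math.tanh(0.5)), rel=1e-12)
        assert adp_lifetime(0.0, P) == pytest.approx(
            P.dADP0 * (1 + math.tanh(0.5)), rel=1e-12)

    def test_frozen_without_hydrolysis(self, rng):
        p0 = ModelParameters(f_hyd=0.0)
        q = np.zeros((20, 6), dtype=np.int8)
        for _ in range(50):
            q, n = atpase_step(q, np.full(20, 0.5), p0, 1e-2, rng)
            assert n == 0
        assert not q.any()

    def test_renewal_occupancy_fraction(self):
        # alternating renewal: ADP dwell fraction = dADP/(dADP + 1/f_hyd)
        r = np.random.default_rng(7)
        X = np.full(400, 0.5)  # dADP = dADP0 = 1/f_hyd -> fraction 1/2
        q = np.zeros((400, 6), dtype=np.int8)
        occ = []
        for i in range(30000):
            q, _ = atpase_step(q, X, P, 0.01, r)
            if i > 2000:
                occ.append(q.mean())
        assert np.mean(occ) == pytest.approx(0.5, abs=0.01)

    def test_oversized_step_raises(self, rng):
        with pytest.raises(IntegrationError):
            atpase_step(np.ones((2, 6), dtype=np.int8), np.full(2, 1.0),
                        ModelParameters(inv_dADP0=2000.0), 1e-3, rng)


class TestHexamerState:
    def test_valid_state_passes(self):
        s = HexamerState(pA=0.3, pB=np.eye(7)[0], D=0.4, X=0.9,
                         q=np.array([0, 1, 0, 1, 1, 0]))
        s.validate()
        assert s.q_mean == pytest.approx(0.5)

    @pytest.mark.parametrize("field,value", [
        ("pA", 1.5), ("D", -0.1), ("X", 2.0),
        ("q", np.array([0, 1, 2, 0, 0, 0])),
    ])
    def test_invalid_state_rejected(self, field, value):
        kw = dict(pA=0.0, pB=np.eye(7)[0], D=0.4, X=0.9,
                  q=np.zeros(6, dtype=int))
        kw[field] = value
        with pytest.raises(ValueError):
            HexamerState(**kw).validate()
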