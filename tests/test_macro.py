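"""Macro-scale vasodynamics operations: delayed myogenic response, coupling,
passive distension, rate limiting, and NVC modulation."""

import numpy as np
import pytest
import scipy.sparse as sp

import vasodyn.macro as m
from vasodyn.macro import CouplingStabilityError, MacroParams


@pytest.fixture
def params():
    return MacroParams()


def make_state(ws0, dmax, p, d0=None):
    ws0 = np.atleast_1d(np.asarray(ws0, dtype=float))
    dmax = np.atleast_1d(np.asarray(dmax, dtype=float))
    d0 = dmax.copy() if d0 is None else np.atleast_1d(np.asarray(d0, float))
    return m.init_ws_avg(ws0, dmax, 0.1 * dmax, d0, p)


class TestInitAndDelay:
    def test_ws_avg_is_laplace_value(self, params):
        # D=17.5 um, IP=50 mmHg, h=1.75 um -> WS = 500 mmHg
        ws0 = 50.0 * 17.5 / 1.75
        state = make_state(ws0, 17.5, params)
        assert state.WS_avg[0] == pytest.approx(500.0)

    def test_prefilled_history_gives_baseline_potential(self, params):
        state = make_state(500.0, 17.5, params)
        assert m.delayed_v_init(state, params)[0] == pytest.approx(-45.0)

    def test_frozen_baseline_not_recomputed(self, params):
        state = make_state(500.0, 17.5, params)
        for _ in range(100):
            state.push_ws(np.array([900.0]))
        assert state.WS_avg[0] == pytest.approx(500.0)

    @pytest.mark.parametrize("dev,expected", [(0.0, -45.0), (100.0, -43.1), (-100.0, -46.9)])
    def test_delayed_potential_examples(self, params, dev, expected):
        state = make_state(500.0, 17.5, params)
        # after delay_steps+1 pushes the first pushed value is MR_D old
        for _ in range(params.delay_steps + 1):
            state.push_ws(np.array([500.0 + dev]))
        assert m.delayed_v_init(state, params)[0] == pytest.approx(expected)

    def test_delay_uses_history_not_current(self, params):
        state = make_state(500.0, 17.5, params)
        state.push_ws(np.array([800.0]))  # recent value, not yet delayed
        assert m.delayed_v_init(state, params)[0] == pytest.approx(-45.0)


class TestCoupling:
    def test_isolated_segment_unchanged(self, params):
        a = sp.csr_matrix((1, 1))
        v = m.couple_potentials(np.array([-42.0]), a, params)
        assert v[0] == pytest.approx(-42.0)

    def test_pair_converges_to_mean(self, params):
        a = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
        v = m.couple_potentials(np.array([-40.0, -50.0]), a, params)
        assert np.allclose(v, [-45.0, -45.0], atol=1e-4)

    def test_single_inner_step_euler(self):
        p = MacroParams(dt2=1e-4, RC=1e-3, dt1=1e-4)  # one inner step, ratio 0.1
        a = sp.csr_matrix(np.array([[0, 1], [1, 0]], dtype=float))
        v = m.couple_potentials(np.array([-40.0, -50.0]), a, p, check_every=10)
        assert np.allclose(v, [-41.0, -49.0], atol=1e-12)

    def test_mean_preserved_on_regular_graph(self, params):
        # ring of 6 segments: degree-uniform
        n = 6
        a = sp.csr_matrix(
            (np.ones(2 * n), (list(range(n)) * 2, [(i + 1) % n for i in range(n)] + [(i - 1) % n for i in range(n)])),
            shape=(n, n),
        )
        rng = np.random.default_rng(0)
        v0 = -45 + rng.normal(size=n)
        v1 = m.couple_potentials(v0, a, params)
        assert v1.mean() == pytest.approx(v0.mean(), abs=1e-9)

    def test_propagator_matches_iteration(self, params):
        rng = np.random.default_rng(1)
        n = 7
        dense = np.triu(rng.random((n, n)) < 0.4, k=1)
        a = sp.csr_matrix((dense | dense.T).astype(float))
        v0 = -45 + rng.normal(size=n)
        # compare against a no-early-exit iteration
        p = MacroParams(coupling_tol=0.0)
        prop = m.coupling_propagator(a, p)
        assert np.allclose(prop @ v0, m.couple_potentials(v0, a, p), atol=1e-9)

    def test_instability_raises(self):
        p = MacroParams(dt2=9e-4, RC=1e-3)  # ratio 0.9; degree 2 violates bound
        a = sp.csr_matrix(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(CouplingStabilityError, match="max_degree"):
            m.couple_potentials(np.array([-40.0, -45.0, -50.0]), a, p)


class TestDiameterComponents:
    @pytest.mark.parametrize("v,expected", [(-45.0, 0.0), (-47.0, 2.0), (-43.1, -1.9)])
    def test_myogenic_component(self, params, v, expected):
        assert m.compute_d_mr(np.array([v]), params)[0] == pytest.approx(expected)

    def test_passive_bounds_and_monotonicity(self, params):
        d_min = np.array([14.76])
        ws = np.linspace(0, 5000, 200)
        d = np.array([m.compute_d_pd(np.array([w]), d_min, params)[0] for w in ws])
        assert d[0] == pytest.approx(14.76)
        assert np.all(np.diff(d) > 0)
        assert np.all(d < 14.76 * 1.5)

    def test_passive_worked_example(self, params):
        # D_WSmin = 14.76, WS = 500, K = 3e-3, alpha = 0.5
        expected = 14.76 * (1 + 0.5 * (1 - np.exp(-1.5)))
        got = m.compute_d_pd(np.array([500.0]), np.array([14.76]), params)[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(20.49, abs=0.01)

    def test_negative_ws_rejected(self, params):
        with pytest.raises(ValueError):
            m.compute_d_pd(np.array([-1.0]), np.array([14.76]), params)


class TestNvcModulation:
    def test_zero_signals_identity(self, params):
        d_mr, damp = m.apply_nvc_modulation(np.array([2.0]), 0.0, 0.0, params)
        assert d_mr[0] == pytest.approx(2.0)
        assert float(damp) == pytest.approx(1.0)

    def test_full_damping_nulls_myogenic_term(self, params):
        d_mr, damp = m.apply_nvc_modulation(np.array([2.0]), 0.0, 1.0, params)
        assert float(d_mr[0] * damp) == pytest.approx(0.0)

    def test_inhibition_arithmetic(self, params):
        d_mr, _ = m.apply_nvc_modulation(np.array([2.0]), 0.5, 0.0, params)
        assert d_mr[0] == pytest.approx(-3.0)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            m.apply_nvc_modulation(np.array([2.0]), 1.5, 0.0, params)


class TestRateLimit:
    def test_within_limits_unchanged(self, params):
        d = m.update_diameter(np.array([10.05]), np.array([10.0]), params)
        assert d[0] == pytest.approx(10.05)

    def test_dilation_clip(self, params):
        # dt1=0.2, 15 %/s -> max +0.3 um from 10 um
        d = m.update_diameter(np.array([10.5]), np.array([10.0]), params)
        assert d[0] == pytest.approx(10.3)

    def test_constriction_clip(self, params):
        # 7.5 %/s -> max -0.15 um from 10 um
        d = m.update_diameter(np.array([9.0]), np.array([10.0]), params)
        assert d[0] == pytest.approx(9.85)
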