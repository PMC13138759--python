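"""Cellular PA-segment model: transfer functions, crossbridge mechanics,
wall balance, and the virtual ex-vivo protocols."""

import numpy as np
import pytest
import scipy.linalg

import vasodyn.cellular as cl
from vasodyn.cellular import CellularParams, CellularPA, MyosinState


@pytest.fixture(scope="module")
def p():
    return CellularParams()


class TestTransferFunctions:
    def test_messenger_sigmoid_endpoints(self, p):
        lo, _ = cl.ws_to_second_messengers(0.0, 800.0, p)
        mid, _ = cl.ws_to_second_messengers(400.0, 800.0, p)
        hi, _ = cl.ws_to_second_messengers(800.0, 800.0, p)
        assert lo < 0.05
        assert mid == pytest.approx(0.5)
        assert hi > 0.95

    def test_messengers_monotone(self, p):
        ws = np.linspace(0, 800, 100)
        ip3, dag = cl.ws_to_second_messengers(ws, 800.0, p)
        assert np.all(np.diff(ip3) > 0)
        assert np.array_equal(ip3, dag)

    def test_kir_maps_mirror(self, p):
        assert cl.ws_to_kir_op_smc(0.0, 800.0, p) > 0.95
        assert cl.ws_to_kir_op_smc(800.0, 800.0, p) < 0.05
        # EC Kir deactivated without flow
        assert cl.wss_to_kir_op_ec(0.0, 60.0, p) < 0.05

    def test_mechano_lag_properties(self):
        assert cl.mechano_lag(0.3, 0.3, 5.0, 0.1) == pytest.approx(0.3)
        # one step of size tau traverses 63.2 % of the gap
        out = cl.mechano_lag(0.0, 1.0, 5.0, 5.0)
        assert out == pytest.approx(1 - np.exp(-1), rel=1e-12)
        assert cl.mechano_lag(0.0, 1.0, 0.0, 0.1) == pytest.approx(1.0)

    def test_nernst_potential(self):
        assert cl.nernst_k(4.0) == pytest.approx(26.7 * np.log(4 / 140), rel=1e-12)
        assert cl.nernst_k(60.0) > cl.nernst_k(4.0)


class TestCrossbridge:
    def test_fraction_conservation_random_walk(self, p):
        rng = np.random.default_rng(0)
        myo = MyosinState.resting(3)
        for _ in range(200):
            ca = rng.uniform(50, 600, 3)
            no = rng.uniform(0, 10, 3)
            myo, tone = cl.crossbridge_step(myo, ca, no, 0.05, p)
            total = myo.M + myo.Mp + myo.AMp + myo.AM
            assert np.allclose(total, 1.0, atol=1e-9)
            assert np.all((tone >= 0) & (tone <= 1))

    def test_no_reduces_tone_at_fixed_ca(self, p):
        tones = []
        for no in (0.0, 5.0, 10.0):
            myo = MyosinState.resting(1)
            for _ in range(4000):
                myo, tone = cl.crossbridge_step(myo, 300.0, no, 0.01, p)
            tones.append(tone[0])
        assert tones[0] > tones[1] > tones[2]

    def test_steady_state_matches_nullspace_oracle(self, p):
        """Integrated steady state equals the rate matrix's null space."""
        ca, no = 300.0, 2.0
        k_mlck = p.k_mlck_max * ca**p.hill_n / (ca**p.hill_n + p.ca_half_mlck**p.hill_n)
        k_mlcp = p.k_mlcp0 * (1 + p.beta_no * no)
        q = cl.crossbridge_rate_matrix(k_mlck, k_mlcp, p)
        null = scipy.linalg.null_space(q)
        assert null.shape[1] == 1
        ss = null[:, 0] / null[:, 0].sum()

        myo = MyosinState.resting(1)
        for _ in range(20000):
            myo, _ = cl.crossbridge_step(myo, ca, no, 0.01, p)
        got = np.array([myo.M[0], myo.Mp[0], myo.AMp[0], myo.AM[0]])
        assert np.allclose(got, ss, atol=1e-4)


class TestWallBalance:
    def test_zero_tone_gives_passive_diameter(self, p):
        d = cl.segment_diameter(0.0, 500.0, 1.0, 16.4, p)
        expected = 0.9 * 16.4 * (1 + p.alpha_passive * (1 - np.exp(-p.K_passive * 500)))
        assert d == pytest.approx(expected, rel=1e-12)

    def test_tone_monotonically_constricts(self, p):
        d = [cl.segment_diameter(t, 500.0, 1.0, 16.4, p) for t in (0.0, 0.3, 0.6)]
        assert d[0] > d[1] > d[2]

    def test_myogenic_tone_arithmetic(self):
        # the reference segment's reported passive/active span
        mt = (21.5 - 12.6) / 21.5 * 100
        assert mt == pytest.approx(41.4, abs=0.05)

    def test_max_tone_develops_reported_mt(self, p):
        d_pass = cl.segment_diameter(0.0, p.ws_max_default, 1.0, 16.4, p)
        d_act = cl.segment_diameter(p.tone_ref, p.ws_max_default, 1.0, 16.4, p)
        mt = (d_pass - d_act) / d_pass * 100
        assert mt == pytest.approx(42.0, abs=5.0)


class TestProtocols:
    def test_passive_mode_zero_tone_everywhere(self, p):
        res = cl.run_pressure_myography([0, 20, 40], "passive", p)
        d_expected = [
            cl.segment_diameter(0.0, (ip + 25.0) * d / (0.1 * 16.4), 1.0, 16.4, p)
            for ip, d in zip([0, 20, 40], res["D"])
        ]
        assert np.allclose(res["D"], d_expected, rtol=1e-6)

    def test_non_monotone_steps_rejected(self, p):
        with pytest.raises(ValueError):
            cl.run_pressure_myography([10, 5, 20], "active", p)

    def test_mt_curve_shape(self, p):
        ip = np.arange(0, 71, 10)
        curve = cl.myogenic_tone_curve(ip, p)
        assert np.all(curve["MT"] >= -1e-9)
        # tone develops with pressure: MT at high IP well above MT at 0
        assert curve["MT"][-1] > curve["MT"][0] + 10

    def test_max_active_diameter_in_low_ip_band(self, p):
        # in-silico pressure axis; the tone transition sits at ~30-35 mmHg
        ip = np.arange(0, 71, 5)
        act = cl.run_pressure_myography(ip, "active", p, exvivo_pressures=False)
        k = int(np.argmax(act["D"]))
        assert 25 <= ip[k] <= 40

    def test_kir_inhibition_constricts(self, p):
        ip = [30, 40, 50]
        ctrl = cl.run_pressure_myography(ip, "active", p)
        inhib = cl.run_pressure_myography(
            ip, "active", p, channel_inhibition={"g_Kir_smc": 0.5}
        )
        assert np.all(inhib["D"] < ctrl["D"])


@pytest.fixture(scope="module")
def grids(p):
    v_grid = np.arange(-100, 41, 2.0)
    return {
        ip: cl.run_voltage_clamp(v_grid, ip, p, exvivo_pressure=False)
        for ip in (30.0, 75.0)
    }


class TestVoltageClamp:
    def test_current_zero_at_rmp(self, p, grids):
        # linear interpolation on the 2 mV grid bounds the root-finding check
        for res in grids.values():
            i_at_rmp = np.interp(res["RMP"], res["V"], res["I"])
            assert abs(i_at_rmp) < 1e-3 * np.abs(res["I"]).max()

    def test_negative_slope_region_at_low_ip(self, grids):
        res = grids[30.0]
        di = np.diff(res["I"])
        assert di.min() < 0  # inward rectification: negative-slope region

    def test_rmr_higher_at_low_ip(self, grids):
        assert grids[30.0]["RMR"] > grids[75.0]["RMR"]

    def test_grid_must_cover_range(self, p):
        with pytest.raises(ValueError):
            cl.run_voltage_clamp(np.arange(-60, 41, 2.0), 20.0, p)
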