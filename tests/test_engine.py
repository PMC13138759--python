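"""Macro-engine behavior: determinism, algorithm ordering, oscillation
phenomenology (synchronization, damping variants), and NVC modulation."""

import numpy as np
import pytest

import vasodyn as v
import vasodyn.metrics as met
from vasodyn.engine import autoregulated_diameters


def cycle_amplitudes(t, d, prominence_frac=0.01):
    import scipy.signal

    prom = prominence_frac * d.mean()
    pk, _ = scipy.signal.find_peaks(d, prominence=prom)
    tr, _ = scipy.signal.find_peaks(-d, prominence=prom)
    n = min(len(pk), len(tr))
    if n == 0:
        return np.array([])
    return np.abs(d[pk[:n]] - d[tr[:n]])


@pytest.fixture(scope="module")
def vasomotion_run():
    cfg = v.SimulationConfig(duration=300.0)
    return v.run_vasomotion_macro(cfg)


class TestAutoregulation:
    def test_full_dilation_at_lower_limit(self, compiled):
        d = autoregulated_diameters(compiled, v.BoundaryConditions(40, 10))
        art = compiled.is_arteriolar
        assert np.allclose(d[art], compiled.d_active_max[art])

    def test_tone_increases_with_pressure(self, compiled):
        d60 = autoregulated_diameters(compiled, v.BoundaryConditions(60, 10))
        d80 = autoregulated_diameters(compiled, v.BoundaryConditions(80, 10))
        art = compiled.is_arteriolar
        assert d80[art].mean() < d60[art].mean() < compiled.d_active_max[art].mean()


class TestVasomotionRun:
    def test_deterministic(self):
        cfg = v.SimulationConfig(duration=30.0)
        a = v.run_vasomotion_macro(cfg)
        b = v.run_vasomotion_macro(cfg)
        assert np.array_equal(a.channels["D"], b.channels["D"])

    def test_sustained_synchronized_oscillation(self, vasomotion_run):
        rec = vasomotion_run
        t = rec.t
        m = t >= 200
        # same-depth segments of different PAs oscillate in phase
        same_depth = [i for i, s in enumerate(rec.segment_ids) if s.endswith("_s2")]
        assert len(same_depth) == 30
        traces = rec.channels["D"][m][:, same_depth]
        ref = traces[:, 0] - traces[:, 0].mean()
        for j in range(1, traces.shape[1]):
            other = traces[:, j] - traces[:, j].mean()
            r = np.corrcoef(ref, other)[0, 1]
            assert r > 0.95

    def test_amplitude_sustained_not_damping(self, vasomotion_run):
        rec = vasomotion_run
        k = rec.segment_ids.index("pa0_s2")
        d = rec.channels["D"][:, k]
        t = rec.t
        a_early = np.ptp(d[(t >= 100) & (t < 200)])
        a_late = np.ptp(d[t >= 200])
        assert a_late > 0.7 * a_early > 0

    def test_constriction_rate_limit_binds_in_synchronized_regime(self, vasomotion_run):
        rec = vasomotion_run
        p = v.MacroParams()
        k = rec.segment_ids.index("pa0_s2")
        d = rec.channels["D"][rec.t >= 200, k]
        step_rate = np.abs(np.diff(d)) / (p.dt1 * d[:-1])
        assert step_rate.max() <= p.DR_dilation + 1e-9
        # realized waveform slope reaches the smaller (constriction) limit
        assert step_rate.max() == pytest.approx(p.DR_constriction, rel=0.10)

    def test_hemodynamics_first_ordering(self):
        """WS recorded at step i is solved from the committed D at step i-1."""
        cfg = v.SimulationConfig(duration=2.0)
        net = v.generate_default_network(cfg.netgen)
        rec = v.run_vasomotion_macro(cfg, net)
        compiled = v.CompiledNetwork(net)
        idx = np.array([compiled.seg_index[s] for s in rec.segment_ids])
        for i in (1, 5, 9):
            d_full = compiled.diameter0.copy()
            d_full[idx] = rec.channels["D"][i - 1]
            st = compiled.solve(d_full, cfg.bc)
            assert np.allclose(st.WS[idx], rec.channels["WS"][i], rtol=1e-9)

    def test_single_pa_oscillation_damps(self):
        cfg = v.SimulationConfig(duration=300.0, macro_only_pa=0)
        rec = v.run_vasomotion_macro(cfg)
        k = rec.segment_ids.index("pa0_s13")
        d = rec.channels["D"][:, k]
        t = rec.t
        early = np.ptp(d[(t >= 50) & (t < 150)])
        late = np.ptp(d[t >= 200])
        assert late < 0.5 * early

    def test_frozen_passive_component_damps_oscillation(self):
        cfg = v.SimulationConfig(duration=400.0, freeze_pd_at=200.0)
        rec = v.run_vasomotion_macro(cfg)
        k = rec.segment_ids.index("pa0_s2")
        t, d = rec.t, rec.channels["D"][:, k]
        pd_ch = rec.channels["D_PD"][:, k]
        assert np.ptp(pd_ch[t >= 200.2]) == pytest.approx(0.0, abs=1e-12)
        amps = cycle_amplitudes(t[t >= 200], d[t >= 200])
        assert len(amps) >= 2
        assert np.all(np.diff(amps) < 1e-9)  # strictly decaying cycle over cycle
        assert np.ptp(d[t >= 350]) < 0.3 * np.ptp(d[(t >= 200) & (t < 250)])

    def test_minimal_delay_gives_fixed_point(self):
        p = v.MacroParams(MR_D=0.2, DR_dilation=5.0, DR_constriction=5.0)
        cfg = v.SimulationConfig(duration=150.0, macro=p)
        rec = v.run_vasomotion_macro(cfg)
        k = rec.segment_ids.index("pa0_s2")
        d = rec.channels["D"][rec.t >= 100, k]
        assert np.ptp(d) < 0.01 * d.mean()

    def test_shorter_delay_reduces_amplitude(self, vasomotion_run):
        cfg3 = v.SimulationConfig(duration=300.0, macro=v.MacroParams(MR_D=3.0))
        rec3 = v.run_vasomotion_macro(cfg3)
        k = rec3.segment_ids.index("pa0_s2")
        a3 = np.ptp(rec3.channels["D"][rec3.t >= 200, k])
        k5 = vasomotion_run.segment_ids.index("pa0_s2")
        a5 = np.ptp(vasomotion_run.channels["D"][vasomotion_run.t >= 200, k5])
        assert a3 < a5


class TestNvcRuns:
    def _gamma_step_down(self, duration=260.0, t_down=150.0, smooth=True):
        t = np.arange(0.0, duration + 0.1, 0.2)
        gb = np.where(t < t_down, 1.0, 0.0) + 0.001 * np.sin(t)  # non-constant
        sig = v.GammaBandSignal(t=t, GB=gb)
        v.normalize_and_smooth(sig)
        if not smooth:
            sig.GB_S = sig.GB_norm.copy()
        return sig

    def test_smoothing_suppresses_post_decline_oscillation(self):
        amps = {}
        for smooth in (True, False):
            cfg = v.SimulationConfig(duration=260.0, gamma=self._gamma_step_down(smooth=smooth))
            rec = v.run_vasomotion_macro(cfg)
            k = rec.segment_ids.index("pa0_s2")
            t, d = rec.t, rec.channels["D"][:, k]
            amps[smooth] = np.ptp(d[(t >= 155) & (t <= 200)])
        assert amps[True] < amps[False]

    def test_astro_rule_cycles_under_sustained_drive(self):
        # a mid-range sustained envelope (a full-range one nulls the myogenic
        # term entirely, leaving nothing for the astrocytic rule to react to)
        t = np.arange(0.0, 160.1, 0.2)
        gb = np.zeros_like(t)
        gb[(t >= 1.0) & (t < 2.0)] = 1.0  # brief burst fixing the range
        gb[(t >= 120.0) & (t < 150.0)] = 0.6
        sig = v.GammaBandSignal(t=t, GB=gb)
        v.normalize_and_smooth(sig)
        astro = v.AstroCouplingParams(refractory=10.0, pulse_duration=2.0)
        cfg = v.SimulationConfig(duration=160.0, gamma=sig, astro=astro)
        rec = v.run_vasomotion_macro(cfg)
        k = rec.segment_ids.index("pa0_s2")
        m = (rec.t >= 120.0) & (rec.t <= 152.0)
        amps = cycle_amplitudes(rec.t[m], rec.channels["D"][m, k])
        assert len(amps) >= 2
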