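"""Phenomenological cellular model of penetrating-arteriole segments.

Each PA segment lumps one arteriolar smooth-muscle cell (SMC) compartment
and one endothelial cell (EC) compartment.  The causal chain realized here:

  wall stress (WS)
    -> [mechanotransduction lag, tau_mct] second messengers (IP3, DAG) and
       SMC Kir open probability
    -> SMC membrane potential (depolarizing TRPM4/TMEM16A-like lumped
       current, Kir / Kv / BK potassium currents, myoendothelial and
       homocellular gap-junction currents)
    -> cytosolic Ca2+ via voltage-operated Ca channels (asymmetric kinetics:
       faster during constriction than dilation)
    -> four-state crossbridge (Hai-Murphy) phosphorylation -> tone
    -> diameter = passive distension - tone-scaled active constriction

Neuro/gliovascular inputs enter as extracellular potassium around the EC or
SMC (Kir conductance), glutamate (Ca2+ in a BK-coupled microdomain), and
NO/cGMP (raises myosin phosphatase activity, desensitizing tone to Ca2+,
and potentiates BK).  Wall shear stress activates EC Kir and an eNOS-like
NO source.  All functional forms are documented sigmoids / first-order lags
with constants collected in :class:`CellularParams`; the chain's time
constants are calibrated so a segment embedded in the network oscillates
with the in-vivo-like ~9.4 s period and stage lags (see
:func:`calibrate_delay_chain`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import scipy.optimize

__all__ = [
    "CellularParams",
    "CellularSegmentState",
    "MyosinState",
    "CellularPA",
    "ws_to_second_messengers",
    "ws_to_kir_op_smc",
    "wss_to_kir_op_ec",
    "mechano_lag",
    "crossbridge_rate_matrix",
    "crossbridge_step",
    "segment_diameter",
    "run_pressure_myography",
    "run_voltage_clamp",
    "calibrate_delay_chain",
]

RT_F = 26.7  # mV, thermal voltage scale for Nernst potentials
K_IN = 140.0  # mM, intracellular potassium


def _sig(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class CellularParams:
    """Constants of the cellular PA-segment model.

    Conductances are in normalized units (the membrane charging time is
    C_m / total conductance); gap-junction conductances derive from the
    physical resistances through fixed conversion scales chosen so the
    myoendothelial junction is comparable to the EC membrane conductance and
    the homocellular junctions give an electrotonic length of a few segments.
    """

    # mechanotransduction
    tau_mct: float = 5.0  # s (1-20 s physiological range)
    sig_k: float = 21.0  # steepness of the quasi-linear sigmoids
    sig_x0: float = 0.5  # midpoint (fraction of the stress normalizer)
    ws_max_default: float = 640.0  # mmHg, standalone normalizer (the
    # reference 250-um segment's WS_max from the default network sweep)
    wss_max_default: float = 60.0  # dyn/cm^2

    # membrane
    C_m: float = 0.14  # normalized capacitance; tau_V ~ C_m / g_total
    g_dep: float = 0.33  # lumped TRPM4/TMEM16A depolarizing conductance
    g_Kir_smc: float = 2.3
    g_Kv: float = 0.93
    g_BK: float = 0.8
    g_Kir_ec: float = 0.3
    E_dep: float = 0.0  # mV
    kir_rect_shift: float = 25.0  # mV above E_K where Kir block sets in
    kir_rect_slope: float = 8.0  # mV
    kv_half: float = -25.0  # mV
    kv_slope: float = 8.0  # mV
    bk_half: float = 20.0  # mV at zero microdomain Ca / NO
    bk_slope: float = 12.0  # mV
    bk_ca_shift: float = 30.0  # mV of BK half-activation shift per unit Ca_GluBK
    bk_no_shift: float = 0.8  # mV per AU of NO/cGMP (the fast neural-NO action
    # is via MLCP; the BK shift is the weaker eNOS-side effect)
    R_MGJ: float = 1.0  # GOhm, myoendothelial gap junction
    R_gap_homocellular: float = 0.1  # GOhm (100 MOhm), between segments
    mgj_conversion: float = 0.3  # normalized conductance per 1/GOhm
    gap_conversion: float = 30.0  # normalized conductance per 1/GOhm; with
    # R_gap = 100 MOhm this gives an electrotonic length of ~20 segments,
    # matching GOhm-scale membrane resistances against 100-MOhm junctions

    # calcium
    tau_ca_fall: float = 1.55  # s, Ca decrease (dilation phase)
    tau_ca_rise: float = 0.4  # s, Ca increase (constriction phase)
    ca_min: float = 100.0  # nM
    ca_range: float = 450.0  # nM
    ca_v_half: float = -40.0  # mV, VOCC activation midpoint
    ca_v_slope: float = 3.5  # mV
    tau_ca_tm: float = 0.5  # s, mechanosensory microdomain
    tau_ca_glubk: float = 0.5  # s, Glu-BK microdomain
    glu_gain: float = 1.0  # microdomain Ca (normalized) per AU glutamate

    # NO / cGMP
    NO_decay_tau: float = 5.0  # s
    eno_gain: float = 1.5  # AU of NO at full WSS activation (eNOS)
    tau_eno: float = 2.0  # s

    # crossbridge (Hai-Murphy) kinetics, per second
    k_mlck_max: float = 1.2  # phosphorylation ceiling (MLCK)
    ca_half_mlck: float = 210.0  # nM, Hill midpoint
    hill_n: float = 4.0
    k_mlcp0: float = 0.3  # basal dephosphorylation (MLCP)
    beta_no: float = 0.3  # MLCP potentiation per AU NO/cGMP
    k3_attach: float = 0.8
    k4_detach: float = 0.28
    k7_latch_detach: float = 0.125
    xb_rate_scale: float = 1.55  # global rate scale (sets the tone-stage lag)
    latch_weight: float = 0.3  # contribution of AM (latch) to tone

    # wall mechanics
    alpha_passive: float = 0.444  # ceiling 0.9*(1+alpha) = 1.3 x d_active_max
    K_passive: float = 3e-3  # per mmHg
    d_ws0_frac: float = 0.9  # unpressurized diameter / d_active_max
    c_tone: float = 0.68  # active constriction scale (um per tone, x ci x dmax)
    tone_ref: float = 0.8  # tone reached at maximal sustained activation

    # protocols
    ip_exvivo_offset: float = 25.0  # mmHg: IP_insilico = IP_exvivo + 25
    dt: float = 1e-4  # s, default integration step
    K_ex_smc0: float = 4.0  # mM baselines
    K_ex_ec0: float = 3.0

    @property
    def g_MGJ(self) -> float:
        return self.mgj_conversion / self.R_MGJ

    @property
    def g_gap(self) -> float:
        return self.gap_conversion / self.R_gap_homocellular


# ---------------------------------------------------------------------------
# transfer functions
# ---------------------------------------------------------------------------

def ws_to_second_messengers(
    ws: np.ndarray | float, ws_max: np.ndarray | float, p: CellularParams = CellularParams()
) -> Tuple[np.ndarray | float, np.ndarray | float]:
    """Steady-state IP3 and DAG targets (AU in [0,1]) from wall stress.

    Quasi-linear sigmoid of x = WS / WS_max with midpoint 0.5: near-zero
    below ~0.2, near-linear in the physiological band, saturating above ~0.8.
    """
    x = np.asarray(ws, dtype=float) / np.asarray(ws_max, dtype=float)
    s = _sig(p.sig_k * (x - p.sig_x0))
    return s, s


def ws_to_kir_op_smc(
    ws: np.ndarray | float, ws_max: np.ndarray | float, p: CellularParams = CellularParams()
) -> np.ndarray | float:
    """SMC Kir open probability: mirror sigmoid, downregulated by wall stress."""
    x = np.asarray(ws, dtype=float) / np.asarray(ws_max, dtype=float)
    return 1.0 - _sig(p.sig_k * (x - p.sig_x0))


def wss_to_kir_op_ec(
    wss: np.ndarray | float, wss_max: np.ndarray | float, p: CellularParams = CellularParams()
) -> np.ndarray | float:
    """EC Kir open probability: activated by wall shear stress (zero without flow)."""
    x = np.asarray(wss, dtype=float) / np.asarray(wss_max, dtype=float)
    return _sig(p.sig_k * (x - p.sig_x0))


def mechano_lag(
    current: np.ndarray | float, target: np.ndarray | float, tau: float, dt: float
) -> np.ndarray | float:
    """Exact first-order relaxation of ``current`` toward ``target`` over ``dt``."""
    if tau <= 0:
        return np.asarray(target, dtype=float) if np.ndim(target) else float(target)
    a = 1.0 - np.exp(-dt / tau)
    return current + (np.asarray(target, dtype=float) - current) * a


def nernst_k(k_ex: np.ndarray | float) -> np.ndarray | float:
    return RT_F * np.log(np.asarray(k_ex, dtype=float) / K_IN)


# ---------------------------------------------------------------------------
# crossbridge mechanics
# ---------------------------------------------------------------------------

@dataclass
class MyosinState:
    """Four-state myosin fractions: free (M), phosphorylated (Mp),
    attached phosphorylated (AMp), attached dephosphorylated latch (AM)."""

    M: np.ndarray
    Mp: np.ndarray
    AMp: np.ndarray
    AM: np.ndarray

    @classmethod
    def resting(cls, n: int) -> "MyosinState":
        return cls(M=np.ones(n), Mp=np.zeros(n), AMp=np.zeros(n), AM=np.zeros(n))

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.M, self.Mp, self.AMp, self.AM])

    def normalize(self) -> None:
        total = self.M + self.Mp + self.AMp + self.AM
        for name in ("M", "Mp", "AMp", "AM"):
            setattr(self, name, np.clip(getattr(self, name), 0.0, None) / total)


def crossbridge_rate_matrix(
    k_mlck: np.ndarray | float, k_mlcp: np.ndarray | float, p: CellularParams
) -> np.ndarray:
    """Rate matrix Q (4x4) of the cycle M->Mp->AMp->AM->M, states ordered
    (M, Mp, AMp, AM); dx/dt = Q @ x.  Scalar rates only (used by the
    steady-state oracle in tests)."""
    s = p.xb_rate_scale
    k1 = float(k_mlck) * s
    k2 = float(k_mlcp) * s
    k3 = p.k3_attach * s
    k4 = p.k4_detach * s
    k5 = k2
    k6 = k1
    k7 = p.k7_latch_detach * s
    q = np.array(
        [
            [-k1, k2, 0.0, k7],
            [k1, -(k2 + k3), k4, 0.0],
            [0.0, k3, -(k4 + k5), k6],
            [0.0, 0.0, k5, -(k6 + k7)],
        ]
    )
    return q


def crossbridge_step(
    myo: MyosinState,
    ca_cyt: np.ndarray | float,
    no_cgmp: np.ndarray | float,
    dt: float,
    p: CellularParams = CellularParams(),
) -> Tuple[MyosinState, np.ndarray]:
    """One Euler step of the four-state kinetics; returns (state, tone).

    Phosphorylation rate follows a Hill function of cytosolic Ca2+; the
    dephosphorylation (MLCP) rate is potentiated by NO/cGMP, which
    desensitizes tone to Ca2+.  Fractions are renormalized to sum to one.
    """
    ca = np.asarray(ca_cyt, dtype=float)
    no = np.asarray(no_cgmp, dtype=float)
    s = p.xb_rate_scale
    k1 = p.k_mlck_max * ca**p.hill_n / (ca**p.hill_n + p.ca_half_mlck**p.hill_n) * s
    k2 = p.k_mlcp0 * (1.0 + p.beta_no * no) * s
    k3, k4, k7 = p.k3_attach * s, p.k4_detach * s, p.k7_latch_detach * s

    m, mp, amp_, am = myo.M, myo.Mp, myo.AMp, myo.AM
    dm = k2 * mp + k7 * am - k1 * m
    dmp = k1 * m + k4 * amp_ - (k2 + k3) * mp
    damp = k3 * mp + k1 * am - (k4 + k2) * amp_
    dam = k2 * amp_ - (k1 + k7) * am
    out = MyosinState(M=m + dt * dm, Mp=mp + dt * dmp, AMp=amp_ + dt * damp, AM=am + dt * dam)
    out.normalize()
    tone = out.AMp + p.latch_weight * out.AM
    return out, tone


def segment_diameter(
    tone: np.ndarray | float,
    ws: np.ndarray | float,
    contractility_index: np.ndarray | float,
    d_active_max: np.ndarray | float,
    p: CellularParams = CellularParams(),
) -> np.ndarray | float:
    """Diameter from the passive-active balance.

    D = D_passive(WS) - c * contractility * tone * d_active_max, with the
    passive curve saturating at ~1.3 x d_active_max and c calibrated so that
    maximal sustained tone at WS_max develops ~42 % myogenic tone.
    """
    ws = np.asarray(ws, dtype=float)
    dmax = np.asarray(d_active_max, dtype=float)
    d_pass = p.d_ws0_frac * dmax * (1.0 + p.alpha_passive * (1.0 - np.exp(-p.K_passive * ws)))
    d = d_pass - p.c_tone * np.asarray(contractility_index) * np.asarray(tone) * dmax
    if np.any(np.asarray(d) <= 0):
        raise RuntimeError("cellular wall model produced nonpositive diameter")
    return d


# ---------------------------------------------------------------------------
# the segment model
# ---------------------------------------------------------------------------

@dataclass
class CellularSegmentState:
    """Dynamic state of n cellular PA segments (all arrays length n)."""

    V_smc: np.ndarray  # mV
    V_ec: np.ndarray  # mV
    Ca_cyt: np.ndarray  # nM
    Ca_TM: np.ndarray  # normalized mechanosensory microdomain Ca
    Ca_GluBK: np.ndarray  # normalized Glu-BK microdomain Ca
    IP3: np.ndarray  # AU [0,1]
    DAG: np.ndarray  # AU [0,1]
    Kir_op_smc: np.ndarray  # [0,1]
    Kir_op_ec: np.ndarray  # [0,1]
    NOcGMP: np.ndarray  # AU (neural + eNOS)
    NO_eNOS: np.ndarray  # AU
    glutamate: np.ndarray  # AU
    K_ex_smc: np.ndarray  # mM
    K_ex_ec: np.ndarray  # mM
    myosin: MyosinState
    tone: np.ndarray
    D: np.ndarray  # um

    @classmethod
    def resting(cls, n: int, d0: np.ndarray, p: CellularParams) -> "CellularSegmentState":
        return cls(
            V_smc=np.full(n, -45.0),
            V_ec=np.full(n, -45.0),
            Ca_cyt=np.full(n, p.ca_min + 75.0),
            Ca_TM=np.zeros(n),
            Ca_GluBK=np.zeros(n),
            IP3=np.full(n, 0.5),
            DAG=np.full(n, 0.5),
            Kir_op_smc=np.full(n, 0.5),
            Kir_op_ec=np.zeros(n),
            NOcGMP=np.zeros(n),
            NO_eNOS=np.zeros(n),
            glutamate=np.zeros(n),
            K_ex_smc=np.full(n, p.K_ex_smc0),
            K_ex_ec=np.full(n, p.K_ex_ec0),
            myosin=MyosinState.resting(n),
            tone=np.full(n, 0.35),
            D=np.asarray(d0, dtype=float).copy(),
        )


class CellularPA:
    """A chain of cellular PA segments with gap-junction coupling.

    ``contractility``, ``d_active_max``, ``h`` are per-segment arrays;
    ``ws_max`` / ``wss_max`` normalize the mechanosensing sigmoids (from a
    network pressure sweep, or the standalone defaults for single-segment
    protocols).
    """

    def __init__(
        self,
        d_active_max: np.ndarray,
        contractility: Optional[np.ndarray] = None,
        ws_max: Optional[np.ndarray] = None,
        wss_max: Optional[np.ndarray] = None,
        params: CellularParams = CellularParams(),
        gap_junctions: bool = True,
    ) -> None:
        self.p = params
        self.d_active_max = np.atleast_1d(np.asarray(d_active_max, dtype=float))
        n = len(self.d_active_max)
        self.n = n
        self.h = 0.1 * self.d_active_max
        self.contractility = (
            np.ones(n) if contractility is None else np.asarray(contractility, dtype=float)
        )
        self.ws_max = (
            np.full(n, params.ws_max_default) if ws_max is None else np.asarray(ws_max, float)
        )
        self.wss_max = (
            np.full(n, params.wss_max_default) if wss_max is None else np.asarray(wss_max, float)
        )
        # mechanosensing midpoints (fraction of the normalizer); per-segment
        # anchoring to the autoregulated baseline emulates the per-depth
        # contractile tuning that keeps tone comparable across the PA
        self.x_mid_ws = np.full(n, params.sig_x0)
        self.x_mid_wss = np.full(n, params.sig_x0)
        self.gap_junctions = gap_junctions and n > 1
        self._gap_inv_cache: Dict[float, np.ndarray] = {}
        self.state = CellularSegmentState.resting(n, self.d_active_max.copy(), params)

    def _gap_smoother(self, dt: float) -> np.ndarray:
        """Implicit (backward-Euler) gap-junction diffusion operator for one
        step: (I + dt*g_gap/C_m * L)^-1 with L the chain Laplacian.  Implicit
        treatment keeps the strong coupling unconditionally stable."""
        key = round(dt, 12)
        m = self._gap_inv_cache.get(key)
        if m is None:
            n = self.n
            lap = np.zeros((n, n))
            for i in range(n - 1):
                lap[i, i] += 1.0
                lap[i + 1, i + 1] += 1.0
                lap[i, i + 1] -= 1.0
                lap[i + 1, i] -= 1.0
            m = np.linalg.inv(np.eye(n) + dt * self.p.g_gap / self.p.C_m * lap)
            self._gap_inv_cache[key] = m
        return m

    def anchor_operating_point(self, ws_ref: np.ndarray, wss_ref: np.ndarray,
                               offset: float = 0.0) -> None:
        """Center the mechanosensing sigmoids on a reference state.

        ``ws_ref`` / ``wss_ref`` are the wall stresses of the autoregulated
        baseline; afterwards every segment sits at (midpoint + ``offset``) of
        its quasi-linear sigmoid there, so tone and mechanoreactivity are
        comparable across cortical depth.
        """
        self.x_mid_ws = np.clip(np.asarray(ws_ref, float) / self.ws_max - offset, 0.15, 0.85)
        self.x_mid_wss = np.clip(np.asarray(wss_ref, float) / self.wss_max - offset, 0.15, 0.85)

    # -- membrane currents (outward positive, normalized) ----------------------
    def _i_kir_smc(self, v: np.ndarray, st: CellularSegmentState) -> np.ndarray:
        p = self.p
        e_k = nernst_k(st.K_ex_smc)
        rect = _sig(-(v - e_k - p.kir_rect_shift) / p.kir_rect_slope)
        return (
            p.g_Kir_smc
            * st.Kir_op_smc
            * np.sqrt(st.K_ex_smc / p.K_ex_smc0)
            * rect
            * (v - e_k)
        )

    def _i_kv(self, v: np.ndarray, st: CellularSegmentState) -> np.ndarray:
        p = self.p
        e_k = nernst_k(st.K_ex_smc)
        return p.g_Kv * _sig((v - p.kv_half) / p.kv_slope) * (v - e_k)

    def _i_bk(self, v: np.ndarray, st: CellularSegmentState) -> np.ndarray:
        p = self.p
        e_k = nernst_k(st.K_ex_smc)
        half = p.bk_half - p.bk_ca_shift * st.Ca_GluBK - p.bk_no_shift * st.NOcGMP
        return p.g_BK * _sig((v - half) / p.bk_slope) * (v - e_k)

    def _i_dep(self, v: np.ndarray, st: CellularSegmentState) -> np.ndarray:
        p = self.p
        act = 0.5 * (st.IP3 + st.DAG) * (0.3 + 0.7 * st.Ca_TM)
        return p.g_dep * act * (v - p.E_dep)

    def _i_kir_ec(self, v: np.ndarray, st: CellularSegmentState) -> np.ndarray:
        p = self.p
        e_k = nernst_k(st.K_ex_ec)
        rect = _sig(-(v - e_k - p.kir_rect_shift) / p.kir_rect_slope)
        return (
            p.g_Kir_ec * st.Kir_op_ec * np.sqrt(st.K_ex_ec / p.K_ex_ec0) * rect * (v - e_k)
        )

    def smc_membrane_current(self, v: np.ndarray, st: CellularSegmentState) -> np.ndarray:
        """Total steady-state SMC membrane current (voltage-clamp view; no
        gap-junction terms)."""
        return self._i_kir_smc(v, st) + self._i_kv(v, st) + self._i_bk(v, st) + self._i_dep(v, st)

    # -- dynamics ----------------------------------------------------------------
    def membrane_and_ca_step(
        self, ws: np.ndarray, wss: np.ndarray, mediators: Dict[str, np.ndarray | float], dt: float
    ) -> None:
        """Advance mechanosensing, potentials, Ca pools and NO by ``dt``.

        ``mediators`` may carry NO (neural, AU), glutamate (AU), K_ex_smc,
        K_ex_ec (mM); omitted entries keep baseline values.
        """
        st, p = self.state, self.p
        if not np.all(np.isfinite(st.V_smc)):
            raise RuntimeError(f"membrane potential diverged: {st.V_smc}")

        st.K_ex_smc = np.broadcast_to(
            np.asarray(mediators.get("K_ex_smc", p.K_ex_smc0), dtype=float), (self.n,)
        )
        st.K_ex_ec = np.broadcast_to(
            np.asarray(mediators.get("K_ex_ec", p.K_ex_ec0), dtype=float), (self.n,)
        )
        st.glutamate = np.broadcast_to(
            np.asarray(mediators.get("glutamate", 0.0), dtype=float), (self.n,)
        )
        no_neural = np.broadcast_to(
            np.asarray(mediators.get("NO", 0.0), dtype=float), (self.n,)
        )

        # mechanotransduction lags (per-segment sigmoid midpoints)
        x = np.asarray(ws, dtype=float) / self.ws_max
        s_ws = _sig(p.sig_k * (x - self.x_mid_ws))
        ip3_t = dag_t = s_ws
        kir_t = 1.0 - s_ws
        st.IP3 = mechano_lag(st.IP3, ip3_t, p.tau_mct, dt)
        st.DAG = mechano_lag(st.DAG, dag_t, p.tau_mct, dt)
        st.Kir_op_smc = mechano_lag(st.Kir_op_smc, kir_t, p.tau_mct, dt)
        x_wss = np.asarray(wss, dtype=float) / self.wss_max
        st.Kir_op_ec = _sig(p.sig_k * (x_wss - self.x_mid_wss))  # fast, WSS-driven
        st.Ca_TM = mechano_lag(st.Ca_TM, 0.5 * (st.IP3 + st.DAG), p.tau_ca_tm, dt)
        st.Ca_GluBK = mechano_lag(st.Ca_GluBK, p.glu_gain * st.glutamate, p.tau_ca_glubk, dt)

        # NO: eNOS (WSS) + neural source, shared cGMP pool
        eno_t = p.eno_gain * _sig(p.sig_k * (x_wss - self.x_mid_wss))
        st.NO_eNOS = mechano_lag(st.NO_eNOS, eno_t, p.tau_eno, dt)
        st.NOcGMP = np.maximum(no_neural + st.NO_eNOS, 0.0)

        # membrane potentials: explicit membrane/MGJ currents, then implicit
        # homocellular gap-junction diffusion along the chain
        i_smc = self.smc_membrane_current(st.V_smc, st)
        i_mgj_smc = p.g_MGJ * (st.V_smc - st.V_ec)
        st.V_smc = st.V_smc - dt / p.C_m * (i_smc + i_mgj_smc)
        i_ec = self._i_kir_ec(st.V_ec, st) + p.g_MGJ * (st.V_ec - st.V_smc)
        st.V_ec = st.V_ec - dt / p.C_m * i_ec
        if self.gap_junctions:
            smoother = self._gap_smoother(dt)
            st.V_smc = smoother @ st.V_smc
            st.V_ec = smoother @ st.V_ec

        # cytosolic calcium via VOCC, asymmetric kinetics
        ca_inf = p.ca_min + p.ca_range * _sig((st.V_smc - p.ca_v_half) / p.ca_v_slope)
        tau_ca = np.where(ca_inf > st.Ca_cyt, p.tau_ca_rise, p.tau_ca_fall)
        st.Ca_cyt = st.Ca_cyt + (ca_inf - st.Ca_cyt) * (1.0 - np.exp(-dt / tau_ca))

    def wall_step(self, ws: np.ndarray, dt: float, clamp_tone: Optional[float] = None) -> None:
        """Advance crossbridge state and commit the diameter."""
        st, p = self.state, self.p
        st.myosin, tone = crossbridge_step(st.myosin, st.Ca_cyt, st.NOcGMP, dt, p)
        st.tone = np.full(self.n, clamp_tone, dtype=float) if clamp_tone is not None else tone
        st.D = np.atleast_1d(
            segment_diameter(st.tone, ws, self.contractility, self.d_active_max, p)
        )

    def step(
        self,
        ip: np.ndarray,
        wss: np.ndarray,
        mediators: Dict[str, np.ndarray | float],
        dt: float,
        clamp_tone: Optional[float] = None,
    ) -> np.ndarray:
        """One integration step with quasi-static wall stress WS = IP*D/h."""
        ws = np.asarray(ip, dtype=float) * self.state.D / self.h
        self.membrane_and_ca_step(ws, np.asarray(wss, dtype=float), mediators, dt)
        self.wall_step(ws, dt, clamp_tone)
        return self.state.D

    def equilibrate(
        self,
        ip: np.ndarray | float,
        wss: np.ndarray | float = 0.0,
        rounds: int = 3,
        **settle_kw,
    ) -> np.ndarray:
        """Settle with self-consistent operating-point anchoring.

        Alternates steady-state relaxation with re-centering of the
        mechanosensing sigmoids on the settled wall stress, emulating a
        vessel tuned to autoregulate at this working pressure.
        """
        ip_arr = np.broadcast_to(np.asarray(ip, dtype=float), (self.n,))
        wss_arr = np.broadcast_to(np.asarray(wss, dtype=float), (self.n,))
        for _ in range(rounds):
            self.settle(ip, wss, **settle_kw)
            self.anchor_operating_point(ip_arr * self.state.D / self.h, wss_arr)
        return self.settle(ip, wss, **settle_kw)

    def settle(
        self,
        ip: np.ndarray | float,
        wss: np.ndarray | float = 0.0,
        mediators: Optional[Dict[str, float]] = None,
        dt: float = 2e-3,
        t_max: float = 200.0,
        tol: float = 1e-7,
        clamp_tone: Optional[float] = None,
    ) -> np.ndarray:
        """Integrate to steady state (relative diameter change < tol per s)."""
        mediators = mediators or {}
        ip = np.broadcast_to(np.asarray(ip, dtype=float), (self.n,))
        wss = np.broadcast_to(np.asarray(wss, dtype=float), (self.n,))
        check = max(int(1.0 / dt), 1)
        d_prev = self.state.D.copy()
        for i in range(int(t_max / dt)):
            self.step(ip, wss, mediators, dt, clamp_tone)
            if (i + 1) % check == 0:
                if np.max(np.abs(self.state.D - d_prev) / d_prev) < tol:
                    break
                d_prev = self.state.D.copy()
        return self.state.D


# ---------------------------------------------------------------------------
# virtual ex-vivo protocols
# ---------------------------------------------------------------------------

def run_pressure_myography(
    ip_steps: Sequence[float],
    mode: str = "active",
    p: CellularParams = CellularParams(),
    d_active_max: float = 16.4,
    contractility: float = 1.0,
    exvivo_pressures: bool = True,
    channel_inhibition: Optional[Dict[str, float]] = None,
) -> Dict[str, np.ndarray]:
    """Virtual pressure myography on one endothelium-denuded segment.

    No-flow condition (WSS = 0, EC Kir deactivated).  ``ip_steps`` are
    ex-vivo pressures (mapped to in-silico IP by the +25 mmHg offset) unless
    ``exvivo_pressures`` is False.  ``mode='passive'`` clamps tone to zero
    (calcium-free bath).  ``channel_inhibition`` scales conductances, e.g.
    ``{"g_Kir_smc": 0.5}`` halves the SMC Kir conductance.

    Returns arrays of IP (as given), steady diameter, V_smc, Ca, and — when
    both passive and active sweeps are run via mode='active' — the myogenic
    tone MT requires a second passive run; use :func:`myogenic_tone_curve`.
    """
    steps = np.asarray(ip_steps, dtype=float)
    if np.any(np.diff(steps) < 0):
        raise ValueError("IP steps must be non-decreasing")
    if mode not in ("active", "passive"):
        raise ValueError("mode must be 'active' or 'passive'")
    if channel_inhibition:
        scaled = {k: getattr(p, k) * v for k, v in channel_inhibition.items()}
        p = replace(p, **scaled)

    pa = CellularPA(np.array([d_active_max]), np.array([contractility]), params=p)
    clamp = 0.0 if mode == "passive" else None
    d_out, v_out, ca_out = [], [], []
    for ip_ex in steps:
        ip = ip_ex + p.ip_exvivo_offset if exvivo_pressures else ip_ex
        pa.settle(ip, wss=0.0, clamp_tone=clamp)
        d_out.append(float(pa.state.D[0]))
        v_out.append(float(pa.state.V_smc[0]))
        ca_out.append(float(pa.state.Ca_cyt[0]))
    return {
        "IP": steps,
        "D": np.array(d_out),
        "V_smc": np.array(v_out),
        "Ca": np.array(ca_out),
    }


def myogenic_tone_curve(
    ip_steps: Sequence[float],
    p: CellularParams = CellularParams(),
    d_active_max: float = 16.4,
    **kw,
) -> Dict[str, np.ndarray]:
    """MT(IP) = (D_passive - D_active) / D_passive x 100 over an IP sweep."""
    act = run_pressure_myography(ip_steps, "active", p, d_active_max, **kw)
    pas = run_pressure_myography(ip_steps, "passive", p, d_active_max, **kw)
    mt = (pas["D"] - act["D"]) / pas["D"] * 100.0
    return {"IP": np.asarray(ip_steps, float), "MT": mt,
            "D_active": act["D"], "D_passive": pas["D"],
            "V_smc": act["V_smc"], "Ca": act["Ca"]}


def run_voltage_clamp(
    v_grid: Sequence[float],
    ip: float,
    p: CellularParams = CellularParams(),
    d_active_max: float = 16.4,
    exvivo_pressure: bool = True,
) -> Dict[str, object]:
    """Steady-state I-V curve of the SMC at the given IP, plus RMP and RMR.

    The segment is pre-equilibrated (unclamped, no flow) at the IP to set the
    WS-dependent gating variables; the clamp current is then the algebraic
    sum of steady-state membrane currents at each command potential.  RMP is
    the bracketing-root zero crossing of I(V); RMR = 1 / (dI/dV) at the RMP.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.min() > -100.0 or v_grid.max() < 40.0:
        raise ValueError("voltage grid must cover [-100, 40] mV")
    pa = CellularPA(np.array([d_active_max]), params=p)
    ip_insilico = ip + p.ip_exvivo_offset if exvivo_pressure else ip
    pa.settle(ip_insilico, wss=0.0)
    st = pa.state

    def current(v: float) -> float:
        return float(pa.smc_membrane_current(np.array([v]), st)[0])

    i_v = np.array([current(v) for v in v_grid])
    sign_change = np.nonzero(np.diff(np.signbit(i_v)))[0]
    if len(sign_change) == 0:
        raise RuntimeError("no zero crossing of I(V) in the grid")
    lo = v_grid[sign_change[0]]
    hi = v_grid[sign_change[0] + 1]
    rmp = scipy.optimize.brentq(current, lo, hi, xtol=1e-10)
    dv = 0.01
    di_dv = (current(rmp + dv) - current(rmp - dv)) / (2 * dv)
    rmr = 1.0 / di_dv if di_dv != 0 else np.inf
    return {"V": v_grid, "I": i_v, "RMP": float(rmp), "RMR": float(rmr)}


# ---------------------------------------------------------------------------
# delay-chain calibration (in-network single-segment oscillation)
# ---------------------------------------------------------------------------

def _extremum_times(t: np.ndarray, x: np.ndarray, kind: str, prominence: float) -> np.ndarray:
    import scipy.signal

    sgn = -1.0 if kind == "min" else 1.0
    idx, _ = scipy.signal.find_peaks(sgn * x, prominence=prominence)
    return t[idx]


def _lag(t_ref: np.ndarray, t_other: np.ndarray, max_lag: float = 6.0) -> float:
    """Median forward lag from each reference extremum to the next other-extremum."""
    lags = []
    for tr in t_ref:
        after = t_other[(t_other >= tr - 0.2) & (t_other <= tr + max_lag)]
        if len(after):
            lags.append(after[0] - tr)
    if not lags:
        raise RuntimeError("could not pair oscillation extrema")
    return float(np.median(lags))


def calibrate_delay_chain(
    p: CellularParams = CellularParams(),
    duration: float = 120.0,
    dt: float = 1e-3,
    window: Tuple[float, float] = (20.0, 110.0),
) -> Dict[str, float]:
    """Measure the stage lags of the oscillating delay chain on one segment.

    Runs a single cellular segment (the reference 250-um-depth PA segment)
    embedded in the default network with all other segments fixed, then
    reads, from extremum timings in the analysis window: the dilation-phase
    lags WS->V_smc, V_smc->Ca, Ca->D (troughs to diameter peak), their sum,
    the constriction-phase lag (WS peak to D trough) and the full period.
    """
    from .engine import autoregulated_diameters
    from .hemodynamics import BoundaryConditions, CompiledNetwork, record_max_stresses
    from .network import generate_default_network

    net = generate_default_network()
    compiled = CompiledNetwork(net)
    bc = BoundaryConditions(60.0, 10.0)
    ws_max, wss_max = record_max_stresses(compiled)

    sid = "pa0_s8"  # depth 255 um: the reference working segment
    k = compiled.seg_index[sid]
    d_full = autoregulated_diameters(compiled, bc)
    pa = CellularPA(
        np.array([compiled.d_active_max[k]]),
        np.array([compiled.contractility[k]]),
        ws_max=np.array([ws_max[k]]),
        wss_max=np.array([wss_max[k]]),
        params=p,
    )
    d0 = d_full[k]
    pa.state.D[:] = d0

    # self-consistent anchoring: settle, re-centre the sigmoids, settle again;
    # then restart from the autoregulated diameter to excite the transient
    dt1 = 0.2
    for _round in range(2):
        for _ in range(int(40.0 / dt1)):
            st = compiled.solve(d_full, bc)
            for _ in range(int(dt1 / dt)):
                pa.step(np.array([st.IP[k]]), np.array([st.WSS[k]]), {}, dt)
            d_full[k] = pa.state.D[0]
        st = compiled.solve(d_full, bc)
        pa.anchor_operating_point(np.array([st.WS[k]]), np.array([st.WSS[k]]))
    d_full[k] = d0
    pa.state.D[:] = d0
    n_outer = int(round(duration / dt1))
    n_inner = int(round(dt1 / dt))
    t_hist, rows = [], []
    ip = wss = None
    for i in range(n_outer):
        st = compiled.solve(d_full, bc)
        ip, wss = st.IP[k], st.WSS[k]
        for _ in range(n_inner):
            pa.step(np.array([ip]), np.array([wss]), {}, dt)
        d_full[k] = pa.state.D[0]
        t_hist.append((i + 1) * dt1)
        rows.append(
            (
                ip * pa.state.D[0] / pa.h[0],
                pa.state.V_smc[0],
                pa.state.Ca_cyt[0],
                pa.state.D[0],
            )
        )
    t = np.array(t_hist)
    ws_tr, v_tr, ca_tr, d_tr = (np.array([r[j] for r in rows]) for j in range(4))

    m = (t >= window[0]) & (t <= window[1])
    t_w = t[m]

    def prom(x):
        return 0.1 * (x[m].max() - x[m].min() + 1e-12)

    ws_min = _extremum_times(t_w, ws_tr[m], "min", prom(ws_tr))
    v_min = _extremum_times(t_w, v_tr[m], "min", prom(v_tr))
    ca_min = _extremum_times(t_w, ca_tr[m], "min", prom(ca_tr))
    d_max = _extremum_times(t_w, d_tr[m], "max", prom(d_tr))
    ws_max_t = _extremum_times(t_w, ws_tr[m], "max", prom(ws_tr))
    d_min = _extremum_times(t_w, d_tr[m], "min", prom(d_tr))
    if min(map(len, (ws_min, v_min, ca_min, d_max, ws_max_t, d_min))) < 2:
        raise RuntimeError("trace is not oscillatory enough to calibrate lags")

    lag_ws_v = _lag(ws_min, v_min)
    lag_v_ca = _lag(v_min, ca_min)
    lag_ca_d = _lag(ca_min, d_max)
    dilation = _lag(ws_min, d_max)
    constriction = _lag(ws_max_t, d_min)
    periods = np.diff(d_max)
    return {
        "lag_ws_to_v": lag_ws_v,
        "lag_v_to_ca": lag_v_ca,
        "lag_ca_to_d": lag_ca_d,
        "dilation_lag_sum": dilation,
        "constriction_lag_sum": constriction,
        "period": float(np.median(periods)),
    }
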