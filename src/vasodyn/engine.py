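"""Coupled hemodynamic-vasodynamic simulation drivers.

The main loop alternates, at the coarse step dt1, a quasi-static network
flow solve (using the diameters committed at the previous step) with a
vasodynamic update of the reactive segments — the macro-scale delayed
myogenic model across all arteriolar segments, or the cellular model on a
single PA.  Hemodynamics always runs first within a step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.optimize

from . import macro as m
from .hemodynamics import BoundaryConditions, CompiledNetwork, ViscosityModel
from .network import (
    NetworkGenConfig,
    VascularNetwork,
    arteriolar_coupling_graph,
    generate_default_network,
)
from .stimuli import (
    AstroCouplingParams,
    AstroTriggerState,
    GammaBandSignal,
    astro_inhibition,
    astro_trigger,
    normalize_and_smooth,
)

__all__ = [
    "SimulationConfig",
    "CellularRunConfig",
    "TimeSeriesRecord",
    "autoregulated_diameters",
    "run_vasomotion_macro",
    "run_cellular_pa",
]


@dataclass
class SimulationConfig:
    """Configuration of a macro-scale vasomotion / functional-hyperemia run."""

    duration: float = 600.0  # s
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    macro: m.MacroParams = field(default_factory=m.MacroParams)
    visc: ViscosityModel = field(default_factory=ViscosityModel)
    netgen: NetworkGenConfig = field(default_factory=NetworkGenConfig)
    seed: int = 0
    # restrict the macro model to the segments of one PA (others held fixed)
    macro_only_pa: Optional[int] = None
    # hold the passive-distension component at its value from this time on
    freeze_pd_at: Optional[float] = None
    gamma: Optional[GammaBandSignal] = None
    astro: Optional[AstroCouplingParams] = None
    coupling: str = "propagator"  # "propagator" | "iterate"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.coupling not in ("propagator", "iterate"):
            raise ValueError("coupling must be 'propagator' or 'iterate'")
        if self.freeze_pd_at is not None and self.freeze_pd_at < 0:
            raise ValueError("freeze time must be within the simulation")


@dataclass
class TimeSeriesRecord:
    """Uniform-grid per-segment time series of a simulation run."""

    t: np.ndarray  # s
    segment_ids: List[str]
    channels: Dict[str, np.ndarray]  # name -> (n_t, n_segments)
    meta: Dict[str, object] = field(default_factory=dict)

    def channel(self, name: str, segment_id: Optional[str] = None) -> np.ndarray:
        arr = self.channels[name]
        if segment_id is None:
            return arr
        return arr[:, self.segment_ids.index(segment_id)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame: time, segment_id, one column per channel."""
        n_t, n_s = len(self.t), len(self.segment_ids)
        data = {
            "time": np.repeat(self.t, n_s),
            "segment_id": np.tile(np.asarray(self.segment_ids, dtype=object), n_t),
        }
        for name, arr in self.channels.items():
            data[name] = arr.reshape(-1)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")


def autoregulated_diameters(
    compiled: CompiledNetwork,
    bc: BoundaryConditions,
    reference_abnp: float = 40.0,
) -> np.ndarray:
    """Initial diameters emulating autoregulation at the working pressure.

    At the lower autoregulation limit (ABNP = ``reference_abnp``) arterioles
    are maximally dilated (D = d_active_max).  At higher working pressures a
    uniform tone scale s < 1 is applied to all arteriolar segments such that
    total network inflow matches the inflow at the lower limit — the flat
    part of the autoregulation curve.  Non-arteriolar diameters are fixed.
    """
    art = compiled.is_arteriolar
    d_ref = compiled.diameter0.copy()
    d_ref[art] = compiled.d_active_max[art]
    if bc.ABNP <= reference_abnp:
        return d_ref
    q_target = _network_inflow(compiled, d_ref, BoundaryConditions(reference_abnp, bc.VBNP))

    def excess(scale: float) -> float:
        d = compiled.diameter0.copy()
        d[art] = scale * compiled.d_active_max[art]
        return _network_inflow(compiled, d, bc) - q_target

    lo, hi = 0.4, 1.0
    if excess(hi) <= 0:
        return d_ref
    scale = scipy.optimize.brentq(excess, lo, hi, xtol=1e-6)
    d = compiled.diameter0.copy()
    d[art] = scale * compiled.d_active_max[art]
    return d


def _network_inflow(
    compiled: CompiledNetwork, diameters: np.ndarray, bc: BoundaryConditions
) -> float:
    st = compiled.solve(diameters, bc)
    q = 0.0
    for k in range(len(compiled.segment_ids)):
        if compiled.a_idx[k] == compiled.abn_idx:
            q += st.Q[k]
        elif compiled.b_idx[k] == compiled.abn_idx:
            q -= st.Q[k]
    return q


def _active_segment_ids(
    net: VascularNetwork, cfg: SimulationConfig, arteriolar_ids: List[str]
) -> List[str]:
    if cfg.macro_only_pa is None:
        return arteriolar_ids
    prefix = f"pa{cfg.macro_only_pa}_s"
    ids = [sid for sid in arteriolar_ids if sid.startswith(prefix)]
    if not ids:
        raise ValueError(f"no PA segments found for PA index {cfg.macro_only_pa}")
    return ids


def run_vasomotion_macro(
    cfg: SimulationConfig, net: Optional[VascularNetwork] = None
) -> TimeSeriesRecord:
    """Run the macro-scale network vasomotion simulation (Algorithm 2 loop).

    Per step: flow solve with the previous diameters -> delayed myogenic
    potential -> gap-junction coupling -> myogenic + passive diameter
    components (optionally modulated by the gamma-band drive and astrocytic
    pulses) -> rate-limited diameter commit.  Deterministic given the
    configuration and seed.
    """
    if net is None:
        net = generate_default_network(cfg.netgen)
    compiled = CompiledNetwork(net, cfg.visc)
    p = cfg.macro

    art_ids = [sid for sid, seg in net.segments.items() if seg.is_arteriolar]
    active_ids = _active_segment_ids(net, cfg, art_ids)
    act_idx = np.array([compiled.seg_index[s] for s in active_ids])

    adjacency = arteriolar_coupling_graph(net)
    sub_adj = {
        sid: {nb for nb in adjacency[sid] if nb in set(active_ids)} for sid in active_ids
    }
    a_mat = m.build_coupling_matrix(sub_adj, active_ids)
    propagator = (
        m.coupling_propagator(a_mat, p) if cfg.coupling == "propagator" else None
    )

    d_full = autoregulated_diameters(compiled, cfg.bc)
    st0 = compiled.solve(d_full, cfg.bc)
    state = m.init_ws_avg(
        st0.WS[act_idx],
        compiled.d_active_max[act_idx],
        compiled.h[act_idx],
        d_full[act_idx],
        p,
    )

    gamma = cfg.gamma
    if gamma is not None and (gamma.GB_norm is None or gamma.GB_S is None):
        gamma = normalize_and_smooth(gamma)
    astro_state = (
        AstroTriggerState.for_segments(len(active_ids)) if cfg.astro else None
    )
    astro_events: List[Tuple[float, str]] = []  # (time, segment_id) log

    n_steps = int(round(cfg.duration / p.dt1))
    t_grid = np.arange(n_steps + 1) * p.dt1
    n_act = len(active_ids)
    rec = {
        name: np.zeros((n_steps + 1, n_act))
        for name in ("D", "D_MR", "D_PD", "V_final", "WS")
    }
    rec["D"][0] = d_full[act_idx]
    rec["WS"][0] = st0.WS[act_idx]
    rec["V_final"][0] = p.V_baseline
    rec["D_PD"][0] = m.compute_d_pd(st0.WS[act_idx], state.D_WSmin, p)

    frozen_pd: Optional[np.ndarray] = None
    hist_window = max(2, int(round(1.0 / p.dt1)) + 1)

    for i in range(1, n_steps + 1):
        t = i * p.dt1
        st = compiled.solve(d_full, cfg.bc)  # hemodynamics first, D(i-1)
        ws = st.WS[act_idx]
        state.push_ws(ws)

        v_init = m.delayed_v_init(state, p)
        if propagator is not None:
            v_final = propagator @ v_init
        else:
            v_final = m.couple_potentials(v_init, a_mat, p)

        d_mr = m.compute_d_mr(v_final, p)
        d_pd = m.compute_d_pd(ws, state.D_WSmin, p)
        if cfg.freeze_pd_at is not None and t >= cfg.freeze_pd_at:
            if frozen_pd is None:
                frozen_pd = d_pd.copy()
            d_pd = frozen_pd

        extra = 0.0
        if astro_state is not None and i >= hist_window:
            firing = astro_trigger(
                rec["D"][i - hist_window : i],
                t_grid[i - hist_window : i],
                cfg.astro,
                t,
                astro_state,
            )
            for j in np.nonzero(firing)[0]:
                astro_events.append((t, active_ids[j]))
            extra = astro_inhibition(t, astro_state, cfg.astro)

        if gamma is not None:
            gi = max(i - p.lag_steps, 0)
            gt = min(gi * p.dt1, gamma.t[-1])
            gb = float(np.interp(gt, gamma.t, gamma.GB_norm))
            gbs = float(np.interp(gt, gamma.t, gamma.GB_S))
            d_mr_mod, damping = m.apply_nvc_modulation(d_mr, gb, gbs, p, extra)
            candidate = d_pd + d_mr_mod * damping
        elif np.any(np.asarray(extra) > 0):
            d_mr_mod, damping = m.apply_nvc_modulation(d_mr, 0.0, 0.0, p, extra)
            candidate = d_pd + d_mr_mod * damping
        else:
            candidate = d_pd + d_mr

        d_new = m.update_diameter(candidate, state.D, p)
        state.D = d_new
        d_full[act_idx] = d_new

        rec["D"][i] = d_new
        rec["D_MR"][i] = d_mr
        rec["D_PD"][i] = d_pd
        rec["V_final"][i] = v_final
        rec["WS"][i] = ws

    return TimeSeriesRecord(
        t=t_grid,
        segment_ids=active_ids,
        channels=rec,
        meta={
            "astro_events": astro_events,
            "ws_avg": state.WS_avg,
            "d_active_max": compiled.d_active_max[act_idx],
            "depth": compiled.depth[act_idx],
            "config": cfg,
        },
    )


# ---------------------------------------------------------------------------
# cellular-PA runs (Algorithm 1 ordering)
# ---------------------------------------------------------------------------


@dataclass
class CellularRunConfig:
    """Configuration of a cellular-level single-PA run within the network."""

    duration: float = 60.0  # s of recorded simulation
    pa_index: int = 0
    bc: BoundaryConditions = field(default_factory=BoundaryConditions)
    netgen: NetworkGenConfig = field(default_factory=NetworkGenConfig)
    cell: "CellularParams" = None  # type: ignore[assignment]
    dt1: float = 0.2  # s, hemodynamic step
    dt_cell: float = 1e-4  # s, cellular integration step
    gap_junctions: bool = True
    protocol: Optional["StimulusProtocol"] = None
    # settle the PA to its damped steady state before recording (emulates
    # letting the initial vasomotion fully damp before applying stimuli)
    pre_settle: bool = True
    pre_settle_max: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        from .cellular import CellularParams

        if self.cell is None:
            self.cell = CellularParams()
        if self.dt_cell >= self.dt1:
            raise ValueError("dt_cell must be smaller than dt1")


def run_cellular_pa(
    cfg: CellularRunConfig, net: Optional[VascularNetwork] = None
) -> TimeSeriesRecord:
    """Simulate one PA with the cellular segment model inside the network.

    Hemodynamics is re-solved every ``dt1`` (0.2 s) with all non-PA segments
    held at their autoregulated diameters; the cellular states advance every
    ``dt_cell``.  If a stimulus protocol is set, mediator levels (NO with the
    depth-dependent onset delay, glutamate, extracellular potassium) are
    evaluated per segment and applied from the protocol's onset time.
    """
    from .cellular import CellularPA
    from .hemodynamics import record_max_stresses
    from .stimuli import mediator_time_course, no_onset_delay

    if net is None:
        net = generate_default_network(cfg.netgen)
    compiled = CompiledNetwork(net)
    ws_max, wss_max = record_max_stresses(compiled)

    prefix = f"pa{cfg.pa_index}_s"
    seg_ids = [s for s in compiled.segment_ids if s.startswith(prefix)]
    if not seg_ids:
        raise ValueError(f"no PA segments with prefix {prefix!r}")
    idx = np.array([compiled.seg_index[s] for s in seg_ids])
    depths = compiled.depth[idx]

    pa = CellularPA(
        compiled.d_active_max[idx],
        compiled.contractility[idx],
        ws_max=ws_max[idx],
        wss_max=wss_max[idx],
        params=cfg.cell,
        gap_junctions=cfg.gap_junctions,
    )
    d_full = autoregulated_diameters(compiled, cfg.bc)
    pa.state.D[:] = d_full[idx]
    st0 = compiled.solve(d_full, cfg.bc)
    pa.anchor_operating_point(st0.WS[idx], st0.WSS[idx])

    n_inner = int(round(cfg.dt1 / cfg.dt_cell))

    def outer_step(t: float, mediators: Dict[str, np.ndarray | float]) -> None:
        st = compiled.solve(d_full, cfg.bc)
        ip, wss = st.IP[idx], st.WSS[idx]
        for _ in range(n_inner):
            pa.step(ip, wss, mediators, cfg.dt_cell)
        d_full[idx] = pa.state.D

    if cfg.pre_settle:
        # settle and re-anchor alternately: the mechanosensing midpoints end
        # up centred on the model's own equilibrium (self-consistent tuning)
        for round_ in range(3):
            d_prev = pa.state.D.copy()
            for j in range(int(cfg.pre_settle_max / (3 * cfg.dt1))):
                outer_step(j * cfg.dt1, {})
                if (j + 1) % 50 == 0:
                    if np.max(np.abs(pa.state.D - d_prev) / d_prev) < 1e-6:
                        break
                    d_prev = pa.state.D.copy()
            if round_ < 2:
                st_a = compiled.solve(d_full, cfg.bc)
                pa.anchor_operating_point(st_a.WS[idx], st_a.WSS[idx])

    n_steps = int(round(cfg.duration / cfg.dt1))
    t_grid = np.arange(n_steps + 1) * cfg.dt1
    channels = {
        name: np.zeros((n_steps + 1, len(seg_ids)))
        for name in ("D", "V_smc", "V_ec", "Ca", "tone", "NO", "WS")
    }

    def snapshot(i: int) -> None:
        st = pa.state
        channels["D"][i] = st.D
        channels["V_smc"][i] = st.V_smc
        channels["V_ec"][i] = st.V_ec
        channels["Ca"][i] = st.Ca_cyt
        channels["tone"][i] = st.tone
        channels["NO"][i] = st.NOcGMP
        channels["WS"][i] = st.D * 0.0  # filled below from the solve

    snapshot(0)
    for i in range(1, n_steps + 1):
        t = i * cfg.dt1
        mediators: Dict[str, np.ndarray | float] = {}
        if cfg.protocol is not None:
            per_seg = [mediator_time_course(t, cfg.protocol, z) for z in depths]
            mediators = {
                key: np.array([m[key] for m in per_seg])
                for key in ("NO", "glutamate", "K_ex_ec", "K_ex_smc")
            }
        st = compiled.solve(d_full, cfg.bc)
        ip, wss = st.IP[idx], st.WSS[idx]
        for _ in range(n_inner):
            pa.step(ip, wss, mediators, cfg.dt_cell)
        d_full[idx] = pa.state.D
        snapshot(i)
        channels["WS"][i] = ip * pa.state.D / pa.h

    return TimeSeriesRecord(
        t=t_grid,
        segment_ids=seg_ids,
        channels=channels,
        meta={"depth": depths, "config": cfg},
    )
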