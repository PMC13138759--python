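"""Macro-scale arteriolar segment model: delayed myogenic response,
passive distension, electrical coupling, and rate-limited diameter updates.

Each arteriolar segment carries a lumped smooth-muscle membrane potential.
The myogenic response depolarizes the segment in proportion to the deviation
of its wall stress, MR_D seconds earlier, from the frozen baseline WS_avg:

    V_init = -45 mV + MR_F * (WS(t - MR_D) - WS_avg)

Adjacent segments exchange charge through gap junctions, modeled as a
diffusive relaxation of membrane potentials on the arteriolar coupling graph
with time constant RC, iterated at the fine step dt2 inside each main step
dt1.  The myogenic diameter component is D_MR = (-45 - V_final) (mV mapped
1:1 to um); the passive component distends with instantaneous wall stress,

    D_PD = D_WSmin * (1 + alpha * (1 - exp(-K * WS))),   D_WSmin = 0.9 * Dmax

and the committed diameter is the sum, clipped to the maximum physiological
dilation (15 %/s) and constriction (7.5 %/s) rates.  During functional
hyperemia the myogenic component is additionally inhibited by the delayed
gamma-band drive and damped by its smoothed envelope:

    D_MR' = -45 - V_final - NMR_Inh * GB(t - lag)
    D     = D_PD + D_MR' * (1 - GB_S(t - lag))
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

__all__ = [
    "MacroParams",
    "MacroState",
    "V_BASELINE",
    "build_coupling_matrix",
    "coupling_propagator",
    "init_ws_avg",
    "delayed_v_init",
    "couple_potentials",
    "compute_d_mr",
    "compute_d_pd",
    "apply_nvc_modulation",
    "update_diameter",
]

V_BASELINE = -45.0  # mV, membrane potential at which the myogenic component is zero


class CouplingStabilityError(RuntimeError):
    """Explicit-Euler coupling iteration violates its stability bound."""


@dataclass(frozen=True)
class MacroParams:
    """Parameters of the macro-scale arteriolar segment model."""

    MR_D: float = 5.0  # s, myogenic response delay
    MR_F: float = 19e-3  # mV per mmHg, myogenic response factor
    RC: float = 1e-3  # s, gap-junction coupling time constant
    dt1: float = 0.2  # s, main (hemodynamic) step
    dt2: float = 1e-4  # s, inner coupling step
    alpha: float = 0.5  # max fractional passive distension above D_WSmin
    K: float = 3e-3  # per mmHg, passive distension rate
    V_baseline: float = V_BASELINE  # mV
    DR_dilation: float = 0.15  # fraction per s
    DR_constriction: float = 0.075  # fraction per s
    NMR_Inh: float = 10.0  # um-equivalent neuronal MR inhibition factor
    nvc_lag: float = 1.9  # s, gamma-band to vasodynamics lag
    mV_to_um: float = 1.0  # um per mV in the MR diameter component
    coupling_tol: float = 1e-6  # mV, inner-loop convergence threshold

    def __post_init__(self) -> None:
        if min(self.MR_D, self.RC, self.dt1, self.dt2) <= 0:
            raise ValueError("time constants and steps must be positive")
        if self.dt2 >= self.RC:
            raise ValueError("dt2 must be smaller than RC")
        if min(self.DR_dilation, self.DR_constriction) <= 0:
            raise ValueError("rate limits must be positive")

    @property
    def delay_steps(self) -> int:
        return int(round(self.MR_D / self.dt1))

    @property
    def lag_steps(self) -> int:
        return int(np.floor(self.nvc_lag / self.dt1))

    @property
    def inner_steps(self) -> int:
        return int(round(self.dt1 / self.dt2))


@dataclass
class MacroState:
    """State of all macro-model segments at one main step (array-aligned)."""

    d_active_max: np.ndarray  # um
    h: np.ndarray  # um
    D: np.ndarray  # um, committed diameter
    WS_avg: np.ndarray  # mmHg, frozen baseline
    WS_hist: np.ndarray  # (delay_steps+1, n) ring buffer of WS
    hist_pos: int = 0
    V_final: Optional[np.ndarray] = None
    frozen_D_PD: Optional[np.ndarray] = None  # set when passive component frozen

    @property
    def D_WSmin(self) -> np.ndarray:
        return 0.9 * self.d_active_max

    def push_ws(self, ws: np.ndarray) -> None:
        self.hist_pos = (self.hist_pos + 1) % self.WS_hist.shape[0]
        self.WS_hist[self.hist_pos] = ws

    def delayed_ws(self, delay_steps: int) -> np.ndarray:
        idx = (self.hist_pos - delay_steps) % self.WS_hist.shape[0]
        return self.WS_hist[idx]


def init_ws_avg(ws0: np.ndarray, d_active_max: np.ndarray, h: np.ndarray,
                D0: np.ndarray, p: MacroParams) -> MacroState:
    """Freeze the wall-stress baseline from the initial hemodynamic state.

    ``ws0`` is WS = IP*D/h at the autoregulated initial state; the ring
    buffer is pre-filled with it so the first delayed reads return baseline
    (and hence V_init = V_baseline).  The baseline is never recomputed.
    """
    ws0 = np.asarray(ws0, dtype=float)
    n_hist = int(round(p.MR_D / p.dt1)) + 1
    hist = np.tile(ws0, (n_hist, 1))
    return MacroState(
        d_active_max=np.asarray(d_active_max, dtype=float),
        h=np.asarray(h, dtype=float),
        D=np.asarray(D0, dtype=float).copy(),
        WS_avg=ws0.copy(),
        WS_hist=hist,
    )


def delayed_v_init(state: MacroState, p: MacroParams) -> np.ndarray:
    """Uncoupled membrane potential from the delayed wall-stress deviation."""
    ws_delayed = state.delayed_ws(p.delay_steps)
    return p.V_baseline + p.MR_F * (ws_delayed - state.WS_avg)


def build_coupling_matrix(
    adjacency: Mapping[str, Set[str]], order: Sequence[str]
) -> sp.csr_matrix:
    """Symmetric 0/1 adjacency over arteriolar segments in the given order."""
    index = {sid: i for i, sid in enumerate(order)}
    rows, cols = [], []
    for sid, nbrs in adjacency.items():
        for nb in nbrs:
            rows.append(index[sid])
            cols.append(index[nb])
    data = np.ones(len(rows))
    a = sp.csr_matrix((data, (rows, cols)), shape=(len(order), len(order)))
    if (a != a.T).nnz:
        raise ValueError("coupling adjacency must be symmetric")
    return a


def couple_potentials(
    v_init: np.ndarray,
    adjacency: sp.spmatrix,
    p: MacroParams,
    check_every: int = 50,
) -> np.ndarray:
    """Relax membrane potentials over the coupling graph for one main step.

    Explicit iteration V <- V + (dt2/RC) * sum_neighbors(V_nb - V), run until
    the largest per-iteration change falls below ``coupling_tol`` (mV) or the
    inner duration reaches dt1.  Mean-preserving on degree-regular graphs.
    """
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    r = p.dt2 / p.RC
    if r * deg.max(initial=0.0) >= 1.0:
        raise CouplingStabilityError(
            f"unstable coupling iteration: dt2/RC * max_degree = "
            f"{r * deg.max():.3f} >= 1; reduce dt2 or RC"
        )
    v = np.asarray(v_init, dtype=float).copy()
    for j in range(p.inner_steps):
        dv = r * (adjacency @ v - deg * v)
        v += dv
        if (j + 1) % check_every == 0 and np.abs(dv).max(initial=0.0) < p.coupling_tol:
            break
    return v


def coupling_propagator(adjacency: sp.spmatrix, p: MacroParams) -> np.ndarray:
    """Dense linear operator equivalent to running the full inner coupling loop.

    One main step of the coupling iteration is the linear map
    M = I + (dt2/RC)(A - diag(deg)); the propagator is M**inner_steps,
    computed once by repeated squaring.  Valid while the adjacency is static;
    it reproduces the iterative loop without early exit (the early exit only
    triggers when further iterations change potentials by < coupling_tol).
    """
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    r = p.dt2 / p.RC
    if r * deg.max(initial=0.0) >= 1.0:
        raise CouplingStabilityError(
            f"unstable coupling iteration: dt2/RC * max_degree = "
            f"{r * deg.max():.3f} >= 1; reduce dt2 or RC"
        )
    m = np.asarray(adjacency.todense(), dtype=float) * r
    m[np.diag_indices_from(m)] += 1.0 - r * deg
    return np.linalg.matrix_power(m, p.inner_steps)


def compute_d_mr(v_final: np.ndarray, p: MacroParams) -> np.ndarray:
    """Myogenic diameter component: positive when hyperpolarized below baseline."""
    return (p.V_baseline - np.asarray(v_final, dtype=float)) * p.mV_to_um


def compute_d_pd(ws_now: np.ndarray, d_ws_min: np.ndarray, p: MacroParams) -> np.ndarray:
    """Passive distension component, saturating at D_WSmin * (1 + alpha)."""
    ws = np.asarray(ws_now, dtype=float)
    if np.any(ws < 0):
        raise ValueError("wall stress must be nonnegative")
    return d_ws_min * (1.0 + p.alpha * (1.0 - np.exp(-p.K * ws)))


def apply_nvc_modulation(
    d_mr: np.ndarray,
    gb_delayed: float | np.ndarray,
    gb_s_delayed: float | np.ndarray,
    p: MacroParams,
    extra_inhibition: float | np.ndarray = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Neurogenic inhibition and NO-like damping of the myogenic component.

    Returns ``(d_mr_inhibited, damping_factor)`` where the diameter
    contribution is ``d_mr_inhibited * damping_factor``.  ``extra_inhibition``
    adds further um-equivalent inhibition (astrocytic potassium pulses).
    """
    gb = np.asarray(gb_delayed, dtype=float)
    gbs = np.asarray(gb_s_delayed, dtype=float)
    if np.any(gb < 0) or np.any(gb > 1) or np.any(gbs < 0) or np.any(gbs > 1):
        raise ValueError("gamma-band signals must be range-normalized to [0, 1]")
    d_mr_mod = np.asarray(d_mr, dtype=float) - p.NMR_Inh * gb - np.asarray(extra_inhibition)
    return d_mr_mod, 1.0 - gbs


def update_diameter(candidate: np.ndarray, d_prev: np.ndarray, p: MacroParams) -> np.ndarray:
    """Commit the diameter, clipped to the physiological rate limits."""
    d_prev = np.asarray(d_prev, dtype=float)
    if np.any(d_prev <= 0):
        raise ValueError("previous diameter must be positive")
    up = p.DR_dilation * p.dt1 * d_prev
    down = p.DR_constriction * p.dt1 * d_prev
    d = np.clip(np.asarray(candidate, dtype=float), d_prev - down, d_prev + up)
    if np.any(d <= 0):
        raise RuntimeError("diameter became nonpositive after rate limiting")
    return d
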