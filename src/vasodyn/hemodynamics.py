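"""Steady-state Poiseuille hemodynamics on the vascular network.

At each vasodynamic time step the blood flow distribution is treated as
quasi-static: nodal pressures solve the linear Kirchhoff system built from
per-segment Poiseuille conductances, with Dirichlet conditions at the artery
and vein boundary nodes.  From the pressure field the solver derives, per
segment, the volumetric flow Q, the intravascular pressure IP (mean of the
end-node pressures), the circumferential wall stress WS = IP*D/h (Laplace)
and the wall shear stress WSS = 32*mu*|Q|/(pi*D^3).

Units: pressure mmHg, flow nl/min, length and diameter um, viscosity mPa*s,
WS mmHg, WSS dyn/cm^2.  All unit conversion happens in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import VascularNetwork

__all__ = [
    "BoundaryConditions",
    "ViscosityModel",
    "HemodynamicState",
    "CompiledNetwork",
    "segment_conductance",
    "solve_pressures",
    "record_max_stresses",
]

# unit conversions
MMHG_TO_PA = 133.322
NL_PER_MIN_TO_M3_PER_S = 1e-12 / 60.0
PA_TO_DYN_CM2 = 10.0

#: diameter scale of a maximally constricted arteriolar segment, relative to
#: its maximal active diameter (matches the reference segment's 12.6/16.4
#: active-diameter span at the top of the autoregulation range)
MAX_CONSTRICTION_SCALE = 12.6 / 16.4


class HemodynamicsError(RuntimeError):
    """Raised on singular / infeasible flow solves."""


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet pressures at the artery (ABN) and vein (VBN) boundary nodes."""

    ABNP: float = 60.0  # mmHg
    VBNP: float = 10.0  # mmHg

    def __post_init__(self) -> None:
        if not self.ABNP > self.VBNP:
            raise ValueError("ABNP must exceed VBNP")


@dataclass(frozen=True)
class ViscosityModel:
    """Apparent blood viscosity law.

    ``constant`` uses ``mu_constant`` everywhere; ``diameter_dependent``
    applies an in-vitro apparent-viscosity law for tube diameter D (um) at a
    discharge hematocrit of 0.45, scaled by the plasma viscosity.
    """

    mode: str = "constant"
    mu_constant: float = 3.0  # mPa*s
    mu_plasma: float = 1.2  # mPa*s, diameter-dependent mode only

    def __call__(self, d_um: float | np.ndarray) -> float | np.ndarray:
        if self.mode == "constant":
            return self.mu_constant if np.isscalar(d_um) else np.full_like(
                np.asarray(d_um, dtype=float), self.mu_constant
            )
        if self.mode == "diameter_dependent":
            d = np.asarray(d_um, dtype=float)
            eta_rel = 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)
            mu = self.mu_plasma * eta_rel
            return float(mu) if np.isscalar(d_um) else mu
        raise ValueError(f"unknown viscosity mode {self.mode!r}")


def segment_conductance(
    d_um: float | np.ndarray,
    l_um: float | np.ndarray,
    visc: ViscosityModel = ViscosityModel(),
) -> float | np.ndarray:
    """Poiseuille conductance G = pi D^4 / (128 mu L), in nl/min per mmHg."""
    d = np.asarray(d_um, dtype=float)
    l = np.asarray(l_um, dtype=float)
    if np.any(d <= 0) or np.any(l <= 0):
        raise ValueError("diameter and length must be positive")
    mu_pa_s = np.asarray(visc(d_um), dtype=float) * 1e-3
    g_si = math.pi * (d * 1e-6) ** 4 / (128.0 * mu_pa_s * (l * 1e-6))
    g = g_si * MMHG_TO_PA / NL_PER_MIN_TO_M3_PER_S
    return float(g) if np.isscalar(d_um) and np.isscalar(l_um) else g


@dataclass
class HemodynamicState:
    """Pressures, flows and wall stresses of the network at one instant."""

    node_ids: Sequence[str]
    segment_ids: Sequence[str]
    node_pressure: np.ndarray  # mmHg, aligned with node_ids
    Q: np.ndarray  # nl/min, signed node_a -> node_b
    IP: np.ndarray  # mmHg
    WS: np.ndarray  # mmHg
    WSS: np.ndarray  # dyn/cm^2

    def pressure_of(self, node_id: str) -> float:
        return float(self.node_pressure[list(self.node_ids).index(node_id)])

    def by_segment(self, channel: str) -> Dict[str, float]:
        arr = getattr(self, channel)
        return {sid: float(v) for sid, v in zip(self.segment_ids, arr)}

    def to_frame(self, time: float = 0.0):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": time,
                "segment_id": list(self.segment_ids),
                "Q": self.Q,
                "IP": self.IP,
                "WS": self.WS,
                "WSS": self.WSS,
            }
        )

    def to_csv(self, path, time: float = 0.0) -> None:
        self.to_frame(time).to_csv(path, index=False, float_format="%.9g")


class CompiledNetwork:
    """Array form of a :class:`VascularNetwork` for repeated flow solves.

    Node and segment orderings are frozen at construction; the sparse
    Laplacian structure is rebuilt per solve (conductances change with the
    diameters) but index arrays are precomputed once.
    """

    def __init__(self, net: VascularNetwork, visc: ViscosityModel = ViscosityModel()):
        self.net = net
        self.visc = visc
        self.node_ids = list(net.nodes)
        self.node_index = {n: i for i, n in enumerate(self.node_ids)}
        segs = list(net.segments.values())
        self.segment_ids = [s.id for s in segs]
        self.seg_index = {s: i for i, s in enumerate(self.segment_ids)}
        self.a_idx = np.array([self.node_index[s.node_a] for s in segs])
        self.b_idx = np.array([self.node_index[s.node_b] for s in segs])
        self.length = np.array([s.length for s in segs])
        self.diameter0 = np.array([s.diameter for s in segs])
        self.d_active_max = np.array([s.d_active_max for s in segs])
        self.h = np.array([s.wall_thickness for s in segs])
        self.depth = np.array([s.cortical_depth for s in segs])
        self.contractility = np.array([s.contractility_index for s in segs])
        self.is_arteriolar = np.array([s.is_arteriolar for s in segs])
        self.cls = np.array([s.cls for s in segs])

        abn, vbn = net.abn, net.vbn
        self.abn_idx = self.node_index[abn.id]
        self.vbn_idx = self.node_index[vbn.id]
        n = len(self.node_ids)
        self.interior = np.array(
            [i for i in range(n) if i not in (self.abn_idx, self.vbn_idx)]
        )
        self._interior_pos = -np.ones(n, dtype=int)
        self._interior_pos[self.interior] = np.arange(len(self.interior))

    # -- solving ---------------------------------------------------------------
    def solve(self, diameters: np.ndarray, bc: BoundaryConditions) -> HemodynamicState:
        d = np.asarray(diameters, dtype=float)
        if d.shape != self.length.shape:
            raise ValueError("diameters array has wrong shape")
        if np.any(d <= 0):
            raise HemodynamicsError("nonpositive diameter in flow solve")
        g = segment_conductance(d, self.length, self.visc)

        n = len(self.node_ids)
        n_int = len(self.interior)
        a, b = self.a_idx, self.b_idx
        pos_a, pos_b = self._interior_pos[a], self._interior_pos[b]

        rows, cols, vals = [], [], []
        rhs = np.zeros(n_int)
        bound_p = np.full(n, np.nan)
        bound_p[self.abn_idx] = bc.ABNP
        bound_p[self.vbn_idx] = bc.VBNP

        both_int = (pos_a >= 0) & (pos_b >= 0)
        # diagonal contributions
        for pos, other_pos, other_idx in ((pos_a, pos_b, b), (pos_b, pos_a, a)):
            m = pos >= 0
            rows.append(pos[m])
            cols.append(pos[m])
            vals.append(g[m])
            mb = m & (other_pos < 0)  # neighbor is a boundary node
            np.add.at(rhs, pos[mb], g[mb] * bound_p[other_idx[mb]])
        # off-diagonals
        rows.append(pos_a[both_int]); cols.append(pos_b[both_int]); vals.append(-g[both_int])
        rows.append(pos_b[both_int]); cols.append(pos_a[both_int]); vals.append(-g[both_int])

        lap = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_int, n_int),
        )
        try:
            p_int = spla.spsolve(lap, rhs)
        except Exception as exc:
            raise HemodynamicsError(f"pressure solve failed: {exc}") from exc
        if not np.all(np.isfinite(p_int)):
            raise HemodynamicsError("pressure solve produced non-finite values "
                                    "(disconnected or singular network?)")

        p = np.empty(n)
        p[self.abn_idx] = bc.ABNP
        p[self.vbn_idx] = bc.VBNP
        p[self.interior] = p_int

        q = g * (p[a] - p[b])  # nl/min, signed a -> b
        ip = 0.5 * (p[a] + p[b])
        ws = ip * d / self.h
        mu_pa_s = np.asarray(self.visc(d), dtype=float) * 1e-3
        q_si = np.abs(q) * NL_PER_MIN_TO_M3_PER_S
        wss = 32.0 * mu_pa_s * q_si / (math.pi * (d * 1e-6) ** 3) * PA_TO_DYN_CM2
        return HemodynamicState(self.node_ids, self.segment_ids, p, q, ip, ws, wss)


def _diameters_from_mapping(
    compiled: CompiledNetwork, diameters: Optional[Mapping[str, float]]
) -> np.ndarray:
    d = compiled.diameter0.copy()
    if diameters:
        for sid, val in diameters.items():
            d[compiled.seg_index[sid]] = val
    return d


def solve_pressures(
    net: VascularNetwork,
    diameters: Optional[Mapping[str, float]] = None,
    bc: Optional[BoundaryConditions] = None,
    visc: ViscosityModel = ViscosityModel(),
) -> HemodynamicState:
    """Solve the network flow problem with per-segment ``diameters`` (um).

    Segments not named in ``diameters`` keep their stored diameter; when
    ``bc`` is omitted the network's stored boundary-node pressures apply.
    """
    compiled = CompiledNetwork(net, visc)
    if bc is None:
        bc = BoundaryConditions(net.abn.boundary_pressure, net.vbn.boundary_pressure)
    return compiled.solve(_diameters_from_mapping(compiled, diameters), bc)


def record_max_stresses(
    compiled: CompiledNetwork,
    abnp_sweep: Iterable[float] = tuple(range(40, 131, 10)),
    vbnp: float = 10.0,
    constriction_scale: float = MAX_CONSTRICTION_SCALE,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment maxima of WS and WSS over an arterial-pressure sweep.

    The sweep must include ABNP = 130 mmHg, where arteriolar segments are
    held maximally constricted (``constriction_scale`` x d_active_max) so the
    recorded WS_max / WSS_max can normalize the mechanosensing transfer
    functions.  Non-arteriolar segments keep their fixed diameters.
    """
    sweep = sorted(set(float(v) for v in abnp_sweep))
    if 130.0 not in sweep:
        raise ValueError("ABNP sweep must include 130 mmHg")
    ws_max = np.zeros(len(compiled.segment_ids))
    wss_max = np.zeros(len(compiled.segment_ids))
    d = compiled.diameter0.copy()
    d[compiled.is_arteriolar] = (
        constriction_scale * compiled.d_active_max[compiled.is_arteriolar]
    )
    for abnp in sweep:
        st = compiled.solve(d, BoundaryConditions(abnp, vbnp))
        ws_max = np.maximum(ws_max, st.WS)
        wss_max = np.maximum(wss_max, st.WSS)
    return ws_max, wss_max
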