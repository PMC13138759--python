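"""Neural and astrocytic drive signals.

Covers the stimulus protocols applied to the cellular PA model (NO /
glutamate / extracellular-potassium impulses and steps, with a
depth-dependent NO onset delay), the gamma-band envelope pipeline used to
modulate the macro-scale myogenic response (synthetic generator, CSV loader,
range normalization, decay-limited smoothing), and the astrocytic
constriction-triggered dilation rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

__all__ = [
    "StimulusProtocol",
    "GammaBandSignal",
    "AstroCouplingParams",
    "AstroTriggerState",
    "no_onset_delay",
    "mediator_time_course",
    "synthetic_gamma",
    "load_gamma_csv",
    "normalize_and_smooth",
    "astro_trigger",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """A neurogenic stimulus: impulse (instant rise, exponential NO decay)
    or step (level held on [t_on, t_off])."""

    kind: str = "impulse"  # "impulse" | "step"
    t_on: float = 0.0  # s
    t_off: float = 0.0  # s (steps only; impulses use decay from t_on)
    levels: Dict[str, float] = field(
        default_factory=lambda: {"NO": 0.0, "glutamate": 0.0,
                                 "K_ex_ec": 3.0, "K_ex_smc": 4.0}
    )
    baseline: Dict[str, float] = field(
        default_factory=lambda: {"NO": 0.0, "glutamate": 0.0,
                                 "K_ex_ec": 3.0, "K_ex_smc": 4.0}
    )
    depth_ref: float = 600.0  # um; below this depth NO rises instantly
    propagation_speed: float = 400.0  # um/s, upward NO onset propagation
    decay_tau: float = 5.0  # s, NO/cGMP degradation time constant

    def __post_init__(self) -> None:
        if self.kind not in ("impulse", "step"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "step" and self.t_off < self.t_on:
            raise ValueError("t_off must be >= t_on")
        if any(v < 0 for v in self.levels.values()):
            raise ValueError("stimulus levels must be nonnegative")


def no_onset_delay(depth: float, proto: StimulusProtocol) -> float:
    """Onset delay (s) of the NO rise at cortical ``depth`` (um).

    Deep segments (depth >= depth_ref) see the rise immediately; above that
    the onset propagates upward at ``propagation_speed``.
    """
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth >= proto.depth_ref:
        return 0.0
    return (proto.depth_ref - depth) / proto.propagation_speed


def mediator_time_course(
    t: float, proto: StimulusProtocol, depth: float = 600.0
) -> Dict[str, float]:
    """Mediator levels at time ``t`` (s) for a segment at ``depth`` (um).

    NO rises after the depth-dependent onset delay and decays exponentially
    with ``decay_tau``; potassium and glutamate rise without the onset delay
    and return to baseline instantly when the stimulus ends.
    """
    out = dict(proto.baseline)
    delay = no_onset_delay(depth, proto)
    rise = proto.t_on + delay
    if proto.kind == "impulse":
        if t >= rise:
            out["NO"] = proto.baseline["NO"] + proto.levels.get("NO", 0.0) * np.exp(
                -(t - rise) / proto.decay_tau
            )
        # non-NO mediators: brief impulse approximated as one decay_tau-free
        # rectangular pulse of 0.5 s (the stimulation itself)
        for key in ("glutamate", "K_ex_ec", "K_ex_smc"):
            if proto.t_on <= t < proto.t_on + 0.5 and key in proto.levels:
                out[key] = proto.levels[key]
    else:  # step
        inside = proto.t_on <= t < proto.t_off
        for key in ("glutamate", "K_ex_ec", "K_ex_smc"):
            if inside and key in proto.levels:
                out[key] = proto.levels[key]
        if t >= rise and "NO" in proto.levels:
            if t < proto.t_off:
                out["NO"] = proto.levels["NO"]
            else:
                out["NO"] = proto.baseline["NO"] + (
                    proto.levels["NO"] - proto.baseline["NO"]
                ) * np.exp(-(t - proto.t_off) / proto.decay_tau)
    return out


@dataclass
class GammaBandSignal:
    """Envelope of gamma-band neural activity on a uniform time grid."""

    t: np.ndarray  # s
    GB: np.ndarray  # raw envelope (arbitrary units, nonnegative)
    GB_norm: Optional[np.ndarray] = None  # range-normalized to [0, 1]
    GB_S: Optional[np.ndarray] = None  # decay-smoothed version of GB_norm
    lag: float = 1.9  # s, lag applied when driving the myogenic response

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def synthetic_gamma(duration: float, dt: float, seed: int = 0) -> GammaBandSignal:
    """Reproducible synthetic gamma-band power envelope.

    Band-limited (0.01-0.3 Hz) positive fluctuations with occasional
    step-like activity transitions, integrated in 0.4 s bins (emulating
    binned gamma-band power) and resampled to ``dt``.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    bin_dt = 0.4
    n = max(int(np.ceil(duration / bin_dt)) + 1, 8)
    tt = np.arange(n) * bin_dt

    # band-limited Gaussian process via FFT filtering
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, bin_dt)
    spec = np.fft.rfft(white)
    band = (freqs >= 0.01) & (freqs <= 0.3)
    spec[~band] = 0.0
    slow = np.fft.irfft(spec, n)
    if slow.std() > 0:
        slow = slow / slow.std()

    # occasional step-like transitions between activity levels
    steps = np.zeros(n)
    level = 0.0
    next_switch = rng.exponential(30.0)
    for i, ti in enumerate(tt):
        if ti >= next_switch:
            level = rng.uniform(0.0, 1.5)
            next_switch = ti + rng.exponential(30.0)
        steps[i] = level
    envelope = np.maximum(1.0 + 0.6 * slow + steps, 0.0)

    t_out = np.arange(0.0, duration + 0.5 * dt, dt)
    gb = np.interp(t_out, tt, envelope)
    return GammaBandSignal(t=t_out, GB=gb)


def load_gamma_csv(path: str | Path, lag: float = 1.9) -> GammaBandSignal:
    """Load a two-column (time_s, power) CSV gamma-band recording."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("gamma-band CSV needs two columns: time_s, power")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    gb = df.iloc[:, 1].to_numpy(dtype=float)
    return GammaBandSignal(t=t, GB=gb, lag=lag)


def normalize_and_smooth(sig: GammaBandSignal, tau_smooth: float = 5.0) -> GammaBandSignal:
    """Range-normalize the envelope and smooth its decreasing trend.

    GB_norm = (GB - min) / (max - min).  GB_S tracks GB_norm instantly on
    increases but relaxes exponentially (time constant ``tau_smooth``) on
    decreases, emulating the slow clearance of neuronally produced NO; hence
    GB_S >= GB_norm everywhere.
    """
    gb = np.asarray(sig.GB, dtype=float)
    rng_ = gb.max() - gb.min()
    if rng_ <= 0:
        raise ValueError("cannot range-normalize a constant signal")
    norm = (gb - gb.min()) / rng_
    dt = sig.dt
    decay = np.exp(-dt / tau_smooth)
    smooth = np.empty_like(norm)
    smooth[0] = norm[0]
    for i in range(1, len(norm)):
        smooth[i] = max(norm[i], smooth[i - 1] * decay)
    sig.GB_norm = norm
    sig.GB_S = smooth
    return sig


@dataclass(frozen=True)
class AstroCouplingParams:
    """Astrocytic constriction-triggered dilation rule.

    Astrocyte endfeet sense rapid arteriolar constriction; when the smoothed
    relative constriction rate exceeds the threshold, a transient potassium
    release inhibits the myogenic response for ``pulse_duration`` seconds,
    then the rule is refractory.
    """

    constriction_rate_threshold: float = 0.02  # fraction of D per s
    k_release_pulse: float = 5.0  # um-equivalent MR inhibition amplitude
    pulse_duration: float = 2.0  # s
    refractory: float = 10.0  # s
    rate_smooth_window: float = 1.0  # s, boxcar for dD/dt smoothing
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.constriction_rate_threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.refractory < self.pulse_duration:
            raise ValueError("refractory must be >= pulse_duration")


@dataclass
class AstroTriggerState:
    """Per-segment bookkeeping for the astrocytic rule."""

    last_event: np.ndarray  # s, time of last event per segment (-inf if none)

    @classmethod
    def for_segments(cls, n: int) -> "AstroTriggerState":
        return cls(last_event=np.full(n, -np.inf))


def astro_trigger(
    d_history: np.ndarray,
    t_history: np.ndarray,
    params: AstroCouplingParams,
    t: float,
    state: AstroTriggerState,
) -> np.ndarray:
    """Evaluate the astrocytic rule at time ``t``.

    ``d_history`` is (n_times, n_segments) of recent diameters on the grid
    ``t_history`` (spanning at least the smoothing window).  Returns a
    boolean array of segments that fire an event now; ``state.last_event``
    is updated for fired segments.
    """
    if not params.enabled:
        return np.zeros(d_history.shape[1], dtype=bool)
    if t_history[-1] - t_history[0] < params.rate_smooth_window - 1e-9:
        return np.zeros(d_history.shape[1], dtype=bool)
    window = t_history >= t_history[-1] - params.rate_smooth_window
    dh = d_history[window]
    th = t_history[window]
    span = th[-1] - th[0]
    if span <= 0:
        return np.zeros(d_history.shape[1], dtype=bool)
    rate = (dh[-1] - dh[0]) / span / np.maximum(dh[-1], 1e-12)  # fractional /s
    firing = rate < -params.constriction_rate_threshold
    firing &= (t - state.last_event) >= params.refractory
    state.last_event[firing] = t
    return firing


def astro_inhibition(
    t: float, state: AstroTriggerState, params: AstroCouplingParams
) -> np.ndarray:
    """Current um-equivalent MR inhibition from active astrocytic pulses."""
    active = (t - state.last_event) < params.pulse_duration
    return np.where(active, params.k_release_pulse, 0.0)
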