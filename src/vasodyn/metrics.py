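"""Summary metrics of simulated vasodynamic traces.

Peak-to-trough oscillation amplitude (as % of mean diameter), dominant
frequency, damping time, myogenic / passive amplitude decomposition, and
dilation onset / propagation-speed estimation from sigmoid fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.optimize
import scipy.signal

__all__ = [
    "MetricsReport",
    "amplitude_and_frequency",
    "decompose_mr_pd",
    "onset_and_propagation",
]


class AnalysisError(RuntimeError):
    """Raised when a trace cannot support the requested analysis."""


@dataclass
class MetricsReport:
    amplitude_pct: float = np.nan  # peak-to-trough, % of mean
    dominant_freq: float = np.nan  # Hz
    damping_time: Optional[float] = None  # s, None if sustained
    mr_share: float = np.nan  # % of oscillation amplitude
    pd_share: float = np.nan
    onset_times: Dict[float, float] = field(default_factory=dict)  # depth -> s
    propagation_speed: Optional[float] = None  # um/s

    def to_dict(self) -> Dict[str, object]:
        return {
            "amplitude_pct": self.amplitude_pct,
            "dominant_freq": self.dominant_freq,
            "damping_time": self.damping_time,
            "mr_share": self.mr_share,
            "pd_share": self.pd_share,
            "onset_times": self.onset_times,
            "propagation_speed": self.propagation_speed,
        }


def _peaks_troughs(x: np.ndarray, prominence: float) -> Tuple[np.ndarray, np.ndarray]:
    peaks, _ = scipy.signal.find_peaks(x, prominence=prominence)
    troughs, _ = scipy.signal.find_peaks(-x, prominence=prominence)
    return peaks, troughs


def amplitude_and_frequency(
    t: np.ndarray,
    x: np.ndarray,
    window: Optional[Tuple[float, float]] = None,
    prominence_frac: float = 0.01,
) -> MetricsReport:
    """Oscillation amplitude (% of mean), dominant frequency and damping time.

    Amplitude is (max - min) / mean * 100 over the analysis window; the
    dominant frequency comes from the periodogram peak; the damping time is
    the first time the cycle amplitude (from peak/trough detection with
    prominence >= ``prominence_frac`` of the mean) falls below 10 % of the
    first cycle's amplitude, or None if oscillation is sustained.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if window is not None:
        lo, hi = window
        if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
            raise AnalysisError(f"window {window} outside trace span")
        mask = (t >= lo) & (t <= hi)
        tw, xw = t[mask], x[mask]
    else:
        tw, xw = t, x
    if len(xw) < 8:
        raise AnalysisError("window too short for oscillation metrics")

    mean = float(xw.mean())
    amp_pct = (xw.max() - xw.min()) / mean * 100.0 if mean else np.nan

    dt = float(tw[1] - tw[0])
    detrended = xw - xw.mean()
    freqs, power = scipy.signal.periodogram(detrended, fs=1.0 / dt)
    dom = float(freqs[1:][np.argmax(power[1:])]) if len(freqs) > 2 else np.nan

    # cycle-amplitude envelope over the FULL trace for damping detection
    prom = prominence_frac * abs(x.mean())
    peaks, troughs = _peaks_troughs(x, prom)
    damping: Optional[float] = None
    if len(peaks) >= 2 and len(troughs) >= 2:
        # per-cycle amplitude: peak minus interpolated trough envelope
        tr_env = np.interp(t[peaks], t[troughs], x[troughs])
        cyc_amp = x[peaks] - tr_env
        if cyc_amp[0] > 0:
            below = np.nonzero(cyc_amp < 0.1 * cyc_amp[0])[0]
            if len(below):
                damping = float(t[peaks][below[0]])
    elif len(peaks) < 2:
        damping = float(t[0])  # no repeated cycles at this prominence

    return MetricsReport(amplitude_pct=amp_pct, dominant_freq=dom, damping_time=damping)


def decompose_mr_pd(
    t: np.ndarray,
    d_total: np.ndarray,
    d_mr: np.ndarray,
    d_pd: np.ndarray,
    window: Optional[Tuple[float, float]] = None,
) -> Tuple[float, float]:
    """Myogenic vs passive share of the oscillation amplitude, in percent.

    Each share is the component's peak-to-trough amplitude over the window
    divided by the total diameter's peak-to-trough amplitude, x100.
    """
    t = np.asarray(t, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
    else:
        mask = np.ones_like(t, dtype=bool)
    tot = np.ptp(np.asarray(d_total, dtype=float)[mask])
    if tot <= 0:
        raise AnalysisError("non-oscillatory trace: zero total peak-to-trough")
    mr = np.ptp(np.asarray(d_mr, dtype=float)[mask]) / tot * 100.0
    pd_ = np.ptp(np.asarray(d_pd, dtype=float)[mask]) / tot * 100.0
    return float(mr), float(pd_)


def _sigmoid(t, base, amp, t50, tau):
    return base + amp / (1.0 + np.exp(-(t - t50) / tau))


def fit_dilation_sigmoid(
    t: np.ndarray, d: np.ndarray, slope_threshold_frac: float = 0.05
) -> Tuple[float, float, np.ndarray]:
    """Fit a 4-parameter sigmoid to a rising diameter transient.

    Returns (onset_time, peak_time, fitted_params).  The onset is the first
    time the fitted curve's derivative crosses ``slope_threshold_frac`` of
    its maximum slope; the peak time is where the raw trace is maximal.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    amp0 = d.max() - d[0]
    if amp0 <= 0:
        raise AnalysisError("no dilation transient to fit")
    p0 = [d[0], amp0, t[np.argmax(np.gradient(d))], max((t[-1] - t[0]) / 20, 1e-3)]
    try:
        popt, _ = scipy.optimize.curve_fit(_sigmoid, t, d, p0=p0, maxfev=20000)
    except Exception as exc:
        resid = np.nan
        raise AnalysisError(f"sigmoid fit failed (residual={resid}): {exc}") from exc
    base, amp, t50, tau = popt
    if tau <= 0 or amp <= 0:
        raise AnalysisError(f"degenerate sigmoid fit: {popt}")
    # derivative amp/(4 tau) at t50; threshold crossing in closed form:
    # s'(t) = amp/tau * u(1-u), u = logistic((t-t50)/tau); solve u(1-u) = f/4
    f = slope_threshold_frac
    disc = np.sqrt(max(1.0 - f, 0.0))
    u = 0.5 * (1.0 - disc)
    onset = t50 + tau * np.log(u / (1.0 - u))
    peak_time = float(t[np.argmax(d)])
    return float(onset), peak_time, popt


def onset_and_propagation(
    traces: Dict[float, Tuple[np.ndarray, np.ndarray]],
    slope_threshold_frac: float = 0.05,
) -> MetricsReport:
    """Dilation onset per depth and upward propagation speed.

    ``traces`` maps cortical depth (um) to (t, diameter) arrays containing a
    rising transient.  The speed is |d depth / d onset| from a least-squares
    line through (onset, depth); identical onsets report speed None with an
    upper-bound flag in ``onset_times`` (all equal).
    """
    if len(traces) < 2:
        raise AnalysisError("need transients at >= 2 depths")
    onsets: Dict[float, float] = {}
    peaks: Dict[float, float] = {}
    for depth, (t, d) in traces.items():
        onset, peak, _ = fit_dilation_sigmoid(t, d, slope_threshold_frac)
        onsets[float(depth)] = onset
        peaks[float(depth)] = peak
    depths = np.array(sorted(onsets))
    ts = np.array([onsets[z] for z in depths])
    span = ts.max() - ts.min()
    if span <= 0:
        return MetricsReport(onset_times=onsets, propagation_speed=None)
    slope = np.polyfit(ts, depths, 1)[0]
    return MetricsReport(onset_times=onsets, propagation_speed=float(abs(slope)))
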