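"""Quantitative metrics: Ca flux integrals, inhibition fraction, AP waveform
metrics, and the supralinearity (convexity) check.

The calcium readout of the biophysical model is the reporter-channel
current; its magnitude integrated over a 100-ms window starting at test
pulse onset plays the role of the fluorescence-transient integral in the
imaging experiments. GABAergic suppression is expressed as
(dCa_ctl - dCa_inh) / dCa_ctl.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cable_model import Trace

__all__ = [
    "CaResponse",
    "InhibitionResult",
    "APMetrics",
    "ConvexityResult",
    "ca_flux_integral",
    "inhibition_fraction",
    "ap_metrics",
    "convexity_check",
]

DEFAULT_WINDOW = 100.0  # ms


@dataclass(frozen=True)
class CaResponse:
    """Integral of a calcium signal over a quantification window.

    ``integral`` is in uA*ms/cm2 for model reporter current, or in
    (dG/Gsat)*ms for imaging traces. The window is the half-open interval
    [t0, t0 + window).
    """

    site: str
    integral: float
    t0: float
    window: float = DEFAULT_WINDOW


@dataclass(frozen=True)
class InhibitionResult:
    """Fractional suppression of the Ca response by inhibition."""

    delta_ctl: float
    delta_inh: float
    fraction: float


@dataclass(frozen=True)
class APMetrics:
    """Action-potential waveform metrics at a recording site."""

    peak: float          # mV
    half_width: float    # ms, full width at half amplitude above baseline
    peak_ica: float      # signed extremum of the Ca current series
    present: bool = True


@dataclass(frozen=True)
class ConvexityResult:
    verdict: bool
    second_differences: np.ndarray


def ca_flux_integral(
    trace: Trace,
    t0: float,
    window: float = DEFAULT_WINDOW,
    series: str = "ica",
    mode: str = "inward",
    site: str = "",
) -> CaResponse:
    """Trapezoidal integral of a Ca signal over [t0, t0 + window).

    ``mode="inward"`` integrates the magnitude of the inward (negative)
    current, clipped at zero, which orients model responses positively;
    ``mode="signed"`` integrates the raw series (used for baseline-
    subtracted fluorescence).
    """
    t = trace.t
    if t0 < t[0] - 1e-9 or t0 + window > t[-1] + 1e-9:
        raise ValueError(
            f"trace [{t[0]}, {t[-1]}] ms does not cover the window "
            f"[{t0}, {t0 + window}] ms"
        )
    m = (t >= t0 - 1e-9) & (t <= t0 + window + 1e-9)
    y = np.asarray(trace[series], dtype=float)[m]
    if mode == "inward":
        y = np.clip(-y, 0.0, None)
    elif mode != "signed":
        raise ValueError(f"unknown mode {mode!r}")
    return CaResponse(
        site=site, integral=float(np.trapezoid(y, t[m])), t0=t0, window=window
    )


def inhibition_fraction(ctl: CaResponse, inh: CaResponse) -> InhibitionResult:
    """(dCa_ctl - dCa_inh) / dCa_ctl for a matched control/inhibited pair."""
    if ctl.site != inh.site:
        raise ValueError(f"site mismatch: {ctl.site!r} vs {inh.site!r}")
    if abs(ctl.window - inh.window) > 1e-9:
        raise ValueError("window mismatch between control and inhibited responses")
    if ctl.integral <= 0:
        raise ValueError("inhibition fraction undefined for nonpositive control response")
    return InhibitionResult(
        delta_ctl=ctl.integral,
        delta_inh=inh.integral,
        fraction=(ctl.integral - inh.integral) / ctl.integral,
    )


def _interp_crossing(t0, y0, t1, y1, level):
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def ap_metrics(
    trace: Trace,
    baseline: float = -64.0,
    series: str = "v",
    ica_series: str = "ica",
    min_amplitude: float = 10.0,
) -> APMetrics:
    """Peak voltage, half-width, and peak Ca current of a single spike.

    The half-width is the full width at baseline + (peak - baseline)/2,
    with linear interpolation between samples; the baseline is the holding
    level, not the instantaneous pre-spike voltage, so widths are
    comparable across train conditions. A waveform rising less than
    ``min_amplitude`` mV above baseline is flagged absent.
    """
    v = np.asarray(trace[series], dtype=float)
    t = trace.t
    k = int(np.argmax(v))
    peak = float(v[k])
    if peak < baseline + min_amplitude:
        return APMetrics(peak=np.nan, half_width=np.nan, peak_ica=np.nan, present=False)
    half = baseline + (peak - baseline) / 2.0

    i = k
    while i > 0 and v[i - 1] >= half:
        i -= 1
    t_left = t[0] if i == 0 else _interp_crossing(t[i - 1], v[i - 1], t[i], v[i], half)
    j = k
    while j < len(v) - 1 and v[j + 1] >= half:
        j += 1
    t_right = (
        t[-1] if j == len(v) - 1
        else _interp_crossing(t[j], v[j], t[j + 1], v[j + 1], half)
    )

    peak_ica = np.nan
    if ica_series in trace.series:
        ica = np.asarray(trace[ica_series], dtype=float)
        peak_ica = float(ica[np.argmax(np.abs(ica))])
    return APMetrics(
        peak=peak, half_width=float(t_right - t_left), peak_ica=peak_ica, present=True
    )


def convexity_check(xs, ys) -> ConvexityResult:
    """Supralinearity verdict from second differences of y(x).

    Points are sorted by x; consecutive-slope differences (second divided
    differences up to positive spacing factors) must all be positive for a
    True verdict. Requires at least 3 points with strictly distinct x.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3:
        raise ValueError("convexity check requires at least 3 points")
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    dx = np.diff(xs)
    if np.any(dx <= 0):
        raise ValueError("x values must be strictly monotone")
    slopes = np.diff(ys) / dx
    second = np.diff(slopes)
    return ConvexityResult(verdict=bool(np.all(second > 0)), second_differences=second)
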