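"""Photobleaching analysis: traces, normalization, decay fits, loss metrics.

A bleaching experiment records the emission spectrum of one continuously
illuminated pixel at 1 s intervals for 100 s. The analysis integrates each
frame over a per-dye wavelength window, min-max normalizes the resulting
trace to [0, 1], fits a (bi-)exponential decay plus baseline, and reports
the fraction of the initial intensity lost by a given time.

Default integration windows: the full recorded spectrum for F18,
578–817 nm for MitoTracker Red and 567–817 nm for ATTO647N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from lmfit import Parameters, minimize

from .spectral import DEFAULT_WAVELENGTH_RANGE, FilterChannel, integrate_band

DEFAULT_WINDOWS = {
    "F18": FilterChannel("full", *DEFAULT_WAVELENGTH_RANGE),
    "MitoTracker Red": FilterChannel("578-817", 578.0, 817.0),
    "ATTO647N": FilterChannel("567-817", 567.0, 817.0),
}


@dataclass
class BleachTrace:
    """Integrated band intensity vs time for one bleaching experiment."""

    times_s: np.ndarray
    intensity: np.ndarray
    window: FilterChannel
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensity must be 1-D and equally long")
        if self.normalized and (
            abs(y.max() - 1.0) > 1e-9 or abs(y.min()) > 1e-9
        ):
            raise ValueError("normalized trace must span [0, 1] exactly")
        self.times_s = t
        self.intensity = y


def trace_from_series(series, window: FilterChannel, dt_s: float = 1.0) -> BleachTrace:
    """Integrate each frame of a spectral time series over the window."""
    if not series:
        raise ValueError("empty spectral series")
    axis = series[0].axis
    for i, spec in enumerate(series):
        if spec.axis != axis:
            raise ValueError(f"frame {i} has a different wavelength axis")
    intensity = np.array([integrate_band(s, window) for s in series])
    times = np.arange(len(series), dtype=float) * dt_s
    return BleachTrace(times_s=times, intensity=intensity, window=window)


def minmax_normalize(trace: BleachTrace) -> BleachTrace:
    """Affine rescale to [0, 1]; idempotent; errors on a constant trace."""
    y = trace.intensity
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        raise ValueError("trace has zero dynamic range; cannot normalize")
    return replace(trace, intensity=(y - lo) / (hi - lo), normalized=True)


def _decay_model(params, t, n_components):
    out = np.full_like(t, params["baseline"].value, dtype=float)
    for i in range(n_components):
        out += params[f"a{i}"].value * np.exp(-t / params[f"tau{i}"].value)
    return out


def fit_decay(trace: BleachTrace, n_components: int = 2) -> dict:
    """Nonlinear least-squares fit of sum_i a_i exp(-t/tau_i) + b.

    Initialization is fixed for determinism: tau guesses log-spaced over
    (t_max/50, t_max/2), equal amplitudes sharing the observed dynamic
    range, baseline at the trace minimum; all parameters bounded >= 0.
    Components are returned sorted by increasing tau.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t, y = trace.times_s, trace.intensity
    if t.size < 3 * (2 * n_components + 1):
        raise ValueError(
            f"need at least {3 * (2 * n_components + 1)} samples for "
            f"{n_components} component(s), got {t.size}"
        )
    t_max = float(t.max())
    taus0 = np.geomspace(t_max / 50.0, t_max / 2.0, n_components)
    span = max(float(y[0] - y.min()), 1e-9)
    params = Parameters()
    # initial values sit strictly inside the bounds: lmfit's bound
    # transform has zero gradient exactly at a bound, which freezes the fit
    params.add("baseline", value=float(y.min()) + 0.01 * span, min=0.0)
    for i in range(n_components):
        params.add(f"a{i}", value=span / n_components, min=0.0)
        params.add(f"tau{i}", value=taus0[i], min=1e-9)
    result = minimize(
        lambda p: _decay_model(p, t, n_components) - y,
        params,
        method="leastsq",
    )
    if not result.success:
        raise RuntimeError(
            f"decay fit did not converge: {result.message}; "
            f"last iterate {result.params.valuesdict()}"
        )
    comps = sorted(
        (
            (result.params[f"tau{i}"].value, result.params[f"a{i}"].value)
            for i in range(n_components)
        ),
    )
    resid = _decay_model(result.params, t, n_components) - y
    return {
        "amplitudes": [a for _, a in comps],
        "taus": [tau for tau, _ in comps],
        "baseline": float(result.params["baseline"].value),
        "residual": float(np.sqrt(np.mean(resid**2))),
    }


def fraction_lost(trace: BleachTrace, t_s: float) -> float:
    """1 − I(t)/I(0), with I(t) linearly interpolated between samples.

    I(0) is the first recorded frame. Intended for min-max normalized
    traces, where the result is the fraction of the initial dynamic range
    lost by time t.
    """
    t = trace.times_s
    if not (t[0] <= t_s <= t[-1]):
        raise ValueError(f"t={t_s} s outside sampled range [{t[0]}, {t[-1]}] s")
    i0 = float(trace.intensity[0])
    if i0 <= 0:
        raise ValueError("initial intensity is not positive")
    it = float(np.interp(t_s, t, trace.intensity))
    return 1.0 - it / i0
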