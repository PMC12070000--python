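"""Discrete-to-continuous torque fusion: Kalman smoothing + low-pass filter.

Because each angle bin owns its own network, the raw per-window prediction
stream jumps whenever the knee crosses a bin boundary.  A scalar
random-walk Kalman filter (state = torque; x_{k+1} = x_k + w, w~N(0,Q);
z_k = x_k + v, v~N(0,R)) absorbs those jumps, and a zero-phase Butterworth
low-pass removes residual ripple, yielding a continuous torque estimate
suitable as a control feedback signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class FusionConfig:
    """Kalman noise variances and low-pass parameters.

    ``kalman_q`` is the process-noise variance (how fast the true torque may
    wander between windows), ``kalman_r`` the measurement-noise variance of
    the raw predictions.  The low-pass cutoff applies to the prediction-rate
    stream (default 5 Hz, comfortably above squat/gait torque bandwidth).
    """

    kalman_q: float = 0.01
    kalman_r: float = 1.0
    lowpass_cut_hz: float = 5.0
    lowpass_order: int = 4

    def __post_init__(self) -> None:
        for name in ("kalman_q", "kalman_r", "lowpass_cut_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.lowpass_order < 1:
            raise ConfigError("lowpass_order must be >= 1")


def kalman_smooth(series: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Causal scalar random-walk Kalman filter.

    Initialized at the first sample with variance R; the standard
    predict/update recursion follows.
    """
    z = np.asarray(series, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise DataError("kalman_smooth expects a non-empty 1-D series")
    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        raise DataError(f"non-finite input at index {bad[0]}")
    q, r = cfg.kalman_q, cfg.kalman_r
    out = np.empty_like(z)
    x, p = z[0], r
    out[0] = x
    for k in range(1, z.size):
        p = p + q
        gain = p / (p + r)
        x = x + gain * (z[k] - x)
        p = (1.0 - gain) * p
        out[k] = x
    return out


def kalman_steady_state_gain(cfg: FusionConfig) -> float:
    """Closed-form steady-state gain of the scalar random-walk filter.

    Solves the scalar Riccati fixed point P = (1-K)(P+Q), K = (P+Q)/(P+Q+R):
    the prior variance M = P+Q satisfies M^2 - Q*M - Q*R = 0.
    """
    q, r = cfg.kalman_q, cfg.kalman_r
    m = (q + np.sqrt(q * q + 4.0 * q * r)) / 2.0
    return float(m / (m + r))


def fuse(
    raw_predictions: np.ndarray, cfg: FusionConfig, rate_hz: float
) -> np.ndarray:
    """Kalman-smooth then zero-phase low-pass a bin-wise prediction stream.

    ``rate_hz`` is the prediction rate (1000 / step_ms for the windowing in
    use).  Output has the same length as the input.
    """
    if rate_hz <= 0:
        raise ConfigError("rate_hz must be positive")
    if cfg.lowpass_cut_hz >= rate_hz / 2:
        raise ConfigError(
            f"lowpass cutoff {cfg.lowpass_cut_hz} Hz must be below the "
            f"prediction Nyquist rate {rate_hz / 2} Hz"
        )
    smoothed = kalman_smooth(raw_predictions, cfg)
    sos = signal.butter(cfg.lowpass_order, cfg.lowpass_cut_hz, fs=rate_hz, output="sos")
    padlen = 3 * (2 * cfg.lowpass_order + 1)
    if smoothed.size <= padlen:
        # too short for filtfilt padding; the Kalman pass alone stands
        return smoothed
    return signal.sosfiltfilt(sos, smoothed)
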