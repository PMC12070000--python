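"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive results with naive loops and textbook formulas,
sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def hampel_flags_bruteforce(x: np.ndarray, window_len: int, k: float) -> np.ndarray:
    """Flag outliers with explicit per-window median/std loops."""
    n = len(x)
    wl = min(window_len, n)
    mask = np.zeros(n, dtype=bool)
    start = 0
    while start < n:
        w = list(x[start : start + wl])
        if len(w) >= 2:
            med = float(np.median(w))
            mean = sum(w) / len(w)
            sd = math.sqrt(sum((v - mean) ** 2 for v in w) / (len(w) - 1))
            for j, v in enumerate(w):
                if abs(v - med) > k * sd:
                    mask[start + j] = True
        start += wl
    return mask


def features_bruteforce(window, eps: float = 0.0) -> tuple[float, float, float, float, float]:
    """RMS, VAR, ZC, WL, MAV via explicit loops."""
    w = [float(v) for v in window]
    n = len(w)
    rms = math.sqrt(sum(v * v for v in w) / n)
    mean = sum(w) / n
    var = sum((v - mean) ** 2 for v in w) / (n - 1)
    zc = 0
    for a, b in zip(w[:-1], w[1:]):
        if a * b < 0 and abs(a) > eps and abs(b) > eps:
            zc += 1
    wl = sum(abs(b - a) for a, b in zip(w[:-1], w[1:]))
    mav = sum(abs(v) for v in w) / n
    return rms, var, float(zc), wl, mav


def pearson_bruteforce(x, y) -> float:
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def rmse_bruteforce(pred, true) -> float:
    return math.sqrt(sum((p - t) ** 2 for p, t in zip(pred, true)) / len(pred))


def r2_bruteforce(pred, true) -> float:
    tm = sum(true) / len(true)
    sse = sum((p - t) ** 2 for p, t in zip(pred, true))
    sst = sum((t - tm) ** 2 for t in true)
    return 1.0 - sse / sst


def pca_leading_eigvec_power_iteration(block: np.ndarray, iters: int = 2000) -> tuple[float, np.ndarray]:
    """Leading eigenpair of the sample covariance via power iteration."""
    x = np.asarray(block, dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    v = np.ones(cov.shape[0]) / math.sqrt(cov.shape[0])
    for _ in range(iters):
        v = cov @ v
        v = v / np.linalg.norm(v)
    lam = float(v @ cov @ v)
    return lam, v


def spectrum_db(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum in dB (freqs, 20*log10 |X|)."""
    x = np.asarray(x, dtype=float)
    amp = np.abs(np.fft.rfft(x)) / len(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    return freqs, 20.0 * np.log10(np.maximum(amp, 1e-300))


def tone_power(x: np.ndarray, fs: float, f0: float, half_bw: float = 1.0) -> float:
    """Power of a spectral line: summed |X|^2 within f0 +/- half_bw."""
    amp = np.abs(np.fft.rfft(x)) / len(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    sel = (freqs >= f0 - half_bw) & (freqs <= f0 + half_bw)
    return float(np.sum(amp[sel] ** 2))
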