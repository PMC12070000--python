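"""sEMG cleaning: band-pass, notch bank, Hampel outlier removal, normalization.

The stages mirror the standard sEMG conditioning chain.  Raw surface EMG
carries a DC offset from the acquisition front end, very slow (0.2-0.5 Hz)
baseline drift from sweat and electrode motion, 50 Hz mains hum with
harmonics, broadband instrumentation noise and sparse impulsive artifacts.
The useful myoelectric content lies between roughly 10 and 500 Hz, so the
chain is:

1. 4th-order Butterworth band-pass (default 10-500 Hz) — removes DC, drift
   and out-of-band noise,
2. a cascade of IIR notch sections at the mains fundamental and harmonics,
3. Hampel outlier replacement in stepping windows (median-centred k-sigma
   rule); flagged samples are replaced by the window median so the channel
   stays time-aligned with the angle/torque series,
4. per-channel min-max normalization onto [-1, 1], with the affine scale
   retained for later streaming use.

Filters run zero-phase (forward-backward) by default for offline analysis; a
causal single-pass mode exists for streaming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigError, DataError
from .recording import EmgRecording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass and notch-bank parameters.

    ``band_low_hz``/``band_high_hz`` are the Butterworth half-power edges;
    ``order`` its order.  The notch bank places one second-order section at
    ``notch_fundamental_hz`` and each harmonic up to ``notch_harmonics``
    (harmonics at or above Nyquist are skipped with a warning), each with
    quality factor ``notch_q``.
    """

    band_low_hz: float = 10.0
    band_high_hz: float = 500.0
    order: int = 4
    notch_fundamental_hz: float = 50.0
    notch_harmonics: int = 9
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ConfigError(
                f"need 0 < band_low ({self.band_low_hz}) < band_high "
                f"({self.band_high_hz})"
            )
        if self.order < 1:
            raise ConfigError(f"filter order must be >= 1, got {self.order}")
        if self.notch_harmonics < 1:
            raise ConfigError("notch_harmonics must be >= 1")
        if self.notch_q <= 0:
            raise ConfigError("notch_q must be positive")

    def validate_for(self, fs: float) -> None:
        nyq = fs / 2
        if self.band_high_hz >= nyq:
            raise ConfigError(
                f"band_high_hz={self.band_high_hz} is at or above the Nyquist "
                f"frequency {nyq} for fs={fs}"
            )
        if self.notch_fundamental_hz >= nyq:
            raise ConfigError(
                f"notch fundamental {self.notch_fundamental_hz} Hz is at or "
                f"above Nyquist {nyq}"
            )


@dataclass(frozen=True)
class HampelConfig:
    """Stepping-window Hampel identifier parameters.

    ``window_len`` samples per window (default 750); a point is flagged when
    its absolute deviation from the window median exceeds ``k`` times the
    window's sample standard deviation (default k=3).
    """

    window_len: int = 750
    k: float = 3.0
    use_mad: bool = False  # robust spread estimate instead of the sample std

    def __post_init__(self) -> None:
        if self.window_len < 3:
            raise ConfigError("window_len must be >= 3")
        if self.k <= 0:
            raise ConfigError("k must be positive")


@dataclass(frozen=True)
class MinMaxScale:
    """Affine map sending [lo, hi] onto [-1, 1]; invertible, serializable."""

    lo: float
    hi: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def invert(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) + 1.0) * (self.hi - self.lo) / 2.0 + self.lo

    def to_dict(self) -> dict:
        return {"lo": self.lo, "hi": self.hi}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxScale":
        return cls(lo=float(d["lo"]), hi=float(d["hi"]))


def _bandpass_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate_for(fs)
    return signal.butter(
        spec.order,
        [spec.band_low_hz, spec.band_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


def notch_sos(spec: FilterSpec, fs: float) -> np.ndarray:
    """Cascade of second-order notches at the fundamental and harmonics."""
    spec.validate_for(fs)
    sections = []
    for h in range(1, spec.notch_harmonics + 1):
        f0 = h * spec.notch_fundamental_hz
        if f0 >= fs / 2:
            log.warning("skipping notch harmonic %.1f Hz >= Nyquist %.1f Hz", f0, fs / 2)
            continue
        b, a = signal.iirnotch(f0, spec.notch_q, fs=fs)
        sections.append(signal.tf2sos(b, a))
    if not sections:
        raise ConfigError("no notch section below Nyquist")
    return np.vstack(sections)


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def bandpass_filter(
    rec: EmgRecording, spec: FilterSpec, zero_phase: bool = True
) -> EmgRecording:
    """Butterworth band-pass every EMG channel; angle/torque untouched."""
    if rec.n_samples == 0:
        raise DataError("cannot filter an empty signal")
    sos = _bandpass_sos(spec, rec.fs)
    return rec.with_samples(_apply_sos(sos, rec.samples, zero_phase))


def notch_filter(
    rec: EmgRecording, spec: FilterSpec, zero_phase: bool = True
) -> EmgRecording:
    """Suppress mains hum and harmonics with a bank of IIR notch sections."""
    if rec.n_samples == 0:
        raise DataError("cannot filter an empty signal")
    sos = notch_sos(spec, rec.fs)
    return rec.with_samples(_apply_sos(sos, rec.samples, zero_phase))


def hampel_clean(
    series: np.ndarray, cfg: HampelConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Median-replace outliers in non-overlapping stepping windows.

    Returns ``(cleaned, mask)`` where ``mask`` is True at flagged indices.
    Windows of ``cfg.window_len`` samples step through the series without
    overlap; a trailing remainder forms a final short window.  Within each
    window a point is flagged when ``|x - median| > k * std`` and replaced by
    the window median.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise DataError("hampel_clean expects a non-empty 1-D series")
    n = x.size
    wl = cfg.window_len
    if wl > n:
        log.info("hampel window (%d) longer than series (%d); using one window", wl, n)
        wl = n
    cleaned = x.copy()
    mask = np.zeros(n, dtype=bool)
    for start in range(0, n, wl):
        w = x[start : start + wl]
        if w.size < 2:
            continue
        med = np.median(w)
        if cfg.use_mad:
            # 1.4826 * MAD estimates sigma for Gaussian data
            spread = 1.4826 * np.median(np.abs(w - med))
        else:
            spread = w.std(ddof=1)
        flags = np.abs(w - med) > cfg.k * spread
        cleaned[start : start + wl][flags] = med
        mask[start : start + wl] = flags
    return cleaned, mask


def normalize_minmax(series: np.ndarray, name: str = "") -> tuple[np.ndarray, MinMaxScale]:
    """Affine-map a series so min -> -1 and max -> +1.

    The returned :class:`MinMaxScale` reproduces the same map on new data
    (e.g. a streaming continuation of the same channel).
    """
    x = np.asarray(series, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        label = f" {name!r}" if name else ""
        raise DataError(f"cannot min-max normalize constant channel{label} (zero range)")
    scale = MinMaxScale(lo=lo, hi=hi)
    return scale.apply(x), scale


@dataclass
class PreprocessResult:
    """Cleaned recording plus per-channel outlier masks and scale parameters."""

    recording: EmgRecording
    outlier_mask: np.ndarray  # (channels, samples) bool
    scales: dict[str, MinMaxScale]


def preprocess_pipeline(
    rec: EmgRecording,
    spec: FilterSpec | None = None,
    hampel: HampelConfig | None = None,
    zero_phase: bool = True,
) -> PreprocessResult:
    """Run band-pass -> notch -> Hampel -> min-max on every channel.

    Angle and torque series are passed through untouched; sample and channel
    counts are preserved.
    """
    spec = spec or FilterSpec()
    hampel = hampel or HampelConfig()
    out = bandpass_filter(rec, spec, zero_phase)
    out = notch_filter(out, spec, zero_phase)
    cleaned = np.empty_like(out.samples)
    mask = np.zeros(out.samples.shape, dtype=bool)
    scales: dict[str, MinMaxScale] = {}
    for i, name in enumerate(out.channel_names):
        cleaned[i], mask[i] = hampel_clean(out.samples[i], hampel)
        cleaned[i], scales[name] = normalize_minmax(cleaned[i], name=name)
    return PreprocessResult(
        recording=out.with_samples(cleaned), outlier_mask=mask, scales=scales
    )
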