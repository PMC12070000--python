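"""Overlapping-window segmentation and time-domain EMG features.

Five classical time-domain features are computed per window and channel:

- RMS  root mean square, sqrt(mean(x^2))
- VAR  sample variance (N-1 divisor)
- ZC   zero crossings: strict sign changes whose flanking samples both
       exceed a small dead-band epsilon (suppresses noise-driven counts)
- WL   waveform length, sum of absolute successive differences
- MAV  mean absolute value

Two window presets are provided: ``acq2000`` (200 ms window, 50 ms step —
75% overlap at 2 kHz, i.e. 400/100 samples) and ``train1000`` (200 ms
window, 100 ms step — 50% overlap at 1 kHz, i.e. 200/100 samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .recording import EmgRecording

FEATURE_NAMES = ("RMS", "VAR", "ZC", "WL", "MAV")

#: default dead-band for the zero-crossing count, in normalized units
ZC_EPS_DEFAULT = 0.01


@dataclass(frozen=True)
class WindowConfig:
    """Overlapping analysis-window geometry, specified in milliseconds."""

    window_len_ms: float = 200.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.step_ms <= self.window_len_ms:
            raise ConfigError(
                f"need 0 < step_ms ({self.step_ms}) <= window_len_ms "
                f"({self.window_len_ms})"
            )

    def in_samples(self, fs: float) -> tuple[int, int]:
        """(window length, stride) in samples at rate ``fs``."""
        length = int(round(self.window_len_ms * fs / 1000.0))
        stride = int(round(self.step_ms * fs / 1000.0))
        return length, stride


#: 2 kHz acquisition preset: 400-sample windows, 100-sample shift (75% overlap)
WINDOW_ACQ2000 = WindowConfig(window_len_ms=200.0, step_ms=50.0)
#: 1 kHz training preset: 200-sample windows, 100-sample shift (50% overlap)
WINDOW_TRAIN1000 = WindowConfig(window_len_ms=200.0, step_ms=100.0)


def segment_windows(
    series_len: int, cfg: WindowConfig, fs: float
) -> list[tuple[int, int]]:
    """Half-open index ranges of the overlapping windows.

    Yields ``floor((series_len - L) / S) + 1`` windows; any trailing
    remainder shorter than a full window is discarded.
    """
    length, stride = cfg.in_samples(fs)
    if series_len < length:
        raise DataError(
            f"series of {series_len} samples is shorter than one window; "
            f"need at least {length}"
        )
    n_win = (series_len - length) // stride + 1
    return [(i * stride, i * stride + length) for i in range(n_win)]


def _features_from_window_matrix(w: np.ndarray, zc_eps: float) -> np.ndarray:
    """Vectorized feature computation on a (n_windows, L) matrix."""
    rms = np.sqrt(np.mean(w**2, axis=1))
    var = w.var(axis=1, ddof=1)
    a, b = w[:, :-1], w[:, 1:]
    zc = np.sum((a * b < 0) & (np.abs(a) > zc_eps) & (np.abs(b) > zc_eps), axis=1)
    wl = np.sum(np.abs(np.diff(w, axis=1)), axis=1)
    mav = np.mean(np.abs(w), axis=1)
    return np.column_stack([rms, var, zc.astype(float), wl, mav])


def compute_features(window: np.ndarray, zc_eps: float = 0.0) -> np.ndarray:
    """Five time-domain features (RMS, VAR, ZC, WL, MAV) of one window."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("feature window must be 1-D with at least 2 samples")
    return _features_from_window_matrix(x[None, :], zc_eps)[0]


@dataclass
class FeatureMatrix:
    """Per-window, per-muscle feature values with aligned angle/torque.

    ``values`` has one row per window and one column per (muscle, feature)
    pair, muscle-major: ``[m1_RMS, m1_VAR, ..., m2_RMS, ...]``.
    """

    values: np.ndarray
    muscles: list[str]
    feature_names: tuple[str, ...]
    window_centers_s: np.ndarray
    aligned_angle: np.ndarray
    aligned_torque: np.ndarray | None = None
    muscle_roles: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_cols = len(self.muscles) * len(self.feature_names)
        if self.values.ndim != 2 or self.values.shape[1] != n_cols:
            raise DataError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.muscles)} muscles x {len(self.feature_names)} features"
            )

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def column_names(self) -> list[str]:
        return [f"{m}_{f}" for m in self.muscles for f in self.feature_names]

    def column(self, muscle: str, feature: str) -> np.ndarray:
        i = self.muscles.index(muscle)
        j = self.feature_names.index(feature)
        return self.values[:, i * len(self.feature_names) + j]

    def block(self, muscle: str, features: tuple[str, ...] | None = None) -> np.ndarray:
        """(windows x features) block for one muscle."""
        features = features or self.feature_names
        cols = [self.column(muscle, f) for f in features]
        return np.column_stack(cols)

    def select(
        self,
        muscles: list[str] | None = None,
        features: tuple[str, ...] | None = None,
    ) -> "FeatureMatrix":
        """Sub-matrix restricted to the given muscles and/or features."""
        muscles = muscles if muscles is not None else self.muscles
        features = features if features is not None else self.feature_names
        blocks = [self.block(m, features) for m in muscles]
        roles = None
        if self.muscle_roles is not None:
            roles = {m: self.muscle_roles[m] for m in muscles if m in self.muscle_roles}
        return FeatureMatrix(
            values=np.hstack(blocks),
            muscles=list(muscles),
            feature_names=tuple(features),
            window_centers_s=self.window_centers_s,
            aligned_angle=self.aligned_angle,
            aligned_torque=self.aligned_torque,
            muscle_roles=roles,
            meta=dict(self.meta),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "t_center_s", self.window_centers_s)
        df["angle_deg"] = self.aligned_angle
        if self.aligned_torque is not None:
            df["torque"] = self.aligned_torque
        return df

    @classmethod
    def concat(cls, parts: list["FeatureMatrix"]) -> "FeatureMatrix":
        """Stack feature matrices from several trials.

        Window centers of later parts are shifted so the combined center
        sequence stays strictly increasing.
        """
        if not parts:
            raise DataError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.muscles != first.muscles or p.feature_names != first.feature_names:
                raise DataError("feature matrices have mismatched columns")
        centers, offset = [], 0.0
        for p in parts:
            centers.append(p.window_centers_s + offset)
            offset = centers[-1][-1] + 1.0
        torque = None
        if all(p.aligned_torque is not None for p in parts):
            torque = np.concatenate([p.aligned_torque for p in parts])
        return cls(
            values=np.vstack([p.values for p in parts]),
            muscles=list(first.muscles),
            feature_names=first.feature_names,
            window_centers_s=np.concatenate(centers),
            aligned_angle=np.concatenate([p.aligned_angle for p in parts]),
            aligned_torque=torque,
            muscle_roles=first.muscle_roles,
        )


def build_feature_matrix(
    rec: EmgRecording,
    cfg: WindowConfig | None = None,
    zc_eps: float = ZC_EPS_DEFAULT,
    torque_alignment: str = "mean",
) -> FeatureMatrix:
    """Window every channel of a (preprocessed) recording and featurize it.

    The angle label of a window is the angle at the window's center sample;
    the torque target is the mean of torque over the window
    (``torque_alignment="center"`` switches to the center sample).
    """
    if rec.angle is None:
        raise DataError("recording has no angle series; required for windowing")
    if torque_alignment not in ("mean", "center"):
        raise ConfigError(f"unknown torque_alignment {torque_alignment!r}")
    cfg = cfg or WindowConfig()
    bounds = segment_windows(rec.n_samples, cfg, rec.fs)
    length, _ = cfg.in_samples(rec.fs)
    starts = np.array([s for s, _ in bounds])
    center_idx = starts + length // 2
    blocks = []
    for ch in rec.samples:
        w = np.lib.stride_tricks.sliding_window_view(ch, length)[starts]
        blocks.append(_features_from_window_matrix(w, zc_eps))
    values = np.hstack(blocks)
    torque = None
    if rec.torque is not None:
        if torque_alignment == "mean":
            tw = np.lib.stride_tricks.sliding_window_view(rec.torque, length)[starts]
            torque = tw.mean(axis=1)
        else:
            torque = rec.torque[center_idx]
    return FeatureMatrix(
        values=values,
        muscles=list(rec.channel_names),
        feature_names=FEATURE_NAMES,
        window_centers_s=(starts + length / 2) / rec.fs,
        aligned_angle=rec.angle[center_idx],
        aligned_torque=torque,
        muscle_roles=dict(rec.channel_roles) if rec.channel_roles else None,
        meta={"fs": rec.fs, "window": (cfg.window_len_ms, cfg.step_ms)},
    )
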