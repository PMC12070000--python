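"""In-memory container for a multichannel sEMG trial.

A recording couples the raw (or cleaned) muscle channels with the sampling
rate and, when available, the synchronized knee-angle and interactive-torque
series.  All downstream stages (filtering, windowing, feature extraction)
operate on this container and preserve its time alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

#: channel roles recognised by the torque sign convention
#: (knee extension positive, knee flexion negative)
ROLE_EXTENSOR = "ext"
ROLE_FLEXOR = "flex"


@dataclass
class EmgRecording:
    """Multichannel sEMG signal plus aligned angle/torque series.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` in volts.
    fs
        Sampling rate in Hz.
    channel_names
        One label per channel (muscle names).
    channel_roles
        Optional mapping ``name -> "ext" | "flex"``.
    angle
        Optional knee angle in degrees, one value per sample.
    torque
        Optional interactive torque (N·m assumed), one value per sample.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    channel_roles: dict[str, str] | None = None
    angle: np.ndarray | None = None
    torque: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.samples.ndim != 2:
            raise DataError("samples must be a (channels, time) matrix")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise DataError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        for label, series in (("angle", self.angle), ("torque", self.torque)):
            if series is not None:
                series = np.asarray(series, dtype=float)
                if series.shape != (self.n_samples,):
                    raise DataError(
                        f"{label} length {series.shape} does not match "
                        f"{self.n_samples} samples"
                    )
                setattr(self, label, series)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def role_of(self, name: str) -> str | None:
        if self.channel_roles is None:
            return None
        return self.channel_roles.get(name)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise DataError(f"no channel named {name!r}") from None
        return self.samples[idx]

    def with_samples(self, samples: np.ndarray) -> "EmgRecording":
        """Copy of this recording with the signal matrix replaced."""
        if samples.shape != self.samples.shape:
            raise DataError(
                f"replacement shape {samples.shape} != {self.samples.shape}"
            )
        return replace(self, samples=np.asarray(samples, dtype=float))
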