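"""Seeded synthetic sEMG + knee-angle + torque generator.

The generator emulates the discrete acquisition protocol end to end so the
whole pipeline is testable without recorded data:

- the EMG model is amplitude-modulated band-limited (10-500 Hz) Gaussian
  noise — the standard phenomenological surface-EMG model — with a channel
  gain driven by the extension or flexion effort envelope depending on the
  muscle's role;
- on top of the clean signal it layers the acquisition artifacts a real
  front end produces: a DC offset (default 1.45 V), slow 0.2-0.5 Hz baseline
  drift, 50 Hz mains hum with harmonics, broadband noise at a configurable
  SNR, and sparse impulsive outliers;
- ground-truth torque is g(angle) * (ext - flex effort) * torque_max with a
  smooth unimodal angle gain g, plus small measurement noise, clipped to
  [-torque_max, torque_max] — extension positive, flexion negative;
- `gen_session_set` reproduces the session structure: fixed-angle trials at
  20..130 degrees in 10-degree steps (with a few degrees of postural
  jitter), two sessions per angle, plus one continuous squat trial for the
  fusion stage.

Every function is reproducible from its seed, and per-trial seeds are
recorded in the session manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import ConfigError, DataError
from .recording import EmgRecording

DEFAULT_CHANNELS = (
    ("rectus_femoris", "ext"),
    ("vastus_medialis", "ext"),
    ("vastus_lateralis", "ext"),
    ("biceps_femoris", "flex"),
    ("semitendinosus", "flex"),
    ("gastrocnemius", "flex"),
)

PROFILES = ("bursts", "squat", "walk", "random")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic acquisition.

    Amplitudes are in volts.  ``emg_amp_v`` is the peak modulation depth of
    the clean myoelectric carrier; ``rest_amp_frac`` the tonic fraction at
    zero effort.  ``broadband_snr_db`` sets white-noise power relative to
    the clean signal.  Outliers arrive at ``outlier_rate_hz`` per second
    with amplitude ``outlier_amp_sd`` standard deviations of the clean
    signal.  The torque angle-gain is a raised cosine over the 20-160 degree
    range with floor ``torque_gain_floor``.
    """

    fs: float = 2000.0
    duration_s: float = 12.0
    n_channels: int = 6
    dc_offset_v: float = 1.45
    drift_band_hz: tuple[float, float] = (0.2, 0.5)
    drift_amp_v: float = 0.4
    hum_hz: float = 50.0
    hum_harmonics: int = 3
    hum_amp_v: float = 0.15
    broadband_snr_db: float = 10.0
    outlier_rate_hz: float = 10.0
    outlier_amp_sd: float = 25.0
    emg_amp_v: float = 0.3
    rest_amp_frac: float = 0.05
    band_hz: tuple[float, float] = (10.0, 500.0)
    torque_max: float = 30.0
    torque_gain_floor: float = 0.35
    torque_noise_sd: float = 0.5
    angle_range: tuple[float, float] = (20.0, 160.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 2 * self.band_hz[1]:
            raise ConfigError(
                f"fs={self.fs} too low for {self.band_hz[1]} Hz EMG content; "
                f"need at least {2 * self.band_hz[1]}"
            )
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        for name in ("dc_offset_v", "drift_amp_v", "hum_amp_v", "emg_amp_v",
                     "outlier_rate_hz", "outlier_amp_sd", "torque_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.n_channels <= len(DEFAULT_CHANNELS):
            raise ConfigError(f"n_channels must be 1..{len(DEFAULT_CHANNELS)}")

    @property
    def channels(self) -> tuple[tuple[str, str], ...]:
        return DEFAULT_CHANNELS[: self.n_channels]


def gen_activation(
    duration_s: float,
    fs_env: float,
    profile: str = "bursts",
    seed: int = 0,
    n_bursts: int = 5,
    period_s: float = 4.0,
) -> np.ndarray:
    """Smooth effort envelope in [0, 1].

    ``bursts``: ``n_bursts`` ramp-hold-release efforts of varying amplitude,
    evenly spaced.  ``squat``/``walk``: periodic raised-cosine effort with
    period ``period_s``.  ``random``: low-pass-filtered noise rescaled to
    [0, 1].
    """
    if duration_s <= 0:
        raise DataError("duration must be positive")
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose one of {PROFILES}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_env))
    t = np.arange(n) / fs_env
    if profile == "bursts":
        env = np.zeros(n)
        slot = duration_s / n_bursts
        for i in range(n_bursts):
            amp = 0.55 + 0.45 * rng.random()
            t0, t1 = i * slot + 0.15 * slot, (i + 1) * slot - 0.15 * slot
            mask = (t >= t0) & (t < t1)
            phase = (t[mask] - t0) / (t1 - t0)
            env[mask] = amp * np.sin(np.pi * phase) ** 2
        return env
    if profile in ("squat", "walk"):
        freq = 1.0 / period_s if profile == "squat" else 2.0 / period_s
        phase = 2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
        return 0.5 - 0.5 * np.cos(phase)
    # random: smoothed noise
    raw = rng.standard_normal(n)
    sos = signal.butter(2, min(1.0, fs_env / 4), fs=fs_env, output="sos")
    smooth = signal.sosfiltfilt(sos, raw)
    lo, hi = smooth.min(), smooth.max()
    return (smooth - lo) / (hi - lo)


def _bandlimited_carrier(n: int, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(4, cfg.band_hz, btype="bandpass", fs=cfg.fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def gen_emg(
    env_ext: np.ndarray,
    env_flex: np.ndarray,
    cfg: SynthConfig,
    seed: int | None = None,
) -> EmgRecording:
    """Multichannel raw sEMG driven by extension/flexion effort envelopes.

    Each channel's modulation envelope follows its role; per-channel gains
    vary so that muscle ranking is non-trivial.  Artifacts (DC, drift, hum,
    broadband noise, outliers) are layered per channel.
    """
    env_ext = np.asarray(env_ext, dtype=float)
    env_flex = np.asarray(env_flex, dtype=float)
    if env_ext.shape != env_flex.shape or env_ext.ndim != 1:
        raise DataError("effort envelopes must be equal-length 1-D series")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = env_ext.size
    t = np.arange(n) / cfg.fs
    names, roles = [], {}
    samples = np.empty((cfg.n_channels, n))
    for i, (name, role) in enumerate(cfg.channels):
        names.append(name)
        roles[name] = role
        env = env_ext if role == "ext" else env_flex
        gain = 0.7 + 0.3 * rng.random()
        sigma = cfg.emg_amp_v * (cfg.rest_amp_frac + (1 - cfg.rest_amp_frac) * gain * env)
        clean = sigma * _bandlimited_carrier(n, cfg, rng)
        ch = clean + cfg.dc_offset_v
        if cfg.drift_amp_v > 0:
            f_drift = rng.uniform(*cfg.drift_band_hz)
            ch = ch + cfg.drift_amp_v * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        if cfg.hum_amp_v > 0:
            for h in range(1, cfg.hum_harmonics + 1):
                f0 = h * cfg.hum_hz
                if f0 >= cfg.fs / 2:
                    break
                ch = ch + (cfg.hum_amp_v / h) * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        clean_rms = float(np.sqrt(np.mean(clean**2)))
        noise_sd = clean_rms / 10 ** (cfg.broadband_snr_db / 20)
        if noise_sd > 0:
            ch = ch + noise_sd * rng.standard_normal(n)
        if cfg.outlier_rate_hz > 0:
            k = rng.poisson(cfg.outlier_rate_hz * n / cfg.fs)
            if k:
                idx = rng.integers(0, n, size=k)
                amp = cfg.outlier_amp_sd * clean.std()
                ch[idx] += amp * rng.choice([-1.0, 1.0], size=k)
        samples[i] = ch
    return EmgRecording(samples=samples, fs=cfg.fs, channel_names=names, channel_roles=roles)


def torque_angle_gain(angle: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Smooth unimodal angle dependence of torque capacity, in [floor, 1].

    A raised cosine peaking mid-range of the joint's 20-160 degree span;
    this is the generator's stored ground truth for recovery tests.
    """
    lo, hi = cfg.angle_range
    phase = np.clip((np.asarray(angle, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return cfg.torque_gain_floor + (1 - cfg.torque_gain_floor) * np.sin(np.pi * phase) ** 2


def gen_torque(
    env_ext: np.ndarray,
    env_flex: np.ndarray,
    angle_series: np.ndarray,
    cfg: SynthConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Ground-truth interactive torque: g(angle)*(ext - flex)*torque_max + noise.

    Extension positive, flexion negative; clipped to [-torque_max, torque_max].
    """
    env_ext = np.asarray(env_ext, dtype=float)
    env_flex = np.asarray(env_flex, dtype=float)
    angle = np.asarray(angle_series, dtype=float)
    if not (env_ext.shape == env_flex.shape == angle.shape):
        raise DataError("envelopes and angle series must have equal length")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    torque = torque_angle_gain(angle, cfg) * (env_ext - env_flex) * cfg.torque_max
    if cfg.torque_noise_sd > 0:
        torque = torque + cfg.torque_noise_sd * rng.standard_normal(angle.size)
    return np.clip(torque, -cfg.torque_max, cfg.torque_max)


def _angle_jitter(n: int, fs: float, rng: np.random.Generator, amp_deg: float = 5.0) -> np.ndarray:
    """Slow postural wander of the 'fixed' knee, clipped to +/- amp_deg."""
    raw = rng.standard_normal(n)
    sos = signal.butter(2, 0.4, fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos, raw)
    smooth = smooth / (smooth.std() or 1.0) * (amp_deg / 3.0)
    return np.clip(smooth, -amp_deg, amp_deg)


def gen_fixed_angle_trial(cfg: SynthConfig, angle_deg: float, seed: int) -> EmgRecording:
    """One fixed-posture trial with interleaved extension and flexion efforts.

    Six effort slots alternate extension/flexion (three each by default
    duration); burst amplitudes vary so the torque sweeps its range.  The
    angle wanders a few degrees around the nominal fixation angle.
    """
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    n_slots = 6
    slot = cfg.duration_s / n_slots
    env_ext = np.zeros(n)
    env_flex = np.zeros(n)
    for i in range(n_slots):
        target = env_ext if i % 2 == 0 else env_flex
        amp = 0.5 + 0.5 * rng.random()
        t0, t1 = i * slot + 0.12 * slot, (i + 1) * slot - 0.12 * slot
        mask = (t >= t0) & (t < t1)
        phase = (t[mask] - t0) / (t1 - t0)
        target[mask] = amp * np.sin(np.pi * phase) ** 2
    angle = angle_deg + _angle_jitter(n, cfg.fs, rng)
    rec = gen_emg(env_ext, env_flex, cfg, seed=int(rng.integers(2**31)))
    rec.angle = angle
    rec.torque = gen_torque(env_ext, env_flex, angle, cfg, seed=int(rng.integers(2**31)))
    rec.meta.update({"nominal_angle": angle_deg, "seed": seed})
    return rec


def gen_squat_trial(
    cfg: SynthConfig, seed: int, duration_s: float = 20.0, period_s: float = 5.0
) -> EmgRecording:
    """Continuous squat trial sweeping the knee through 40-130 degrees.

    Extensor effort is phase-locked to descent depth (load-bearing), with a
    small flexor co-activation; used to exercise bin routing and fusion.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    phase = 2 * np.pi * t / period_s
    angle = 85.0 - 45.0 * np.cos(phase)  # 40 (stand) .. 130 (deep squat)
    depth = 0.5 - 0.5 * np.cos(phase)
    env_ext = 0.1 + 0.85 * depth
    env_flex = 0.05 + 0.1 * (1 - depth)
    rec = gen_emg(env_ext, env_flex, cfg, seed=int(rng.integers(2**31)))
    rec.angle = angle
    rec.torque = gen_torque(env_ext, env_flex, angle, cfg, seed=int(rng.integers(2**31)))
    rec.meta.update({"profile": "squat", "seed": seed})
    return rec


@dataclass
class Trial:
    recording: EmgRecording
    angle: float | None  # nominal fixation angle; None for continuous trials
    session: int
    seed: int


@dataclass
class SessionSet:
    """The full synthetic study: fixed-angle trials plus one continuous trial."""

    trials: list[Trial]
    continuous: Trial
    config: SynthConfig
    angles: tuple[float, ...]
    sessions_per_angle: int

    def by_session(self, session: int) -> list[Trial]:
        return [t for t in self.trials if t.session == session]

    def manifest(self) -> dict:
        return {
            "base_seed": self.config.seed,
            "fs": self.config.fs,
            "sessions_per_angle": self.sessions_per_angle,
            "angles": list(self.angles),
            "trials": [
                {"angle": t.angle, "session": t.session, "seed": t.seed}
                for t in self.trials
            ],
            "continuous": {"profile": "squat", "seed": self.continuous.seed},
        }


def _trial_seed(base_seed: int, angle: float, session: int) -> int:
    return int((base_seed * 1000003 + int(angle) * 131 + session * 7 + 1) % (2**31))


def gen_session_set(
    cfg: SynthConfig,
    angles: tuple[float, ...] = tuple(float(a) for a in range(20, 131, 10)),
    sessions_per_angle: int = 2,
) -> SessionSet:
    """Generate the discrete acquisition protocol: every angle x session.

    Defaults give 12 angles x 2 sessions = 24 fixed-angle trials plus one
    continuous squat trial.  Per-trial seeds derive deterministically from
    the base seed and are recorded in the manifest, so any trial can be
    regenerated in isolation.
    """
    lo, hi = cfg.angle_range
    if any(a < lo or a > hi for a in angles):
        raise ConfigError(f"angles must lie within {cfg.angle_range}")
    trials = []
    for session in range(sessions_per_angle):
        for angle in angles:
            seed = _trial_seed(cfg.seed, angle, session)
            trials.append(
                Trial(
                    recording=gen_fixed_angle_trial(cfg, angle, seed),
                    angle=angle,
                    session=session,
                    seed=seed,
                )
            )
    cont_seed = _trial_seed(cfg.seed, 999, 99)
    continuous = Trial(
        recording=gen_squat_trial(cfg, cont_seed), angle=None, session=0, seed=cont_seed
    )
    return SessionSet(
        trials=trials,
        continuous=continuous,
        config=cfg,
        angles=tuple(angles),
        sessions_per_angle=sessions_per_angle,
    )
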