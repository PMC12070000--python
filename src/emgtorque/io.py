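"""Trial CSV readers/writers, session-set persistence, config hashing.

Interchange format is plain CSV with header::

    time_s, <muscle>_<role>, ..., angle_deg[, torque]

where ``<role>`` is ``ext`` or ``flex``.  The sampling rate is inferred from
the time column (which must be uniform to within 1 ppm) unless given
explicitly.  Session sets are a directory of trial CSVs plus a
``manifest.json`` listing angle, session and seed per trial.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .recording import EmgRecording
from .synth import SessionSet, SynthConfig, Trial

ROLES = ("ext", "flex")


def config_hash(obj) -> str:
    """Short stable hash of a (nested) config for artifact provenance."""

    def canon(o):
        if is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **canon(asdict(o))}
        if isinstance(o, dict):
            return {str(k): canon(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [canon(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    blob = json.dumps(canon(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _split_channel_header(col: str) -> tuple[str, str | None]:
    for role in ROLES:
        suffix = f"_{role}"
        if col.endswith(suffix):
            return col[: -len(suffix)], role
    return col, None


def write_trial(rec: EmgRecording, path: str | Path) -> Path:
    """Write a recording as a trial CSV (role encoded as column suffix)."""
    path = Path(path)
    cols = {"time_s": rec.time}
    for i, name in enumerate(rec.channel_names):
        role = rec.role_of(name)
        header = f"{name}_{role}" if role else name
        cols[header] = rec.samples[i]
    if rec.angle is None:
        raise DataError("trial CSV requires an angle series")
    cols["angle_deg"] = rec.angle
    if rec.torque is not None:
        cols["torque"] = rec.torque
    # 17 significant digits guarantee a bit-exact float64 round-trip
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def read_trial(path: str | Path, fs: float | None = None) -> EmgRecording:
    """Parse a trial CSV into a recording; fs inferred from the time column.

    The time column must be strictly increasing with a uniform step (1 ppm
    relative tolerance); the first offending index is reported otherwise.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns or "angle_deg" not in df.columns:
        raise DataError(f"{path}: trial CSV needs 'time_s' and 'angle_deg' columns")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: trial needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise DataError(f"{path}: time not strictly increasing at row {bad}")
    step = float(np.median(dt))
    off = np.abs(dt - step) > step * 1e-6 + 1e-12
    if np.any(off):
        bad = int(np.flatnonzero(off)[0]) + 1
        raise DataError(f"{path}: non-uniform time step at row {bad}")
    if fs is None:
        fs = 1.0 / step
    channel_cols = [c for c in df.columns if c not in ("time_s", "angle_deg", "torque")]
    if not channel_cols:
        raise DataError(f"{path}: no EMG channel columns found")
    names, roles = [], {}
    for col in channel_cols:
        name, role = _split_channel_header(col)
        names.append(name)
        if role:
            roles[name] = role
    return EmgRecording(
        samples=df[channel_cols].to_numpy(dtype=float).T,
        fs=fs,
        channel_names=names,
        channel_roles=roles or None,
        angle=df["angle_deg"].to_numpy(dtype=float),
        torque=df["torque"].to_numpy(dtype=float) if "torque" in df.columns else None,
        meta={"path": str(path)},
    )


def _trial_filename(angle: float | None, session: int) -> str:
    if angle is None:
        return "trial_continuous.csv"
    return f"trial_a{int(angle):03d}_s{session}.csv"


def write_session_set(ss: SessionSet, out_dir: str | Path) -> Path:
    """Write all trials as CSVs plus a manifest.json into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = ss.manifest()
    manifest["config_hash"] = config_hash(ss.config)
    for entry, trial in zip(manifest["trials"], ss.trials):
        fname = _trial_filename(trial.angle, trial.session)
        write_trial(trial.recording, out_dir / fname)
        entry["file"] = fname
    cont_name = _trial_filename(None, 0)
    write_trial(ss.continuous.recording, out_dir / cont_name)
    manifest["continuous"]["file"] = cont_name
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out_dir


def load_session_set(data_dir: str | Path) -> SessionSet:
    """Read a simulated session directory back into memory."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    cfg = SynthConfig(fs=float(manifest["fs"]), seed=int(manifest["base_seed"]))
    trials = []
    for entry in manifest["trials"]:
        rec = read_trial(data_dir / entry["file"])
        rec.meta["nominal_angle"] = entry["angle"]
        trials.append(
            Trial(
                recording=rec,
                angle=float(entry["angle"]),
                session=int(entry["session"]),
                seed=int(entry["seed"]),
            )
        )
    cont = manifest["continuous"]
    continuous = Trial(
        recording=read_trial(data_dir / cont["file"]),
        angle=None,
        session=0,
        seed=int(cont["seed"]),
    )
    return SessionSet(
        trials=trials,
        continuous=continuous,
        config=cfg,
        angles=tuple(float(a) for a in manifest["angles"]),
        sessions_per_angle=int(manifest["sessions_per_angle"]),
    )
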