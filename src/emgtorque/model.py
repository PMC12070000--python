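"""Per-angle-bin feed-forward (BP) torque regression.

The knee's range of motion is discretized into 10-degree bins (centers 20,
30, ..., 130 by default).  One small back-propagation network per bin maps a
1x7 input — six per-muscle PC scores plus the knee angle, all scaled to
[-1, 1] — to the interactive joint torque.  Networks are n_in-m-1 with tanh
hidden units and a linear output, trained full-batch with momentum, L2
weight decay, a plateau-driven learning-rate schedule and early stopping.
Predictions are clamped to a biomechanically plausible range (default
[-30, 30] N·m).

The hidden-layer width m is either fixed (10 by default) or selected by
validation RMSE over a candidate list from the classic m <= sqrt(n_in +
n_out) + alpha heuristic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DataError
from .features import FeatureMatrix
from .pca import PcaModel, transform
from .selection import pearson_corr

log = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: (bin centers, below-range?) pairs already warned about, to avoid log floods
_clamp_warned: set = set()


@dataclass(frozen=True)
class BinSpec:
    """Equally spaced angle-bin centers with a half-width in degrees."""

    centers: tuple[float, ...] = tuple(float(a) for a in range(20, 131, 10))
    half_width: float = 5.0

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.size < 1:
            raise ConfigError("bin spec needs at least one center")
        if c.size > 1:
            steps = np.diff(c)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ConfigError("bin centers must be strictly increasing and equally spaced")
        if self.half_width <= 0:
            raise ConfigError("half_width must be positive")

    def nearest_center(self, angle: float) -> float:
        """Center of the bin nearest to ``angle``; ties resolve to the lower center."""
        c = np.asarray(self.centers)
        idx = int(np.argmin(np.abs(c - angle)))  # argmin takes the first = lower center
        if angle < c[0] - self.half_width or angle > c[-1] + self.half_width:
            key = (self.centers, angle < c[0])
            if key not in _clamp_warned:  # warn once per bin layout and side
                _clamp_warned.add(key)
                log.warning(
                    "angle %.1f outside binned range [%g, %g]; clamped to edge bin %g "
                    "(warning suppressed for further angles on this side)",
                    angle, c[0] - self.half_width, c[-1] + self.half_width, c[idx],
                )
        return float(c[idx])


@dataclass(frozen=True)
class TrainConfig:
    """Training regime for one bin network.

    Full-batch gradient descent with momentum on MSE + L2; the learning rate
    halves when the validation loss plateaus for ``lr_patience`` epochs and
    training stops after ``patience`` epochs without improvement (best
    weights are restored).
    """

    max_epochs: int = 1000
    patience: int = 50
    l2_lambda: float = 1e-4
    lr_init: float = 0.1
    lr_decay: float = 0.5
    lr_min: float = 1e-5
    lr_patience: int = 15
    momentum: float = 0.9
    val_fraction: float = 0.2
    output_clamp: tuple[float, float] = (-30.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ConfigError("val_fraction must be in (0, 1)")
        if self.output_clamp[0] >= self.output_clamp[1]:
            raise ConfigError("output_clamp low must be below high")
        if not 0 <= self.momentum < 1:
            raise ConfigError("momentum must be in [0, 1)")


@dataclass
class ColumnScaler:
    """Per-column min-max map onto [-1, 1], fitted on training data."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "ColumnScaler":
        x = np.asarray(x, dtype=float)
        lo, hi = x.min(axis=0), x.max(axis=0)
        span = hi - lo
        if np.any(span == 0):
            # constant columns (e.g. near-constant angle within one bin) map to 0
            hi = np.where(span == 0, lo + 1.0, hi)
        return cls(lo=lo, hi=hi)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def to_dict(self) -> dict:
        return {"lo": self.lo.tolist(), "hi": self.hi.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnScaler":
        return cls(lo=np.asarray(d["lo"], float), hi=np.asarray(d["hi"], float))


def hidden_node_candidates(n_in: int, n_out: int = 1, alpha_max: int = 10) -> list[int]:
    """Candidate hidden-layer widths from m <= sqrt(n_in + n_out) + alpha.

    alpha ranges over 0..alpha_max; the list is deduplicated and ascending,
    never empty (at least ceil(sqrt(n_in + n_out))).
    """
    if n_in < 1 or n_out < 1:
        raise ConfigError("n_in and n_out must be >= 1")
    base = np.sqrt(n_in + n_out)
    lo = int(np.ceil(base))
    hi = int(np.floor(base)) + alpha_max
    return sorted({lo} | set(range(lo, hi + 1)))


@dataclass
class BinModel:
    """One trained n_in-m-1 network with its output scaling and training log."""

    w1: np.ndarray  # (n_in, m)
    b1: np.ndarray  # (m,)
    w2: np.ndarray  # (m,)
    b2: float
    hidden_nodes: int
    y_mean: float
    y_std: float
    output_clamp: tuple[float, float]
    training_log: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_in(self) -> int:
        return self.w1.shape[0]

    def forward(self, x_scaled: np.ndarray) -> np.ndarray:
        """Clamped torque prediction for scaled inputs (rows)."""
        x = np.atleast_2d(np.asarray(x_scaled, dtype=float))
        h = np.tanh(x @ self.w1 + self.b1)
        y = (h @ self.w2 + self.b2) * self.y_std + self.y_mean
        return np.clip(y, *self.output_clamp)

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
            "hidden_nodes": int(self.hidden_nodes),
            "y_mean": float(self.y_mean),
            "y_std": float(self.y_std),
            "output_clamp": list(self.output_clamp),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinModel":
        return cls(
            w1=np.asarray(d["w1"], float),
            b1=np.asarray(d["b1"], float),
            w2=np.asarray(d["w2"], float),
            b2=float(d["b2"]),
            hidden_nodes=int(d["hidden_nodes"]),
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
            output_clamp=(float(d["output_clamp"][0]), float(d["output_clamp"][1])),
        )


def train_bin_model(
    x_scaled: np.ndarray, y: np.ndarray, m: int, cfg: TrainConfig
) -> BinModel:
    """Train one bin network on scaled inputs and raw torque targets.

    The validation split is the chronologically last ``val_fraction`` of the
    rows (windows overlap in time, so a random split would leak).  Targets
    are standardized internally; predictions are de-standardized and clamped.
    """
    x = np.asarray(x_scaled, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise DataError("X must be (N, n_in) with matching target length")
    n = x.shape[0]
    if n < 20:
        raise DataError(f"need at least 20 samples to train a bin model, got {n}")
    if m < 1:
        raise ConfigError("hidden node count must be >= 1")

    n_val = max(1, int(round(cfg.val_fraction * n)))
    xt, xv = x[: n - n_val], x[n - n_val :]
    yt, yv = y[: n - n_val], y[n - n_val :]

    y_mean = float(yt.mean())
    y_std = float(yt.std()) or 1.0
    yts = (yt - y_mean) / y_std
    yvs = (yv - y_mean) / y_std

    rng = np.random.default_rng(cfg.seed)
    n_in = x.shape[1]
    w1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, m))
    b1 = np.zeros(m)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
    b2 = 0.0
    vel = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]

    lr = cfg.lr_init
    best_val = np.inf
    best = (w1.copy(), b1.copy(), w2.copy(), b2)
    since_best = 0
    since_decay = 0
    training_log: list[tuple[float, float]] = []
    nt = xt.shape[0]

    for epoch in range(cfg.max_epochs):
        h = np.tanh(xt @ w1 + b1)
        pred = h @ w2 + b2
        err = pred - yts
        train_loss = float(np.mean(err**2))
        if not np.isfinite(train_loss):
            raise DataError(f"non-finite training loss at epoch {epoch}")

        g_out = 2.0 * err / nt
        gw2 = h.T @ g_out + 2.0 * cfg.l2_lambda * w2
        gb2 = float(g_out.sum())
        gh = np.outer(g_out, w2) * (1.0 - h**2)
        gw1 = xt.T @ gh + 2.0 * cfg.l2_lambda * w1
        gb1 = gh.sum(axis=0)

        vel[0] = cfg.momentum * vel[0] - lr * gw1
        vel[1] = cfg.momentum * vel[1] - lr * gb1
        vel[2] = cfg.momentum * vel[2] - lr * gw2
        vel[3] = cfg.momentum * vel[3] - lr * gb2
        w1 = w1 + vel[0]
        b1 = b1 + vel[1]
        w2 = w2 + vel[2]
        b2 = b2 + vel[3]

        hv = np.tanh(xv @ w1 + b1)
        val_loss = float(np.mean((hv @ w2 + b2 - yvs) ** 2))
        training_log.append((train_loss, val_loss))

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = (w1.copy(), b1.copy(), w2.copy(), b2)
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
        if since_decay >= cfg.lr_patience and lr > cfg.lr_min:
            lr = max(lr * cfg.lr_decay, cfg.lr_min)
            since_decay = 0
        if since_best >= cfg.patience:
            break

    w1, b1, w2, b2 = best
    return BinModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        hidden_nodes=m, y_mean=y_mean, y_std=y_std,
        output_clamp=cfg.output_clamp, training_log=training_log,
    )


def select_hidden_nodes(
    x_scaled: np.ndarray,
    y: np.ndarray,
    candidates: list[int],
    cfg: TrainConfig,
) -> tuple[int, list[dict]]:
    """Train one model per candidate width; return the argmin-RMSE width.

    The table lists validation RMSE and Pearson r per candidate so the
    width-vs-error trade-off can be inspected.  Ties go to the smaller width.
    """
    if not candidates:
        raise ConfigError("candidate list is empty")
    x = np.asarray(x_scaled, dtype=float)
    y = np.asarray(y, dtype=float)
    n_val = max(1, int(round(cfg.val_fraction * x.shape[0])))
    xv, yv = x[-n_val:], y[-n_val:]
    table = []
    for m in sorted(set(candidates)):
        model = train_bin_model(x, y, m, cfg)
        pred = model.forward(xv)
        rmse = float(np.sqrt(np.mean((pred - yv) ** 2)))
        try:
            r = pearson_corr(pred, yv)
        except DataError:
            r = float("nan")
        table.append({"m": m, "rmse": rmse, "r": r})
    best = min(table, key=lambda row: (row["rmse"], row["m"]))
    return int(best["m"]), table


@dataclass
class TorqueEnsemble:
    """Everything needed to map raw features + angle to torque.

    Holds the bin spec, one network per bin (or None for untrained bins), the
    per-muscle PCA models, the retained-feature list and the shared input
    scaler fitted on pooled training inputs.
    """

    bin_spec: BinSpec
    models: dict[float, BinModel | None]
    input_scaler: ColumnScaler
    pca_models: dict[str, PcaModel]
    retained_features: tuple[str, ...]
    muscles: list[str]
    metadata: dict = field(default_factory=dict)

    def trained_centers(self) -> list[float]:
        return [c for c, m in self.models.items() if m is not None]

    def _model_for(self, angle: float) -> BinModel:
        center = self.bin_spec.nearest_center(angle)
        model = self.models.get(center)
        if model is None:
            trained = self.trained_centers()
            if not trained:
                raise DataError("ensemble has no trained bins")
            fallback = min(trained, key=lambda c: (abs(c - center), c))
            log.warning("bin %g untrained; falling back to nearest trained bin %g",
                        center, fallback)
            model = self.models[fallback]
        return model

    def predict(self, features: np.ndarray, angle: float) -> float:
        """Torque for one window given its PC-score vector and angle."""
        features = np.asarray(features, dtype=float).ravel()
        x = np.concatenate([features, [angle]])[None, :]
        model = self._model_for(angle)
        if x.shape[1] != model.n_in:
            raise DataError(f"expected {model.n_in - 1} features, got {features.size}")
        return float(model.forward(self.input_scaler.apply(x))[0])

    def transform_features(self, fm: FeatureMatrix) -> np.ndarray:
        """Raw (unscaled) 1x(6+1) inputs for every window of a feature matrix."""
        scores = transform(fm, self.pca_models, self.retained_features)
        return np.column_stack([scores, fm.aligned_angle])

    def predict_series(self, fm: FeatureMatrix) -> np.ndarray:
        """Per-window torque prediction, routing each window to its angle bin."""
        x_raw = self.transform_features(fm)
        xs = self.input_scaler.apply(x_raw)
        out = np.empty(fm.n_windows)
        for i in range(fm.n_windows):
            out[i] = float(self._model_for(fm.aligned_angle[i]).forward(xs[i : i + 1])[0])
        return out

    def to_json(self) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "bin_spec": {
                "centers": list(self.bin_spec.centers),
                "half_width": self.bin_spec.half_width,
            },
            "models": {
                str(c): (m.to_dict() if m is not None else None)
                for c, m in self.models.items()
            },
            "input_scaler": self.input_scaler.to_dict(),
            "pca_models": {k: v.to_dict() for k, v in self.pca_models.items()},
            "retained_features": list(self.retained_features),
            "muscles": list(self.muscles),
            "metadata": self.metadata,
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TorqueEnsemble":
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise DataError(f"unsupported model format {doc.get('format_version')}")
        return cls(
            bin_spec=BinSpec(
                centers=tuple(doc["bin_spec"]["centers"]),
                half_width=float(doc["bin_spec"]["half_width"]),
            ),
            models={
                float(c): (BinModel.from_dict(m) if m is not None else None)
                for c, m in doc["models"].items()
            },
            input_scaler=ColumnScaler.from_dict(doc["input_scaler"]),
            pca_models={k: PcaModel.from_dict(v) for k, v in doc["pca_models"].items()},
            retained_features=tuple(doc["retained_features"]),
            muscles=list(doc["muscles"]),
            metadata=doc.get("metadata", {}),
        )


def train_ensemble(
    datasets: dict[float, tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    bin_spec: BinSpec,
    pca_models: dict[str, PcaModel],
    retained_features: tuple[str, ...],
    muscles: list[str],
    hidden_nodes: int = 10,
    metadata: dict | None = None,
) -> TorqueEnsemble:
    """Train one network per angle bin from raw (X, y) pairs.

    ``datasets`` maps bin centers to (raw 7-column inputs, torque targets).
    A shared input scaler is fitted on the pooled inputs; each bin trains
    with its own derived seed (base seed + bin index) so the whole ensemble
    is reproducible from one seed.  Bins without data are marked untrained.
    """
    with_data = {c: d for c, d in datasets.items() if d is not None and len(d[1])}
    if not with_data:
        raise DataError("no bin has training data")
    pooled = np.vstack([x for x, _ in with_data.values()])
    scaler = ColumnScaler.fit(pooled)
    models: dict[float, BinModel | None] = {}
    for i, center in enumerate(bin_spec.centers):
        data = with_data.get(float(center))
        if data is None:
            models[float(center)] = None
            log.warning("bin %g has no training data; marked untrained", center)
            continue
        x, y = data
        bin_cfg = replace(cfg, seed=cfg.seed + i)
        models[float(center)] = train_bin_model(scaler.apply(x), y, hidden_nodes, bin_cfg)
    meta = dict(metadata or {})
    meta.setdefault("seed", cfg.seed)
    meta.setdefault("hidden_nodes", hidden_nodes)
    return TorqueEnsemble(
        bin_spec=bin_spec,
        models=models,
        input_scaler=scaler,
        pca_models=pca_models,
        retained_features=retained_features,
        muscles=muscles,
        metadata=meta,
    )
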