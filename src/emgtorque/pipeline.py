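"""End-to-end orchestration: preprocess -> features -> screen -> PCA ->
per-bin training -> evaluation -> discrete-to-continuous fusion.

Session 0 of each angle trains the bin networks; session 1 is the held-out
test set.  The continuous trial (squat) exercises bin routing and fusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .features import FeatureMatrix, WindowConfig, build_feature_matrix
from .fusion import FusionConfig, fuse
from .io import config_hash
from .metrics import evaluate_by_bin
from .model import BinSpec, TorqueEnsemble, TrainConfig, train_ensemble
from .pca import fit_pca_per_muscle, transform as pca_transform
from .preprocess import FilterSpec, HampelConfig, preprocess_pipeline
from .selection import ScreeningReport, screen_features, select_muscles
from .synth import SessionSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage's parameters in one validated bundle."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    hampel: HampelConfig = field(default_factory=HampelConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    drop_count: int = 1
    n_extensors: int = 2
    n_flexors: int = 1
    n_components: int = 2
    hidden_nodes: int = 10
    bin_spec: BinSpec = field(default_factory=BinSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    preprocess_enabled: bool = True


@dataclass
class PipelineResult:
    """Artifacts of one end-to-end run."""

    screening: ScreeningReport
    ensemble: TorqueEnsemble
    report: pd.DataFrame  # per-bin RMSE/R2/r + mean row
    continuous: pd.DataFrame  # t_s, torque_raw, torque_fused, torque_true
    config_hash: str

    @property
    def mean_metrics(self) -> dict[str, float]:
        row = self.report[self.report["angle"] == "mean"].iloc[0]
        return {"RMSE": float(row["RMSE"]), "R2": float(row["R2"]), "r": float(row["r"])}


def featurize_trial(rec, cfg: PipelineConfig) -> FeatureMatrix:
    """Preprocess (unless disabled) and featurize one trial."""
    if cfg.preprocess_enabled:
        rec = preprocess_pipeline(rec, cfg.filter_spec, cfg.hampel).recording
    return build_feature_matrix(rec, cfg.window)


def run_pipeline(
    session_set: SessionSet, cfg: PipelineConfig | None = None, seed: int = 0
) -> PipelineResult:
    """Train on session 0, evaluate per bin on session 1, fuse the squat trial."""
    cfg = cfg or PipelineConfig()
    train_cfg = replace(cfg.train, seed=seed)

    train_trials = session_set.by_session(0)
    test_trials = session_set.by_session(1)
    if not train_trials or not test_trials:
        raise DataError("session set needs at least two sessions per angle")

    train_fms = {t.angle: featurize_trial(t.recording, cfg) for t in train_trials}
    test_fms = [featurize_trial(t.recording, cfg) for t in test_trials]

    pooled_train = FeatureMatrix.concat(list(train_fms.values()))
    screening = screen_features(pooled_train, drop_count=cfg.drop_count)
    muscles = select_muscles(screening, cfg.n_extensors, cfg.n_flexors)
    log.info("retained features %s; selected muscles %s",
             screening.retained_features, muscles)

    pca_models = fit_pca_per_muscle(
        pooled_train, screening.retained_features, muscles, cfg.n_components
    )

    # assemble per-bin training sets from the trials' nominal angles
    datasets = {}
    for angle, fm in train_fms.items():
        scores = pca_transform(fm, pca_models, screening.retained_features)
        x_raw = np.column_stack([scores, fm.aligned_angle])
        datasets[float(angle)] = (x_raw, fm.aligned_torque)

    ensemble = train_ensemble(
        datasets,
        train_cfg,
        cfg.bin_spec,
        pca_models,
        screening.retained_features,
        muscles,
        hidden_nodes=cfg.hidden_nodes,
        metadata={"config_hash": config_hash(cfg), "seed": seed},
    )

    test_fm = FeatureMatrix.concat(test_fms)
    report = evaluate_by_bin(ensemble, test_fm)

    cont_fm = featurize_trial(session_set.continuous.recording, cfg)
    raw_pred = ensemble.predict_series(cont_fm)
    rate_hz = 1000.0 / cfg.window.step_ms
    fused = fuse(raw_pred, cfg.fusion, rate_hz)
    continuous = pd.DataFrame(
        {
            "t_s": cont_fm.window_centers_s,
            "torque_raw": raw_pred,
            "torque_fused": fused,
            "torque_true": cont_fm.aligned_torque,
        }
    )
    return PipelineResult(
        screening=screening,
        ensemble=ensemble,
        report=report,
        continuous=continuous,
        config_hash=config_hash(cfg),
    )
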