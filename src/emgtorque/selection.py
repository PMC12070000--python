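"""Pearson-correlation feature screening and muscle ranking.

Each time-domain feature of each muscle is correlated against the interactive
torque across windows.  Features are scored by the mean absolute correlation
over muscles and the weakest ones dropped (zero-crossing count is typically
the casualty); muscles are then ranked by their mean |r| over the retained
features, optionally within the extensor and flexor groups separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .features import FeatureMatrix


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("pearson_corr expects two equal-length 1-D series")
    if x.size < 3:
        raise DataError("need at least 3 samples for a meaningful correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined for a constant series")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


@dataclass
class ScreeningReport:
    """Correlation matrix, feature decision and muscle ranking."""

    corr: pd.DataFrame  # muscles x features, Pearson r vs torque
    feature_scores: pd.Series  # mean |r| per feature, descending
    retained_features: tuple[str, ...]
    dropped_features: tuple[str, ...]
    muscle_roles: dict[str, str] | None = None
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "retained_features": list(self.retained_features),
            "dropped_features": list(self.dropped_features),
            "feature_scores": {k: float(v) for k, v in self.feature_scores.items()},
        }


def screen_features(
    fm: FeatureMatrix,
    drop_count: int = 1,
    fixed_angle: float | None = None,
    angle_tol: float = 5.0,
) -> ScreeningReport:
    """Correlate every (muscle, feature) column with torque and drop the weakest.

    Features are ranked by mean |r| across muscles; the lowest ``drop_count``
    are removed.  ``fixed_angle`` restricts the windows to those within
    ``angle_tol`` degrees of one posture, reproducing a fixed-knee-angle
    screening protocol.
    """
    if fm.aligned_torque is None:
        raise DataError("feature matrix has no torque column; cannot screen")
    if not 0 <= drop_count < len(fm.feature_names):
        raise ConfigError(
            f"drop_count={drop_count} out of range for "
            f"{len(fm.feature_names)} features"
        )
    keep = slice(None)
    torque = fm.aligned_torque
    if fixed_angle is not None:
        keep = np.abs(fm.aligned_angle - fixed_angle) <= angle_tol
        if np.count_nonzero(keep) < 3:
            raise DataError(f"fewer than 3 windows within {angle_tol} deg of {fixed_angle}")
        torque = torque[keep]
    corr = pd.DataFrame(
        index=list(fm.muscles), columns=list(fm.feature_names), dtype=float
    )
    for m in fm.muscles:
        for f in fm.feature_names:
            col = fm.column(m, f)[keep]
            if np.ptp(col) == 0:
                # a constant feature carries no torque information; score 0
                corr.loc[m, f] = 0.0
            else:
                corr.loc[m, f] = pearson_corr(col, torque)
    scores = corr.abs().mean(axis=0).sort_values(ascending=False, kind="stable")
    dropped = tuple(scores.index[len(scores) - drop_count :]) if drop_count else ()
    retained = tuple(f for f in fm.feature_names if f not in dropped)
    return ScreeningReport(
        corr=corr,
        feature_scores=scores,
        retained_features=retained,
        dropped_features=dropped,
        muscle_roles=dict(fm.muscle_roles) if fm.muscle_roles else None,
        meta={"drop_count": drop_count, "fixed_angle": fixed_angle},
    )


def rank_muscles(
    report: ScreeningReport, retained_only: bool = True
) -> list[tuple[str, float]]:
    """Muscles ordered by mean |r| over the (retained) features, descending.

    Ties are broken by channel order (the order of rows in the report).
    """
    features = list(report.retained_features if retained_only else report.corr.columns)
    if not features:
        raise DataError("no features retained; cannot rank muscles")
    scores = report.corr[features].abs().mean(axis=1)
    order = sorted(
        range(len(scores)), key=lambda i: (-scores.iloc[i], i)
    )  # stable: ties keep channel order
    return [(scores.index[i], float(scores.iloc[i])) for i in order]


def select_muscles(
    report: ScreeningReport, n_extensors: int = 2, n_flexors: int = 1
) -> list[str]:
    """Top-ranked extensors and flexors, in channel order.

    Requires muscle roles on the report.  The final channel set is a
    configuration choice (different studies keep different triples); the
    default keeps two extensors and one flexor, reflecting that exoskeleton
    assistance acts mainly during knee extension.
    """
    if report.muscle_roles is None:
        raise DataError("screening report carries no muscle roles")
    ranking = rank_muscles(report)
    chosen: list[str] = []
    for role, want in (("ext", n_extensors), ("flex", n_flexors)):
        picked = [m for m, _ in ranking if report.muscle_roles.get(m) == role][:want]
        if len(picked) < want:
            raise DataError(f"only {len(picked)} {role} muscles available, need {want}")
        chosen.extend(picked)
    # preserve original channel order for deterministic column layout
    order = {m: i for i, m in enumerate(report.corr.index)}
    return sorted(chosen, key=lambda m: order[m])
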