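"""Regression evaluation: RMSE, coefficient of determination, Pearson r.

`evaluate_by_bin` reproduces the per-angle report format: one row of
(RMSE, R^2, r) per angle bin of the test data plus an unweighted mean row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .features import FeatureMatrix
from .model import TorqueEnsemble
from .selection import pearson_corr


@dataclass(frozen=True)
class EvalMetrics:
    rmse: float
    r2: float
    r: float
    n: int


def rmse(pred: np.ndarray, true: np.ndarray) -> float:
    """Root mean square error, sqrt(mean((pred - true)^2))."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise DataError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def r_squared(pred: np.ndarray, true: np.ndarray) -> float:
    """1 - SSE/SST; can be negative for predictions worse than the mean."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise DataError("r_squared needs two equal-length non-empty vectors")
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        raise DataError("R^2 undefined: true values are constant")
    return 1.0 - float(np.sum((p - t) ** 2)) / sst


def evaluate(pred: np.ndarray, true: np.ndarray) -> EvalMetrics:
    return EvalMetrics(
        rmse=rmse(pred, true),
        r2=r_squared(pred, true),
        r=pearson_corr(pred, true),
        n=len(np.asarray(true)),
    )


def evaluate_by_bin(ensemble: TorqueEnsemble, fm_test: FeatureMatrix) -> pd.DataFrame:
    """Per-bin metrics of an ensemble on held-out windows, plus a mean row.

    Windows are routed to bins by their angle (nearest center).  Bins with
    fewer than 3 test windows are skipped.  The final ``mean`` row is the
    unweighted arithmetic mean of the bin rows.
    """
    if fm_test.aligned_torque is None:
        raise DataError("test feature matrix has no torque column")
    if fm_test.n_windows == 0:
        raise DataError("empty test set")
    pred = ensemble.predict_series(fm_test)
    true = fm_test.aligned_torque
    centers = np.array(
        [ensemble.bin_spec.nearest_center(a) for a in fm_test.aligned_angle]
    )
    rows = []
    for c in ensemble.bin_spec.centers:
        mask = centers == c
        if np.count_nonzero(mask) < 3:
            continue
        m = evaluate(pred[mask], true[mask])
        rows.append({"angle": c, "RMSE": m.rmse, "R2": m.r2, "r": m.r, "n": m.n})
    if not rows:
        raise DataError("no bin has enough test windows")
    df = pd.DataFrame(rows)
    mean_row = {
        "angle": "mean",
        "RMSE": df["RMSE"].mean(),
        "R2": df["R2"].mean(),
        "r": df["r"].mean(),
        "n": int(df["n"].sum()),
    }
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
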