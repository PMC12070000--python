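"""Per-muscle principal component analysis of the retained features.

Each muscle's retained time-domain features (typically RMS, VAR, WL, MAV) are
decorrelated by an eigen-decomposition of their sample covariance; the first
two components usually carry ~99% of the variance, so the default keeps two
per muscle.  The decomposition is written out explicitly (center, covariance
with N-1 divisor, symmetric eigen-solve, descending eigenvalues) so the
serialized model is a plain, reproducible set of means and loadings.

Sign convention: the entry of largest magnitude in each eigenvector is made
positive, so refitting on the same data reproduces identical loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .features import FeatureMatrix


@dataclass
class PcaModel:
    """Centering vector, orthonormal loadings and variance ratios for one block."""

    mean_vec: np.ndarray  # (n,)
    loadings: np.ndarray  # (n, n), columns are eigenvectors, descending variance
    variance_ratios: np.ndarray  # (n,), non-negative, sums to 1
    n_components: int = 2

    def to_dict(self) -> dict:
        return {
            "mean_vec": self.mean_vec.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_ratios": self.variance_ratios.tolist(),
            "n_components": int(self.n_components),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            mean_vec=np.asarray(d["mean_vec"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            variance_ratios=np.asarray(d["variance_ratios"], dtype=float),
            n_components=int(d["n_components"]),
        )


def fit_pca(feature_block: np.ndarray, n_components: int = 2) -> PcaModel:
    """Fit a PCA on an (M samples x n features) block.

    Zero-variance columns are permitted and simply contribute zero
    eigenvalues.  Raises on fewer than 2 samples.
    """
    x = np.asarray(feature_block, dtype=float)
    if x.ndim != 2:
        raise DataError("feature block must be 2-D (samples x features)")
    m, n = x.shape
    if m < 2:
        raise DataError(f"need at least 2 samples to fit a PCA, got {m}")
    if m < n:
        raise DataError(f"need at least as many samples ({m}) as features ({n})")
    if not 1 <= n_components <= n:
        raise ConfigError(f"n_components={n_components} out of range 1..{n}")
    mean_vec = x.mean(axis=0)
    xc = x - mean_vec
    cov = xc.T @ xc / (m - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|entry| component of each eigenvector positive
    for j in range(n):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    total = eigvals.sum()
    if total <= 0:
        raise DataError("feature block has zero total variance")
    return PcaModel(
        mean_vec=mean_vec,
        loadings=eigvecs,
        variance_ratios=eigvals / total,
        n_components=n_components,
    )


def transform_block(block: np.ndarray, model: PcaModel, n_components: int | None = None) -> np.ndarray:
    """Project a (samples x features) block onto the leading components."""
    x = np.asarray(block, dtype=float)
    n = model.mean_vec.size
    if x.ndim != 2 or x.shape[1] != n:
        raise DataError(f"block width {x.shape} does not match model width {n}")
    m = n_components if n_components is not None else model.n_components
    return (x - model.mean_vec) @ model.loadings[:, :m]


def select_n_components(model: PcaModel, cum_threshold: float = 0.99) -> int:
    """Smallest component count whose cumulative variance ratio meets the threshold."""
    if not 0 < cum_threshold <= 1:
        raise ConfigError(f"cum_threshold must be in (0, 1], got {cum_threshold}")
    cum = np.cumsum(model.variance_ratios)
    return int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)


def fit_pca_per_muscle(
    fm: FeatureMatrix,
    features: tuple[str, ...],
    muscles: list[str] | None = None,
    n_components: int = 2,
) -> dict[str, PcaModel]:
    """Independent PCA per muscle on its retained-feature block."""
    muscles = muscles if muscles is not None else fm.muscles
    return {
        m: fit_pca(fm.block(m, features), n_components=n_components) for m in muscles
    }


def transform(
    fm: FeatureMatrix,
    models: dict[str, PcaModel],
    features: tuple[str, ...],
    n_components: int | None = None,
) -> np.ndarray:
    """Per-muscle PC scores, horizontally stacked in model-key order.

    Returns a (windows x n_muscles*n_components) matrix; column order is
    ``[m1_PC1, m1_PC2, ..., m2_PC1, ...]``.
    """
    blocks = []
    for m, model in models.items():
        if m not in fm.muscles:
            raise DataError(f"feature matrix lacks muscle {m!r} required by the PCA")
        blocks.append(transform_block(fm.block(m, features), model, n_components))
    return np.hstack(blocks)
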