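"""Linear dimensionality reduction of poses via the covariance matrix.

Principal components are the eigenvectors of the sample covariance matrix of
the training poses, ordered by descending eigenvalue.  Encoding projects
mean-centred poses onto the top-k components; decoding is the transposed
projection plus the mean, which is the best rank-k linear reconstruction in
squared error.  Eigenvector sign is fixed (largest-magnitude loading made
positive) so repeated fits are bitwise identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import PoseSample, stack_poses


class NotEnoughSamplesError(ValueError):
    pass


class LatentWidthError(ValueError):
    pass


@dataclass
class PCAModel:
    mean: np.ndarray  # (d,)
    components: np.ndarray  # (d, d), orthonormal rows, eigenvalue-ordered
    eigenvalues: np.ndarray  # (d,), descending, >= 0

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    def explained_variance_ratio(self, k: int | None = None) -> np.ndarray:
        ev = self.eigenvalues if k is None else self.eigenvalues[:k]
        return ev / self.eigenvalues.sum()

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean=self.mean,
            components=self.components,
            eigenvalues=self.eigenvalues,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path) as data:
            return cls(
                mean=data["mean"],
                components=data["components"],
                eigenvalues=data["eigenvalues"],
            )


def _as_matrix(poses) -> np.ndarray:
    if isinstance(poses, np.ndarray):
        return poses
    if poses and isinstance(poses[0], PoseSample):
        return stack_poses(poses)
    return np.asarray(poses, dtype=float)


def fit_pca(poses) -> PCAModel:
    """Eigendecomposition of the sample (population) covariance matrix."""
    x = _as_matrix(poses)
    n, d = x.shape
    if n <= d:
        raise NotEnoughSamplesError(f"need more than {d} poses, got {n}")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=0)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    components = eigenvectors[:, order].T  # rows are components
    # sign convention: largest-magnitude loading of each component positive
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean=mean, components=components, eigenvalues=eigenvalues)


def encode_pca(model: PCAModel, poses, k: int = 2) -> np.ndarray:
    """Scores of the top-k principal components, shape (n, k)."""
    if not 1 <= k <= model.n_features:
        raise LatentWidthError(f"k must be in [1, {model.n_features}], got {k}")
    x = _as_matrix(poses)
    return (x - model.mean) @ model.components[:k].T


def decode_pca(model: PCAModel, latent: np.ndarray) -> np.ndarray:
    """Reconstruction ``mean + latent @ components[:k]``."""
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] > model.components.shape[0]:
        raise LatentWidthError("latent width exceeds component count")
    return model.mean + latent @ model.components[: latent.shape[1]]
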