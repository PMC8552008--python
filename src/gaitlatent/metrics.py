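"""Reconstruction and latent-structure metrics shared by all reducers.

Variance Accounted For (VAF) follows

    VAF(%) = (1 - var(y - yhat) / var(y)) * 100

with the scalar variance of multichannel data defined by *pooling*:
``sum_c var(y_c - yhat_c) / sum_c var(y_c)``.  This reduces to the scalar
formula for one channel and makes the PCA identity exact: at latent width k
the VAF of a PCA reconstruction equals the cumulative explained-variance
ratio of the top-k eigenvalues.  Population (ddof=0) variances are used
throughout for the same reason.

RMSE is reported in standardized units, where 1.0 is the error of always
reconstructing the pooled mean pose — so any value above 1 means the model
is doing worse than that trivial baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class ZeroVarianceError(ValueError):
    """The input signal (or latent) has no variance to account for."""


@dataclass
class VAFReport:
    """Pooled VAF (%) of one reducer on one dataset at one latent width."""

    reducer_id: str
    dataset_id: str
    latent_width: int
    value: float  # percent; <= 100, may be negative


@dataclass
class RMSEReport:
    """Standardized-unit RMSE of one reducer on one dataset."""

    reducer_id: str
    dataset_id: str
    value: float  # >= 0; 1.0 is the mean-pose baseline


def reports_to_frame(reports):
    """Tabulate VAF/RMSE reports as a pandas DataFrame for CSV export."""
    import pandas as pd

    return pd.DataFrame([vars(r) for r in reports])


def _flatten_samples(a: np.ndarray) -> np.ndarray:
    """View an (n, ...) sample array as (n*, channels): windows are pooled
    over timesteps so sequence reducers are scored on every entry."""
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        return a[:, None]
    return a.reshape(-1, a.shape[-1])


def vaf(y: np.ndarray, y_hat: np.ndarray, per_channel: bool = False):
    """Variance Accounted For, in percent.

    ``per_channel=True`` returns the vector of per-channel VAFs instead of
    the pooled scalar.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    yf, rf = _flatten_samples(y), _flatten_samples(y - y_hat)
    var_y = yf.var(axis=0)
    var_r = rf.var(axis=0)
    if per_channel:
        if np.any(var_y <= 0):
            raise ZeroVarianceError("a channel of y has zero variance")
        return (1.0 - var_r / var_y) * 100.0
    total = var_y.sum()
    if total <= 0:
        raise ZeroVarianceError("y has zero variance")
    return float((1.0 - var_r.sum() / total) * 100.0)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean squared error over all samples and channels."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass
class DimensionalVariance:
    """Per-latent-dimension variance ratios (nonnegative, summing to 1)."""

    reducer_id: str
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)


def dimensional_variance(
    latent: np.ndarray, reducer_id: str = ""
) -> DimensionalVariance:
    """Normalized variance of each latent dimension.

    For a PCA score matrix this coincides with the normalized eigenvalue
    distribution over the kept components.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[0] < 2:
        raise ValueError("latent must be (n >= 2, k)")
    variances = latent.var(axis=0)
    total = variances.sum()
    if total <= 0:
        raise ZeroVarianceError("latent has zero total variance")
    return DimensionalVariance(reducer_id=reducer_id, ratios=variances / total)


def variance_entropy(dv: DimensionalVariance | np.ndarray) -> float:
    """Shannon entropy (nats) of a dimensional-variance distribution.

    Maximal (ln k) when variance is shared evenly across dimensions; 0 when
    a single dimension carries everything.
    """
    ratios = dv.ratios if isinstance(dv, DimensionalVariance) else np.asarray(dv)
    return float(stats.entropy(ratios))


def circular_correlation(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Fisher-Lee circular-circular correlation of two angle samples.

    Equals +-1 when one angle is a rotation (or reflection) of the other;
    near 0 for unrelated angles.  Used to check that latent trajectories of
    steady gait are ordered by gait phase.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("alpha and beta must be equal-length 1-D arrays")
    n = a.size
    A = np.sum(np.cos(a) * np.cos(b))
    B = np.sum(np.sin(a) * np.sin(b))
    C = np.sum(np.cos(a) * np.sin(b))
    D = np.sum(np.sin(a) * np.cos(b))
    E = np.sum(np.cos(2 * a))
    F = np.sum(np.sin(2 * a))
    G = np.sum(np.cos(2 * b))
    H = np.sum(np.sin(2 * b))
    denom = np.sqrt((n**2 - E**2 - F**2) * (n**2 - G**2 - H**2))
    if denom == 0:
        raise ZeroVarianceError("degenerate angular distribution")
    return float(4 * (A * B - C * D) / denom)


def circular_rank_correlation(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Rank-based (hence monotone-invariant) circular correlation.

    Both angle samples are replaced by their circular ranks
    ``2 pi rank / n`` before applying the Fisher-Lee coefficient; the
    absolute value is returned so orientation of the latent loop does not
    matter.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    n = a.size
    ra = 2 * np.pi * stats.rankdata(np.mod(a, 2 * np.pi)) / n
    rb = 2 * np.pi * stats.rankdata(np.mod(b, 2 * np.pi)) / n
    return abs(circular_correlation(ra, rb))


def latent_angles(latent: np.ndarray) -> np.ndarray:
    """Angle of each 2-D latent point around the centroid of the cloud."""
    latent = np.asarray(latent, dtype=float)
    if latent.ndim != 2 or latent.shape[1] != 2:
        raise ValueError("latent must be (n, 2)")
    centered = latent - latent.mean(axis=0)
    return np.arctan2(centered[:, 1], centered[:, 0])
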