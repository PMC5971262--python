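"""Multivariate outlier removal by Mahalanobis distance and a chi-square cut.

Under a multivariate-normal working model, the squared Mahalanobis distance
of a d-dimensional sample from the pooled mean follows a chi-square
distribution with d degrees of freedom.  Rows whose squared distance exceeds
the chi-square quantile (default the 97.5th percentile, d = 80) are removed
in a single class-blind pass; labels stay aligned with the kept rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .features import FeatureDataset

__all__ = [
    "OutlierReport",
    "chi2_quantile",
    "mahalanobis_sq",
    "regularize_covariance",
    "filter_outliers",
]

logger = logging.getLogger(__name__)

#: Condition-number threshold above which the ridge is applied.
COND_MAX = 1e12
#: Ridge scale: eps * trace(Sigma)/d added to the diagonal.
RIDGE_EPS = 1e-8


def chi2_quantile(p: float, df: int) -> float:
    """Inverse chi-square CDF (quantile function)."""
    if not 0 < p < 1:
        raise ValueError(f"probability must lie in (0, 1), got {p}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.chi2.ppf(p, df))


def regularize_covariance(sigma: np.ndarray) -> np.ndarray:
    """Add a small ridge to the diagonal when sigma is ill-conditioned.

    The ridge is ``RIDGE_EPS * trace(sigma)/d`` and is applied only when the
    condition number exceeds ``COND_MAX``; the event is logged.  Near-singular
    covariances do occur here: adjacent SFE endpoints of neighbouring
    quarters are the same sample, making feature columns collinear.
    """
    sigma = np.asarray(sigma, dtype=float)
    d = sigma.shape[0]
    cond = np.linalg.cond(sigma)
    if cond > COND_MAX:
        ridge = RIDGE_EPS * np.trace(sigma) / d
        if ridge <= 0:
            ridge = RIDGE_EPS
        logger.info("covariance condition number %.3g > %.0g; adding ridge %.3g",
                    cond, COND_MAX, ridge)
        sigma = sigma + ridge * np.eye(d)
    return sigma


def _cho_factor(sigma: np.ndarray):
    sigma = regularize_covariance(sigma)
    try:
        return linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(sigma)
        raise linalg.LinAlgError(
            f"covariance is singular even after regularization "
            f"(condition number {cond:.3g})"
        ) from exc


def mahalanobis_sq(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float | np.ndarray:
    """Squared Mahalanobis distance (x-mu)' sigma^-1 (x-mu).

    Evaluated via a Cholesky solve — no explicit inverse.  ``x`` may be a
    single vector or an (n, d) matrix of rows.
    """
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    single = x.ndim == 1
    diff = (np.atleast_2d(x) - mu).T  # (d, n)
    factor = _cho_factor(sigma)
    z = linalg.cho_solve(factor, diff)
    d2 = np.einsum("ij,ij->j", diff, z)
    d2 = np.maximum(d2, 0.0)
    return float(d2[0]) if single else d2


@dataclass
class OutlierReport:
    kept_indices: np.ndarray
    removed_indices: np.ndarray
    threshold: float
    distances: np.ndarray

    @property
    def removed_fraction(self) -> float:
        n = self.distances.shape[0]
        return self.removed_indices.shape[0] / n if n else 0.0

    def summary(self, labels=None) -> dict:
        out = {
            "threshold": self.threshold,
            "n_total": int(self.distances.shape[0]),
            "n_kept": int(self.kept_indices.shape[0]),
            "n_removed": int(self.removed_indices.shape[0]),
        }
        if labels is not None:
            labels = np.asarray(labels, dtype=object)
            for cls in np.unique(labels.astype(str)):
                mask = labels == cls
                out[f"kept_{cls}"] = int(np.isin(np.where(mask)[0], self.kept_indices).sum())
        return out


def filter_outliers(
    data: FeatureDataset, quantile: float = 0.975
) -> tuple[FeatureDataset, OutlierReport]:
    """Drop rows whose squared Mahalanobis distance exceeds the chi-square cut.

    Mean and covariance are estimated once from the pooled dataset (all
    classes together, n-1 divisor); the threshold is
    ``chi2_quantile(quantile, d)`` with d the feature dimension.
    """
    X = data.matrix
    n, d = X.shape
    if n <= d + 1:
        raise ValueError(
            f"need more than {d + 1} samples to estimate a rank-{d} covariance, got {n}"
        )
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    d2 = mahalanobis_sq(X, mu, sigma)
    threshold = chi2_quantile(quantile, d)
    keep = d2 <= threshold
    report = OutlierReport(
        kept_indices=np.flatnonzero(keep),
        removed_indices=np.flatnonzero(~keep),
        threshold=threshold,
        distances=d2,
    )
    return data.subset(report.kept_indices), report
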