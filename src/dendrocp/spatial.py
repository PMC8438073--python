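"""Spatially explicit random effects (SERE): exponential distance-decay covariance.

The random field is zero-mean Gaussian with Cov(SERE_i, SERE_j) =
sigma2 * exp(-phi * d_ij), where d_ij is the Euclidean distance between the
trees' (or sites') coordinates. phi is the inverse correlation range and
sigma2 the marginal variance of the field.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = ["pairwise_distances", "sere_covariance"]


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix for an (n, 2) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError(f"coords must be (n, 2), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain non-finite values")
    return cdist(coords, coords)


def sere_covariance(
    coords: np.ndarray,
    phi: float,
    sigma2: float,
    *,
    jitter: float = 0.0,
) -> np.ndarray:
    """Covariance matrix sigma2 * exp(-phi * d_ij) of the spatial random effect.

    Parameters
    ----------
    coords
        (n, 2) coordinates, or a precomputed (n, n) distance matrix.
    phi
        Distance-decay rate (> 0); correlation at distance d is exp(-phi*d).
    sigma2
        Marginal variance (> 0); the zero-distance covariance.
    jitter
        Optional non-negative value added to the diagonal for numerical
        positive-definiteness; any addition is logged.
    """
    if phi <= 0:
        raise ValueError(f"phi must be > 0, got {phi}")
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2 and coords.shape[0] == coords.shape[1] and (
        coords.shape[1] != 2 or np.allclose(np.diag(coords), 0.0)
    ):
        d = coords
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite values")
    else:
        d = pairwise_distances(coords)
    cov = sigma2 * np.exp(-phi * d)
    if jitter > 0:
        logger.info("adding diagonal jitter %.3g to SERE covariance", jitter)
        cov = cov + jitter * np.eye(cov.shape[0])
    return cov
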