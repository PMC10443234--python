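"""Noise-covariance estimation for Mahalanobis-metric distances.

The cross-validated Mahalanobis distance needs a channel noise covariance.
We use the sample covariance of within-class residuals, pooled across
classes (and, for cross-context distances, across contexts: a single metric
must apply to both difference vectors), with diagonal-loading shrinkage

    Sigma_hat = (1 - gamma) * S + gamma * diag(S)

which keeps the matrix invertible from ~10 up to hundreds of channels.
The default shrinkage is 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .datasets import TrialSet
from .exceptions import (
    DimensionError,
    InsufficientDataError,
    NumericalError,
    ValidationError,
)

__all__ = [
    "NoiseCovariance",
    "estimate_noise_covariance",
    "pooled_noise_covariance",
]

DEFAULT_SHRINKAGE = 0.05


@dataclass
class NoiseCovariance:
    """A (shrunk) channel noise covariance matrix.

    ``matrix`` is symmetric ``(n_channels, n_channels)``; ``shrinkage`` is
    the diagonal-loading weight in ``[0, 1]`` that was applied.
    """

    matrix: np.ndarray
    shrinkage: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise DimensionError("covariance matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValidationError("covariance matrix must be symmetric")
        if not (0.0 <= self.shrinkage <= 1.0):
            raise ValidationError("shrinkage must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        """Return ``Sigma^{-1} @ rhs`` (rhs has channels on its first axis)."""
        try:
            cho = scipy.linalg.cho_factor(self.matrix)
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(
                "noise covariance is singular; re-estimate with nonzero "
                "shrinkage (diagonal loading)"
            ) from exc
        return scipy.linalg.cho_solve(cho, rhs)


def estimate_noise_covariance(
    residuals: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    ddof: int | None = None,
) -> NoiseCovariance:
    """Estimate a shrunk noise covariance from residual observations.

    Parameters
    ----------
    residuals : ndarray, shape (n_obs, n_channels)
        Residuals (e.g. trials minus their class mean). The column means are
        removed before forming the cross-product matrix.
    shrinkage : float in [0, 1]
        Diagonal-loading weight; ``1`` returns exactly ``diag(S)``.
    ddof : int, optional
        Divisor is ``n_obs - ddof``; defaults to 1 (sample covariance). Pass
        the number of group means that were subtracted when the residuals
        come from pooled groups.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2:
        raise DimensionError("residuals must be 2-D (n_obs, n_channels)")
    if not np.all(np.isfinite(residuals)):
        raise ValidationError("residuals contain non-finite values")
    n_obs = residuals.shape[0]
    if ddof is None:
        ddof = 1
    if n_obs < 2 or n_obs - ddof < 1:
        raise InsufficientDataError(
            f"need more than {ddof} observations, got {n_obs}"
        )
    if not (0.0 <= shrinkage <= 1.0):
        raise ValidationError("shrinkage must lie in [0, 1]")
    centred = residuals - residuals.mean(axis=0)
    s = centred.T @ centred / (n_obs - ddof)
    shrunk = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
    return NoiseCovariance(matrix=shrunk, shrinkage=shrinkage)


def _class_residuals(ts: TrialSet) -> tuple[np.ndarray, int]:
    """Within-class residuals of one trial set, flattened over time.

    Time-resolved data contribute each (trial, time) sample as one
    observation after removing the per-class per-time mean. Returns the
    stacked residuals ``(n_obs, n_channels)`` and the degrees of freedom
    consumed by the subtracted class means.
    """
    data = ts.data if ts.is_time_resolved else ts.data[..., None]
    resid = np.empty_like(data)
    for c in (1, 2):
        mask = ts.labels == c
        resid[mask] = data[mask] - data[mask].mean(axis=0, keepdims=True)
    # (trials, channels, times) -> (trials*times, channels)
    flat = np.moveaxis(resid, 1, 2).reshape(-1, ts.n_channels)
    dof_lost = 2 * ts.n_times  # one mean per class per time point
    return flat, flat.shape[0] - dof_lost


def pooled_noise_covariance(
    trial_sets: Sequence[TrialSet] | TrialSet,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> NoiseCovariance:
    """Noise covariance pooled over classes (and contexts, if several sets).

    Sums the within-class residual cross-products of every trial set and
    divides by the pooled degrees of freedom, then applies diagonal-loading
    shrinkage.
    """
    if isinstance(trial_sets, TrialSet):
        trial_sets = [trial_sets]
    if not trial_sets:
        raise InsufficientDataError("no trial sets given")
    n_channels = trial_sets[0].n_channels
    ssq = np.zeros((n_channels, n_channels))
    dof = 0
    for ts in trial_sets:
        if ts.n_channels != n_channels:
            raise DimensionError("trial sets disagree on channel count")
        flat, d = _class_residuals(ts)
        ssq += flat.T @ flat
        dof += d
    if dof < 1:
        raise InsufficientDataError("pooled residuals have no degrees of freedom")
    s = ssq / dof
    shrunk = (1.0 - shrinkage) * s + shrinkage * np.diag(np.diag(s))
    return NoiseCovariance(matrix=shrunk, shrinkage=shrinkage)
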