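"""Group-level inference: t-tests, the identity test, cluster permutation.

All tests operate on one value per biological replicate (subject or
simulated repetition). The cluster permutation test controls the
family-wise error over time points (1-D) or time-by-time maps (2-D) with
the max-statistic construction: pointwise one-sample t-values are
thresholded at ``cluster_alpha``, suprathreshold points are grouped by
adjacency (runs in 1-D, 4-neighbour connectivity in 2-D), each cluster's
mass is the sum of its t-values, and the observed masses are referred to
the permutation distribution of the maximum cluster mass under random
per-replicate sign flips.

Ties between an observed mass and a permutation mass count toward the
null, and the identity flip is included through the ``(1 + #) / (n + 1)``
p-value, so the smallest attainable p is ``1 / (n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional

import numpy as np
import scipy.ndimage
import scipy.stats

from .exceptions import DegenerateSampleError, ValidationError

__all__ = [
    "Tail",
    "ClusterTestResult",
    "one_sample_t",
    "paired_t",
    "identity_test",
    "cluster_permutation",
]

Tail = Literal["two-sided", "greater", "less"]
_TAILS = ("two-sided", "greater", "less")


def _check_tail(tail: str) -> None:
    if tail not in _TAILS:
        raise ValidationError(f"tail must be one of {_TAILS}, got {tail!r}")


def one_sample_t(
    values: np.ndarray, null_mean: float = 0.0, tail: Tail = "two-sided"
) -> tuple[float, float]:
    """Classical one-sample t-test against ``null_mean``.

    Returns ``(t, p)`` for the requested tail. Raises
    :class:`DegenerateSampleError` for samples with zero variance.
    """
    _check_tail(tail)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValidationError("need a 1-D sample with >= 2 values")
    if np.std(values, ddof=1) == 0.0:
        raise DegenerateSampleError("sample has zero variance")
    res = scipy.stats.ttest_1samp(values, null_mean, alternative=tail)
    return float(res.statistic), float(res.pvalue)


def paired_t(
    a: np.ndarray, b: np.ndarray, tail: Tail = "two-sided"
) -> tuple[float, float]:
    """Paired t-test of ``a`` vs ``b`` (t on the differences ``a - b``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, tail)


def identity_test(
    empirical: np.ndarray, expected: np.ndarray
) -> tuple[float, float]:
    """Test whether generalization falls short of its identity expectation.

    Paired one-tailed t-test of ``empirical < expected`` across replicates.
    Rejection licenses the inference that the two representations are not
    identical -- an inference that survives spatial mixing, because mixing
    can only increase the similarity of measured representations. The
    expectation being a lower bound makes the test conservative.
    """
    return paired_t(empirical, expected, tail="less")


@dataclass
class ClusterTestResult:
    """Clusters of a permutation test with their mass-based p-values.

    ``cluster_extents`` holds, per cluster, the tuple of index arrays
    (``np.nonzero`` style) addressing its points in the data grid.
    """

    cluster_masses: np.ndarray
    cluster_extents: List[tuple]
    cluster_p: np.ndarray
    n_permutations: int
    tail: Tail
    t_map: np.ndarray
    threshold: float

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean mask over clusters with ``p < alpha``."""
        return self.cluster_p < alpha

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Boolean map over the data grid covered by significant clusters."""
        mask = np.zeros(self.t_map.shape, dtype=bool)
        for keep, extent in zip(self.significant(alpha), self.cluster_extents):
            if keep:
                mask[extent] = True
        return mask


def _t_from_flips(
    flips: np.ndarray, values: np.ndarray, ssq: np.ndarray
) -> np.ndarray:
    """Pointwise t-maps for a batch of sign-flip vectors.

    Sign flips leave the per-point sum of squares unchanged, so only the
    mean needs recomputing: t = mean / sqrt(var / n).
    """
    n = values.shape[0]
    means = flips @ values / n  # (batch, n_points)
    var = (ssq[None, :] - n * means**2) / (n - 1)
    var = np.clip(var, 1e-300, None)
    return means / np.sqrt(var / n)


def _clusters(
    t_map: np.ndarray, threshold: float, tail: Tail, structure: np.ndarray
) -> tuple[list, list]:
    """Suprathreshold clusters and their signed masses for one t-map."""
    masses, extents = [], []
    signs = (1.0,) if tail == "greater" else (-1.0,) if tail == "less" else (1.0, -1.0)
    for sign in signs:
        mask = sign * t_map >= threshold
        if not mask.any():
            continue
        labelled, n_lab = scipy.ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            extent = np.nonzero(labelled == lab)
            masses.append(float(t_map[extent].sum()))
            extents.append(extent)
    return masses, extents


def _max_null_masses(
    t_perm: np.ndarray, threshold: float, tail: Tail, structure: np.ndarray
) -> np.ndarray:
    out = np.zeros(t_perm.shape[0])
    for i, tm in enumerate(t_perm):
        masses, _ = _clusters(tm, threshold, tail, structure)
        if masses:
            out[i] = max(abs(m) for m in masses)
    return out


def cluster_permutation(
    values: np.ndarray,
    cluster_alpha: float = 0.05,
    n_permutations: int = 1000,
    tail: Tail = "two-sided",
    rng: Optional[np.random.Generator] = None,
    connectivity: int = 4,
) -> ClusterTestResult:
    """Cluster-based sign-flip permutation test against a zero mean.

    Parameters
    ----------
    values : ndarray, shape (n_replicates, n_points) or (n_replicates, n1, n2)
        One value per replicate and grid point.
    cluster_alpha : float
        Pointwise cluster-forming threshold (converted to a t quantile).
    n_permutations : int
        Number of random sign-flip permutations.
    tail : {'two-sided', 'greater', 'less'}
        Direction of the pointwise tests. Two-sided forms positive and
        negative clusters separately and compares |mass| to the null.
    connectivity : {4, 8}
        Neighbourhood for 2-D cluster formation; ignored for 1-D data.
    """
    _check_tail(tail)
    if rng is None:
        rng = np.random.default_rng()
    values = np.asarray(values, dtype=float)
    if values.ndim not in (2, 3):
        raise ValidationError("values must be (replicates, points[, points])")
    if values.shape[0] < 2:
        raise ValidationError("need >= 2 replicates")
    if n_permutations < 1:
        raise ValidationError("need >= 1 permutation")
    n_rep = values.shape[0]
    grid_shape = values.shape[1:]
    flat = values.reshape(n_rep, -1)
    ssq = np.einsum("rp,rp->p", flat, flat)
    sd = flat.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise DegenerateSampleError("zero variance at every grid point")

    if values.ndim == 3:
        if connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        structure = scipy.ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    else:
        structure = np.ones(3, dtype=bool)

    df = n_rep - 1
    if tail == "two-sided":
        threshold = float(scipy.stats.t.ppf(1 - cluster_alpha / 2, df))
    else:
        threshold = float(scipy.stats.t.ppf(1 - cluster_alpha, df))

    t_obs = _t_from_flips(np.ones((1, n_rep)), flat, ssq)[0].reshape(grid_shape)
    masses, extents = _clusters(t_obs, threshold, tail, structure)

    null = np.zeros(n_permutations)
    batch = max(1, min(n_permutations, int(4e7 // max(flat.size, 1)) or 1))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        flips = rng.choice((-1.0, 1.0), size=(b, n_rep))
        t_perm = _t_from_flips(flips, flat, ssq).reshape((b,) + grid_shape)
        null[done : done + b] = _max_null_masses(t_perm, threshold, tail, structure)
        done += b

    if masses:
        obs = np.abs(np.asarray(masses))
        # ties count toward the null (conservative)
        exceed = (null[None, :] >= obs[:, None]).sum(axis=1)
        p = (1.0 + exceed) / (n_permutations + 1.0)
    else:
        obs = np.empty(0)
        p = np.empty(0)
    return ClusterTestResult(
        cluster_masses=np.asarray(masses, dtype=float),
        cluster_extents=extents,
        cluster_p=p,
        n_permutations=n_permutations,
        tail=tail,
        t_map=t_obs,
        threshold=threshold,
    )
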