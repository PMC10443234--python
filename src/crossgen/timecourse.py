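"""Time-resolved information, cross-context and cross-temporal generalization.

These functions operate on a single replicate's time-resolved
:class:`~crossgen.datasets.TrialSet` (``n_trials x n_channels x n_times``)
and return plain per-time arrays; :mod:`crossgen.model` stacks them across
replicates and adds the group statistics.

One fold assignment is shared across all time points of a replicate so
cross-temporal products compare like with like, and the identity
expectation is always computed per replicate *before* any averaging: the
geometric mean and the across-replicate average do not commute, and taking
the expectation on group-averaged information values over-estimates it
whenever the information ratio varies across replicates.

``synth_meg_example`` generates a self-contained stand-in for a
two-hemifield, two-contrast MEG study: an early context-specific
representation (consistent across replicates and spatially mixed into the
channels, hence spuriously generalizing) transitions into a late shared,
stable representation.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence

import numpy as np

from .covariance import NoiseCovariance
from .datasets import TrialSet
from .exceptions import DimensionError, ValidationError
from .metrics import expected_generalization_identity
from .mixing import gaussian_mixing_matrix

__all__ = [
    "information_timecourse",
    "cross_context_timecourse",
    "temporal_generalization_matrix",
    "synth_meg_example",
]


def _fold_deltas(ts: TrialSet, fold_assignment: np.ndarray) -> np.ndarray:
    """Per-fold class mean differences, shape ``(2, n_channels, n_times)``."""
    if not ts.is_time_resolved:
        raise DimensionError("expected time-resolved data (trials x chan x time)")
    fold_assignment = np.asarray(fold_assignment)
    out = np.empty((2, ts.n_channels, ts.n_times))
    for f in (1, 2):
        out[f - 1] = ts.class_mean_difference(fold_assignment == f)
    return out


def information_timecourse(
    trials: TrialSet,
    cov: NoiseCovariance,
    fold_assignment: np.ndarray,
) -> np.ndarray:
    """Cross-validated Mahalanobis information at every time point.

    Applies the two-fold crossnobis estimator independently per time point
    with a shared fold assignment and the supplied (typically
    time-pooled) noise covariance. Returns shape ``(n_times,)``.
    """
    d = _fold_deltas(trials, fold_assignment)
    w = cov.solve(d[1])  # (channels, times)
    return np.einsum("ct,ct->t", d[0], w)


def cross_context_timecourse(
    trials_a: TrialSet,
    trials_b: TrialSet,
    cov: NoiseCovariance,
    fold_a: np.ndarray,
    fold_b: np.ndarray,
) -> dict:
    """Per-time generalization between two contexts of one replicate.

    Returns a dict of ``(n_times,)`` arrays: ``info_a``, ``info_b``,
    ``empirical``, ``expected`` (identity expectation from this
    replicate's two information values), ``min_reference`` and
    ``relative`` (NaN where the expectation is not positive).
    """
    if trials_a.n_times != trials_b.n_times:
        raise DimensionError("contexts disagree on the number of time points")
    if trials_a.time_axis is not None and trials_b.time_axis is not None:
        if not np.allclose(trials_a.time_axis, trials_b.time_axis):
            raise DimensionError("contexts disagree on the time axis")
    da = _fold_deltas(trials_a, fold_a)
    db = _fold_deltas(trials_b, fold_b)
    wa = np.stack([cov.solve(da[0]), cov.solve(da[1])])
    wb = np.stack([cov.solve(db[0]), cov.solve(db[1])])
    info_a = np.einsum("ct,ct->t", da[0], wa[1])
    info_b = np.einsum("ct,ct->t", db[0], wb[1])
    empirical = 0.5 * (
        np.einsum("ct,ct->t", da[0], wb[1]) + np.einsum("ct,ct->t", da[1], wb[0])
    )
    expected = np.sqrt(np.clip(info_a, 0, None) * np.clip(info_b, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = np.where(expected > 0, empirical / expected, np.nan)
    return {
        "info_a": info_a,
        "info_b": info_b,
        "empirical": empirical,
        "expected": expected,
        "min_reference": np.minimum(info_a, info_b),
        "relative": relative,
    }


def temporal_generalization_matrix(
    trials: TrialSet,
    cov: NoiseCovariance,
    fold_assignment: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-temporal generalization of one replicate's representation.

    ``empirical[t1, t2]`` is the cross-validated product of the fold-wise
    difference vectors at train time ``t1`` and test time ``t2``, averaged
    over the two fold orderings; its diagonal equals the within-time
    information exactly (same folds). ``expected_stable[t1, t2]`` is the
    identity expectation ``sqrt(info(t1) * info(t2))`` under a perfectly
    stable representation, symmetric in its two time indices.
    """
    if trials.n_times < 2:
        raise ValidationError("need >= 2 time points")
    d = _fold_deltas(trials, fold_assignment)
    w = np.stack([cov.solve(d[0]), cov.solve(d[1])])
    empirical = 0.5 * (d[0].T @ w[1] + d[1].T @ w[0])
    info = np.diag(empirical).copy()
    clipped = np.clip(info, 0, None)
    expected_stable = np.sqrt(np.outer(clipped, clipped))
    return empirical, expected_stable


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=-1, keepdims=True)
    return np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)


def _component(rng: np.random.Generator, support: np.ndarray, n_latent: int):
    v = np.zeros(n_latent)
    v[support] = np.abs(rng.standard_normal(len(support)))
    return v / np.linalg.norm(v)


def synth_meg_example(
    n_replicates: int = 19,
    n_channels: int = 30,
    n_times: int = 40,
    onset_index: int = 10,
    early_overlap: float = 0.0,
    late_overlap: float = 0.8,
    snr_profile: Optional[Sequence[float]] = None,
    rotation: str = "dynamic",
    seed: int = 0,
    n_trials: int = 200,
    n_latent: int = 100,
    mixing_sd: float = 4.0,
) -> tuple[List[TrialSet], List[TrialSet]]:
    """Synthetic stand-in for a two-context, two-class MEG dataset.

    Class-difference patterns live in an ``n_latent``-dimensional source
    space and are spatially mixed into ``n_channels`` measurement channels
    by Gaussian kernels (SD ``mixing_sd`` latent units); channel noise is
    i.i.d. standard normal. All pattern components are consistent across
    replicates (the spatial topography is stable over subjects), which is
    what makes early spurious generalization group-significant.

    With ``rotation='dynamic'`` the latent pattern of each context rotates
    over time from an early component pair with cross-context cosine
    ``early_overlap`` to a late, temporally stable pair with cosine
    ``late_overlap``; ``rotation='stable'`` uses the late pair throughout.
    ``snr_profile`` gives the true per-time channel-level crossnobis
    distance (default: 0 before ``onset_index``, saturating at 4 after);
    the signal scale at each time is set so the profile holds exactly.

    Returns two lists of time-resolved :class:`TrialSet` (context A and
    context B), one entry per replicate; the time axis is in seconds at
    50 Hz with stimulus onset at ``onset_index``.
    """
    for name, v in (("early_overlap", early_overlap), ("late_overlap", late_overlap)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1]")
    if rotation not in ("dynamic", "stable"):
        raise ValidationError("rotation must be 'dynamic' or 'stable'")
    if not (0 <= onset_index < n_times):
        raise ValidationError("onset_index must lie inside the time axis")
    if n_trials % 2:
        raise ValidationError("n_trials must be even")
    rng = np.random.default_rng(seed)
    t = np.arange(n_times, dtype=float)
    if snr_profile is None:
        snr_profile = np.where(
            t >= onset_index, 4.0 * (1.0 - np.exp(-(t - onset_index) / 3.0)), 0.0
        )
    snr_profile = np.asarray(snr_profile, dtype=float)
    if snr_profile.shape != (n_times,) or np.any(snr_profile < 0):
        raise ValidationError("snr_profile must be n_times non-negative values")

    # Five disjoint, spatially contiguous latent supports (block order:
    # late-A specific | early A | early B | shared | late-B specific).
    # The early supports of the two contexts are adjacent, so spatial
    # mixing leaks a small consistent overlap between them -- the source
    # of the spurious early generalization; the context-specific late
    # supports are far apart.
    k = n_latent // 5
    blocks = [np.arange(i * k, (i + 1) * k) for i in range(5)]
    h_a = _component(rng, blocks[0], n_latent)
    u_a, u_b = _component(rng, blocks[1], n_latent), _component(rng, blocks[2], n_latent)
    g = _component(rng, blocks[3], n_latent)
    h_b = _component(rng, blocks[4], n_latent)
    e_a = u_a
    e_b = early_overlap * u_a + math.sqrt(1.0 - early_overlap**2) * u_b
    l_a = math.sqrt(late_overlap) * g + math.sqrt(1.0 - late_overlap) * h_a
    l_b = math.sqrt(late_overlap) * g + math.sqrt(1.0 - late_overlap) * h_b

    # temporal envelopes of the early-to-late rotation
    rel_t = t - onset_index
    early_env = np.exp(-0.5 * ((rel_t - 3.0) / 2.5) ** 2) * (rel_t >= 0)
    late_env = (1.0 / (1.0 + np.exp(-(rel_t - 8.0) / 1.5))) * (rel_t >= 0)
    mix = gaussian_mixing_matrix(n_latent, n_channels, mixing_sd)

    patterns = np.empty((2, n_channels, n_times))
    for c, (e_c, l_c) in enumerate(((e_a, l_a), (e_b, l_b))):
        if rotation == "stable":
            latent = np.tile(l_c[:, None], (1, n_times))
        else:
            latent = e_c[:, None] * early_env + l_c[:, None] * late_env
        latent = _unit_rows(latent.T).T  # unit latent norm per time (where nonzero)
        chan = mix @ latent
        norms = np.linalg.norm(chan, axis=0)
        scale = np.divide(
            np.sqrt(snr_profile), norms, out=np.zeros(n_times), where=norms > 0
        )
        patterns[c] = chan * scale

    time_axis = (t - onset_index) * 0.02
    half = n_trials // 2
    labels = np.r_[np.ones(half, dtype=int), np.full(half, 2, dtype=int)]
    signs = np.where(labels == 1, 0.5, -0.5)
    out: tuple[List[TrialSet], List[TrialSet]] = ([], [])
    for r in range(n_replicates):
        for c in range(2):
            noise = rng.standard_normal((n_trials, n_channels, n_times))
            data = noise + signs[:, None, None] * patterns[c][None]
            out[c].append(
                TrialSet(
                    data=data,
                    labels=labels.copy(),
                    context_id="A" if c == 0 else "B",
                    replicate_id=f"rep-{r:02d}",
                    time_axis=time_axis,
                )
            )
    return out
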