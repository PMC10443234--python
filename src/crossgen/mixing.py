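"""Sensor-mixing simulation: spurious generalization from spatial smoothing.

Generative model
----------------
Two experimental contexts each recruit a *disjoint* subset of a population
of neurons (default: 100 neurons split evenly), so the two class-difference
representations are exactly orthogonal at the neuron level and any
statistically significant cross-context generalization is a false positive
by construction.

Each selective neuron's class-difference weight has a half-normal magnitude
and a sign that is +1 with probability ``(1 + uniformity) / 2``:
``uniformity = 1`` makes every selective neuron prefer class 1,
``uniformity = 0`` makes the signs symmetric. Across repetitions (subjects)
the weights are a variance-preserving mixture

    w_rep = sqrt(stability) * w_shared + sqrt(1 - stability) * w_individual

so ``stability = 1`` reuses one pattern everywhere, ``stability = 0`` draws
independent patterns, and the across-repetition correlation of selective
weights is approximately ``stability``.

Trials add unit Gaussian noise per neuron; neuron activity is spatially
mixed into a small number of sensors by Gaussian kernels over the neuron
index (default 10 sensors, kernel SD 25 neurons, rows normalized to unit
sum). Analysis runs at the sensor level: pooled within-class residual
covariance with diagonal-loading shrinkage, two-fold cross-validated
Mahalanobis distances, cross-context generalization, and a two-tailed
one-sample t-test of the per-repetition generalization values against 0.

The engine draws sensor noise directly from N(0, Mix Mix') via the
symmetric matrix square root, which is exactly the distribution of mixed
neuron noise; ``return_trials=True`` materialises equivalent trial arrays
for cross-checks against the per-TrialSet metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import scipy.stats

from .covariance import DEFAULT_SHRINKAGE
from .exceptions import CalibrationError, ValidationError

__all__ = [
    "MixingSimConfig",
    "NeuralPattern",
    "MixingRunResult",
    "FalsePositiveResult",
    "gaussian_mixing_matrix",
    "draw_patterns",
    "simulate_context_trials",
    "calibrate_signal_scale",
    "run_mixing_experiment",
    "false_positive_rate",
]


@dataclass
class MixingSimConfig:
    """Parameters of the sensor-mixing simulation.

    Defaults reproduce the reference setting: 100 neurons mixed into 10
    sensors with a Gaussian kernel of SD 25 neurons, 1000 trials per
    context, 20 repetitions per run, alpha 0.05, 1000 runs.
    ``target_m`` is the average sensor-level cross-validated Mahalanobis
    distance that defines the SNR condition.
    """

    n_neurons: int = 100
    n_sensors: int = 10
    mixing_sd: float = 25.0
    n_trials_per_context: int = 1000
    n_repetitions: int = 20
    uniformity: float = 0.0
    stability: float = 0.0
    target_m: float = 0.25
    alpha: float = 0.05
    n_runs: int = 1000
    seed: int = 0
    shrinkage: float = DEFAULT_SHRINKAGE
    identity_mixing: bool = False

    def __post_init__(self) -> None:
        for name in ("n_neurons", "n_sensors", "n_trials_per_context",
                     "n_repetitions", "n_runs"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive count")
        if self.mixing_sd <= 0:
            raise ValidationError("mixing_sd must be > 0")
        for name in ("uniformity", "stability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.target_m < 0:
            raise ValidationError("target_m must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (0.0 <= self.shrinkage <= 1.0):
            raise ValidationError("shrinkage must lie in [0, 1]")
        if self.n_trials_per_context % 4:
            raise ValidationError(
                "n_trials_per_context must be a multiple of 4 "
                "(balanced classes in two folds)"
            )
        if self.identity_mixing and self.n_sensors != self.n_neurons:
            raise ValidationError(
                "identity mixing requires n_sensors == n_neurons"
            )


@dataclass
class NeuralPattern:
    """Neuron-level class-difference weights of one repetition.

    ``weights`` is ``(n_contexts, n_neurons)``; ``selective_sets`` holds the
    per-context neuron index sets, disjoint across contexts so the two
    context patterns are exactly orthogonal.
    """

    weights: np.ndarray
    selective_sets: List[np.ndarray]

    def __post_init__(self) -> None:
        sets = [np.asarray(s) for s in self.selective_sets]
        flat = np.concatenate(sets)
        if len(np.unique(flat)) != len(flat):
            raise ValidationError("selective sets must be disjoint")
        for c, s in enumerate(sets):
            off = np.ones(self.weights.shape[1], dtype=bool)
            off[s] = False
            if np.any(self.weights[c, off] != 0.0):
                raise ValidationError(
                    "weights outside a context's selective set must be 0"
                )


@dataclass
class MixingRunResult:
    """Per-repetition outcomes of one simulation run."""

    generalization: np.ndarray  # (n_repetitions,)
    information: np.ndarray     # (n_repetitions, 2 contexts)
    t: float
    p: float
    signal_scale: float


@dataclass
class FalsePositiveResult:
    """False-positive-rate estimate with exact binomial 95% CI."""

    n_runs: int
    n_significant: int
    proportion: float
    ci_low: float
    ci_high: float
    group_t: np.ndarray = field(repr=False)
    group_p: np.ndarray = field(repr=False)
    signal_scale: float = math.nan


def gaussian_mixing_matrix(
    n_neurons: int, n_sensors: int, sd: float
) -> np.ndarray:
    """Sensor-by-neuron mixing weights from Gaussian kernels.

    Sensor centres are evenly spaced over the neuron index range; each row
    is a Gaussian kernel of standard deviation ``sd`` (in neuron-index
    units), truncated at the array edges and normalized to unit sum.
    """
    if n_neurons < 1 or n_sensors < 1:
        raise ValidationError("counts must be positive")
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    idx = np.arange(n_neurons, dtype=float)
    centers = (np.arange(n_sensors) + 0.5) * n_neurons / n_sensors - 0.5
    kern = np.exp(-0.5 * ((idx[None, :] - centers[:, None]) / sd) ** 2)
    return kern / kern.sum(axis=1, keepdims=True)


def _mixing_operator(config: MixingSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Mixing matrix and symmetric square root of the sensor noise covariance."""
    if config.identity_mixing:
        eye = np.eye(config.n_neurons)
        return eye, eye
    mix = gaussian_mixing_matrix(
        config.n_neurons, config.n_sensors, config.mixing_sd
    )
    w, v = np.linalg.eigh(mix @ mix.T)
    root = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    return mix, root


def _draw_weights(
    rng: np.random.Generator, shape: tuple, uniformity: float
) -> np.ndarray:
    mags = np.abs(rng.standard_normal(shape))
    signs = np.where(rng.random(shape) < (1.0 + uniformity) / 2.0, 1.0, -1.0)
    return mags * signs


def _pattern_batch(
    rng: np.random.Generator, config: MixingSimConfig, n_runs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Neuron-level weights ``(runs, reps, 2, n_neurons)`` and selective sets.

    Selective sets (one random disjoint half of the neurons per context) and
    the shared pattern component are drawn once per run; individual
    components are drawn per repetition.
    """
    n = config.n_neurons
    k = n // 2
    reps = config.n_repetitions
    order = np.argsort(rng.random((n_runs, n)), axis=1)
    sets = np.stack([order[:, :k], order[:, k : 2 * k]], axis=1)  # (runs, 2, k)
    shared = _draw_weights(rng, (n_runs, 1, 2, k), config.uniformity)
    indiv = _draw_weights(rng, (n_runs, reps, 2, k), config.uniformity)
    s = config.stability
    w_sel = math.sqrt(s) * shared + math.sqrt(1.0 - s) * indiv
    weights = np.zeros((n_runs, reps, 2, n))
    idx = np.broadcast_to(sets[:, None, :, :], w_sel.shape)
    np.put_along_axis(weights, idx, w_sel, axis=3)
    return weights, sets


def draw_patterns(
    config: MixingSimConfig, rng: np.random.Generator
) -> List[NeuralPattern]:
    """Draw one run's neuron-level patterns, one per repetition."""
    weights, sets = _pattern_batch(rng, config, n_runs=1)
    return [
        NeuralPattern(
            weights=weights[0, r],
            selective_sets=[sets[0, 0], sets[0, 1]],
        )
        for r in range(config.n_repetitions)
    ]


def simulate_context_trials(
    pattern_row: np.ndarray,
    signal_scale: float,
    n_trials: int,
    rng: np.random.Generator,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one context's neuron-level trials.

    Class-1 trials get ``+signal_scale * pattern / 2``, class-2 trials the
    negative, plus i.i.d. standard normal noise per neuron and trial
    (``noise=False`` is a deterministic test hook). Classes are balanced;
    ``n_trials`` must be even.
    """
    if n_trials % 2:
        raise ValidationError("n_trials must be even (balanced classes)")
    if signal_scale < 0:
        raise ValidationError("signal_scale must be >= 0")
    pattern_row = np.asarray(pattern_row, dtype=float)
    half = n_trials // 2
    labels = np.r_[np.ones(half, dtype=int), np.full(half, 2, dtype=int)]
    signs = np.where(labels == 1, 0.5, -0.5)
    data = signs[:, None] * (signal_scale * pattern_row)[None, :]
    if noise:
        data = data + rng.standard_normal((n_trials, len(pattern_row)))
    return data, labels


def _simulate_stats(
    rng: np.random.Generator,
    config: MixingSimConfig,
    scale: float,
    n_runs: int,
    return_trials: bool = False,
):
    """Vectorised engine: per-run, per-repetition crossnobis statistics.

    Returns ``(gen, info)`` with shapes ``(n_runs, reps)`` and
    ``(n_runs, reps, 2)``; with ``return_trials=True`` additionally the
    sensor trial arrays ``(n_runs, reps, 2, n_trials, n_sensors)``, labels
    and fold assignment used, for equivalence checks against the public
    per-TrialSet metrics.

    Trial layout within a context: fold 1 then fold 2, each holding
    ``n/4`` class-1 followed by ``n/4`` class-2 trials. Noise is i.i.d.,
    so this fixed layout is distributionally equivalent to a random
    stratified split.
    """
    mix, noise_root = _mixing_operator(config)
    n = config.n_trials_per_context
    q = n // 4
    reps = config.n_repetitions
    n_sens = mix.shape[0]
    gamma = config.shrinkage

    weights, _ = _pattern_batch(rng, config, n_runs)
    patt = weights @ mix.T  # (runs, reps, 2, sensors)

    z = rng.standard_normal((n_runs, reps, 2, n, n_sens))
    noise = z @ noise_root  # sensor-level noise, exact covariance Mix Mix'
    del z
    # (runs, reps, ctx, fold, class, q, sensors)
    noise_g = noise.reshape(n_runs, reps, 2, 2, 2, q, n_sens)
    grp_means = noise_g.mean(axis=5)  # (runs, reps, ctx, fold, class, sens)
    fold_noise_diff = grp_means[..., 0, :] - grp_means[..., 1, :]
    deltas = scale * patt[:, :, :, None, :] + fold_noise_diff
    # residuals about per-(context, class) means, pooled over contexts
    class_means = noise_g.mean(axis=(3, 5))  # (runs, reps, ctx, class, sens)
    resid = noise_g - class_means[:, :, :, None, :, None, :]
    ssq = np.einsum("abcdefs,abcdefu->absu", resid, resid)
    dof = 2 * (n - 2)
    cov = ssq / dof
    diag = np.einsum("...ss->...s", cov)
    cov = (1.0 - gamma) * cov
    step = cov.shape[-1] + 1
    cov.reshape(n_runs, reps, -1)[:, :, ::step] += gamma * diag

    rhs = np.moveaxis(deltas.reshape(n_runs, reps, 4, n_sens), 2, 3)
    sol = np.linalg.solve(cov, rhs)  # (runs, reps, sens, 4): A1 A2 B1 B2
    sol = np.moveaxis(sol, 3, 2).reshape(n_runs, reps, 2, 2, n_sens)
    info = np.einsum("abcs,abcs->abc", deltas[:, :, :, 0, :], sol[:, :, :, 1, :])
    gen = 0.5 * (
        np.einsum("abs,abs->ab", deltas[:, :, 0, 0, :], sol[:, :, 1, 1, :])
        + np.einsum("abs,abs->ab", deltas[:, :, 0, 1, :], sol[:, :, 1, 0, :])
    )
    if not return_trials:
        return gen, info
    signs = np.tile(np.r_[np.full(q, 0.5), np.full(q, -0.5)], 2)
    trials = noise + signs[None, None, None, :, None] * (
        scale * patt[:, :, :, None, :]
    )
    labels = np.tile(np.r_[np.ones(q, int), np.full(q, 2, int)], 2)
    folds = np.r_[np.ones(2 * q, int), np.full(2 * q, 2, int)]
    return gen, info, trials, labels, folds


def _chunked_stats(
    seed_seq: np.random.SeedSequence, config: MixingSimConfig, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``config.n_runs`` runs in memory-bounded chunks."""
    per_run = (
        config.n_repetitions * 2 * config.n_trials_per_context
        * max(config.n_sensors, 1)
    )
    chunk = max(1, int(2.5e7 // max(per_run, 1)))
    gens, infos = [], []
    remaining = config.n_runs
    children = seed_seq.spawn(math.ceil(config.n_runs / chunk))
    for child in children:
        b = min(chunk, remaining)
        rng = np.random.default_rng(child)
        g, i = _simulate_stats(rng, config, scale, b)
        gens.append(g)
        infos.append(i)
        remaining -= b
    return np.concatenate(gens), np.concatenate(infos)


def calibrate_signal_scale(
    target_m: float,
    config: MixingSimConfig,
    rng: Optional[np.random.Generator] = None,
    n_probe: int = 400,
    tol: float = 0.05,
    max_iter: int = 40,
) -> float:
    """Signal scale whose expected sensor-level crossnobis distance is ``target_m``.

    Monotone bisection on Monte-Carlo estimates with common random numbers
    (the same probe noise is replayed at every candidate scale, which makes
    the estimated distance monotone in the scale). The probe simulates
    ``n_probe`` repetitions through the full sensor-level analysis.
    Calibration tolerance: ``tol`` (relative, default 5%).
    """
    if target_m < 0:
        raise ValidationError("target_m must be >= 0")
    if target_m == 0:
        return 0.0
    if rng is None:
        rng = np.random.default_rng(config.seed)
    probe_seed = int(rng.integers(2**31 - 1))
    probe_cfg = replace(config, n_repetitions=n_probe, n_runs=1)

    def mean_m(scale: float) -> float:
        _, info = _simulate_stats(
            np.random.default_rng(probe_seed), probe_cfg, scale, n_runs=1
        )
        return float(info.mean())

    m1 = mean_m(1.0)
    if m1 <= 0:
        raise CalibrationError("probe distance at unit scale is not positive")
    # quadratic guess, then bracket and bisect
    s = math.sqrt(target_m / m1)
    lo, hi = 0.0, s
    it = 0
    while mean_m(hi) < target_m:
        lo, hi = hi, hi * 2.0
        it += 1
        if it > max_iter:
            raise CalibrationError(
                f"could not bracket target_m={target_m}; "
                f"last probe {mean_m(hi / 2):.4g} at scale {hi / 2:.4g}"
            )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m_mid = mean_m(mid)
        if abs(m_mid - target_m) <= tol * target_m:
            return mid
        if m_mid < target_m:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach +/-{tol:.0%} of target_m={target_m} "
        f"in {max_iter} iterations (bracket [{lo:.4g}, {hi:.4g}])"
    )


def _group_test(gen: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed one-sample t-test across repetitions, vectorised over runs."""
    reps = gen.shape[1]
    mean = gen.mean(axis=1)
    sd = gen.std(axis=1, ddof=1)
    sd = np.clip(sd, 1e-300, None)
    t = mean / (sd / math.sqrt(reps))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=reps - 1)
    return t, p


def run_mixing_experiment(
    config: MixingSimConfig,
    rng: Optional[np.random.Generator] = None,
    signal_scale: Optional[float] = None,
) -> MixingRunResult:
    """One simulation run: per-repetition generalization plus the group test.

    The signal scale is calibrated to ``config.target_m`` unless supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if signal_scale is None:
        signal_scale = calibrate_signal_scale(config.target_m, config, rng)
    gen, info = _simulate_stats(rng, config, signal_scale, n_runs=1)
    t, p = _group_test(gen)
    return MixingRunResult(
        generalization=gen[0],
        information=info[0],
        t=float(t[0]),
        p=float(p[0]),
        signal_scale=signal_scale,
    )


def false_positive_rate(
    config: MixingSimConfig,
    signal_scale: Optional[float] = None,
) -> FalsePositiveResult:
    """Fraction of runs with a significant group test, with exact binomial CI.

    Ground truth is orthogonal in every run, so every significant group
    test (two-tailed p < ``config.alpha``) is a false positive.
    """
    root = np.random.SeedSequence(config.seed)
    cal_seq, run_seq = root.spawn(2)
    if signal_scale is None:
        signal_scale = calibrate_signal_scale(
            config.target_m, config, np.random.default_rng(cal_seq)
        )
    gen, _ = _chunked_stats(run_seq, config, signal_scale)
    t, p = _group_test(gen)
    k = int(np.sum(p < config.alpha))
    ci = scipy.stats.binomtest(k, config.n_runs).proportion_ci(
        confidence_level=0.95, method="exact"
    )
    return FalsePositiveResult(
        n_runs=config.n_runs,
        n_significant=k,
        proportion=k / config.n_runs,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        group_t=t,
        group_p=p,
        signal_scale=signal_scale,
    )
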