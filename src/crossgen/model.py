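"""Model/Results interface for the full pattern-generalization analysis.

`PatternGeneralizationModel` is built from two groups of time-resolved
trial sets (context A and context B, one per replicate); ``fit()`` runs
the complete pipeline -- per-replicate noise covariances, time-resolved
crossnobis information, cross-context generalization with its identity
expectation, cross-temporal generalization maps, and the group-level
cluster permutation tests -- and returns a
:class:`PatternGeneralizationResults` carrying the estimates, their
across-replicate uncertainties and a ``summary()`` table.

Everything nonlinear (the identity expectation, relative generalization)
is computed per replicate before averaging; the commuted variant
(expectation of group-averaged information) is intentionally not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .covariance import DEFAULT_SHRINKAGE, NoiseCovariance, pooled_noise_covariance
from .datasets import TrialSet, make_folds
from .exceptions import DimensionError, ValidationError
from .stats import ClusterTestResult, cluster_permutation, identity_test, one_sample_t
from .timecourse import cross_context_timecourse, temporal_generalization_matrix

__all__ = [
    "TimecourseResult",
    "TemporalGeneralizationMaps",
    "PatternGeneralizationModel",
    "PatternGeneralizationResults",
]


@dataclass
class TimecourseResult:
    """Stacked per-replicate time-resolved estimates.

    All arrays are ``(n_replicates, n_times)``; ``relative`` holds NaN
    where a replicate's identity expectation was not positive. The
    expectation is computed per replicate before any averaging.
    """

    times: np.ndarray
    info_a: np.ndarray
    info_b: np.ndarray
    generalization: np.ndarray
    expected: np.ndarray
    min_reference: np.ndarray
    relative: np.ndarray

    def group_relative(self) -> tuple[np.ndarray, np.ndarray]:
        """NaN-aware group mean of relative generalization and the
        per-time count of excluded (undefined) cells."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(self.relative, axis=0)
        excluded = np.isnan(self.relative).sum(axis=0)
        return mean, excluded

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-(replicate, time) table."""
        n_rep, n_t = self.info_a.shape
        rep, tix = np.meshgrid(np.arange(n_rep), np.arange(n_t), indexing="ij")
        return pd.DataFrame(
            {
                "replicate": rep.ravel(),
                "time": np.broadcast_to(self.times, (n_rep, n_t)).ravel(),
                "info_a": self.info_a.ravel(),
                "info_b": self.info_b.ravel(),
                "empirical": self.generalization.ravel(),
                "expected": self.expected.ravel(),
                "min_reference": self.min_reference.ravel(),
                "relative": self.relative.ravel(),
            }
        )


@dataclass
class TemporalGeneralizationMaps:
    """Per-replicate cross-temporal maps, ``(n_replicates, n_times, n_times)``.

    ``difference = empirical - expected_stable`` feeds the one-tailed
    dynamics test (empirical below the perfectly-stable expectation).
    """

    times: np.ndarray
    empirical: np.ndarray
    expected_stable: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.empirical - self.expected_stable


class PatternGeneralizationModel:
    """Cross-context pattern-generalization analysis of a cohort.

    Parameters
    ----------
    trials_a, trials_b : sequence of TrialSet
        Time-resolved trial sets of the two contexts, index-aligned by
        replicate. Channel counts and time axes must agree.
    shrinkage : float
        Diagonal-loading shrinkage of the per-replicate noise covariance
        (pooled over both contexts, all classes and time points).
    """

    def __init__(
        self,
        trials_a: Sequence[TrialSet],
        trials_b: Sequence[TrialSet],
        shrinkage: float = DEFAULT_SHRINKAGE,
    ) -> None:
        if len(trials_a) != len(trials_b) or not trials_a:
            raise ValidationError("need equally many trial sets per context")
        for ta, tb in zip(trials_a, trials_b):
            if not (ta.is_time_resolved and tb.is_time_resolved):
                raise DimensionError("model expects time-resolved trial sets")
            if ta.n_channels != tb.n_channels or ta.n_times != tb.n_times:
                raise DimensionError("contexts disagree on channels or times")
        self.trials_a = list(trials_a)
        self.trials_b = list(trials_b)
        self.shrinkage = shrinkage

    @classmethod
    def from_hdf5(
        cls,
        path: Path | str,
        context_a: str,
        context_b: str,
        shrinkage: float = DEFAULT_SHRINKAGE,
    ) -> "PatternGeneralizationModel":
        """Build the model from a trial-set container file."""
        from .datasets import load_trial_sets

        sets = load_trial_sets(path)
        by_ctx: dict[str, dict[str, TrialSet]] = {}
        for ts in sets:
            by_ctx.setdefault(ts.context_id, {})[ts.replicate_id] = ts
        for ctx in (context_a, context_b):
            if ctx not in by_ctx:
                raise ValidationError(f"context '{ctx}' not found in {path}")
        reps = sorted(set(by_ctx[context_a]) & set(by_ctx[context_b]))
        if not reps:
            raise ValidationError("no replicate holds both contexts")
        return cls(
            [by_ctx[context_a][r] for r in reps],
            [by_ctx[context_b][r] for r in reps],
            shrinkage=shrinkage,
        )

    @property
    def n_replicates(self) -> int:
        return len(self.trials_a)

    def fit(
        self,
        alpha: float = 0.05,
        cluster_alpha: float = 0.05,
        n_permutations: int = 1000,
        temporal: bool = True,
        seed: int = 0,
    ) -> "PatternGeneralizationResults":
        """Run the full pipeline and return the results object.

        ``seed`` drives the fold assignments and the permutation draws;
        a fixed seed makes the fit fully reproducible.
        """
        root = np.random.SeedSequence(seed)
        fold_seq, perm_seq = root.spawn(2)
        fold_rng = np.random.default_rng(fold_seq)
        times = (
            self.trials_a[0].time_axis
            if self.trials_a[0].time_axis is not None
            else np.arange(self.trials_a[0].n_times, dtype=float)
        )
        n_rep = self.n_replicates
        n_t = len(times)
        tc = {
            k: np.empty((n_rep, n_t))
            for k in ("info_a", "info_b", "empirical", "expected",
                      "min_reference", "relative")
        }
        emp_maps = np.empty((n_rep, n_t, n_t)) if temporal else None
        exp_maps = np.empty((n_rep, n_t, n_t)) if temporal else None
        for r, (ta, tb) in enumerate(zip(self.trials_a, self.trials_b)):
            cov = pooled_noise_covariance([ta, tb], shrinkage=self.shrinkage)
            fa = make_folds(ta.labels, fold_rng)
            fb = make_folds(tb.labels, fold_rng)
            res = cross_context_timecourse(ta, tb, cov, fa, fb)
            for k in tc:
                tc[k][r] = res[k]
            if temporal:
                ea, sa = temporal_generalization_matrix(ta, cov, fa)
                eb, sb = temporal_generalization_matrix(tb, cov, fb)
                emp_maps[r] = 0.5 * (ea + eb)
                exp_maps[r] = 0.5 * (sa + sb)
        timecourse = TimecourseResult(
            times=times,
            info_a=tc["info_a"],
            info_b=tc["info_b"],
            generalization=tc["empirical"],
            expected=tc["expected"],
            min_reference=tc["min_reference"],
            relative=tc["relative"],
        )
        perm_rngs = [np.random.default_rng(s) for s in perm_seq.spawn(5)]
        clusters = {
            "info_a": cluster_permutation(
                timecourse.info_a, cluster_alpha, n_permutations, "greater",
                perm_rngs[0],
            ),
            "info_b": cluster_permutation(
                timecourse.info_b, cluster_alpha, n_permutations, "greater",
                perm_rngs[1],
            ),
            "generalization": cluster_permutation(
                timecourse.generalization, cluster_alpha, n_permutations,
                "two-sided", perm_rngs[2],
            ),
            "identity": cluster_permutation(
                timecourse.generalization - timecourse.expected,
                cluster_alpha, n_permutations, "less", perm_rngs[3],
            ),
        }
        maps = None
        if temporal:
            maps = TemporalGeneralizationMaps(
                times=times, empirical=emp_maps, expected_stable=exp_maps
            )
            clusters["dynamics"] = cluster_permutation(
                maps.difference, cluster_alpha, n_permutations, "less",
                perm_rngs[4],
            )
        return PatternGeneralizationResults(
            model=self,
            timecourse=timecourse,
            temporal_maps=maps,
            clusters=clusters,
            alpha=alpha,
            cluster_alpha=cluster_alpha,
            n_permutations=n_permutations,
            seed=seed,
        )


@dataclass
class PatternGeneralizationResults:
    """Estimates, uncertainties and group tests of a fitted analysis."""

    model: PatternGeneralizationModel
    timecourse: TimecourseResult
    temporal_maps: Optional[TemporalGeneralizationMaps]
    clusters: dict
    alpha: float
    cluster_alpha: float
    n_permutations: int
    seed: int

    def window_mask(self, t_lo: float, t_hi: float) -> np.ndarray:
        t = self.timecourse.times
        return (t >= t_lo) & (t < t_hi)

    def window_statistics(self, t_lo: float, t_hi: float) -> dict:
        """Group tests on values averaged over a time window.

        Returns the two-tailed test of generalization vs 0, the one-tailed
        identity test, and the NaN-aware mean relative generalization with
        its excluded-cell count.
        """
        mask = self.window_mask(t_lo, t_hi)
        if not mask.any():
            raise ValidationError("empty time window")
        gen = self.timecourse.generalization[:, mask].mean(axis=1)
        exp = self.timecourse.expected[:, mask].mean(axis=1)
        t0, p0 = one_sample_t(gen, 0.0, "two-sided")
        ti, pi = identity_test(gen, exp)
        rel = self.timecourse.relative[:, mask]
        with np.errstate(invalid="ignore"):
            mean_rel = float(np.nanmean(rel))
        return {
            "t_vs_zero": t0,
            "p_vs_zero": p0,
            "t_identity": ti,
            "p_identity": pi,
            "mean_relative": mean_rel,
            "n_relative_undefined": int(np.isnan(rel).sum()),
            "mean_generalization": float(gen.mean()),
            "mean_expected": float(exp.mean()),
        }

    def _cluster_rows(self) -> pd.DataFrame:
        rows = []
        for name, res in self.clusters.items():
            for i, (mass, p) in enumerate(
                zip(res.cluster_masses, res.cluster_p)
            ):
                extent = res.cluster_extents[i]
                if len(extent) == 1:
                    t_idx = extent[0]
                    span = (
                        self.timecourse.times[t_idx.min()],
                        self.timecourse.times[t_idx.max()],
                    )
                else:
                    span = (
                        self.timecourse.times[extent[0].min()],
                        self.timecourse.times[extent[0].max()],
                    )
                rows.append(
                    {
                        "test": name,
                        "cluster": i,
                        "mass": mass,
                        "p": p,
                        "t_start": span[0],
                        "t_end": span[1],
                        "n_points": len(extent[0]),
                        "significant": p < self.alpha,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        tc = self.timecourse
        mean_rel, excluded = tc.group_relative()
        lines = [
            "Pattern generalization analysis",
            "=" * 47,
            f"replicates: {self.model.n_replicates}"
            f"   time points: {len(tc.times)}"
            f"   permutations: {self.n_permutations}",
            f"alpha: {self.alpha}   cluster alpha: {self.cluster_alpha}"
            f"   seed: {self.seed}",
            "",
            f"peak information (context A): {tc.info_a.mean(axis=0).max():8.3f}",
            f"peak information (context B): {tc.info_b.mean(axis=0).max():8.3f}",
            f"peak generalization:          "
            f"{tc.generalization.mean(axis=0).max():8.3f}",
            f"peak identity expectation:    {tc.expected.mean(axis=0).max():8.3f}",
            f"relative generalization cells excluded (undefined): "
            f"{int(excluded.sum())}",
            "",
            "clusters (mass-based permutation p):",
        ]
        table = self._cluster_rows()
        if table.empty:
            lines.append("  none formed")
        else:
            for _, row in table.iterrows():
                star = " *" if row.significant else ""
                lines.append(
                    f"  {row.test:15s} mass={row['mass']:9.2f} "
                    f"p={row.p:6.4f} span=[{row.t_start:+.3f}, "
                    f"{row.t_end:+.3f}] s{star}"
                )
        return "\n".join(lines)

    def save(self, out_dir: Path | str, seed: Optional[int] = None,
             force: bool = False) -> dict:
        """Write timecourse CSV, cluster CSV and map arrays with a manifest."""
        from .reporting import write_results

        tables = {
            "timecourse": self.timecourse.to_frame(),
            "clusters": self._cluster_rows(),
        }
        arrays = {}
        if self.temporal_maps is not None:
            arrays["empirical_maps"] = self.temporal_maps.empirical
            arrays["expected_stable_maps"] = self.temporal_maps.expected_stable
            arrays["times"] = self.temporal_maps.times
        config = {
            "alpha": self.alpha,
            "cluster_alpha": self.cluster_alpha,
            "n_permutations": self.n_permutations,
            "n_replicates": self.model.n_replicates,
        }
        return write_results(
            out_dir, tables=tables, arrays=arrays, config=config,
            seed=self.seed if seed is None else seed, force=force,
        )
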