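"""Trial-level data containers and HDF5 I/O.

The unit of analysis is a :class:`TrialSet`: all trials of one experimental
context recorded in one replicate (subject, session, or simulated
repetition), as an array of shape ``(n_trials, n_channels)`` or
``(n_trials, n_channels, n_times)`` with a binary class label per trial.

On disk a dataset is a single HDF5 file with one group per
``(replicate, context)`` pair plus a small CSV sidecar summarising the
contents, so a dataset can be inspected without opening the HDF5 file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .exceptions import DimensionError, FoldError, FormatError, ValidationError

__all__ = [
    "TrialSet",
    "make_folds",
    "save_trial_sets",
    "load_trial_sets",
    "sidecar_path",
]


@dataclass
class TrialSet:
    """Labelled multichannel trials for one context and one replicate.

    Parameters
    ----------
    data : ndarray
        ``(n_trials, n_channels)`` or ``(n_trials, n_channels, n_times)``,
        arbitrary signal units. Must be finite.
    labels : ndarray of int
        Per-trial class indicator in ``{1, 2}``. Both classes must appear at
        least twice (two-fold cross-validation needs one trial per class per
        fold).
    context_id, replicate_id : str
        Opaque provenance identifiers.
    time_axis : ndarray, optional
        Time stamps in seconds; required length ``n_times`` when the data are
        time-resolved.
    """

    data: np.ndarray
    labels: np.ndarray
    context_id: str = "ctx"
    replicate_id: str = "rep"
    time_axis: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim not in (2, 3):
            raise DimensionError(
                f"data must be 2-D or 3-D, got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains non-finite values")
        if self.labels.ndim != 1 or len(self.labels) != self.data.shape[0]:
            raise ValidationError(
                "labels must be a vector with one entry per trial"
            )
        classes = np.unique(self.labels)
        if not np.all(np.isin(classes, (1, 2))) or len(classes) != 2:
            raise ValidationError("labels must contain both classes 1 and 2")
        for c in (1, 2):
            if np.sum(self.labels == c) < 2:
                raise ValidationError(
                    f"class {c} needs >= 2 trials for two-fold cross-validation"
                )
        if self.time_axis is not None:
            self.time_axis = np.asarray(self.time_axis, dtype=float)
            if self.data.ndim != 3 or len(self.time_axis) != self.data.shape[2]:
                raise DimensionError(
                    "time_axis length must equal the data's time dimension"
                )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2] if self.data.ndim == 3 else 1

    @property
    def is_time_resolved(self) -> bool:
        return self.data.ndim == 3

    def class_mean_difference(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Class-1-minus-class-2 mean difference, optionally over a trial mask."""
        data = self.data if mask is None else self.data[mask]
        labels = self.labels if mask is None else self.labels[mask]
        if not (np.any(labels == 1) and np.any(labels == 2)):
            raise FoldError("selected trials miss one of the two classes")
        return data[labels == 1].mean(axis=0) - data[labels == 2].mean(axis=0)


def make_folds(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Assign each trial to fold 1 or 2, stratified by class.

    Trials of each class are randomly permuted and split into two halves, so
    both folds contain both classes (sizes differ by at most one for odd
    class counts).
    """
    labels = np.asarray(labels)
    folds = np.empty(len(labels), dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise FoldError(f"class {c} has fewer than 2 trials")
        idx = rng.permutation(idx)
        half = len(idx) // 2
        folds[idx[:half]] = 1
        folds[idx[half:]] = 2
    return folds


def _group_name(ts: TrialSet) -> str:
    return f"replicate-{ts.replicate_id}/context-{ts.context_id}"


def sidecar_path(path: Path | str) -> Path:
    return Path(path).with_suffix(".csv")


def save_trial_sets(
    path: Path | str,
    trial_sets: Sequence[TrialSet],
    write_sidecar: bool = True,
) -> Path:
    """Write trial sets to one HDF5 file plus a CSV sidecar.

    Layout: one group ``replicate-<id>/context-<id>`` per trial set, holding
    datasets ``data`` and ``labels`` (and ``time_axis`` when present).
    """
    path = Path(path)
    rows = []
    with h5py.File(path, "w") as f:
        for ts in trial_sets:
            g = f.create_group(_group_name(ts))
            g.create_dataset("data", data=ts.data)
            g.create_dataset("labels", data=ts.labels)
            if ts.time_axis is not None:
                g.create_dataset("time_axis", data=ts.time_axis)
            g.attrs["replicate_id"] = str(ts.replicate_id)
            g.attrs["context_id"] = str(ts.context_id)
            rows.append(
                {
                    "replicate_id": ts.replicate_id,
                    "context_id": ts.context_id,
                    "n_trials": ts.n_trials,
                    "n_channels": ts.n_channels,
                    "n_times": ts.n_times,
                }
            )
    if write_sidecar:
        pd.DataFrame(rows).to_csv(sidecar_path(path), index=False)
    return path


def load_trial_sets(path: Path | str) -> list[TrialSet]:
    """Load every trial set stored in an HDF5 dataset container."""
    path = Path(path)
    out: list[TrialSet] = []
    with h5py.File(path, "r") as f:
        for rep_name in sorted(f.keys()):
            rep = f[rep_name]
            if not isinstance(rep, h5py.Group):
                raise FormatError(f"unexpected top-level dataset '{rep_name}'")
            for ctx_name in sorted(rep.keys()):
                g = rep[ctx_name]
                for req in ("data", "labels"):
                    if req not in g:
                        raise FormatError(
                            f"group '{rep_name}/{ctx_name}' misses '{req}'"
                        )
                time_axis = g["time_axis"][()] if "time_axis" in g else None
                out.append(
                    TrialSet(
                        data=g["data"][()],
                        labels=g["labels"][()],
                        replicate_id=str(g.attrs.get("replicate_id", rep_name)),
                        context_id=str(g.attrs.get("context_id", ctx_name)),
                        time_axis=time_axis,
                    )
                )
    return out


def dataclass_asdict(obj) -> dict:
    """`dataclasses.asdict` that tolerates numpy scalars (for manifests)."""
    def convert(v):
        if isinstance(v, np.generic):
            return v.item()
        return v

    return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
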