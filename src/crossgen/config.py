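"""YAML run configuration with strict validation.

A configuration document holds a global ``seed``, ``out_dir`` and
``log_level`` plus per-command parameter blocks (``mixing``, ``forward``,
``analysis``). Every numeric field is validated against its module's
invariants before any computation, unknown keys are rejected by name, and
the effective configuration (defaults filled in) can be echoed into the
output directory so a run is reproducible from its artefacts alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .mixing import MixingSimConfig

__all__ = [
    "ForwardSimConfig",
    "AnalysisConfig",
    "RunConfig",
    "load_config",
    "write_effective_config",
]


@dataclass
class ForwardSimConfig:
    """Settings of the leadfield false-positive-rate grid."""

    n_subjects: int = 19
    n_sources: int = 600
    n_sensors: int = 272
    n_areas: int = 30
    smoothness_mm: float = 40.0
    n_selective: int = 10
    n_trials: int = 1000
    target_ms: tuple = (0.0156, 0.25, 4.0)
    n_runs: int = 100
    alpha: float = 0.05
    shrinkage: float = 0.05

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_sources", "n_sensors", "n_areas",
                     "n_selective", "n_trials", "n_runs"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"'{name}' must be a positive count")
        if self.n_subjects < 2:
            raise ConfigError("'n_subjects' must be >= 2")
        if self.n_areas < 2:
            raise ConfigError("'n_areas' must be >= 2")
        if self.smoothness_mm <= 0:
            raise ConfigError("'smoothness_mm' must be > 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("'alpha' must lie in (0, 1)")
        if not (0 <= self.shrinkage <= 1):
            raise ConfigError("'shrinkage' must lie in [0, 1]")
        self.target_ms = tuple(float(m) for m in self.target_ms)
        if any(m < 0 for m in self.target_ms):
            raise ConfigError("'target_ms' entries must be >= 0")


@dataclass
class AnalysisConfig:
    """Settings of the time-resolved analysis pipeline."""

    context_a: str = "A"
    context_b: str = "B"
    shrinkage: float = 0.05
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    temporal: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "cluster_alpha"):
            if not (0 < getattr(self, name) < 1):
                raise ConfigError(f"'{name}' must lie in (0, 1)")
        if not (0 <= self.shrinkage <= 1):
            raise ConfigError("'shrinkage' must lie in [0, 1]")
        if self.n_permutations < 1:
            raise ConfigError("'n_permutations' must be >= 1")


@dataclass
class RunConfig:
    """Validated global configuration with per-command blocks."""

    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    mixing: MixingSimConfig = field(default_factory=MixingSimConfig)
    forward: ForwardSimConfig = field(default_factory=ForwardSimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.log_level not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError("'log_level' must be DEBUG/INFO/WARNING/ERROR")


def _build(cls, doc: dict, block: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - fields
    if unknown:
        raise ConfigError(
            f"unknown key '{sorted(unknown)[0]}' in block '{block}'"
        )
    try:
        return cls(**doc)
    except ConfigError:
        raise
    except Exception as exc:  # module ValidationError -> named ConfigError
        raise ConfigError(f"invalid value in block '{block}': {exc}") from exc


def load_config(path: Path | str | None = None, overrides: dict | None = None
                ) -> RunConfig:
    """Load and validate a YAML configuration.

    An empty (or absent) document yields the all-defaults configuration.
    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending key. ``overrides`` is a nested dict merged on top of the
    document (used by CLI flags).
    """
    doc: dict = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config parse error: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config document must be a mapping")
        doc = loaded
    for key, sub in (overrides or {}).items():
        if isinstance(sub, dict):
            doc.setdefault(key, {})
            if not isinstance(doc[key], dict):
                raise ConfigError(f"block '{key}' must be a mapping")
            doc[key].update({k: v for k, v in sub.items() if v is not None})
        elif sub is not None:
            doc[key] = sub

    top_keys = {"seed", "out_dir", "log_level", "mixing", "forward", "analysis"}
    unknown = set(doc) - top_keys
    if unknown:
        raise ConfigError(f"unknown key '{sorted(unknown)[0]}'")
    for block in ("mixing", "forward", "analysis"):
        if block in doc and not isinstance(doc[block], dict):
            raise ConfigError(f"block '{block}' must be a mapping")
    mixing = _build(MixingSimConfig, doc.get("mixing", {}), "mixing")
    forward = _build(ForwardSimConfig, doc.get("forward", {}), "forward")
    analysis = _build(AnalysisConfig, doc.get("analysis", {}), "analysis")
    return RunConfig(
        seed=int(doc.get("seed", 0)),
        out_dir=str(doc.get("out_dir", "results")),
        log_level=str(doc.get("log_level", "INFO")),
        mixing=mixing,
        forward=forward,
        analysis=analysis,
    )


def config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["forward"]["target_ms"] = list(d["forward"]["target_ms"])
    return d


def write_effective_config(cfg: RunConfig, out_dir: Path | str) -> Path:
    """Echo the effective (defaults-filled) configuration as YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "effective_config.yaml"
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
    return path
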