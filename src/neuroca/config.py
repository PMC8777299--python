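"""Experiment configuration: YAML schema, validation and round-tripping.

A config file has up to four sections (all optional; omitted keys take the
documented defaults):

.. code-block:: yaml

    lattice:
      rows: 128        # >= 3
      cols: 128        # >= 3
      n_layers: 1
      boundary: toroidal          # or spherical
      neighborhood: totalistic    # or outer_totalistic
      ext_fraction: 0.0           # clamped-cell fraction in [0, 1]
      ext_value: 1.0
      seed: 0
      timesteps: 100
    activation:
      order: linear    # or nonlinear (then a1 is fixed at 1)
      a0: 0.2
      a1: 0.6
      a2: 0.8
      b: 1.0
    analysis:
      tol_zero: 1.0e-4   # quiescence threshold on the steady state
      t_fast: 10         # fast/slow decay cutoff (timesteps)
      osc_amp: 1.0e-3    # minimum period-2 amplitude
      corr_length: 5.0   # 1a/1b coherence cutoff (cells)
      seeds: [0, 1, 2]
    output:
      outdir: results
      snapshot_times: [10]

Unknown keys are rejected by name.  Configs round-trip losslessly through
:func:`save_config` / :func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .activation import ActivationParams
from .lattice import ConfigError, LatticeConfig

__all__ = [
    "AnalysisSettings",
    "OutputSettings",
    "ExperimentConfig",
    "from_dict",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass(frozen=True)
class AnalysisSettings:
    tol_zero: float = 1e-4
    t_fast: int = 10
    osc_amp: float = 1e-3
    corr_length: float = 5.0
    seeds: tuple = (0, 1, 2)

    def __post_init__(self):
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))
        if self.tol_zero <= 0 or self.osc_amp <= 0:
            raise ConfigError("tolerances must be positive")


@dataclass(frozen=True)
class OutputSettings:
    outdir: str = "results"
    snapshot_times: tuple = (10,)

    def __post_init__(self):
        object.__setattr__(
            self, "snapshot_times", tuple(int(t) for t in self.snapshot_times)
        )


@dataclass(frozen=True)
class ExperimentConfig:
    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    activation: ActivationParams = field(default_factory=lambda: ActivationParams.linear(0.2, 0.6, 0.8))
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    output: OutputSettings = field(default_factory=OutputSettings)

    def to_dict(self) -> dict:
        return {
            "lattice": dataclasses.asdict(self.lattice),
            "activation": dataclasses.asdict(self.activation),
            "analysis": {
                **dataclasses.asdict(self.analysis),
                "seeds": list(self.analysis.seeds),
            },
            "output": {
                "outdir": self.output.outdir,
                "snapshot_times": list(self.output.snapshot_times),
            },
        }


_SECTIONS = {
    "lattice": LatticeConfig,
    "activation": ActivationParams,
    "analysis": AnalysisSettings,
    "output": OutputSettings,
}


def _build_section(name: str, cls, data: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key {sorted(unknown)[0]!r} in section {name!r}"
        )
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def from_dict(data: dict) -> ExperimentConfig:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section {sorted(unknown)[0]!r}")
    kw = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kw[name] = _build_section(name, cls, section)
    return ExperimentConfig(**kw)


def load_config(path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return from_dict(data)


def save_config(cfg: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable sha256 of the canonical YAML form (for run logs)."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
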