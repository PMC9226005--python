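"""Run configuration: YAML loading, validation, seed derivation.

A run configuration groups the per-stage configuration blocks under the
keys ``simulation``, ``pipeline``, ``negative`` and ``model``, plus a
global ``seed``, ``log_level`` and ``outdir``. Unknown keys are rejected
with a suggestion; an empty file yields all published defaults. The
global seed deterministically derives one sub-seed per stage (CRC32 of
the stage name mixed into the seed, modulo 2^31) so stages can be rerun
independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import difflib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chimera import PipelineConfig
from .dataset import NegativeConfig
from .errors import ConfigurationError, ParameterError
from .model import ModelConfig
from .simulate import SimulationConfig

_SECTIONS = {
    "simulation": SimulationConfig,
    "pipeline": PipelineConfig,
    "negative": NegativeConfig,
    "model": ModelConfig,
}
_GLOBALS = {"seed", "log_level", "outdir"}


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed = (global_seed * 1000003 + crc32(stage)) mod 2^31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    negative: NegativeConfig = field(default_factory=NegativeConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0
    log_level: str = "INFO"
    outdir: str = "isomirnet-run"

    def with_derived_seeds(self) -> "RunConfig":
        """Copy with each stage's seed derived from the global seed."""
        return dataclasses.replace(
            self,
            simulation=dataclasses.replace(
                self.simulation, seed=derive_seed(self.seed, "simulation")),
            negative=dataclasses.replace(
                self.negative, rng_seed=derive_seed(self.seed, "negative")),
            model=dataclasses.replace(
                self.model, seed=derive_seed(self.seed, "model")),
        )


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            hint = difflib.get_close_matches(key, sorted(valid), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigurationError(
                f"unknown key {section}.{key!r}{suggestion}"
            )
    try:
        return cls(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        })
    except (TypeError, ParameterError) as exc:
        raise ConfigurationError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; an empty/missing body means defaults."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigurationError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        elif key in _GLOBALS:
            kwargs[key] = value
        else:
            pool = sorted(_SECTIONS) + sorted(_GLOBALS)
            hint = difflib.get_close_matches(key, pool, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigurationError(f"unknown key {key!r}{suggestion}")
    cfg = RunConfig(**kwargs)
    if not isinstance(cfg.seed, int) or cfg.seed < 0:
        raise ConfigurationError("seed must be a non-negative integer")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
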