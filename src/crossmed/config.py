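"""Study configuration (YAML) and tabular output helpers."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .popgen import ConfigurationError, ScenarioSpec
from .sampler import SamplingDesign, SamplingMethod

__all__ = ["StudyConfig", "load_config", "save_config", "write_summary"]

_KNOWN_KEYS = {
    "scenarios", "methods", "strategies", "N", "n", "R", "seed",
    "link", "output_dir",
}
_KNOWN_STRATEGIES = {"NEITHER", "FIRST_ONLY", "SECOND_ONLY", "BOTH"}
_KNOWN_METHODS = {m.name for m in SamplingMethod}


@dataclass(frozen=True)
class StudyConfig:
    """Validated configuration for a full or partial simulation study."""

    scenarios: tuple[int, ...] = tuple(range(1, 9))
    methods: tuple[str, ...] = ("COV", "COV_MED", "COV_TRT", "SRS")
    strategies: tuple[str, ...] = ("NEITHER", "FIRST_ONLY", "SECOND_ONLY", "BOTH")
    N: int = 90_000
    n: int = 9_000
    R: int = 1000
    seed: int = 0
    link: str = "logistic"
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ConfigurationError("scenarios must be nonempty")
        bad = [s for s in self.scenarios if s not in range(1, 9)]
        if bad:
            raise ConfigurationError(f"unknown scenarios {bad}; valid ids are 1..8")
        bad = [m for m in self.methods if m not in _KNOWN_METHODS]
        if bad:
            raise ConfigurationError(f"unknown sampling methods {bad}")
        bad = [s for s in self.strategies if s not in _KNOWN_STRATEGIES]
        if bad:
            raise ConfigurationError(f"unknown strategies {bad}")
        if self.n > self.N:
            raise ConfigurationError(f"sample size n={self.n} exceeds population N={self.N}")
        if self.N < 3 or self.n < 2:
            raise ConfigurationError("N must be >= 3 and n >= 2")
        if self.R < 2:
            raise ConfigurationError("R must be >= 2")
        # Fail fast: every requested scenario must have a feasible mediator law.
        for sid in self.scenarios:
            ScenarioSpec.default(sid)

    def sampling_design(self, method: str) -> SamplingDesign:
        return SamplingDesign.default(SamplingMethod[method], self.n)


def load_config(path) -> StudyConfig:
    """Load and validate a YAML study configuration.

    Unknown keys are rejected (a typo should fail loudly, not silently
    fall back to a default).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; known keys {sorted(_KNOWN_KEYS)}"
        )
    for key in ("scenarios", "methods", "strategies"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        return StudyConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from None


def save_config(config: StudyConfig, path) -> None:
    data = asdict(config)
    for key in ("scenarios", "methods", "strategies"):
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_summary(rows: pd.DataFrame, path) -> None:
    """Write a summary table as CSV with stable order and float format.

    Floats are rendered with 12 significant digits so that identical
    runs yield byte-identical files.
    """
    if len(rows) == 0:
        raise ValueError("refusing to write an empty summary")
    rows.to_csv(path, index=False, float_format="%.12g")
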