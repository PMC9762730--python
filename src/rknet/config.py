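"""Declarative run configuration shared by the CLI and the pipeline.

A config file is YAML with optional ``windowing``, ``extractor``,
``clustering``, ``mapping`` and ``output`` sections; every key has a default
so an empty file is a valid config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    # windowing
    window_center: float = 40.0
    window_width: float = 400.0
    # extractor
    extractor_name: str = "reference"
    input_size: Tuple[int, int] = (64, 64)
    normalize_features: bool = True
    # clustering
    k: int = 2
    init_method: str = "k-means++"
    n_restarts: int = 10
    max_iter: int = 300
    tol: float = 1e-6
    scope: str = "per-series"  # or "pooled"
    # mapping
    rule: str = "foreground-mass"
    min_centroid_separation: float = 1.0  # flag low-contrast series below this
    # run
    seed: int = 0

    def __post_init__(self):
        if self.scope not in ("per-series", "pooled"):
            raise ConfigError(f"scope must be per-series or pooled, got {self.scope!r}")
        if self.rule not in ("foreground-mass", "exemplar", "majority-size"):
            raise ConfigError(f"unknown mapping rule {self.rule!r}")
        if self.window_width <= 0:
            raise ConfigError("window_width must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d


_SECTION_KEYS = {
    "windowing": {"window_center", "window_width"},
    "extractor": {"extractor_name", "input_size", "normalize_features"},
    "clustering": {"k", "init_method", "n_restarts", "max_iter", "tol", "scope"},
    "mapping": {"rule", "min_centroid_separation"},
    "output": set(),
}


def load_config(path: Optional[str] = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        for section, keys in _SECTION_KEYS.items():
            sub = raw.pop(section, {}) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"config section {section!r} is not a mapping")
            for key, val in sub.items():
                if keys and key not in keys:
                    raise ConfigError(f"unknown key {key!r} in section {section!r}")
                values[key] = val
        values.update(raw)  # top-level keys such as seed
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "input_size" in values:
        values["input_size"] = tuple(values["input_size"])
    try:
        return PipelineConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
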