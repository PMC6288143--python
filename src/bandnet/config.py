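"""Run configuration: a flat, losslessly serializable record of every
knob a pipeline run uses, logged verbatim (with a content hash) so runs
are reproducible from their logs."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # bands: name -> [f_low_hz, f_high_hz]
    bands: dict[str, list[float]] = field(
        default_factory=lambda: {
            "low": [0.01, 0.06],
            "intermediate": [0.06, 0.15],
            "high": [0.15, 0.20],
        }
    )
    threshold_mode: str = "density"  # "absolute" | "density"
    threshold_value: float | None = None
    density: float = 0.15
    normalize: bool = True
    include_full: bool = True
    # graph-metric options
    n_random: int = 20
    n_perm: int = 999
    hub_k: int | None = None
    delta: float | None = None
    # classification options
    kernel_depth: int = 2
    weights_mode: str = "select"
    grid_step: float = 0.25
    n_folds: int = 10
    regularization_C: float = 1.0
    classifier: str = "kelm"
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
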