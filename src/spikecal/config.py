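"""Run configuration: one serializable object holding every tunable.

Defaults are defined here, once; the YAML round-trip (write -> read) is
exact for any configuration built from plain numbers and strings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .simulate import SimConfig, TrackShape


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    track_shape: TrackShape = field(default_factory=TrackShape)
    # thresholds
    padj_threshold: float = 0.05
    fold_threshold: float = 1.4
    correlation_gate: float = 0.95
    # windows (bp)
    promoter_window: int = 1000          # gene classification, TSS +/- window
    pausing_promoter: tuple[int, int] = (-30, 300)
    flank_bp: int = 500
    profile_bin_bp: int = 10
    pseudocount: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.track_shape, dict):
            self.track_shape = TrackShape(**self.track_shape)
        self.pausing_promoter = tuple(self.pausing_promoter)  # type: ignore[assignment]
        if not (0 < self.padj_threshold < 1):
            raise ValidationError("padj_threshold must be in (0, 1)")
        if self.fold_threshold < 1:
            raise ValidationError("fold_threshold must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pausing_promoter"] = list(self.pausing_promoter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ValidationError(f"config file not found: {path}")
        with open(p) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @property
    def digest(self) -> str:
        """Stable hash of the full configuration (stamped on outputs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
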