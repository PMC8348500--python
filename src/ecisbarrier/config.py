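"""Run configuration: protocol, electrode, presets and analysis settings.

A structured YAML config file drives the CLI; flags override file values.
The configuration hash plus the seed fully determine every output of a run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ElectrodeModel
from .pipeline import CAPACITANCE_READOUT_HZ, RESISTANCE_READOUT_HZ
from .synthetic import DEFAULT_ELECTRODE, PRESET_NAMES, AcquisitionProtocol

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated settings for a simulate → fit → analyze → report run."""

    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    electrode: ElectrodeModel = DEFAULT_ELECTRODE
    presets: tuple = PRESET_NAMES
    resistance_readout_hz: float = RESISTANCE_READOUT_HZ
    capacitance_readout_hz: float = CAPACITANCE_READOUT_HZ
    auc_interval: tuple = (0.0, 100.0)
    midpoint_h: float = 24.0
    seed: int = 0
    noise: bool = True
    output_dir: str = "ecis_run"

    def __post_init__(self) -> None:
        grid = self.protocol.frequency_grid
        for f in (self.resistance_readout_hz, self.capacitance_readout_hz):
            if not any(abs(f - g) < 1e-9 for g in grid):
                raise ValueError(f"readout frequency {f} Hz not in protocol grid {grid}")
        t0, t1 = self.auc_interval
        if not (0.0 <= t0 < t1 <= self.protocol.post_treatment_h):
            raise ValueError("AUC interval must lie within the post-treatment window")
        if not 0.0 <= self.midpoint_h <= self.protocol.post_treatment_h:
            raise ValueError("midpoint must lie within the post-treatment window")
        unknown = [p for p in self.presets if p not in PRESET_NAMES]
        if unknown:
            raise ValueError(f"unknown presets {unknown}; valid: {PRESET_NAMES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "protocol" in kwargs:
            kwargs["protocol"] = AcquisitionProtocol(**kwargs["protocol"])
        if "electrode" in kwargs:
            kwargs["electrode"] = ElectrodeModel(**kwargs["electrode"])
        if "presets" in kwargs:
            kwargs["presets"] = tuple(kwargs["presets"])
        if "auc_interval" in kwargs:
            kwargs["auc_interval"] = tuple(kwargs["auc_interval"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["electrode"] = asdict(self.electrode)
        d["protocol"] = asdict(self.protocol)
        return d

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON form (excludes nothing)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
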