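"""Run configuration: every tunable of the pipeline with its default.

Defaults follow the algorithm's stated operating point: 10-s epochs
(0.1 Hz, the device's highest proximity rate), RSSI anchors −45/−90 dBm,
anti-hopping run length 2 samples (20 s), transition window ±1 epoch.
Every field can be overridden from a YAML mapping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    epoch_s: float = 10.0
    model_id: str = "model3"
    corridor_weight: float = 1.0  # model 3's w
    step_threshold: int = 2
    min_run: int = 2  # anti-hopping stability, samples
    transition_window: int = 1  # epochs flagged each side of a change
    rssi_near_dbm: float = -45.0
    rssi_cutoff_dbm: float = -90.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, source: str | Path | None, **overrides) -> "RunConfig":
        data: dict = {}
        if source is not None:
            text = Path(source).read_text() if Path(str(source)).exists() else str(source)
            loaded = yaml.safe_load(text) or {}
            if not isinstance(loaded, dict):
                raise ValueError("run config must be a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(**data)

    def motion_model(self):
        from .motion import MotionModel

        return MotionModel(
            model_id=self.model_id,
            corridor_weight=self.corridor_weight,
            step_threshold=self.step_threshold,
        )
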