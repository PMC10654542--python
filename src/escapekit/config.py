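"""Pipeline configuration with JSON round-trip and a stable content hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["PipelineConfig", "stage_seed", "STAGE_OFFSETS"]

#: child-seed counter scheme: stage seed = base seed * 1000 + offset
STAGE_OFFSETS = {
    "generate": 1,
    "simulate": 2,
    "extract": 3,
    "detect": 4,
    "analyze": 5,
}


def stage_seed(base_seed: int, stage: str) -> int:
    return base_seed * 1000 + STAGE_OFFSETS[stage]


@dataclass
class PipelineConfig:
    """Geometry constants, condition maps, thresholds and cohort sizing."""

    fruit_position: float = 2.5
    shelter_position: float = -2.5
    participant_speed: float = -2.0  # signed toward the shelter
    tti_map: dict = field(default_factory=lambda: {"short": 1.5, "long": 5.0})
    contact_radius: float = 0.4
    door_block_radius: float = 1.0
    shelter_radius: float = 0.5
    initiation_radius: float = 0.5
    min_outward: float = 0.3
    smooth_window: float = 0.1
    appear_window: float = 1.5
    min_epoch_duration: float = 12.5
    dt: float = 1.0 / 90.0
    n_subjects: int = 10
    epochs_per_cell: int = 1
    detector_max_miss: float = 0.05
    detector_n_volume: int = 20
    detector_reps: int = 100
    n_audio_clips: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "contact_radius",
            "door_block_radius",
            "shelter_radius",
            "initiation_radius",
            "dt",
            "appear_window",
            "min_epoch_duration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fruit_position == self.shelter_position:
            raise ValueError("fruit and shelter positions must differ")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
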