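"""Analysis configuration: defaults, file loading, strict validation.

Every effective value is echoed into the run summary so that a run is
fully replayable from its own output.  Unknown keys are rejected rather
than ignored -- a typo in a config file must not silently fall back to
a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from .errors import InputError


@dataclass
class AnalysisConfig:
    """Complete parameter set for one analysis run.

    Units: window/neighborhood in mm, pixel spacing in mm/px, frame
    rate in Hz.  ``pixel_spacing_mm`` and ``frame_rate_hz`` act as
    overrides for containers without calibration metadata (raw stacks,
    frame directories); for DICOM/video they take precedence over tags.
    """

    input: str = ""
    roi: str = ""
    lesion_mask: str | None = None
    out_prefix: str | None = None

    n_frames: int = 70
    frame_rate_hz: float | None = None
    pixel_spacing_mm: tuple[float, float] | None = None
    window_mm: float = 2.0
    neighborhood_mm: float = 2.0

    motion: bool = True
    search_radius_px: int = 8
    subpixel: bool = False

    palette: str = "blue_red"
    alpha: float = 0.5
    display_min_level: int = 32

    level_threshold: int = 32
    min_fraction: float = 0.05
    min_component_px: int = 25

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise InputError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0.0 <= self.alpha <= 1.0:
            raise InputError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0 <= self.display_min_level <= 255:
            raise InputError("display_min_level must lie in 0-255")
        if not 0 <= self.level_threshold <= 255:
            raise InputError("level_threshold must lie in 0-255")
        if self.window_mm <= 0 or self.neighborhood_mm <= 0:
            raise InputError("window_mm and neighborhood_mm must be > 0")
        if self.pixel_spacing_mm is not None:
            self.pixel_spacing_mm = (float(self.pixel_spacing_mm[0]),
                                     float(self.pixel_spacing_mm[1]))

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any], **overrides: Any) -> "AnalysisConfig":
        unknown = set(data) - cls.field_names()
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        merged = {**data, **{k: v for k, v in overrides.items() if v is not None}}
        return cls(**merged)

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "AnalysisConfig":
        path = Path(path)
        if not path.exists():
            raise InputError(f"no such config file: {path}")
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            import json

            data = json.loads(text)
        if not isinstance(data, Mapping):
            raise InputError(f"{path}: config must be a mapping")
        return cls.from_mapping(data, **overrides)

    def to_json_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if d["pixel_spacing_mm"] is not None:
            d["pixel_spacing_mm"] = list(d["pixel_spacing_mm"])
        return d
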