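"""Analysis configuration: every threshold of the pipeline in one record.

Defaults are the study's printed values; everything is overridable and the
configuration (with its hash and seed) is echoed into every output so runs
are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class AnalysisConfig:
    # spatial maps
    bin_size_cm: float = 16.0
    visit_min: int = 5
    n_shifts_place: int = 1000
    display_clip_percentile: float = 97.0
    landmark_radius_cm: float = 10.0
    # triggered averages
    sta_half_window_s: float = 4.0
    n_shifts_sta: int = 100
    min_shift_s: float = 30.0
    speed_floor_cm_s: float = 0.5
    min_spikes: int = 10
    # EOD processing
    blank_half_window_s: float = 2.8e-3
    grid_dt_s: float = 1.0 / 15.0
    down_threshold_hz: float = 50.0
    down_min_duration_s: float = 1.0
    # kinematics
    speed_threshold_cm_s: float = 1.0
    speed_smooth_frames: int = 1
    # egocentric
    egocentric_downsample: int = 20
    egocentric_window_cm: float = 10.0
    ptlm_exclusion_percentile: float = 10.0
    body_length_cm: float = 15.0
    raster_block_px: int = 10
    # randomness
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
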