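"""Pipeline-wide configuration with acquisition-matched defaults.

Defaults encode the analysis settings the pipeline was designed around:
70 nm/pixel sampling with a 0.5 μm z-step, the 60-pixel strict overlap rule
for synaptic pairing, the 0.335 μm apparent-diameter background cutoff, and
the 0.1 μm / 3 μm / 0.25 μm spine and dendrite acceptance thresholds.  Every
run serializes its effective configuration alongside its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imgproc import PreprocessConfig
from .puncta import DetectionConfig, PairingConfig
from .spines import SpineFilter

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.07
    z_step_um: float = 0.5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    spine_filter: SpineFilter = field(default_factory=SpineFilter)
    prune_length_um: float = 2.0
    stats_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        # keep the shared pixel size consistent across sub-configs
        self.detection.pixel_size_um = self.pixel_size_um
        self.pairing.pixel_size_um = self.pixel_size_um

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        # inf does not survive YAML round-trips portably
        if d["detection"]["snr_min"] == float("inf"):
            d["detection"]["snr_min"] = "inf"
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        det = dict(d.get("detection", {}))
        if det.get("snr_min") == "inf":
            det["snr_min"] = float("inf")
        kwargs = {
            k: d[k]
            for k in ("pixel_size_um", "z_step_um", "prune_length_um",
                      "stats_alpha", "seed")
            if k in d
        }
        return cls(
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            detection=DetectionConfig(**det),
            pairing=PairingConfig(**d.get("pairing", {})),
            spine_filter=SpineFilter(**d.get("spine_filter", {})),
            **kwargs,
        )
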