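"""Run configuration: one structured TOML file drives the pipelines.

Every analysis threshold is a configurable default, never a hard-coded
constant; outputs echo the thresholds and a config hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .imu import ImuDialect
from .segmentation import SegmentationParams
from .vision import DEFAULT_SKIN_AB, MirrorModel


@dataclass
class RunConfig:
    """Aggregated configuration of the trial/cohort pipelines."""

    dialect: ImuDialect = field(default_factory=ImuDialect)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    mirror: MirrorModel = field(default_factory=MirrorModel)
    speed_channel: str = "rotational"
    unit_threshold: float | None = None
    reference_skin_ab: tuple[float, float] = DEFAULT_SKIN_AB
    kmeans_restarts: int = 10
    min_component_px: int = 25
    pano_shape: tuple[int, int] = (140, 360)
    seed: int = 0

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (tuple, list)):
                return [conv(v) for v in x]
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x
        return {k: conv(getattr(self, k))
                for k in (f.name for f in dataclasses.fields(self))}

    def hash(self) -> str:
        """Short stable digest of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kwargs = {}
        if "dialect" in raw:
            kwargs["dialect"] = ImuDialect(**raw["dialect"])
        if "segmentation" in raw:
            kwargs["segmentation"] = SegmentationParams(**raw["segmentation"])
        if "mirror" in raw:
            m = dict(raw["mirror"])
            for key in ("center_px",):
                if key in m:
                    m[key] = tuple(m[key])
            if "calibration_table" in m:
                m["calibration_table"] = np.asarray(m["calibration_table"], float)
            kwargs["mirror"] = MirrorModel(**m)
        for key in ("speed_channel", "unit_threshold", "kmeans_restarts",
                    "min_component_px", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "reference_skin_ab" in raw:
            kwargs["reference_skin_ab"] = tuple(raw["reference_skin_ab"])
        if "pano_shape" in raw:
            kwargs["pano_shape"] = tuple(raw["pano_shape"])
        return cls(**kwargs)


def load_config(path=None) -> RunConfig:
    """Load a TOML run configuration, or the defaults when path is None."""
    if path is None:
        return RunConfig()
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    return RunConfig.from_toml(p)
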