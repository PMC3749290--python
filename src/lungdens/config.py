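"""Pipeline configuration: defaults, YAML round-trip, precedence handling.

Every default here equals the corresponding module-level default, so an
empty config reproduces library behaviour exactly.  Precedence at the CLI is
flag > config file > built-in default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .ct_io import DEFAULT_CALIBRATION_TOLERANCE_HU
from .densitometry import EMPHYSEMA_THRESHOLD_HU
from .segmentation import SegmentationParams
from .synthetic import CohortSpec, CystSpec, Fev1Link, PhantomSpec

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "lungdens_out"
    emphysema_threshold_hu: float = EMPHYSEMA_THRESHOLD_HU
    calibration_tolerance_hu: float = DEFAULT_CALIBRATION_TOLERANCE_HU
    alpha: float = 0.05
    log_level: str = "INFO"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        d.pop("schema_version", None)
        seg = d.pop("segmentation", {}) or {}
        if seg.get("trachea_seed") is not None:
            seg["trachea_seed"] = tuple(seg["trachea_seed"])
        ph = d.pop("phantom", {}) or {}
        for key in ("grid_shape", "spacing", "body_semiaxes", "lung_semiaxes", "lung_center_cols"):
            if key in ph and ph[key] is not None:
                ph[key] = tuple(ph[key])
        ph["cysts"] = tuple(
            CystSpec(**{**c, "center_frac": tuple(c["center_frac"])})
            for c in (ph.get("cysts") or ())
        )
        co = d.pop("cohort", {}) or {}
        for key in ("age_range_cf", "age_range_control"):
            if key in co and co[key] is not None:
                co[key] = tuple(co[key])
        if "fev1_link" in co and isinstance(co["fev1_link"], dict):
            co["fev1_link"] = Fev1Link(**co["fev1_link"])
        return cls(
            segmentation=SegmentationParams(**seg),
            phantom=PhantomSpec(**ph),
            cohort=CohortSpec(**co),
            **d,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _plain(obj: Any) -> Any:
    """Convert tuples (and nested structures) to YAML-safe plain types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
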