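"""Pipeline configuration: one nested, strictly-validated model.

Unknown keys are rejected so a typo in a config file fails loudly rather
than silently running with defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SegmentationConfig(_Strict):
    scales_px: tuple[float, ...] = (1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0)
    presmooth_sigma_px: float = 1.0
    image_blend_weight: float = 0.5
    use_enhanced: bool = True
    method: str = "global-otsu"
    fixed_threshold: float | None = None
    quantile: float | None = None
    min_component_px: int = 30
    fill_holes_px: int = 20


class GraphConfig(_Strict):
    prune_spur_um: float = 10.0
    caliber_threshold_um: float = 20.0
    bifurcation_caliber_frac: float = 0.25
    min_bifurcations_for_ks: int = 5


class RegionConfig(_Strict):
    foveal_diameter_mm: float = 1.0
    parafoveal_outer_diameter_mm: float = 3.0
    faz_search_diameter_mm: float = 1.5


class GEEConfig(_Strict):
    working_correlation: str = "exchangeable"  # or "independence" sensitivity run
    adherence_definition: str = "mean"          # "mean" (≥4 hr/night) or "nightly" (≥4 hr on ≥80% nights)
    min_clusters: int = 10


class PipelineConfig(_Strict):
    fov_mm: float = 3.0
    segmentation: SegmentationConfig = SegmentationConfig()
    graph: GraphConfig = GraphConfig()
    regions: RegionConfig = RegionConfig()
    gee: GEEConfig = GEEConfig()
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    def config_hash(self) -> str:
        """Stable short hash embedded in outputs for provenance."""
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
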