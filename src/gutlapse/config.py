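"""Run-level configuration shared across pipeline stages.

Physical scales default to the imaging geometry the pipeline assumes:
hourly multi-channel z-stacks with a 3 µm z-step. Every analysis default
lives here so that a run can be reproduced from its echoed config alone.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class AnalysisConfig:
    """All tunable knobs of the analysis pipeline, with units.

    Attributes
    ----------
    pixel_size : float
        Lateral pixel size in µm/px.
    z_step : float
        Axial step between z-slices in µm (default 3).
    frame_interval : float
        Time between frames in hours (default 1).
    link_radius_um : float
        Maximum mother-to-daughter distance for parentless lineage linking.
    roi_size, overlap, max_shift : int
        Registration ROI tiling and search window, in pixels.
    min_area_px : int
        Smallest connected component kept in the dual-channel overlap mask.
    background_window_um : float
        Side of the square window used for local-median background.
    min_quiescence_h : float
        Hours a non-dividing sister must be observed after its sibling's
        division to call the pair non-co-dividing.
    tilt_max_deg, neighborhood_radius_um : float
        Epithelium flatness test: maximum fitted plane tilt and the radius
        within which neighbor nuclei are collected.
    area_fold_min, gfp_fold_max : float
        Differentiation call: minimum nuclear-area fold change and maximum
        GFP fold change between the reference and comparison frames.
    seed : int
        Seed for every stochastic step in a run.
    """

    pixel_size: float = 0.5
    z_step: float = 3.0
    frame_interval: float = 1.0
    link_radius_um: float = 10.0
    roi_size: int = 256
    overlap: int = 64
    max_shift: int = 20
    min_area_px: int = 20
    background_window_um: float = 50.0
    min_quiescence_h: float = 6.0
    tilt_max_deg: float = 10.0
    neighborhood_radius_um: float = 30.0
    area_fold_min: float = 1.5
    gfp_fold_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "z_step", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**data)
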