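"""Patient-case container: one prostate boundary plus labelled target ROIs."""

from __future__ import annotations

import dataclasses
from typing import Any

from .mesh_io import SurfaceMesh


@dataclasses.dataclass
class ProstateCase:
    """One patient's surfaces in a shared anatomical frame (mm).

    ``rois`` maps the lesion label (e.g. ``"roi_1"``) to its closed surface.
    ``metadata`` carries optional clinical context (PI-RADS, grades, volumes)
    that the geometry pipeline ignores but manifests echo.
    """

    case_id: str
    boundary: SurfaceMesh
    rois: dict[str, SurfaceMesh]
    metadata: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not self.rois:
            raise ValueError(f"case {self.case_id}: at least one ROI required")
        frames = {self.boundary.frame_label} | {
            m.frame_label for m in self.rois.values()}
        if len(frames) != 1:
            raise ValueError(
                f"case {self.case_id}: meshes in mixed frames {sorted(frames)}")

    @property
    def frame_label(self) -> str:
        return self.boundary.frame_label
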