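"""Polygon region-of-interest segmentation and area computation.

A cell (or sub-cellular region) is delimited by a manually picked polygon so
that no signal from outside it enters the analysis; the polygon area in µm²
is the normalizer for class densities. Boundary points count as inside
(closed-region semantics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .core import BindingSiteSet, LocalizationTable
from .errors import GeometryError


@dataclass
class ROIPolygon:
    """A simple (non-self-intersecting) polygon with positive area, in nm."""

    vertices: np.ndarray
    label: str = "roi"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise GeometryError(f"ROI '{self.label}' needs >= 3 (x, y) vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"ROI '{self.label}' is degenerate (self-intersecting or flat)")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @classmethod
    def rectangle(
        cls, width_nm: float, height_nm: float, x0_nm: float = 0.0, y0_nm: float = 0.0,
        label: str = "roi",
    ) -> "ROIPolygon":
        v = [
            (x0_nm, y0_nm),
            (x0_nm + width_nm, y0_nm),
            (x0_nm + width_nm, y0_nm + height_nm),
            (x0_nm, y0_nm + height_nm),
        ]
        return cls(np.array(v), label)

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: point strictly inside or on the boundary."""
        if len(xy) == 0:
            return np.zeros(0, dtype=bool)
        pts = shapely.points(xy[:, 0], xy[:, 1])
        return shapely.covers(self._polygon, pts)


def clip_to_roi(obj, roi: ROIPolygon):
    """Retain only localizations / sites inside (or on) the ROI polygon.

    Accepts a :class:`LocalizationTable` or :class:`BindingSiteSet` and
    returns the same type with row order preserved.
    """
    if isinstance(obj, LocalizationTable):
        mask = roi.contains(obj.xy)
        return obj.with_locs(obj.locs.loc[mask])
    if isinstance(obj, BindingSiteSet):
        mask = roi.contains(obj.xy)
        return obj.with_sites(obj.sites.loc[mask])
    raise TypeError(f"cannot clip object of type {type(obj).__name__}")


def roi_area_um2(roi: ROIPolygon) -> float:
    """Polygon (shoelace) area, converted nm² -> µm²."""
    return roi.polygon.area / 1e6


# ROI interchange format: CSV with columns label,vertex_index,x_nm,y_nm.

def write_rois_csv(rois: list[ROIPolygon], path: str | Path) -> None:
    rows = []
    for roi in rois:
        for i, (x, y) in enumerate(roi.vertices):
            rows.append({"label": roi.label, "vertex_index": i, "x_nm": x, "y_nm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_rois_csv(path: str | Path) -> list[ROIPolygon]:
    df = pd.read_csv(path)
    rois = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("vertex_index")
        rois.append(ROIPolygon(grp[["x_nm", "y_nm"]].to_numpy(), str(label)))
    return rois
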