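"""GlyCo class construction: grouping binding sites at the 5-nm scale.

Lectin binding sites closer than a cut-off (default 5 nm, the length scale at
or below which bound epitopes plausibly belong to one glycan) are grouped —
within the same channel and across channels — by single-linkage connected
components over the pooled site set. Each group of two or more sites defines
a class identified by the multiset of its channel labels (canonical label:
labels sorted alphabetically, joined by "+", repeats kept, e.g.
"AAL+WGA+WGA"). Class counts are normalized by the ROI area to densities per
square micrometre, and instance centroids give per-class spatial maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._spatial import components_from_labels, radius_component_labels
from .core import BindingSiteSet
from .errors import ParameterError

DEFAULT_CUTOFF_NM = 5.0


@dataclass
class SiteGroup:
    """One connected component of pooled sites: members and their geometry."""

    channels: list[str]  # one entry per member site, in pooled order
    xy: np.ndarray  # (size, 2) member positions, nm

    @property
    def size(self) -> int:
        return len(self.channels)

    @property
    def label(self) -> str:
        return "+".join(sorted(self.channels))

    @property
    def centroid(self) -> np.ndarray:
        return self.xy.mean(axis=0)


@dataclass
class GlycoClassTable:
    """Per-class counts, densities and instances for one sample.

    ``classes`` columns: label, size, count, density_per_um2.
    ``instances`` columns: label, centroid_x_nm, centroid_y_nm,
    member_channels (the canonical label again, one row per group).
    """

    classes: pd.DataFrame
    instances: pd.DataFrame
    roi_area_um2: float
    n_singletons: int
    n_sites_total: int

    def density_of(self, label: str) -> float:
        row = self.classes.loc[self.classes["label"] == label, "density_per_um2"]
        return float(row.iloc[0]) if len(row) else 0.0

    def to_csv(self, path: str | Path) -> None:
        self.classes.to_csv(path, index=False)


def group_sites(
    sites_by_channel: list[BindingSiteSet], cutoff_nm: float = DEFAULT_CUTOFF_NM
) -> list[SiteGroup]:
    """Single-linkage components over ALL sites (all channels pooled).

    A site joins a group via any member within ``cutoff_nm``; every site
    lands in exactly one component (singletons included).
    """
    if cutoff_nm <= 0:
        raise ParameterError(f"cutoff_nm must be > 0, got {cutoff_nm}")
    xs, labels = [], []
    for s in sites_by_channel:
        xs.append(s.xy)
        labels.extend([s.channel_label] * len(s))
    if not xs or sum(map(len, xs)) == 0:
        return []
    xy = np.vstack(xs)
    labels = np.array(labels)
    comp = radius_component_labels(xy, cutoff_nm)
    return [
        SiteGroup(list(labels[idx]), xy[idx]) for idx in components_from_labels(comp)
    ]


def classify_groups(groups: list[SiteGroup], roi_area_um2: float) -> GlycoClassTable:
    """Map size >= 2 groups to canonical classes; singletons are counted only."""
    if roi_area_um2 <= 0:
        raise ParameterError(f"roi_area_um2 must be > 0, got {roi_area_um2}")
    n_singletons = sum(1 for g in groups if g.size == 1)
    n_sites_total = sum(g.size for g in groups)
    inst_rows = []
    for g in groups:
        if g.size < 2:
            continue
        cx, cy = g.centroid
        inst_rows.append(
            {
                "label": g.label,
                "size": g.size,
                "centroid_x_nm": cx,
                "centroid_y_nm": cy,
                "member_channels": g.label,
            }
        )
    instances = pd.DataFrame(
        inst_rows, columns=["label", "size", "centroid_x_nm", "centroid_y_nm", "member_channels"]
    )
    if len(instances):
        agg = (
            instances.groupby("label", sort=True)
            .agg(size=("size", "first"), count=("label", "size"))
            .reset_index()
        )
        agg["density_per_um2"] = agg["count"] / roi_area_um2
    else:
        agg = pd.DataFrame(columns=["label", "size", "count", "density_per_um2"])
    return GlycoClassTable(
        classes=agg,
        instances=instances,
        roi_area_um2=roi_area_um2,
        n_singletons=n_singletons,
        n_sites_total=n_sites_total,
    )


def top_classes(table: GlycoClassTable, n: int = 10) -> pd.DataFrame:
    """The n most frequent classes: count descending, ties lexicographic."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    df = table.classes.sort_values(
        ["count", "label"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df.head(n)


def class_map(table: GlycoClassTable) -> dict[str, np.ndarray]:
    """Per-class point layer of instance centroids, for spatial mapping."""
    layers: dict[str, np.ndarray] = {}
    for label, grp in table.instances.groupby("label", sort=True):
        layers[label] = grp[["centroid_x_nm", "centroid_y_nm"]].to_numpy()
    return layers
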