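"""Binding-site calling: radius clustering, temporal filtering, centres.

Repeated imager binding to one docking strand produces a localization cloud;
clouds are grouped as connected components of the graph linking localizations
within a radius (default twice the NeNA precision), clusters with fewer than
two localizations are discarded, and clusters whose events pile into a single
short time bin (> 90% of events in one 200-frame bin, i.e. 1% of a
20,000-frame stack) are rejected as unspecific sticking. Surviving cluster
centres (unweighted means) are the lectin binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._spatial import components_from_labels, radius_component_labels
from .core import BindingSiteSet, LocalizationTable
from .errors import ParameterError


@dataclass
class ClusterParams:
    """Site-calling parameters; defaults reproduce the standard pipeline
    values for a 20,000-frame acquisition."""

    radius_nm: float
    min_locs: int = 2
    time_bin_frames: int | None = None  # default: 1% of the stack
    max_bin_fraction: float = 0.9

    def __post_init__(self):
        if self.radius_nm <= 0:
            raise ParameterError(f"radius_nm must be > 0, got {self.radius_nm}")
        if self.min_locs < 2:
            raise ParameterError(f"min_locs must be >= 2, got {self.min_locs}")
        if not 0 < self.max_bin_fraction <= 1:
            raise ParameterError("max_bin_fraction must lie in (0, 1]")

    def resolve_time_bin(self, n_frames: int) -> int:
        if self.time_bin_frames is not None:
            return self.time_bin_frames
        return max(1, round(0.01 * n_frames))


@dataclass
class ClusterReport:
    n_clusters_raw: int
    n_rejected_temporal: int

    @property
    def n_sites(self) -> int:
        return self.n_clusters_raw - self.n_rejected_temporal


def cluster_localizations(
    table: LocalizationTable, params: ClusterParams
) -> list[np.ndarray]:
    """Connected components of the distance-<=radius graph, >= min_locs members.

    Each localization belongs to at most one cluster; components are
    order-independent by construction.
    """
    labels = radius_component_labels(table.xy, params.radius_nm)
    comps = components_from_labels(labels)
    return [c for c in comps if len(c) >= params.min_locs]


def temporal_filter(frames: np.ndarray, n_frames: int, params: ClusterParams) -> bool:
    """Keep a cluster unless one fixed time bin holds > max_bin_fraction of events.

    Bins are consecutive, non-overlapping, anchored at frame 0 (the last bin
    may be short). Returns True to keep, False to reject as sticking.
    """
    frames = np.asarray(frames)
    if len(frames) == 0:
        raise ParameterError("temporal filter needs a non-empty cluster")
    tb = params.resolve_time_bin(n_frames)
    counts = np.bincount(frames // tb)
    return bool(counts.max() / len(frames) <= params.max_bin_fraction)


def site_centres(
    table: LocalizationTable, clusters: list[np.ndarray]
) -> BindingSiteSet:
    """Unweighted mean position per surviving cluster, sorted by (x, y)."""
    xy = table.xy
    frames = table.frames
    rows = [
        {
            "x_nm": xy[c, 0].mean(),
            "y_nm": xy[c, 1].mean(),
            "n_locs": len(c),
            "first_frame": int(frames[c].min()),
            "last_frame": int(frames[c].max()),
        }
        for c in clusters
    ]
    df = pd.DataFrame(rows, columns=["x_nm", "y_nm", "n_locs", "first_frame", "last_frame"])
    if len(df):
        df = df.sort_values(["x_nm", "y_nm"], kind="stable").reset_index(drop=True)
    return BindingSiteSet(table.channel_label, df)


def call_sites(
    table: LocalizationTable, params: ClusterParams
) -> tuple[BindingSiteSet, ClusterReport]:
    """Cluster, apply the temporal sticking filter, return centres + counts."""
    clusters = cluster_localizations(table, params)
    frames = table.frames
    surviving = [c for c in clusters if temporal_filter(frames[c], table.n_frames, params)]
    report = ClusterReport(
        n_clusters_raw=len(clusters),
        n_rejected_temporal=len(clusters) - len(surviving),
    )
    return site_centres(table, surviving), report
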