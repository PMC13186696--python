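"""First-nearest-neighbour distance histograms and the K x K peak matrix.

For every ordered pair of channels (including a channel against itself, self
match excluded) the distance from each source binding site to its nearest
target site is histogrammed; the mode of each histogram — the "peak" NN
distance — is collected into a K x K matrix (row = source channel, column =
target). Peaks are found on a centred moving-average smoothing of the counts
(raw counts are kept); ties go to the smaller distance. Full normalized
histograms can also be concatenated into a per-sample feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._spatial import nearest_neighbor_distances
from .core import BindingSiteSet
from .errors import EmptyHistogramError, ParameterError, UndefinedPairError

DEFAULT_BIN_NM = 1.0
DEFAULT_RANGE_NM = 200.0
DEFAULT_SMOOTH_BINS = 5


@dataclass
class NNHistogram:
    source_channel: str
    target_channel: str
    bin_edges_nm: np.ndarray
    counts: np.ndarray  # raw counts; smoothing is applied for peak finding only
    peak_nm: float

    @property
    def bin_centres_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])

    @property
    def normalized_counts(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise EmptyHistogramError(
                f"histogram {self.source_channel}->{self.target_channel} is empty"
            )
        return self.counts / total


@dataclass
class NNPeakMatrix:
    """K x K first-NN peak distances (nm); NaN marks a missing pair."""

    channel_order: list[str]
    peaks: np.ndarray
    histograms: dict[tuple[str, str], NNHistogram]

    @property
    def K(self) -> int:
        return len(self.channel_order)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.peaks, index=self.channel_order, columns=self.channel_order)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="source")


def nn_distances(
    source: BindingSiteSet, target: BindingSiteSet, same_channel: bool = False
) -> np.ndarray:
    """Euclidean distance from each source site to its nearest target site.

    With ``same_channel`` the source site itself is excluded from candidates.
    Raises :class:`UndefinedPairError` when the target is empty (or a
    singleton self-target).
    """
    if len(target) == 0 or (same_channel and len(source) < 2):
        raise UndefinedPairError(
            f"NN undefined: {source.channel_label}->{target.channel_label} "
            f"(target size {len(target)})"
        )
    return nearest_neighbor_distances(source.xy, target.xy, exclude_self=same_channel)


def nn_histogram(
    distances: np.ndarray,
    bin_nm: float = DEFAULT_BIN_NM,
    range_nm: float = DEFAULT_RANGE_NM,
    smooth_window_bins: int | str = DEFAULT_SMOOTH_BINS,
    source_channel: str = "",
    target_channel: str = "",
) -> NNHistogram:
    """Bin distances on [0, range_nm] and locate the peak on smoothed counts.

    Smoothing is a centred moving average of ``smooth_window_bins`` (odd)
    bins, edge-normalized so boundary bins are not biased downward; the peak
    is the centre of the global-maximum smoothed bin, ties broken toward the
    smallest distance. ``smooth_window_bins="auto"`` scales the window with
    the sample spread (half the standard deviation) — a mode estimator is
    only consistent if its bandwidth grows with the distribution's width, so
    prefer "auto" when distributions are broad relative to the bin.
    """
    if bin_nm <= 0 or range_nm <= 0:
        raise ParameterError("bin_nm and range_nm must be > 0")
    d = np.asarray(distances, dtype=np.float64)
    if len(d) == 0:
        raise ParameterError("nn_histogram needs >= 1 distance")
    if smooth_window_bins == "auto":
        w = int(round(0.5 * d.std() / bin_nm))
        smooth_window_bins = max(5, w if w % 2 else w + 1)
    if smooth_window_bins < 1 or smooth_window_bins % 2 == 0:
        raise ParameterError("smooth_window_bins must be a positive odd integer")
    edges = np.arange(0.0, range_nm + bin_nm, bin_nm)
    counts, _ = np.histogram(d, bins=edges)
    if counts.sum() == 0:
        raise EmptyHistogramError(
            f"all {len(d)} distances exceed the histogram range {range_nm} nm"
        )
    kernel = np.ones(smooth_window_bins)
    smoothed = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones_like(counts, dtype=float), kernel, mode="same"
    )
    # a moving average flattens an isolated spike into a plateau of equal
    # smoothed values; break plateau ties by the raw counts, then toward the
    # smallest distance
    top = np.flatnonzero(smoothed == smoothed.max())
    peak_idx = int(top[np.argmax(counts[top])])
    peak_nm = float(0.5 * (edges[peak_idx] + edges[peak_idx + 1]))
    return NNHistogram(source_channel, target_channel, edges, counts, peak_nm)


def peak_matrix(
    sites_by_channel: list[BindingSiteSet],
    bin_nm: float = DEFAULT_BIN_NM,
    range_nm: float = DEFAULT_RANGE_NM,
    smooth_window_bins: int = DEFAULT_SMOOTH_BINS,
) -> NNPeakMatrix:
    """Peak of every ordered channel-pair NN histogram, as a K x K matrix.

    Pairs whose NN distances are undefined (empty channel) or whose
    histogram is empty are flagged as NaN rather than raising.
    """
    labels = [s.channel_label for s in sites_by_channel]
    K = len(labels)
    peaks = np.full((K, K), np.nan)
    histograms: dict[tuple[str, str], NNHistogram] = {}
    for i, src in enumerate(sites_by_channel):
        for j, tgt in enumerate(sites_by_channel):
            try:
                d = nn_distances(src, tgt, same_channel=(i == j))
                h = nn_histogram(
                    d, bin_nm, range_nm, smooth_window_bins, labels[i], labels[j]
                )
            except (UndefinedPairError, EmptyHistogramError, ParameterError):
                continue
            peaks[i, j] = h.peak_nm
            histograms[(labels[i], labels[j])] = h
    return NNPeakMatrix(labels, peaks, histograms)


def full_distribution_features(
    matrix: NNPeakMatrix,
) -> tuple[np.ndarray, list[str]]:
    """Concatenate all K^2 normalized NN histograms into one feature vector.

    Each histogram's raw counts are normalized to sum 1; segments are ordered
    by (source, target) channel order. All histograms must share the binning;
    a missing (empty) histogram is an error, not silent zeros.
    """
    labels = matrix.channel_order
    ref_edges = None
    segments, names = [], []
    for src in labels:
        for tgt in labels:
            h = matrix.histograms.get((src, tgt))
            if h is None:
                raise EmptyHistogramError(
                    f"missing NN histogram {src}->{tgt}; cannot build full-distribution features"
                )
            if ref_edges is None:
                ref_edges = h.bin_edges_nm
            elif len(h.bin_edges_nm) != len(ref_edges) or not np.allclose(
                h.bin_edges_nm, ref_edges
            ):
                raise ParameterError("inconsistent histogram binning across channel pairs")
            segments.append(h.normalized_counts)
            centres = h.bin_centres_nm
            names.extend(f"{src}->{tgt}@{c:g}nm" for c in centres)
    return np.concatenate(segments), names


def histograms_to_long_frame(matrix: NNPeakMatrix) -> pd.DataFrame:
    """Long-format export: source, target, bin_centre_nm, count."""
    rows = []
    for (src, tgt), h in matrix.histograms.items():
        for c, n in zip(h.bin_centres_nm, h.counts):
            rows.append({"source": src, "target": tgt, "bin_centre_nm": c, "count": int(n)})
    return pd.DataFrame(rows)
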