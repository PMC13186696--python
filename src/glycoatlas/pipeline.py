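"""End-to-end orchestration: load -> register -> clip -> precision -> sites
-> NN matrix -> GlyCo -> features -> PCA, with a YAML results manifest.

The in-memory entry point is :func:`analyze_channels`, which takes one
sample's multi-channel localization tables (plus an optional ROI) through
fiducial detection, residual drift correction, channel alignment to the
first channel, fiducial removal, ROI clipping, per-channel NeNA precision,
clustering at 2*sigma with the temporal sticking filter, the NN peak matrix
and the GlyCo class table. :func:`run_pipeline` wraps it for file-based
multi-sample runs, adds the PCA embedding across samples, and writes plain
CSV/YAML outputs so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DEFAULT_PIXEL_SIZE_NM,
    BindingSiteSet,
    ChannelSet,
    LocalizationTable,
    read_localizations,
    write_binding_sites,
)
from .embedding import FEATURE_MODES, assemble_features, loadings_report, run_pca, separation_score
from .errors import GlycoAtlasError, PipelineStageError
from .glyco import DEFAULT_CUTOFF_NM, GlycoClassTable, classify_groups, group_sites
from .nn import NNPeakMatrix, histograms_to_long_frame, peak_matrix
from .precision import PrecisionEstimate, estimate_precision
from .registration import (
    ChannelTransform,
    DriftTrace,
    FiducialTrack,
    align_channels,
    apply_drift,
    detect_fiducials,
    estimate_drift,
    remove_fiducial_localizations,
)
from .roi import ROIPolygon, clip_to_roi, read_rois_csv, roi_area_um2
from .sites import ClusterParams, ClusterReport, call_sites

logger = logging.getLogger("glycoatlas")


@dataclass
class SampleConfig:
    sample_id: str
    condition: str
    channel_paths: dict[str, str]  # label -> localization table path
    roi_path: str | None = None  # CSV with label,vertex_index,x_nm,y_nm


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the standard analysis
    (130-nm pixels, 2*sigma clustering radius, min 2 locs, 1%-of-stack time
    bins at a 90% threshold, 5-nm GlyCo cut-off, K x K peak matrix)."""

    samples: list[SampleConfig]
    out_dir: str
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    align_mode: str = "translation"
    fiducial_min_presence: float = 0.5
    fiducial_link_radius_nm: float = 500.0
    skip_registration: bool = False
    cluster_radius_nm: float | None = None  # None: per-channel 2*sigma(NeNA)
    min_locs: int = 2
    max_bin_fraction: float = 0.9
    time_bin_frames: int | None = None
    nn_bin_nm: float = 1.0
    nn_range_nm: float = 200.0
    nn_smooth_bins: int | str = 5  # "auto": window scales with histogram width
    glyco_cutoff_nm: float = DEFAULT_CUTOFF_NM
    feature_modes: tuple[str, ...] = ("nn_peaks", "glyco")
    n_components: int = 2
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["samples"] = [SampleConfig(**s) for s in raw["samples"]]
        if "feature_modes" in raw:
            raw["feature_modes"] = tuple(raw["feature_modes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["samples"] = [dict(s.__dict__) for s in self.samples]
        d["feature_modes"] = list(self.feature_modes)
        return d


@dataclass
class SampleAnalysis:
    """Everything one sample's analysis produced, in memory."""

    tables: dict[str, LocalizationTable]  # registered, fiducial-free, clipped
    fiducial_tracks: dict[str, list[FiducialTrack]]
    drift_traces: dict[str, DriftTrace]
    transforms: dict[str, ChannelTransform]
    precisions: dict[str, PrecisionEstimate]
    sites_by_channel: list[BindingSiteSet]
    cluster_reports: dict[str, ClusterReport]
    peak_matrix: NNPeakMatrix
    glyco_table: GlycoClassTable
    roi_area_um2: float


def _stage(name: str):
    """Context guard: re-raise any stage error naming the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def analyze_channels(
    tables: dict[str, LocalizationTable] | ChannelSet,
    roi: ROIPolygon | None = None,
    config: RunConfig | None = None,
) -> SampleAnalysis:
    """Run all per-sample stages on in-memory localization tables."""
    if config is None:
        config = RunConfig(samples=[], out_dir="")
    if isinstance(tables, ChannelSet):
        tables = {t.channel_label: t for t in tables}
    else:
        tables = dict(tables)
    labels = list(tables)

    tracks: dict[str, list[FiducialTrack]] = {}
    traces: dict[str, DriftTrace] = {}
    transforms: dict[str, ChannelTransform] = {}
    if not config.skip_registration:
        with _stage("registration"):
            for lab in labels:
                t = tables[lab]
                tr = detect_fiducials(
                    t, config.fiducial_min_presence, config.fiducial_link_radius_nm
                )
                if tr:
                    trace = estimate_drift(tr, t.n_frames)
                    traces[lab] = trace
                    t = apply_drift(t, trace)
                else:
                    logger.warning(
                        "channel %s: no fiducials, skipping drift correction", lab
                    )
                tables[lab] = t
            # re-detect on corrected tables for alignment and exclusion
            for lab in labels:
                tracks[lab] = detect_fiducials(
                    tables[lab], config.fiducial_min_presence, config.fiducial_link_radius_nm
                )
            ref = labels[0]
            for lab in labels[1:]:
                if tracks[ref] and tracks[lab]:
                    tf = align_channels(tracks[ref], tracks[lab], config.align_mode)
                    tables[lab] = tf.apply(tables[lab])
                    transforms[lab] = tf
            for lab in labels:  # beads are not glycan signal
                tables[lab] = remove_fiducial_localizations(
                    tables[lab], tracks[lab], config.fiducial_link_radius_nm
                )

    area = None
    if roi is not None:
        with _stage("roi_clip"):
            tables = {lab: clip_to_roi(t, roi) for lab, t in tables.items()}
            area = roi_area_um2(roi)

    with _stage("precision"):
        precisions = {lab: estimate_precision(t) for lab, t in tables.items()}

    with _stage("site_calling"):
        sites_by_channel: list[BindingSiteSet] = []
        reports: dict[str, ClusterReport] = {}
        for lab in labels:
            radius = config.cluster_radius_nm or precisions[lab].clustering_radius_nm
            params = ClusterParams(
                radius_nm=radius,
                min_locs=config.min_locs,
                time_bin_frames=config.time_bin_frames,
                max_bin_fraction=config.max_bin_fraction,
            )
            sites, report = call_sites(tables[lab], params)
            sites_by_channel.append(sites)
            reports[lab] = report

    with _stage("nn_analysis"):
        matrix = peak_matrix(
            sites_by_channel, config.nn_bin_nm, config.nn_range_nm, config.nn_smooth_bins
        )

    with _stage("glyco"):
        if area is None:
            allxy = np.vstack([s.xy for s in sites_by_channel if len(s)])
            span = allxy.max(axis=0) - allxy.min(axis=0)
            area = float(span[0] * span[1] / 1e6)
        groups = group_sites(sites_by_channel, config.glyco_cutoff_nm)
        table = classify_groups(groups, area)

    return SampleAnalysis(
        tables=tables,
        fiducial_tracks=tracks,
        drift_traces=traces,
        transforms=transforms,
        precisions=precisions,
        sites_by_channel=sites_by_channel,
        cluster_reports=reports,
        peak_matrix=matrix,
        glyco_table=table,
        roi_area_um2=area,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def process_sample(sample: SampleConfig, config: RunConfig, out_dir: Path) -> dict:
    """File-based wrapper: load one sample, analyze, write stage outputs."""
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        tables = {}
        for label, path in sample.channel_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"channel '{label}': missing file {path}")
            tables[label] = read_localizations(path, config.pixel_size_nm, label)
        n_locs = {k: len(t) for k, t in tables.items()}

    roi = None
    if sample.roi_path:
        with _stage("roi"):
            roi = read_rois_csv(sample.roi_path)[0]

    res = analyze_channels(tables, roi, config)

    for lab, trace in res.drift_traces.items():
        trace.to_csv(out_dir / f"drift_{lab}.csv")
    pd.DataFrame(
        [
            {
                "channel": lab,
                "tx_nm": tf.tx_nm,
                "ty_nm": tf.ty_nm,
                "theta_rad": tf.theta_rad,
                "residual_rms_nm": tf.residual_rms_nm,
                "n_matched": tf.n_matched,
            }
            for lab, tf in res.transforms.items()
        ]
    ).to_csv(out_dir / "channel_transforms.csv", index=False)
    pd.DataFrame(
        [
            {
                "channel": lab,
                "sigma_nm": est.sigma_nm,
                "n_pairs": est.n_pairs,
                "background_fraction": est.background_fraction,
                "reliable": est.reliable,
            }
            for lab, est in res.precisions.items()
        ]
    ).to_csv(out_dir / "precision.csv", index=False)
    for sites in res.sites_by_channel:
        write_binding_sites(sites, out_dir / f"sites_{sites.channel_label}.csv")
    res.peak_matrix.to_csv(out_dir / "nn_peak_matrix.csv")
    histograms_to_long_frame(res.peak_matrix).to_csv(
        out_dir / "nn_histograms.csv", index=False
    )
    res.glyco_table.classes.to_csv(out_dir / "glyco_classes.csv", index=False)
    res.glyco_table.instances.to_csv(out_dir / "glyco_instances.csv", index=False)

    return {
        "sample_id": sample.sample_id,
        "condition": sample.condition,
        "n_localizations": n_locs,
        "roi_area_um2": float(res.roi_area_um2),
        "precision_nm": {k: float(v.sigma_nm) for k, v in res.precisions.items()},
        "cluster_counts": {
            lab: {
                "clusters_raw": rep.n_clusters_raw,
                "rejected_temporal": rep.n_rejected_temporal,
                "sites": rep.n_sites,
            }
            for lab, rep in res.cluster_reports.items()
        },
        "n_missing_nn_pairs": int(res.peak_matrix.missing.sum()),
        "n_classes": int(len(res.glyco_table.classes)),
        "n_singletons": int(res.glyco_table.n_singletons),
        "_analysis": res,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the results manifest."""
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "glycoatlas", "version": __version__},
        "config": config.to_dict(),
        "samples": [],
    }
    per_sample = []
    try:
        for sample in config.samples:
            section = process_sample(sample, config, out_root / sample.sample_id)
            per_sample.append(section)
            manifest["samples"].append({k: v for k, v in section.items() if k != "_analysis"})

        if len(per_sample) >= 2:
            with _stage("embedding"):
                ids = [s["sample_id"] for s in per_sample]
                conds = [s["condition"] for s in per_sample]
                emb_section = {}
                for mode in config.feature_modes:
                    if mode not in FEATURE_MODES:
                        raise PipelineStageError("embedding", f"unknown feature mode '{mode}'")
                    objs = [
                        s["_analysis"].glyco_table if mode == "glyco"
                        else s["_analysis"].peak_matrix
                        for s in per_sample
                    ]
                    fm = assemble_features(objs, mode, ids, conds)
                    emb = run_pca(fm, config.n_components)
                    scores = pd.DataFrame(
                        emb.scores,
                        columns=[f"PC{i + 1}" for i in range(emb.scores.shape[1])],
                    )
                    scores.insert(0, "sample_id", ids)
                    scores.insert(1, "condition", conds)
                    scores.to_csv(out_root / f"pca_scores_{mode}.csv", index=False)
                    loadings_report(emb).to_csv(
                        out_root / f"pca_loadings_{mode}.csv", index=False
                    )
                    emb_section[mode] = {
                        "explained_variance_ratio": [
                            float(v) for v in emb.explained_variance_ratio
                        ],
                    }
                    cond_counts = np.unique(np.asarray(conds), return_counts=True)[1]
                    if len(cond_counts) >= 2 and cond_counts.min() >= 2:
                        emb_section[mode]["silhouette"] = separation_score(emb)
                manifest["embedding"] = emb_section
    except GlycoAtlasError as exc:
        (out_root / "FAILED").write_text(str(exc))
        raise

    manifest["checksums"] = {
        str(p.relative_to(out_root)): _sha256(p) for p in sorted(out_root.rglob("*.csv"))
    }
    with open(out_root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
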