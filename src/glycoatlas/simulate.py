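"""Synthetic multi-channel DNA-PAINT scene generator with full ground truth.

Emulates the acquisition the analysis pipeline expects: for each channel of a
lectin panel, binding sites are planted in a polygon ROI (a configurable
fraction of them as multi-channel "motif" instances — co-located site groups
within a few nanometres that downstream GlyCo grouping should recover as
classes), each site emits a Poisson number of blink events at uniformly
random frames over a 20,000-frame stack, every localization is displaced by
isotropic Gaussian noise (the localization precision) and by the cumulative
stage drift of its frame, gold fiducials emit in every frame with small
jitter, and unspecific sticking artifacts emit many events confined to one
short time window. The generator returns both the localization tables and a
:class:`GroundTruth` so every pipeline stage has a recoverable truth; a
fixed seed reproduces the scene bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BindingSiteSet, ChannelSet, LocalizationTable, DEFAULT_N_FRAMES
from .errors import SceneSpecError
from .registration import DriftTrace
from .roi import ROIPolygon

DEFAULT_PANEL = ("AAL", "PHA-L", "PSA", "SNA", "WGA")


@dataclass
class Motif:
    """A planted glycan class: a multiset of channel labels co-located
    within ``motif_radius_nm`` of a common anchor."""

    channels: tuple[str, ...]
    weight: float = 1.0

    @property
    def label(self) -> str:
        return "+".join(sorted(self.channels))

    @property
    def size(self) -> int:
        return len(self.channels)


@dataclass
class SceneSpec:
    """Study conditions for one synthetic field of view.

    Defaults emulate a typical acquisition: 20,000 frames at 100 ms, ~10
    blink events per docking site, 5-nm localization precision, slow linear
    stage drift, a handful of gold beads outside the cell ROI, and sparse
    sticking artifacts confined to 200-frame windows.
    """

    seed: int = 0
    field_size_nm: tuple[float, float] = (10_000.0, 10_000.0)
    roi_margin_nm: float = 1_000.0  # ROI = field inset by this margin; beads live outside
    channels: tuple[str, ...] = DEFAULT_PANEL
    site_density_per_um2: float | dict = 10.0
    motifs: list[Motif] = field(default_factory=list)
    motif_fraction: float = 0.0  # fraction of all sites that belong to motifs
    motif_radius_nm: float = 4.0  # internal spacing ~ U[1, radius]
    min_separation_nm: float = 50.0  # between anchors/background sites
    n_frames: int = DEFAULT_N_FRAMES
    mean_events_per_site: float = 10.0
    min_events_per_site: int = 2  # sites emitting < 2 events are undetectable by design
    mean_bright_frames: float = 3.0  # binding-event duration, geometric (>= 1 frame)
    sigma_nm: float | dict = 5.0
    drift_mode: str = "linear"  # "linear" | "random_walk" | "none"
    drift_velocity_nm_per_frame: tuple[float, float] = (0.01, -0.007)
    drift_step_nm: float = 0.02  # random-walk step per frame
    n_fiducials: int = 4
    fiducial_jitter_nm: float = 2.0
    fiducial_roi_clearance_nm: float = 600.0  # beads stay this far outside the ROI
    channel_shift_nm: dict = field(default_factory=dict)  # per-round misalignment
    sticking_per_um2: float = 0.2  # per channel
    sticking_window_frames: int = 200
    sticking_mean_events: float = 30.0
    # windows start on multiples of the window length, so a sticker sits in
    # one bin of the (frame-0 anchored) temporal-filter partition
    sticking_aligned: bool = True
    photons_mean: float = 5_000.0
    fiducial_photons_mean: float = 50_000.0

    def density_of(self, channel: str) -> float:
        if isinstance(self.site_density_per_um2, dict):
            return float(self.site_density_per_um2.get(channel, 0.0))
        return float(self.site_density_per_um2)

    def sigma_of(self, channel: str) -> float:
        if isinstance(self.sigma_nm, dict):
            return float(self.sigma_nm[channel])
        return float(self.sigma_nm)

    def validate(self) -> None:
        if self.n_frames <= 0 or self.motif_fraction < 0 or self.motif_fraction > 1:
            raise SceneSpecError("n_frames must be > 0 and motif_fraction in [0, 1]")
        for m in self.motifs:
            unknown = set(m.channels) - set(self.channels)
            if unknown:
                raise SceneSpecError(f"motif channel(s) {sorted(unknown)} not in panel")
            if m.weight < 0:
                raise SceneSpecError("motif weights must be non-negative")
        if self.motifs and self.motif_fraction > 0:
            total = sum(m.weight for m in self.motifs)
            if total <= 0:
                raise SceneSpecError("motif weights must sum to > 0")

    @property
    def roi(self) -> ROIPolygon:
        w, h = self.field_size_nm
        m = self.roi_margin_nm
        return ROIPolygon.rectangle(w - 2 * m, h - 2 * m, m, m, label="cell")


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle comparisons."""

    sites_by_channel: dict[str, np.ndarray]  # true site positions (no drift/noise)
    motif_instances: pd.DataFrame  # label, anchor_x_nm, anchor_y_nm, size
    site_channels: list[str]  # pooled channel label per planted site
    site_xy: np.ndarray  # pooled planted positions, same order
    drift: DriftTrace
    fiducial_xy: np.ndarray  # (n_fiducials, 2) true bead positions
    sticking_by_channel: dict[str, np.ndarray]

    def true_binding_sites(self, channel: str) -> BindingSiteSet:
        xy = self.sites_by_channel[channel]
        df = pd.DataFrame(
            {
                "x_nm": xy[:, 0],
                "y_nm": xy[:, 1],
                "n_locs": 2,
                "first_frame": 0,
                "last_frame": 0,
            }
        )
        return BindingSiteSet(channel, df)


class _HardCoreGrid:
    """Cell-hash for O(1) minimum-separation checks during dart throwing."""

    def __init__(self, min_sep: float, points: np.ndarray | None = None):
        self.min_sep = min_sep
        self.cell = max(min_sep, 1e-9)
        self.cells: dict[tuple[int, int], list[np.ndarray]] = {}
        if points is not None:
            for p in points:
                self.add(p)

    def _key(self, p) -> tuple[int, int]:
        return (int(np.floor(p[0] / self.cell)), int(np.floor(p[1] / self.cell)))

    def ok(self, p) -> bool:
        kx, ky = self._key(p)
        for ix in range(kx - 1, kx + 2):
            for iy in range(ky - 1, ky + 2):
                for q in self.cells.get((ix, iy), ()):
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < self.min_sep**2:
                        return False
        return True

    def add(self, p) -> None:
        self.cells.setdefault(self._key(p), []).append(np.asarray(p, dtype=float))


def _dart_throw(
    rng: np.random.Generator,
    n: int,
    roi: ROIPolygon,
    min_sep: float,
    existing: np.ndarray | None = None,
    max_attempts_factor: int = 200,
) -> np.ndarray:
    """CSR placement with an optional hard-core minimum separation."""
    (x0, y0), (x1, y1) = roi.vertices.min(axis=0), roi.vertices.max(axis=0)
    if min_sep <= 0:
        # plain CSR: rejection-sample into the polygon in bulk
        pts = np.zeros((0, 2))
        while len(pts) < n:
            cand = rng.uniform((x0, y0), (x1, y1), size=(max(2 * (n - len(pts)), 64), 2))
            cand = cand[roi.contains(cand)]
            pts = np.vstack([pts, cand])
        return pts[:n]
    grid = _HardCoreGrid(min_sep, existing)
    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n and attempts < max_attempts_factor * max(n, 1):
        attempts += 1
        cand = rng.uniform((x0, y0), (x1, y1), size=2)
        if not roi.contains(cand[None, :])[0]:
            continue
        if grid.ok(cand):
            placed.append(cand)
            grid.add(cand)
    if len(placed) < n:
        raise SceneSpecError(
            f"could not place {n} sites at min separation {min_sep} nm "
            f"(placed {len(placed)}); lower the density or the separation"
        )
    return np.array(placed)


def _make_drift(spec: SceneSpec, rng: np.random.Generator) -> DriftTrace:
    t = np.arange(spec.n_frames, dtype=np.float64)
    if spec.drift_mode == "none":
        dx = dy = np.zeros(spec.n_frames)
    elif spec.drift_mode == "linear":
        vx, vy = spec.drift_velocity_nm_per_frame
        dx, dy = vx * t, vy * t
    elif spec.drift_mode == "random_walk":
        dx = np.cumsum(rng.normal(0, spec.drift_step_nm, spec.n_frames))
        dy = np.cumsum(rng.normal(0, spec.drift_step_nm, spec.n_frames))
    else:
        raise SceneSpecError(f"unknown drift_mode '{spec.drift_mode}'")
    # the trace as applied (not re-centred); estimators recentre their own
    return DriftTrace(dx, dy)


def _emit(
    rng: np.random.Generator,
    site_xy: np.ndarray,
    n_events: np.ndarray,
    spec: SceneSpec,
    sigma: float,
    drift: DriftTrace,
    photons_mean: float,
) -> pd.DataFrame:
    """Blink events at uniform start frames; each event stays bright for a
    geometric number of frames (mean ``mean_bright_frames``) and yields one
    independently noised localization per bright frame — the adjacent-frame
    pairs the precision estimator feeds on."""
    rows_x, rows_y, rows_f = [], [], []
    p_off = 1.0 / max(spec.mean_bright_frames, 1.0)
    for (sx, sy), k in zip(site_xy, n_events):
        if k == 0:
            continue
        starts = rng.integers(0, spec.n_frames, size=k)
        lengths = rng.geometric(p_off, size=k)
        fr = np.concatenate(
            [np.arange(s, min(s + l, spec.n_frames)) for s, l in zip(starts, lengths)]
        )
        noise = rng.normal(0.0, sigma, size=(len(fr), 2)) if sigma > 0 else np.zeros((len(fr), 2))
        rows_x.append(sx + noise[:, 0] + drift.dx_nm[fr])
        rows_y.append(sy + noise[:, 1] + drift.dy_nm[fr])
        rows_f.append(fr)
    if not rows_f:
        return pd.DataFrame({"frame": [], "x_nm": [], "y_nm": [], "photons": []})
    fr = np.concatenate(rows_f)
    return pd.DataFrame(
        {
            "frame": fr,
            "x_nm": np.concatenate(rows_x),
            "y_nm": np.concatenate(rows_y),
            "photons": rng.exponential(photons_mean, size=len(fr)) + photons_mean / 2,
        }
    )


def generate_scene(spec: SceneSpec) -> tuple[ChannelSet, GroundTruth]:
    """Generate one multi-channel scene and its ground truth.

    Deterministic for a fixed ``spec.seed``: the same spec yields
    bit-identical localization tables and truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    roi = spec.roi
    area_um2 = roi.polygon.area / 1e6

    # --- how many sites per channel, and how many motif instances ---
    n_target = {c: rng.poisson(spec.density_of(c) * area_um2) for c in spec.channels}
    total_sites = sum(n_target.values())
    motif_counts: list[int] = []
    if spec.motifs and spec.motif_fraction > 0 and total_sites > 0:
        wsum = sum(m.weight for m in spec.motifs)
        mean_size = sum(m.weight / wsum * m.size for m in spec.motifs)
        n_instances = int(round(spec.motif_fraction * total_sites / mean_size))
        motif_counts = list(
            rng.multinomial(n_instances, [m.weight / wsum for m in spec.motifs])
        )
    else:
        motif_counts = [0] * len(spec.motifs)

    # --- place motif anchors, then satellites, then background sites ---
    sites: dict[str, list[np.ndarray]] = {c: [] for c in spec.channels}
    inst_rows = []
    n_anchor = sum(motif_counts)
    anchors = (
        _dart_throw(rng, n_anchor, roi, spec.min_separation_nm)
        if n_anchor
        else np.zeros((0, 2))
    )
    ai = 0
    used = {c: 0 for c in spec.channels}
    for motif, cnt in zip(spec.motifs, motif_counts):
        for _ in range(cnt):
            anchor = anchors[ai]
            ai += 1
            for k, ch in enumerate(motif.channels):
                if k == 0:
                    pos = anchor
                else:
                    r = rng.uniform(1.0, spec.motif_radius_nm)
                    phi = rng.uniform(0, 2 * np.pi)
                    pos = anchor + r * np.array([np.cos(phi), np.sin(phi)])
                sites[ch].append(pos)
                used[ch] += 1
            inst_rows.append(
                {
                    "label": motif.label,
                    "anchor_x_nm": anchor[0],
                    "anchor_y_nm": anchor[1],
                    "size": motif.size,
                }
            )
    existing = anchors
    for c in spec.channels:
        n_bg = max(0, n_target[c] - used[c])
        if n_bg:
            bg = _dart_throw(rng, n_bg, roi, spec.min_separation_nm, existing=existing)
            sites[c].extend(bg)
            existing = np.vstack([existing, bg]) if len(existing) else bg
    sites_xy = {
        c: (np.array(v) if v else np.zeros((0, 2))) for c, v in sites.items()
    }

    drift = _make_drift(spec, rng)

    # --- fiducials: in the margin, clear of the ROI, emitting every frame ---
    from shapely.geometry import Point

    w, h = spec.field_size_nm
    fid_xy = []
    while len(fid_xy) < spec.n_fiducials:
        cand = rng.uniform((0, 0), (w, h), size=2)
        if (
            roi.polygon.distance(Point(cand)) > spec.fiducial_roi_clearance_nm
            and all(np.hypot(*(cand - f)) > 2000.0 for f in fid_xy)
        ):
            fid_xy.append(cand)
    fid_xy = np.array(fid_xy) if fid_xy else np.zeros((0, 2))

    # --- emit localizations per channel ---
    tables = []
    sticking: dict[str, np.ndarray] = {}
    for c in spec.channels:
        sigma = spec.sigma_of(c)
        xy = sites_xy[c]
        n_ev = rng.poisson(spec.mean_events_per_site, size=len(xy))
        n_ev = np.maximum(n_ev, spec.min_events_per_site)
        parts = [_emit(rng, xy, n_ev, spec, sigma, drift, spec.photons_mean)]

        n_stick = rng.poisson(spec.sticking_per_um2 * area_um2)
        stick_xy = (
            _dart_throw(rng, n_stick, roi, spec.min_separation_nm, existing=existing)
            if n_stick
            else np.zeros((0, 2))
        )
        sticking[c] = stick_xy
        if n_stick:
            if spec.sticking_aligned:
                starts = rng.integers(
                    0, max(1, spec.n_frames // spec.sticking_window_frames), n_stick
                ) * spec.sticking_window_frames
            else:
                starts = rng.integers(
                    0, max(1, spec.n_frames - spec.sticking_window_frames), n_stick
                )
            k_ev = np.maximum(rng.poisson(spec.sticking_mean_events, n_stick), 3)
            for (sx, sy), st, k in zip(stick_xy, starts, k_ev):
                fr = rng.integers(st, st + spec.sticking_window_frames, size=k)
                noise = rng.normal(0.0, sigma, size=(k, 2))
                parts.append(
                    pd.DataFrame(
                        {
                            "frame": fr,
                            "x_nm": sx + noise[:, 0] + drift.dx_nm[fr],
                            "y_nm": sy + noise[:, 1] + drift.dy_nm[fr],
                            "photons": rng.exponential(spec.photons_mean, size=k)
                            + spec.photons_mean / 2,
                        }
                    )
                )

        if len(fid_xy):
            fr = np.tile(np.arange(spec.n_frames), len(fid_xy))
            base = np.repeat(fid_xy, spec.n_frames, axis=0)
            jit = rng.normal(0.0, spec.fiducial_jitter_nm, size=(len(fr), 2))
            parts.append(
                pd.DataFrame(
                    {
                        "frame": fr,
                        "x_nm": base[:, 0] + jit[:, 0] + drift.dx_nm[fr],
                        "y_nm": base[:, 1] + jit[:, 1] + drift.dy_nm[fr],
                        "photons": rng.exponential(
                            spec.fiducial_photons_mean, size=len(fr)
                        )
                        + spec.fiducial_photons_mean,
                    }
                )
            )
        locs = pd.concat(parts, ignore_index=True)
        locs["frame"] = locs["frame"].astype(np.int64)
        sx, sy = spec.channel_shift_nm.get(c, (0.0, 0.0))
        if sx or sy:  # round-to-round misalignment shifts beads and signal alike
            locs["x_nm"] = locs["x_nm"] + sx
            locs["y_nm"] = locs["y_nm"] + sy
        locs = locs.sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)
        tables.append(LocalizationTable(c, spec.n_frames, locs))

    pooled_channels: list[str] = []
    pooled_xy: list[np.ndarray] = []
    for c in spec.channels:
        pooled_channels.extend([c] * len(sites_xy[c]))
        pooled_xy.append(sites_xy[c])
    truth = GroundTruth(
        sites_by_channel=sites_xy,
        motif_instances=pd.DataFrame(
            inst_rows, columns=["label", "anchor_x_nm", "anchor_y_nm", "size"]
        ),
        site_channels=pooled_channels,
        site_xy=np.vstack(pooled_xy) if pooled_xy else np.zeros((0, 2)),
        drift=drift,
        fiducial_xy=fid_xy,
        sticking_by_channel=sticking,
    )
    return ChannelSet(tables), truth


def two_condition_panel_specs(
    seed: int, n_per_condition: int = 6
) -> list[tuple[SceneSpec, str]]:
    """Scene specs for two synthetic cellular states, for embedding demos.

    Both states share a 5-lectin panel at 8 sites/µm² over a ~100 µm² cell
    ROI with two planted classes. State B carries a global remodelling
    signature relative to state A, the way a genuine cellular state change
    shifts the whole lectin profile rather than a single readout: the
    "SNA+WGA" class density doubles while "AAL+PSA+WGA" drops to ~0.7x
    (motif fraction 0.36 -> 0.45, weights 0.5/0.5 -> 0.75/0.25), and every
    channel's site density shifts by its own factor — PHA-L spacing
    stretches 1.5x (density / 2.25), AAL 1.25x, SNA 1.1x, while PSA and WGA
    compact (spacing x0.83 and x0.91). Analyze the scenes with a histogram
    range covering the widest spacings (>= 500 nm) and adaptive peak
    smoothing.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_condition)
    motifs_a = [Motif(("SNA", "WGA"), 0.5), Motif(("AAL", "PSA", "WGA"), 0.5)]
    motifs_b = [Motif(("SNA", "WGA"), 0.75), Motif(("AAL", "PSA", "WGA"), 0.25)]
    density_b = {
        "PHA-L": 8.0 / 2.25,
        "AAL": 8.0 / 1.5625,
        "SNA": 8.0 / 1.21,
        "PSA": 8.0 * 1.44,
        "WGA": 8.0 * 1.21,
    }
    out = []
    for i in range(n_per_condition):
        out.append(
            (
                SceneSpec(
                    seed=int(child_seeds[i]),
                    field_size_nm=(12_000.0, 12_000.0),
                    site_density_per_um2={c: 8.0 for c in DEFAULT_PANEL},
                    motifs=motifs_a,
                    motif_fraction=0.36,
                    n_fiducials=3,
                ),
                "A",
            )
        )
    for i in range(n_per_condition):
        out.append(
            (
                SceneSpec(
                    seed=int(child_seeds[n_per_condition + i]),
                    field_size_nm=(12_000.0, 12_000.0),
                    site_density_per_um2=density_b,
                    motifs=motifs_b,
                    motif_fraction=0.45,
                    n_fiducials=3,
                ),
                "B",
            )
        )
    return out


def truth_match(
    called: BindingSiteSet | np.ndarray,
    truth_xy: np.ndarray,
    match_radius_nm: float = 10.0,
) -> dict:
    """Greedy one-to-one matching of called sites to planted sites.

    Candidate pairs within the match radius are consumed in ascending
    distance order; returns recall, precision, position RMSE over matches
    and the matched count.
    """
    from scipy.spatial import cKDTree

    called_xy = called.xy if isinstance(called, BindingSiteSet) else np.asarray(called)
    n_called, n_truth = len(called_xy), len(truth_xy)
    if n_called == 0 or n_truth == 0:
        return {"recall": 0.0, "precision": 0.0, "rmse_nm": np.nan, "n_matched": 0}
    tree = cKDTree(truth_xy)
    pairs = []
    for i, pt in enumerate(called_xy):
        for j in tree.query_ball_point(pt, match_radius_nm):
            d = float(np.hypot(*(pt - truth_xy[j])))
            pairs.append((d, i, j))
    pairs.sort()
    used_c, used_t = set(), set()
    sq = []
    for d, i, j in pairs:
        if i not in used_c and j not in used_t:
            used_c.add(i)
            used_t.add(j)
            sq.append(d * d)
    n_matched = len(sq)
    return {
        "recall": n_matched / n_truth,
        "precision": n_matched / n_called,
        "rmse_nm": float(np.sqrt(np.mean(sq))) if sq else np.nan,
        "n_matched": n_matched,
    }
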