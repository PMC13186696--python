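"""Core data model and I/O for single-molecule localization tables.

The central containers are :class:`LocalizationTable` (one DNA-PAINT channel:
frame, x, y, photons, with coordinates held in nanometres), :class:`ChannelSet`
(an ordered multi-channel panel) and :class:`BindingSiteSet` (cluster centres
surviving all filters — the inferred lectin binding sites).

On-disk formats follow SMLM conventions: an HDF5 file with a structured
dataset named ``locs`` (fields ``frame``, ``x``, ``y``, ``photons``,
coordinates in camera pixels, Picasso-compatible) plus a YAML sidecar carrying
``n_frames``, ``pixel_size_nm`` and ``channel_label``; or an equivalent CSV
with the same columns. Coordinates are converted to nanometres at load time
and every downstream module works in nanometres only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ParameterError

logger = logging.getLogger("glycoatlas")

#: Mandatory fields of a localization table on disk (pixel units).
LOC_FIELDS = ("frame", "x", "y", "photons")

#: Effective camera pixel size in nm (100x objective, 2x2 binning).
DEFAULT_PIXEL_SIZE_NM = 130.0

#: Default acquisition length in frames (100 ms frame time).
DEFAULT_N_FRAMES = 20_000


@dataclass
class LocalizationTable:
    """Drift-corrected localizations of one channel, coordinates in nm.

    ``locs`` has columns ``frame`` (int, 0-based), ``x_nm``, ``y_nm``
    (float64, image convention: origin upper-left, y increasing downward) and
    ``photons``. Invariants: all frames in ``[0, n_frames)``, all coordinates
    finite.
    """

    channel_label: str
    n_frames: int
    locs: pd.DataFrame
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM

    def __post_init__(self):
        if self.n_frames <= 0:
            raise FormatError(f"n_frames must be positive, got {self.n_frames}")
        missing = [c for c in ("frame", "x_nm", "y_nm", "photons") if c not in self.locs.columns]
        if missing:
            raise FormatError(f"localization table missing column(s): {', '.join(missing)}")
        self.locs = self.locs.reset_index(drop=True).astype(
            {"frame": np.int64, "x_nm": np.float64, "y_nm": np.float64, "photons": np.float64}
        )
        if len(self.locs):
            fr = self.locs["frame"].to_numpy()
            if fr.min() < 0 or fr.max() >= self.n_frames:
                raise FormatError(
                    f"frames outside [0, {self.n_frames}) in channel '{self.channel_label}'"
                )
            if not np.isfinite(self.locs[["x_nm", "y_nm"]].to_numpy()).all():
                raise FormatError(f"non-finite coordinates in channel '{self.channel_label}'")

    def __len__(self) -> int:
        return len(self.locs)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return self.locs[["x_nm", "y_nm"]].to_numpy()

    @property
    def frames(self) -> np.ndarray:
        return self.locs["frame"].to_numpy()

    def with_locs(self, locs: pd.DataFrame) -> "LocalizationTable":
        """Copy of this table with a replaced localization frame."""
        return LocalizationTable(self.channel_label, self.n_frames, locs, self.pixel_size_nm)


@dataclass
class ChannelSet:
    """Ordered multi-channel panel (typically K = 5, or 6 with DBCO)."""

    channels: list[LocalizationTable]

    def __post_init__(self):
        labels = [c.channel_label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise FormatError(f"duplicate channel labels: {labels}")

    @property
    def K(self) -> int:
        return len(self.channels)

    @property
    def labels(self) -> list[str]:
        return [c.channel_label for c in self.channels]

    def __iter__(self):
        return iter(self.channels)

    def __getitem__(self, label: str) -> LocalizationTable:
        for c in self.channels:
            if c.channel_label == label:
                return c
        raise KeyError(label)


@dataclass
class BindingSiteSet:
    """Cluster centres of one channel: the inferred lectin binding sites.

    ``sites`` columns: ``x_nm``, ``y_nm``, ``n_locs`` (>= 2), ``first_frame``,
    ``last_frame``.
    """

    channel_label: str
    sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["x_nm", "y_nm", "n_locs", "first_frame", "last_frame"]
        )
    )

    def __post_init__(self):
        self.sites = self.sites.reset_index(drop=True)
        if len(self.sites) and (self.sites["n_locs"].to_numpy() < 2).any():
            raise FormatError("binding sites require n_locs >= 2")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def xy(self) -> np.ndarray:
        return self.sites[["x_nm", "y_nm"]].to_numpy(dtype=np.float64)

    def with_sites(self, sites: pd.DataFrame) -> "BindingSiteSet":
        return BindingSiteSet(self.channel_label, sites)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
        if not isinstance(meta, dict):
            raise FormatError(f"sidecar {sc} is not a mapping")
        return meta
    return {}


def read_localizations(
    path: str | Path,
    pixel_size_nm: float | None = None,
    channel_label: str | None = None,
    strict: bool = False,
) -> LocalizationTable:
    """Read an HDF5 (``locs`` dataset) or CSV localization table.

    On-disk coordinates are in camera pixels; they are multiplied by
    ``pixel_size_nm`` (argument, else sidecar value) on load. Records with
    non-finite coordinates are dropped with a logged count, or rejected with a
    :class:`FormatError` when ``strict`` is true.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = [c for c in LOC_FIELDS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing mandatory field '{missing[0]}'")
    else:
        with h5py.File(path, "r") as fh:
            if "locs" not in fh:
                raise FormatError(f"{path}: missing mandatory dataset 'locs'")
            raw = fh["locs"][()]
        missing = [c for c in LOC_FIELDS if c not in (raw.dtype.names or ())]
        if missing:
            raise FormatError(f"{path}: missing mandatory field '{missing[0]}'")
        df = pd.DataFrame({c: raw[c] for c in raw.dtype.names})

    if pixel_size_nm is None:
        pixel_size_nm = meta.get("pixel_size_nm")
    if pixel_size_nm is None:
        raise ParameterError(
            f"{path}: pixel size unknown (no argument and no sidecar 'pixel_size_nm')"
        )
    if pixel_size_nm <= 0:
        raise ParameterError(f"pixel_size_nm must be > 0, got {pixel_size_nm}")

    bad = ~np.isfinite(df[["x", "y"]].to_numpy(dtype=np.float64)).all(axis=1)
    if bad.any():
        if strict:
            raise FormatError(f"{path}: {int(bad.sum())} record(s) with non-finite coordinates")
        logger.warning("%s: dropping %d record(s) with non-finite coordinates", path, bad.sum())
        df = df.loc[~bad]

    locs = pd.DataFrame(
        {
            "frame": df["frame"].to_numpy(dtype=np.int64),
            "x_nm": df["x"].to_numpy(dtype=np.float64) * pixel_size_nm,
            "y_nm": df["y"].to_numpy(dtype=np.float64) * pixel_size_nm,
            "photons": df["photons"].to_numpy(dtype=np.float64),
        }
    )
    n_frames = int(meta.get("n_frames", 0)) or (
        int(locs["frame"].max()) + 1 if len(locs) else DEFAULT_N_FRAMES
    )
    label = channel_label or meta.get("channel_label") or path.stem
    return LocalizationTable(label, n_frames, locs, float(pixel_size_nm))


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table (HDF5 ``locs`` dataset or CSV, by extension) + YAML sidecar.

    Coordinates are stored in camera pixels (``x_nm / pixel_size_nm``) as
    float64, so a write/read round trip is exact to floating precision.
    """
    path = Path(path)
    px = table.pixel_size_nm
    out = pd.DataFrame(
        {
            "frame": table.locs["frame"].to_numpy(),
            "x": table.locs["x_nm"].to_numpy() / px,
            "y": table.locs["y_nm"].to_numpy() / px,
            "photons": table.locs["photons"].to_numpy(),
        }
    )
    if path.suffix.lower() == ".csv":
        out.to_csv(path, index=False)
    else:
        rec = np.zeros(
            len(out),
            dtype=[("frame", "<i8"), ("x", "<f8"), ("y", "<f8"), ("photons", "<f8")],
        )
        for c in LOC_FIELDS:
            rec[c] = out[c].to_numpy()
        with h5py.File(path, "w") as fh:
            fh.create_dataset("locs", data=rec)
    meta = {
        "channel_label": table.channel_label,
        "n_frames": int(table.n_frames),
        "pixel_size_nm": float(px),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def write_binding_sites(sites: BindingSiteSet, path: str | Path) -> None:
    df = sites.sites.copy()
    df.insert(0, "channel", sites.channel_label)
    df.to_csv(path, index=False)


def read_binding_sites(path: str | Path) -> BindingSiteSet:
    df = pd.read_csv(path)
    label = str(df["channel"].iloc[0]) if len(df) else Path(path).stem
    return BindingSiteSet(label, df.drop(columns=["channel"], errors="ignore"))


def render_histogram_image(
    table: LocalizationTable, bin_nm: float, extent_nm: tuple[float, float] | None = None
) -> np.ndarray:
    """2D localization-count image for QC rendering.

    Returns an integer array (rows = y, columns = x) whose sum equals the
    number of in-bounds localizations. ``extent_nm`` is (width, height); by
    default it spans the data.
    """
    if bin_nm <= 0:
        raise ParameterError(f"bin_nm must be > 0, got {bin_nm}")
    xy = table.xy
    if extent_nm is None:
        if len(xy) == 0:
            return np.zeros((1, 1), dtype=np.int64)
        extent_nm = (float(xy[:, 0].max()) + bin_nm, float(xy[:, 1].max()) + bin_nm)
    x_edges = np.arange(0.0, extent_nm[0] + bin_nm, bin_nm)
    y_edges = np.arange(0.0, extent_nm[1] + bin_nm, bin_nm)
    img, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(y_edges, x_edges))
    return img.astype(np.int64)
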