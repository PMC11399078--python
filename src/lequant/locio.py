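"""Localization and molecule table I/O, clustering, and density estimation.

Coordinates are stored in nanometers internally.  On-disk tables (Picasso-style
HDF5 ``locs`` datasets and CSV files) hold camera-pixel coordinates and are
converted on read/write with a single scalar pixel size.

Clustering follows a neighbor-count local-maximum rule: a localization seeds a
cluster when its neighbor count within ``radius`` is maximal among its
neighbors; members are all localizations within ``radius`` of their nearest
seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import shapely
import yaml
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, box

from lequant.errors import DataError, FormatError, ParameterError

__all__ = [
    "LocalizationTable",
    "MoleculeSet",
    "ROI",
    "read_localizations",
    "write_localizations",
    "cluster_localizations",
    "weighted_center",
    "molecules_from_clusters",
    "binder_density",
]

LOC_FIELDS = ("frame", "x", "y", "photons", "lpx", "lpy")

#: fields scaled by the pixel size when converting between px and nm
_SPATIAL_FIELDS = ("x", "y", "lpx", "lpy")


@dataclass
class LocalizationTable:
    """Per-localization records for one imaging channel, coordinates in nm."""

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    photons: np.ndarray
    lpx: np.ndarray
    lpy: np.ndarray
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        for name in ("x", "y", "photons", "lpx", "lpy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.frame)
        for name in LOC_FIELDS:
            if len(getattr(self, name)) != n:
                raise DataError(f"field '{name}' has length {len(getattr(self, name))}, expected {n}")
        if n:
            if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
                raise DataError("non-finite coordinates in localization table")
            if (self.lpx <= 0).any() or (self.lpy <= 0).any():
                raise DataError("localization precisions must be strictly positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x, self.y])

    def subset(self, index: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(
            frame=self.frame[index],
            x=self.x[index],
            y=self.y[index],
            photons=self.photons[index],
            lpx=self.lpx[index],
            lpy=self.lpy[index],
            channel_label=self.channel_label,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in LOC_FIELDS})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, channel_label: str = "") -> "LocalizationTable":
        missing = [name for name in LOC_FIELDS if name not in df.columns]
        if missing:
            raise FormatError(f"missing required field(s): {', '.join(missing)}")
        return cls(
            frame=df["frame"].to_numpy(),
            x=df["x"].to_numpy(dtype=np.float64),
            y=df["y"].to_numpy(dtype=np.float64),
            photons=df["photons"].to_numpy(dtype=np.float64),
            lpx=df["lpx"].to_numpy(dtype=np.float64),
            lpy=df["lpy"].to_numpy(dtype=np.float64),
            channel_label=channel_label,
        )


class ROI:
    """Region of interest: a rectangle or simple polygon, coordinates in nm.

    Areas are reported in µm².  Containment includes the boundary.
    """

    def __init__(self, geometry: Polygon):
        if not isinstance(geometry, Polygon):
            raise ParameterError("ROI geometry must be a polygon")
        if not geometry.is_valid:
            raise ParameterError("ROI polygon must be simple (non-self-intersecting)")
        if geometry.area <= 0:
            raise ParameterError("ROI area must be positive")
        self.geometry = geometry

    @classmethod
    def rectangle(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "ROI":
        if not (xmax > xmin and ymax > ymin):
            raise ParameterError("rectangle ROI requires xmax > xmin and ymax > ymin")
        return cls(box(xmin, ymin, xmax, ymax))

    @classmethod
    def polygon(cls, vertices: Sequence[tuple[float, float]]) -> "ROI":
        return cls(Polygon(vertices))

    @classmethod
    def bounding(cls, x: np.ndarray, y: np.ndarray, pad_nm: float = 1.0) -> "ROI":
        """Bounding rectangle of a point set, padded so all points are interior."""
        if len(x) == 0:
            raise ParameterError("cannot build a bounding ROI from an empty point set")
        return cls.rectangle(
            float(np.min(x)) - pad_nm,
            float(np.min(y)) - pad_nm,
            float(np.max(x)) + pad_nm,
            float(np.max(y)) + pad_nm,
        )

    @property
    def area_nm2(self) -> float:
        return float(self.geometry.area)

    @property
    def area_um2(self) -> float:
        return self.area_nm2 / 1e6

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.geometry.bounds

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-ROI test (boundary counts as inside)."""
        return shapely.intersects_xy(self.geometry, np.asarray(x), np.asarray(y))

    def __repr__(self) -> str:  # pragma: no cover
        xmin, ymin, xmax, ymax = self.bounds
        return f"ROI(bounds=({xmin:.0f}, {ymin:.0f}, {xmax:.0f}, {ymax:.0f}) nm, area={self.area_um2:.2f} µm²)"


@dataclass
class MoleculeSet:
    """Clustered molecule centers with uncertainties, inside a region of interest."""

    molecule_id: np.ndarray
    xc: np.ndarray
    yc: np.ndarray
    n_locs: np.ndarray
    center_uncertainty: np.ndarray
    roi: ROI

    def __post_init__(self) -> None:
        self.molecule_id = np.asarray(self.molecule_id, dtype=np.int64)
        self.xc = np.asarray(self.xc, dtype=np.float64)
        self.yc = np.asarray(self.yc, dtype=np.float64)
        self.n_locs = np.asarray(self.n_locs, dtype=np.int64)
        self.center_uncertainty = np.asarray(self.center_uncertainty, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.molecule_id)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.xc, self.yc])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "molecule_id": self.molecule_id,
                "xc_nm": self.xc,
                "yc_nm": self.yc,
                "n_locs": self.n_locs,
                "center_uncertainty_nm": self.center_uncertainty,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, roi: ROI | None = None) -> "MoleculeSet":
        df = pd.read_csv(path, comment="#")
        required = ["molecule_id", "xc_nm", "yc_nm", "n_locs", "center_uncertainty_nm"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"missing required field(s): {', '.join(missing)}")
        if roi is None:
            if len(df):
                roi = ROI.bounding(df["xc_nm"].to_numpy(), df["yc_nm"].to_numpy())
            else:
                roi = ROI.rectangle(0.0, 0.0, 1.0, 1.0)
        return cls(
            molecule_id=df["molecule_id"].to_numpy(),
            xc=df["xc_nm"].to_numpy(),
            yc=df["yc_nm"].to_numpy(),
            n_locs=df["n_locs"].to_numpy(),
            center_uncertainty=df["center_uncertainty_nm"].to_numpy(),
            roi=roi,
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def read_localizations(
    path: str | Path,
    format: str | None = None,
    pixel_size_nm: float = 130.0,
    channel_label: str = "",
) -> LocalizationTable:
    """Read a localization table; px coordinates are converted to nm.

    Parameters
    ----------
    path
        HDF5 file with a ``locs`` record dataset (fields frame, x, y,
        photons, lpx, lpy; spatial fields in camera pixels) or a CSV with
        the same column names.
    format
        ``"hdf5"`` or ``"csv"``; inferred from the suffix when omitted.
    pixel_size_nm
        Effective camera pixel size used for the px → nm conversion.
    """
    if pixel_size_nm <= 0:
        raise ParameterError(f"pixel_size_nm must be positive, got {pixel_size_nm}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "locs" not in f:
                raise FormatError(f"{path}: no 'locs' dataset")
            locs = f["locs"][()]
        names = locs.dtype.names or ()
        missing = [name for name in LOC_FIELDS if name not in names]
        if missing:
            raise FormatError(f"{path}: missing required field(s): {', '.join(missing)}")
        df = pd.DataFrame({name: locs[name] for name in LOC_FIELDS})
    elif fmt == "csv":
        df = pd.read_csv(path, comment="#")
        missing = [name for name in LOC_FIELDS if name not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required field(s): {', '.join(missing)}")
    else:
        raise ParameterError(f"unknown format {fmt!r}; expected 'hdf5' or 'csv'")
    for name in _SPATIAL_FIELDS:
        df[name] = df[name].astype(np.float64) * pixel_size_nm
    return LocalizationTable.from_dataframe(df, channel_label=channel_label or path.stem)


def write_localizations(
    table: LocalizationTable,
    path: str | Path,
    format: str | None = None,
    pixel_size_nm: float = 130.0,
) -> None:
    """Write a localization table, converting nm back to camera pixels.

    HDF5 output is a Picasso-style ``locs`` record dataset plus a YAML
    sidecar recording the pixel size; CSV output carries a units comment line.
    """
    if pixel_size_nm <= 0:
        raise ParameterError(f"pixel_size_nm must be positive, got {pixel_size_nm}")
    path = Path(path)
    fmt = _infer_format(path, format)
    df = table.to_dataframe()
    for name in _SPATIAL_FIELDS:
        df[name] = df[name] / pixel_size_nm
    if fmt == "hdf5":
        dtype = np.dtype(
            [("frame", "u4"), ("x", "f8"), ("y", "f8"), ("photons", "f8"), ("lpx", "f8"), ("lpy", "f8")]
        )
        rec = np.zeros(len(df), dtype=dtype)
        for name in LOC_FIELDS:
            rec[name] = df[name].to_numpy()
        with h5py.File(path, "w") as f:
            f.create_dataset("locs", data=rec)
        meta = {
            "Pixelsize": float(pixel_size_nm),
            "Channel": table.channel_label,
            "Generated by": "lequant",
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write("# units: x,y,lpx,lpy in camera pixels; photons in counts\n")
            fh.write(f"# pixel_size_nm: {pixel_size_nm}\n")
            df.to_csv(fh, index=False)
    else:
        raise ParameterError(f"unknown format {fmt!r}; expected 'hdf5' or 'csv'")


def cluster_localizations(
    locs: LocalizationTable,
    radius: float,
    min_locs: int = 10,
    frame_spread_check: bool = False,
    min_frame_spread_fraction: float = 0.2,
) -> np.ndarray:
    """Assign localizations to circular clusters around local density maxima.

    Each localization's neighbor count within ``radius`` is computed; a
    localization seeds a cluster when no neighbor has a higher count (ties
    broken by lexicographic (x, y) position so the result is independent of
    row order).  Every localization joins its nearest seed within ``radius``,
    or is labeled noise (−1).  Clusters with fewer than ``min_locs`` members
    are dissolved into noise.

    With ``frame_spread_check`` enabled, clusters whose inter-quartile frame
    range spans less than ``min_frame_spread_fraction`` of the acquisition are
    discarded — transient sticking artifacts produce temporally compact
    clusters, genuine molecules are revisited throughout the acquisition.

    Returns
    -------
    ndarray of int
        Per-localization cluster id (dense, 0-based), −1 for noise.
    """
    if radius <= 0:
        raise ParameterError(f"radius must be positive, got {radius}")
    if min_locs < 1:
        raise ParameterError(f"min_locs must be >= 1, got {min_locs}")
    n = len(locs)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels

    xy = locs.xy
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, r=radius)
    counts = np.fromiter((len(nb) for nb in neighbors), dtype=np.int64, count=n)

    # rank by (count desc, x, y, row); a point seeds iff it holds the best
    # rank within its own neighborhood
    order = np.lexsort((np.arange(n), locs.y, locs.x, -counts))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    seed_mask = np.fromiter(
        (rank[i] == min(rank[j] for j in nb) for i, nb in enumerate(neighbors)),
        dtype=bool,
        count=n,
    )
    seeds = np.flatnonzero(seed_mask)
    if len(seeds) == 0:
        return labels

    seed_tree = cKDTree(xy[seeds])
    dist, nearest = seed_tree.query(xy, k=1, distance_upper_bound=radius)
    assigned = np.isfinite(dist)
    labels[assigned] = nearest[assigned]

    # enforce the minimum cluster size
    sizes = np.bincount(labels[labels >= 0], minlength=len(seeds))
    small = np.flatnonzero(sizes < min_locs)
    if len(small):
        labels[np.isin(labels, small)] = -1

    if frame_spread_check:
        total_frames = float(locs.frame.max()) + 1.0
        for cid in np.unique(labels[labels >= 0]):
            frames = locs.frame[labels == cid]
            iqr = np.percentile(frames, 75) - np.percentile(frames, 25)
            if iqr < min_frame_spread_fraction * total_frames:
                labels[labels == cid] = -1

    # dense relabeling, ordered by seed rank for determinism
    kept = np.unique(labels[labels >= 0])
    remap = np.full(len(seeds), -1, dtype=np.int64)
    remap[kept] = np.arange(len(kept))
    labels[labels >= 0] = remap[labels[labels >= 0]]
    return labels


def weighted_center(locs: LocalizationTable) -> tuple[float, float, float]:
    """Precision-weighted cluster center and its standard error.

    Weights are the squared inverse localization precisions per axis:
    ``xc = Σ(x_i/lpx_i²)/Σ(1/lpx_i²)`` (and analogously for y).  The center
    uncertainty is the root mean square of the per-axis standard errors
    ``sqrt(1/Σw)``.
    """
    if len(locs) == 0:
        raise DataError("cannot compute the center of an empty cluster")
    if (locs.lpx <= 0).any() or (locs.lpy <= 0).any():
        raise DataError("localization precisions must be strictly positive")
    wx = 1.0 / locs.lpx**2
    wy = 1.0 / locs.lpy**2
    xc = float(np.sum(locs.x * wx) / np.sum(wx))
    yc = float(np.sum(locs.y * wy) / np.sum(wy))
    sx2 = 1.0 / np.sum(wx)
    sy2 = 1.0 / np.sum(wy)
    return xc, yc, float(np.sqrt(0.5 * (sx2 + sy2)))


def molecules_from_clusters(
    locs: LocalizationTable,
    assignment: np.ndarray,
    roi: ROI | None = None,
) -> MoleculeSet:
    """Collapse a cluster assignment into one molecule per cluster.

    Molecules whose weighted center falls outside ``roi`` are dropped; ids are
    re-issued densely.  When ``roi`` is None the bounding rectangle of the
    centers is used.
    """
    assignment = np.asarray(assignment)
    valid = assignment >= 0
    cluster_ids = np.unique(assignment[valid])
    if len(cluster_ids):
        # vectorized weighted_center over all clusters at once
        lab = np.searchsorted(cluster_ids, assignment[valid])
        k = len(cluster_ids)
        wx = 1.0 / locs.lpx[valid] ** 2
        wy = 1.0 / locs.lpy[valid] ** 2
        swx = np.bincount(lab, weights=wx, minlength=k)
        swy = np.bincount(lab, weights=wy, minlength=k)
        xc = np.bincount(lab, weights=locs.x[valid] * wx, minlength=k) / swx
        yc = np.bincount(lab, weights=locs.y[valid] * wy, minlength=k) / swy
        unc = np.sqrt(0.5 * (1.0 / swx + 1.0 / swy))
        nl = np.bincount(lab, minlength=k)
    else:
        xc = yc = unc = np.empty(0)
        nl = np.empty(0, dtype=np.int64)
    if roi is None:
        roi = (
            ROI.bounding(xc, yc)
            if len(cluster_ids)
            else ROI.rectangle(0.0, 0.0, 1.0, 1.0)
        )
    inside = roi.contains(xc, yc) if len(cluster_ids) else np.zeros(0, dtype=bool)
    return MoleculeSet(
        molecule_id=np.arange(int(inside.sum())),
        xc=xc[inside],
        yc=yc[inside],
        n_locs=nl[inside],
        center_uncertainty=unc[inside],
        roi=roi,
    )


def binder_density(mols: MoleculeSet) -> float:
    """Molecule density in molecules per µm² over the set's ROI."""
    return len(mols) / mols.roi.area_um2
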