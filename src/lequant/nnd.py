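"""Nearest-neighbor distances within and across channels, and their
density-normalized histograms.

Distances are exact; a KD-tree is used for the neighbor queries so large
fields stay fast without approximation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from lequant.errors import ParameterError

__all__ = ["NNDHistogram", "cross_nnd", "self_nnd", "histogram_nnd", "default_bin_edges"]


def default_bin_edges(bin_width_nm: float = 10.0, d_max_nm: float = 1000.0) -> np.ndarray:
    """Uniform bin edges from 0 to ``d_max_nm`` (default 10 nm bins to 1 µm)."""
    return np.arange(0.0, d_max_nm + bin_width_nm / 2, bin_width_nm)


def _as_points(obj) -> np.ndarray:
    """Coerce an (n, 2) array, MoleculeSet, or PointField to coordinates.

    PointFields contribute only their detected points.
    """
    if hasattr(obj, "detected_xy"):
        pts = obj.detected_xy
    elif hasattr(obj, "xy"):
        pts = obj.xy
    else:
        pts = np.asarray(obj, dtype=np.float64)
    return np.asarray(pts, dtype=np.float64).reshape(-1, 2)


def cross_nnd(ref, target) -> np.ndarray:
    """Distance from each reference point to its nearest target point.

    Note the asymmetry: ``cross_nnd(a, b)`` and ``cross_nnd(b, a)`` differ in
    general (different lengths and values).
    """
    ref = _as_points(ref)
    target = _as_points(target)
    if len(target) == 0:
        raise ParameterError("cross_nnd: target point set is empty, no neighbor defined")
    if len(ref) == 0:
        return np.empty(0)
    dist, _ = cKDTree(target).query(ref, k=1)
    return np.asarray(dist, dtype=np.float64)


def self_nnd(points) -> np.ndarray:
    """Distance from each point to its nearest other point (self excluded)."""
    points = _as_points(points)
    if len(points) < 2:
        raise ParameterError("self_nnd requires at least 2 points")
    dist, _ = cKDTree(points).query(points, k=2)
    return np.asarray(dist[:, 1], dtype=np.float64)


@dataclass
class NNDHistogram:
    """Binned NND distribution, normalized as a probability density.

    Distances beyond the last bin edge are not discarded: they contribute to
    ``overflow_mass`` so that the in-range integral plus the overflow mass
    sums to one.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_points: int
    overflow_mass: float = 0.0
    raw_distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if len(self.density) != len(self.bin_edges) - 1:
            raise ParameterError("density must have one entry per bin")

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def total_mass(self) -> float:
        """In-range integral plus overflow; 1.0 whenever n_points > 0."""
        return float(np.sum(self.density * self.bin_widths) + self.overflow_mass)

    def to_dict(self) -> dict:
        return {
            "bin_edges_nm": self.bin_edges.tolist(),
            "density_per_nm": self.density.tolist(),
            "n_points": int(self.n_points),
            "overflow_mass": float(self.overflow_mass),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "NNDHistogram":
        return cls(
            bin_edges=np.asarray(d["bin_edges_nm"]),
            density=np.asarray(d["density_per_nm"]),
            n_points=int(d["n_points"]),
            overflow_mass=float(d.get("overflow_mass", 0.0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NNDHistogram":
        return cls.from_dict(json.loads(Path(path).read_text()))


def histogram_nnd(
    distances: np.ndarray,
    bin_edges: np.ndarray | None = None,
    keep_raw: bool = False,
) -> NNDHistogram:
    """Density-normalized histogram of nearest-neighbor distances.

    Normalization uses the total number of distances including any beyond the
    last edge, which are recorded as ``overflow_mass``.
    """
    distances = np.asarray(distances, dtype=np.float64).ravel()
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    if len(bin_edges) < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ParameterError("bin_edges must be strictly increasing with >= 2 entries")
    if len(distances) and (distances < 0).any():
        raise ParameterError("distances must be >= 0")
    n = len(distances)
    if n == 0:
        return NNDHistogram(
            bin_edges=bin_edges,
            density=np.zeros(len(bin_edges) - 1),
            n_points=0,
            overflow_mass=0.0,
            raw_distances=distances if keep_raw else None,
        )
    counts, _ = np.histogram(distances, bins=bin_edges)
    overflow = int(np.sum(distances > bin_edges[-1]))
    density = counts / (n * np.diff(bin_edges))
    return NNDHistogram(
        bin_edges=bin_edges,
        density=density,
        n_points=n,
        overflow_mass=overflow / n,
        raw_distances=distances if keep_raw else None,
    )
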