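"""CSR forward model: monomer/dimer point fields with linkage geometry,
positional uncertainty, and detection thinning.

Point counts are Poisson(density × area).  Dimer centers are drawn inside the
ROI; the two partners sit at ±d_off/2 from the center along a uniformly random
orientation, so the pair separation equals d_off exactly before positional
noise is applied.  Partner points that land slightly outside the ROI are kept
(no clipping) so edge effects match an experiment analyzed in the same ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from lequant.errors import ParameterError
from lequant.locio import ROI

__all__ = [
    "SimulationParams",
    "PointField",
    "realization_rng",
    "simulate_monomers",
    "simulate_dimers",
    "apply_uncertainty",
    "thin_by_detection",
    "simulate_two_channel_field",
    "simulate_single_channel_field",
]

MONOMER = 0
DIMER_PARTNER = 1

_PROVENANCE_NAMES = {MONOMER: "monomer", DIMER_PARTNER: "dimer_partner"}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the two-population CSR forward model.

    Densities are in molecules (or dimer entities) per µm²; distances in nm.
    ``labeling_efficiency`` is only used by the single-channel oligomer model.
    """

    roi: ROI
    rho_ref_mono: float = 0.0
    rho_target_mono: float = 0.0
    rho_dimer: float = 0.0
    d_off: float = 15.0
    uncertainty: float = 5.0
    labeling_efficiency: float = 1.0
    n_realizations: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rho_ref_mono", "rho_target_mono", "rho_dimer"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.d_off < 0:
            raise ParameterError("d_off must be >= 0")
        if self.uncertainty < 0:
            raise ParameterError("uncertainty must be >= 0")
        if not 0.0 <= self.labeling_efficiency <= 1.0:
            raise ParameterError("labeling_efficiency must be in [0, 1]")
        if self.n_realizations < 1:
            raise ParameterError("n_realizations must be >= 1")

    @classmethod
    def single_channel(
        cls,
        roi: ROI,
        rho_mono: float,
        rho_dimer: float,
        d_off: float = 15.0,
        uncertainty: float = 5.0,
        labeling_efficiency: float = 1.0,
        n_realizations: int = 1,
        seed: int = 0,
    ) -> "SimulationParams":
        """Parameters for a single-channel field: monomers plus homo-dimers.

        The monomer density is carried in ``rho_ref_mono``.
        """
        return cls(
            roi=roi,
            rho_ref_mono=rho_mono,
            rho_target_mono=0.0,
            rho_dimer=rho_dimer,
            d_off=d_off,
            uncertainty=uncertainty,
            labeling_efficiency=labeling_efficiency,
            n_realizations=n_realizations,
            seed=seed,
        )


@dataclass
class PointField:
    """A set of molecule positions for one channel.

    ``provenance`` tags each point as monomer (0) or dimer partner (1).
    ``dimer_pairing`` holds, for each dimer partner, the index of its partner
    (−1 for monomers); for two-channel simulations the index refers to the
    companion channel's field, for single-channel fields to this field itself.
    ``detected`` marks points surviving detection thinning.
    """

    channel: str
    points: np.ndarray
    provenance: np.ndarray
    dimer_pairing: np.ndarray
    detected: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        n = len(self.points)
        self.provenance = np.asarray(self.provenance, dtype=np.int8)
        self.dimer_pairing = np.asarray(self.dimer_pairing, dtype=np.int64)
        self.detected = np.asarray(self.detected, dtype=bool)
        for name in ("provenance", "dimer_pairing", "detected"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"PointField.{name} length mismatch")

    @classmethod
    def empty(cls, channel: str) -> "PointField":
        return cls(
            channel=channel,
            points=np.empty((0, 2)),
            provenance=np.empty(0, dtype=np.int8),
            dimer_pairing=np.empty(0, dtype=np.int64),
            detected=np.empty(0, dtype=bool),
        )

    @classmethod
    def from_points(
        cls, channel: str, points: np.ndarray, provenance: int = MONOMER
    ) -> "PointField":
        points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        n = len(points)
        return cls(
            channel=channel,
            points=points,
            provenance=np.full(n, provenance, dtype=np.int8),
            dimer_pairing=np.full(n, -1, dtype=np.int64),
            detected=np.ones(n, dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points

    @property
    def detected_xy(self) -> np.ndarray:
        return self.points[self.detected]

    def concat(self, other: "PointField") -> "PointField":
        """Concatenate two fields of the same channel; pairing indices in
        ``other`` that point into a companion field are preserved as-is."""
        return PointField(
            channel=self.channel,
            points=np.vstack([self.points, other.points]),
            provenance=np.concatenate([self.provenance, other.provenance]),
            dimer_pairing=np.concatenate([self.dimer_pairing, other.dimer_pairing]),
            detected=np.concatenate([self.detected, other.detected]),
        )


def realization_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible RNG stream for one realization."""
    return np.random.default_rng([int(seed), int(index)])


def _uniform_in_roi(n: int, roi: ROI, rng: np.random.Generator) -> np.ndarray:
    """Draw n points uniformly inside the ROI by rejection from its bounds."""
    if n == 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = roi.bounds
    out = np.empty((n, 2))
    filled = 0
    # acceptance ratio = roi area / bbox area; guaranteed 1 for rectangles
    frac = max(roi.area_nm2 / ((xmax - xmin) * (ymax - ymin)), 1e-6)
    while filled < n:
        m = int(np.ceil((n - filled) / frac * 1.1)) + 16
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = cand[roi.contains(cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_monomers(
    density: float, roi: ROI, rng: np.random.Generator, channel: str = "single"
) -> PointField:
    """CSR monomer field: Poisson count, positions uniform over the ROI."""
    if density < 0:
        raise ParameterError("density must be >= 0")
    n = rng.poisson(density * roi.area_um2)
    return PointField.from_points(channel, _uniform_in_roi(n, roi, rng))


def simulate_dimers(
    density: float,
    d_off: float,
    roi: ROI,
    rng: np.random.Generator,
    channel_a: str = "reference",
    channel_b: str = "target",
) -> tuple[PointField, PointField]:
    """CSR dimer field: centers uniform in the ROI, partners at ±d_off/2
    along a uniformly random orientation (exact separation d_off pre-noise)."""
    if density < 0:
        raise ParameterError("density must be >= 0")
    if d_off < 0:
        raise ParameterError("d_off must be >= 0")
    n = rng.poisson(density * roi.area_um2)
    centers = _uniform_in_roi(n, roi, rng)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    half = 0.5 * d_off * np.column_stack([np.cos(theta), np.sin(theta)])
    pairing = np.arange(n, dtype=np.int64)
    make = lambda ch, pts: PointField(
        channel=ch,
        points=pts,
        provenance=np.full(n, DIMER_PARTNER, dtype=np.int8),
        dimer_pairing=pairing.copy(),
        detected=np.ones(n, dtype=bool),
    )
    return make(channel_a, centers + half), make(channel_b, centers - half)


def apply_uncertainty(
    field: PointField, sigma: float, rng: np.random.Generator
) -> PointField:
    """Displace every point by isotropic Gaussian noise (per-axis sd sigma)."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0 or len(field) == 0:
        return replace(field, points=field.points.copy())
    return replace(field, points=field.points + rng.normal(0.0, sigma, field.points.shape))


def thin_by_detection(
    field: PointField, fraction: float, rng: np.random.Generator
) -> PointField:
    """Mark each point detected independently with probability ``fraction``.

    Points are retained (with pairing intact); consumers read ``detected``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError("fraction must be in [0, 1]")
    keep = rng.random(len(field)) < fraction
    return replace(field, detected=field.detected & keep)


def simulate_two_channel_field(
    params: SimulationParams, rng: np.random.Generator
) -> tuple[PointField, PointField]:
    """Reference and target channels: monomers plus hetero-dimer partners.

    Pairing indices refer to positions in the companion channel's field.
    Positional uncertainty is applied to every point; no thinning (channel
    densities are matched to observed densities by construction).
    """
    ref_mono = simulate_monomers(params.rho_ref_mono, params.roi, rng, "reference")
    tgt_mono = simulate_monomers(params.rho_target_mono, params.roi, rng, "target")
    dim_a, dim_b = simulate_dimers(params.rho_dimer, params.d_off, params.roi, rng)
    # offset pairing so indices address the concatenated companion field
    dim_a.dimer_pairing += len(tgt_mono)
    dim_b.dimer_pairing += len(ref_mono)
    ref = apply_uncertainty(ref_mono.concat(dim_a), params.uncertainty, rng)
    target = apply_uncertainty(tgt_mono.concat(dim_b), params.uncertainty, rng)
    return ref, target


def simulate_single_channel_field(
    params: SimulationParams, rng: np.random.Generator
) -> PointField:
    """Single imaged channel: monomers plus both homo-dimer partners, with
    positional uncertainty and detection thinning at ``labeling_efficiency``.

    The monomer density is read from ``params.rho_ref_mono`` (see
    :meth:`SimulationParams.single_channel`); each dimer entity contributes
    two molecules, so the expected detected density is
    ``(rho_mono + 2·rho_dimer) × labeling_efficiency``.
    """
    mono = simulate_monomers(params.rho_ref_mono, params.roi, rng, "single")
    dim_a, dim_b = simulate_dimers(
        params.rho_dimer, params.d_off, params.roi, rng, "single", "single"
    )
    n_mono, n_dim = len(mono), len(dim_a)
    # self-referential pairing inside the concatenated field
    dim_a.dimer_pairing += n_mono + n_dim
    dim_b.dimer_pairing += n_mono
    out = mono.concat(dim_a).concat(dim_b)
    out = apply_uncertainty(out, params.uncertainty, rng)
    return thin_by_detection(out, params.labeling_efficiency, rng)
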