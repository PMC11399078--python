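"""Synthetic-data generator: ground-truth molecule fields and realistic
localization tables, so every pipeline stage is testable without downloads.

Only the spatial statistics the analysis consumes are emulated — each
molecule becomes a cloud of localizations with Gaussian scatter at the drawn
precision.  Binding kinetics, photophysics and camera noise are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lequant.errors import ParameterError
from lequant.locio import LocalizationTable
from lequant.simulate import (
    PointField,
    SimulationParams,
    simulate_two_channel_field,
)

__all__ = ["FixtureConfig", "generate_ground_truth", "generate_localizations", "write_truth"]


@dataclass(frozen=True)
class FixtureConfig:
    """Configuration of a synthetic two-channel localization fixture.

    ``loc_precision_nm`` is either a scalar (constant precision) or a
    ``(mean, sd)`` pair of a lognormal distribution.
    """

    sim: SimulationParams
    mean_locs_per_molecule: float = 20.0
    loc_precision_nm: float | tuple[float, float] = 5.0
    n_frames: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_locs_per_molecule <= 0:
            raise ParameterError("mean_locs_per_molecule must be positive")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")


def generate_ground_truth(
    config: FixtureConfig,
) -> tuple[PointField, PointField, dict]:
    """Simulate the two-channel ground truth and its truth record.

    The truth record stores per-molecule population tags, the dimer pairing,
    and the true labeling efficiency implied by the densities,
    ``rho_dimer / (rho_ref_mono + rho_dimer)``.
    """
    rng = np.random.default_rng(config.seed)
    ref, target = simulate_two_channel_field(config.sim, rng)
    denom = config.sim.rho_ref_mono + config.sim.rho_dimer
    true_le = config.sim.rho_dimer / denom if denom > 0 else 0.0
    truth = {
        "true_labeling_efficiency": true_le,
        "rho_ref_mono_um2": config.sim.rho_ref_mono,
        "rho_target_mono_um2": config.sim.rho_target_mono,
        "rho_dimer_um2": config.sim.rho_dimer,
        "d_off_nm": config.sim.d_off,
        "uncertainty_nm": config.sim.uncertainty,
        "seed": config.seed,
        "n_ref_molecules": len(ref),
        "n_target_molecules": len(target),
        "ref_provenance": ref.provenance.tolist(),
        "target_provenance": target.provenance.tolist(),
        "ref_pairing": ref.dimer_pairing.tolist(),
        "target_pairing": target.dimer_pairing.tolist(),
        "ref_points_nm": ref.points.tolist(),
        "target_points_nm": target.points.tolist(),
    }
    return ref, target, truth


def _draw_precisions(
    spec: float | tuple[float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    mean, sd = spec
    if mean <= 0:
        raise ParameterError("lognormal precision mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def generate_localizations(
    field: PointField,
    config: FixtureConfig,
    rng: np.random.Generator | None = None,
) -> LocalizationTable:
    """Expand each detected molecule into a cloud of localizations.

    Per molecule the localization count is Poisson (truncated to >= 1 so
    every ground-truth molecule is in principle recoverable — detection
    failures are modeled exclusively by thinning upstream); each localization
    is offset by per-axis Gaussian noise at its drawn precision, and frames
    are uniform over the acquisition.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    centers = field.detected_xy
    n_mol = len(centers)
    counts = rng.poisson(config.mean_locs_per_molecule, n_mol)
    while (counts == 0).any():  # zero-truncated Poisson by redrawing
        zeros = counts == 0
        counts[zeros] = rng.poisson(config.mean_locs_per_molecule, int(zeros.sum()))
    total = int(counts.sum())
    mol_index = np.repeat(np.arange(n_mol), counts)
    precisions = _draw_precisions(config.loc_precision_nm, total, rng)
    # stored precisions must stay positive even in the degenerate zero-noise case
    lp = np.maximum(precisions, 1e-9)
    offsets = rng.normal(0.0, 1.0, (total, 2)) * precisions[:, None]
    xy = centers[mol_index] + offsets
    return LocalizationTable(
        frame=rng.integers(0, config.n_frames, total),
        x=xy[:, 0],
        y=xy[:, 1],
        photons=rng.gamma(2.0, 2500.0, total),
        lpx=lp,
        lpy=lp,
        channel_label=field.channel,
    )


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2))
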