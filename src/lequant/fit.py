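"""Least-squares estimation of labeling efficiency and dimer fractions.

Both fits share one design: scan a one-dimensional candidate grid, and for
each candidate average the NND histogram of ``n_realizations`` simulated CSR
fields whose densities are constrained to match the experimentally observed
channel densities.  Common random numbers (the same per-realization seeds for
every candidate) keep the Monte-Carlo residual curve smooth so the argmin is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from lequant.errors import ParameterError
from lequant.locio import ROI
from lequant.nnd import NNDHistogram, cross_nnd, histogram_nnd, self_nnd
from lequant.simulate import (
    SimulationParams,
    realization_rng,
    simulate_single_channel_field,
    simulate_two_channel_field,
)

__all__ = [
    "FitConfig",
    "LEFitResult",
    "DimerFitResult",
    "labeling_efficiency",
    "fit_labeling_efficiency",
    "fit_dimer_fraction",
    "correct_dimer_fraction",
]


def labeling_efficiency(n_ref: float, n_ref_target: float) -> float:
    """Fraction of reference-positive constructs that also carry the target:
    ``n_ref_target / (n_ref + n_ref_target)``."""
    if n_ref < 0 or n_ref_target < 0:
        raise ParameterError("counts must be >= 0")
    total = n_ref + n_ref_target
    if total == 0:
        raise ParameterError("labeling_efficiency undefined for zero total count")
    return n_ref_target / total


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the grid-scan least-squares fit.

    ``d_max_nm`` restricts the residual to short distances — the long tail
    carries only density information already matched by construction.
    """

    grid_step: float = 0.01
    n_realizations: int = 20
    d_max_nm: float = 500.0
    seed: int = 0
    refine: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.grid_step <= 0.5:
            raise ParameterError("grid_step must be in (0, 0.5]")
        if self.n_realizations < 1:
            raise ParameterError("n_realizations must be >= 1")
        if self.d_max_nm <= 0:
            raise ParameterError("d_max_nm must be positive")


def _residual_mask(bin_edges: np.ndarray, d_max_nm: float) -> np.ndarray:
    return bin_edges[1:] <= d_max_nm + 1e-9


def _mean_sim_density(hists: list[np.ndarray]) -> np.ndarray:
    return np.mean(np.asarray(hists), axis=0)


def _parabolic_refine(grid: np.ndarray, residuals: np.ndarray, i: int) -> float:
    """Quadratic interpolation of the residual minimum (within one grid step)."""
    if i == 0 or i == len(grid) - 1:
        return float(grid[i])
    y0, y1, y2 = residuals[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(grid[i])
    shift = 0.5 * (y0 - y2) / denom
    step = grid[i + 1] - grid[i]
    return float(np.clip(grid[i] + shift * step, grid[i - 1], grid[i + 1]))


@dataclass
class LEFitResult:
    """Result of the cross-NND labeling-efficiency fit."""

    labeling_efficiency: float
    p_ref: float
    p_ref_target: float
    grid: np.ndarray
    residual_curve: np.ndarray
    best_residual: float
    n_realizations_used: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "labeling_efficiency": self.labeling_efficiency,
            "p_ref": self.p_ref,
            "p_ref_target": self.p_ref_target,
            "grid": np.asarray(self.grid).tolist(),
            "residual_curve": np.asarray(self.residual_curve).tolist(),
            "best_residual": self.best_residual,
            "n_realizations_used": self.n_realizations_used,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_labeling_efficiency(
    exp_hist: NNDHistogram,
    rho_ref_obs: float,
    rho_target_obs: float,
    d_off: float,
    uncertainty: float,
    roi: ROI,
    config: FitConfig = FitConfig(),
) -> LEFitResult:
    """Estimate labeling efficiency from a reference→target cross-NND histogram.

    Candidate efficiencies are scanned over [0, LE_max] with
    ``LE_max = min(1, rho_target_obs/rho_ref_obs)``.  For each candidate the
    simulated densities are matched to the observed ones:
    ``rho_dimer = LE·rho_ref_obs``, ``rho_ref_mono = rho_ref_obs − rho_dimer``,
    ``rho_target_mono = rho_target_obs − rho_dimer``.  The candidate whose
    mean simulated cross-NND histogram has the smallest sum of squared per-bin
    density differences (over bins up to ``d_max_nm``) wins.
    """
    if rho_ref_obs <= 0 or rho_target_obs <= 0:
        raise ParameterError("observed densities must be positive")
    if exp_hist.n_points <= 0:
        raise ParameterError("experimental histogram is empty")
    if roi.area_um2 <= 0:
        raise ParameterError("ROI area must be positive")

    le_max = min(1.0, rho_target_obs / rho_ref_obs)
    grid = np.arange(0.0, le_max + config.grid_step / 2, config.grid_step)
    grid = np.clip(grid, 0.0, le_max)
    if len(grid) < 2:
        raise ParameterError("degenerate candidate grid; decrease grid_step")

    edges = exp_hist.bin_edges
    mask = _residual_mask(edges, config.d_max_nm)
    residuals = np.empty(len(grid))
    for gi, le in enumerate(grid):
        rho_dimer = le * rho_ref_obs
        params = SimulationParams(
            roi=roi,
            rho_ref_mono=max(rho_ref_obs - rho_dimer, 0.0),
            rho_target_mono=max(rho_target_obs - rho_dimer, 0.0),
            rho_dimer=rho_dimer,
            d_off=d_off,
            uncertainty=uncertainty,
        )
        sim_dens = []
        for k in range(config.n_realizations):
            rng = realization_rng(config.seed, k)
            ref, target = simulate_two_channel_field(params, rng)
            if len(target) == 0 or len(ref) == 0:
                sim_dens.append(np.zeros(len(edges) - 1))
                continue
            d = cross_nnd(ref, target)
            sim_dens.append(histogram_nnd(d, edges).density)
        mean_dens = _mean_sim_density(sim_dens)
        residuals[gi] = float(np.sum((mean_dens[mask] - exp_hist.density[mask]) ** 2))

    best = int(np.argmin(residuals))
    le_hat = _parabolic_refine(grid, residuals, best) if config.refine else float(grid[best])
    return LEFitResult(
        labeling_efficiency=le_hat,
        p_ref=1.0 - le_hat,
        p_ref_target=le_hat,
        grid=grid,
        residual_curve=residuals,
        best_residual=float(residuals[best]),
        n_realizations_used=config.n_realizations,
        seed=config.seed,
    )


@dataclass
class DimerFitResult:
    """Result of the self-NND monomer/dimer mixture fit.

    ``dimer_fraction`` is the fraction of molecules residing in dimers,
    ``2·rho_dimer / (rho_mono + 2·rho_dimer)``; the entity-based alternative
    is exposed as :attr:`dimer_fraction_entities`.
    """

    dimer_fraction: float
    rho_mono: float
    rho_dimer: float
    labeling_efficiency: float
    apparent: bool
    grid: np.ndarray
    residual_curve: np.ndarray
    best_residual: float
    seed: int
    # inputs retained so a corrected re-fit can reuse them
    exp_hist: NNDHistogram | None = None
    rho_obs: float | None = None
    d_off: float | None = None
    uncertainty: float | None = None
    roi: ROI | None = None
    config: FitConfig | None = None
    apparent_result: "DimerFitResult | None" = None

    @property
    def dimer_fraction_entities(self) -> float:
        """Dimer entities among all entities: rho_dimer/(rho_mono + rho_dimer)."""
        denom = self.rho_mono + self.rho_dimer
        return self.rho_dimer / denom if denom > 0 else 0.0

    def to_dict(self) -> dict:
        d = {
            "dimer_fraction": self.dimer_fraction,
            "dimer_fraction_entities": self.dimer_fraction_entities,
            "rho_mono_um2": self.rho_mono,
            "rho_dimer_um2": self.rho_dimer,
            "labeling_efficiency": self.labeling_efficiency,
            "apparent": self.apparent,
            "grid": np.asarray(self.grid).tolist(),
            "residual_curve": np.asarray(self.residual_curve).tolist(),
            "best_residual": self.best_residual,
            "seed": self.seed,
        }
        if self.apparent_result is not None:
            d["apparent_result"] = self.apparent_result.to_dict()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def fit_dimer_fraction(
    exp_hist: NNDHistogram,
    rho_obs: float,
    labeling_efficiency: float,
    d_off: float,
    uncertainty: float,
    roi: ROI,
    config: FitConfig = FitConfig(),
) -> DimerFitResult:
    """Estimate the dimer fraction from a single-channel self-NND histogram.

    Candidate molecule-dimer-fractions f are scanned over [0, 1].  Each f
    fixes the ground-truth densities through the observed-density constraint
    ``(rho_mono + 2·rho_dimer) × labeling_efficiency = rho_obs``; the forward
    model simulates monomers plus homo-dimers, thins by the labeling
    efficiency, and self-NND histograms are compared by least squares.  An
    "apparent" fit is obtained by passing ``labeling_efficiency = 1``.
    """
    if rho_obs <= 0:
        raise ParameterError("observed density must be positive")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ParameterError("labeling_efficiency must be in (0, 1]")
    if exp_hist.n_points <= 0:
        raise ParameterError("experimental histogram is empty")

    rho_total = rho_obs / labeling_efficiency  # ground-truth molecule density
    grid = np.arange(0.0, 1.0 + config.grid_step / 2, config.grid_step)
    grid = np.clip(grid, 0.0, 1.0)
    edges = exp_hist.bin_edges
    mask = _residual_mask(edges, config.d_max_nm)
    residuals = np.empty(len(grid))
    for gi, f in enumerate(grid):
        rho_dimer = 0.5 * f * rho_total
        rho_mono = (1.0 - f) * rho_total
        params = SimulationParams.single_channel(
            roi=roi,
            rho_mono=rho_mono,
            rho_dimer=rho_dimer,
            d_off=d_off,
            uncertainty=uncertainty,
            labeling_efficiency=labeling_efficiency,
        )
        sim_dens = []
        for k in range(config.n_realizations):
            rng = realization_rng(config.seed, k)
            fld = simulate_single_channel_field(params, rng)
            pts = fld.detected_xy
            if len(pts) < 2:
                sim_dens.append(np.zeros(len(edges) - 1))
                continue
            sim_dens.append(histogram_nnd(self_nnd(pts), edges).density)
        mean_dens = _mean_sim_density(sim_dens)
        residuals[gi] = float(np.sum((mean_dens[mask] - exp_hist.density[mask]) ** 2))

    best = int(np.argmin(residuals))
    f_hat = _parabolic_refine(grid, residuals, best) if config.refine else float(grid[best])
    return DimerFitResult(
        dimer_fraction=f_hat,
        rho_mono=(1.0 - f_hat) * rho_total,
        rho_dimer=0.5 * f_hat * rho_total,
        labeling_efficiency=labeling_efficiency,
        apparent=labeling_efficiency >= 1.0,
        grid=grid,
        residual_curve=residuals,
        best_residual=float(residuals[best]),
        seed=config.seed,
        exp_hist=exp_hist,
        rho_obs=rho_obs,
        d_off=d_off,
        uncertainty=uncertainty,
        roi=roi,
        config=config,
    )


def correct_dimer_fraction(
    apparent_fit: DimerFitResult, labeling_efficiency: float
) -> DimerFitResult:
    """Re-run an apparent (LE = 1) dimer fit with the measured labeling
    efficiency on the same histogram and configuration."""
    if not apparent_fit.apparent:
        raise ParameterError("correct_dimer_fraction expects an apparent fit")
    if not 0.0 < labeling_efficiency <= 1.0:
        raise ParameterError("labeling_efficiency must be in (0, 1]")
    if apparent_fit.exp_hist is None:
        raise ParameterError("apparent fit does not retain its inputs")
    corrected = fit_dimer_fraction(
        exp_hist=apparent_fit.exp_hist,
        rho_obs=apparent_fit.rho_obs,
        labeling_efficiency=labeling_efficiency,
        d_off=apparent_fit.d_off,
        uncertainty=apparent_fit.uncertainty,
        roi=apparent_fit.roi,
        config=apparent_fit.config,
    )
    corrected.apparent = False
    corrected.apparent_result = apparent_fit
    return corrected
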