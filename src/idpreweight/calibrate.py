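"""Three-step, single-free-parameter calibration of restraint strengths.

The only scientific knob is the Kish-ratio threshold (default 0.10): the
fraction of the prior ensemble that must survive reweighting.  The protocol:

1. estimate sigma_MD for every data point from the per-frame series
   (blocking analysis);
2. for each data type alone, find the smallest per-type regularization
   sigma_reg whose reweighted ensemble keeps K >= threshold;
3. restrain with all data types at once, rescaling every per-type sigma_reg
   by a common factor, and find the smallest global factor whose final
   ensemble keeps K >= threshold.

The global factor rescales the per-type sigma_reg values (not the composed
sigma_i), so sigma_i = sqrt(sigma_MD^2 + (sigma_reg,type * global)^2).

K is empirically non-decreasing in sigma_reg (weaker restraints perturb the
prior less), which justifies the bracketing grid + bisection search used
here.  The search returns the feasible (K >= threshold) end of the final
bracket, so the threshold guarantee holds for every successful run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import ExperimentalDataset, ObservableBlock, normalize_weights
from .errors import flyvbjerg_sigma
from .maxent import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOLERANCE,
    LagrangeState,
    ReweightResult,
    solve,
)

__all__ = [
    "CalibrationResult",
    "CalibrationError",
    "SigmaGridSpec",
    "calibrate_per_type",
    "calibrate_global",
    "run_protocol",
]

log = logging.getLogger(__name__)

DEFAULT_KISH_TARGET = 0.10


class CalibrationError(RuntimeError):
    """No regularization value on the search grid reaches the Kish target."""

    def __init__(self, message: str, scan_trace=None):
        super().__init__(message)
        self.scan_trace = scan_trace or []


@dataclass
class SigmaGridSpec:
    """Log-spaced bracketing grid + bisection refinement for sigma searches."""

    lo: float = 1e-3          # grid bounds, in units of the block's data scale
    hi: float = 1e3
    n_points: int = 40
    max_bisect: int = 30
    rel_precision: float = 1e-3

    def grid(self, scale: float = 1.0) -> np.ndarray:
        return np.geomspace(self.lo * scale, self.hi * scale, self.n_points)


@dataclass
class CalibrationResult:
    kish_target: float
    per_type_sigma_reg: dict[str, float]
    sigma_reg_global: float
    final: ReweightResult
    scan_trace: list[tuple[float, float, dict[str, float]]] = field(default_factory=list)
    sigma_md: dict[str, np.ndarray] = field(default_factory=dict)


def _scaled_dataset(dataset: ExperimentalDataset, factor: float) -> ExperimentalDataset:
    return ExperimentalDataset(
        [b.with_sigma_reg(b.sigma_reg * factor) for b in dataset]
    )


def _search_min_sigma(
    evaluate,
    grid: np.ndarray,
    kish_target: float,
    grid_spec: SigmaGridSpec,
    trace: list,
):
    """Smallest x on a refined log grid with evaluate(x).kish >= kish_target.

    ``evaluate(x, lambda0)`` maps a sigma value (with optional warm-start
    multipliers) to a ReweightResult.  The grid is walked from the largest
    (weakest-restraint) value downward, warm-starting each solve from its
    neighbor, until the Kish ratio first drops below target; bisection then
    refines the bracketing interval.  Returns (x, ReweightResult at x).
    """
    res = evaluate(grid[-1], None)
    trace.append((float(grid[-1]), res.kish, dict(res.per_block_rmse)))
    if res.kish < kish_target:
        raise CalibrationError(
            f"largest grid sigma {grid[-1]:.3g} still gives Kish "
            f"{res.kish:.4f} < target {kish_target}",
            scan_trace=trace,
        )
    feasible = res
    lo = None
    for i in range(len(grid) - 2, -1, -1):
        lam = feasible.lambda_state.lambdas
        res = evaluate(grid[i], lam)
        trace.append((float(grid[i]), res.kish, dict(res.per_block_rmse)))
        if res.kish >= kish_target:
            feasible = res
        else:
            lo, hi = float(grid[i]), float(grid[i + 1])
            break
    else:
        return float(grid[0]), feasible

    best = feasible
    for _ in range(grid_spec.max_bisect):
        if (hi - lo) <= grid_spec.rel_precision * hi:
            break
        mid = float(np.sqrt(lo * hi))  # bisect in log space
        res = evaluate(mid, best.lambda_state.lambdas)
        trace.append((mid, res.kish, dict(res.per_block_rmse)))
        if res.kish >= kish_target:
            hi, best = mid, res
        else:
            lo = mid
    return hi, best


def calibrate_per_type(
    prior,
    block: ObservableBlock,
    kish_target: float = DEFAULT_KISH_TARGET,
    grid_spec: SigmaGridSpec | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[float, list]:
    """Step 2: smallest sigma_reg keeping K >= target with this block alone.

    Returns (sigma_reg, scan trace of (sigma, K, rmse) triples).
    """
    if not 0 < kish_target <= 1:
        raise ValueError("kish_target must be in (0, 1]")
    grid_spec = grid_spec or SigmaGridSpec()
    prior = normalize_weights(prior)

    # scale-aware bracket: median absolute prior misfit of this block
    misfit = np.abs(block.exp_values - block.predictions.T @ prior)
    scale = float(np.median(misfit))
    if scale <= 0:
        scale = float(np.max(misfit)) or 1.0

    trace: list = []

    def evaluate(sig_reg, lambda0=None):
        ds = ExperimentalDataset([block.with_sigma_reg(sig_reg)])
        return solve(prior, ds, tolerance=tolerance, max_iter=max_iter,
                     lambda0=lambda0)

    sigma, _ = _search_min_sigma(
        evaluate, grid_spec.grid(scale), kish_target, grid_spec, trace
    )
    log.info("per-type sigma_reg[%s] = %.4g", block.data_type, sigma)
    return sigma, trace


def calibrate_global(
    prior,
    dataset: ExperimentalDataset,
    per_type_sigma_reg: dict[str, float],
    kish_target: float = DEFAULT_KISH_TARGET,
    grid_spec: SigmaGridSpec | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[float, ReweightResult, list]:
    """Step 3: smallest global factor on the per-type sigma_reg keeping K >= target.

    Returns (sigma_reg_global, final ReweightResult, scan trace).
    """
    grid_spec = grid_spec or SigmaGridSpec()
    prior = normalize_weights(prior)
    base = ExperimentalDataset(
        [b.with_sigma_reg(per_type_sigma_reg[b.data_type]) for b in dataset]
    )
    trace: list = []

    def evaluate(factor, lambda0=None):
        return solve(prior, _scaled_dataset(base, factor),
                     tolerance=tolerance, max_iter=max_iter, lambda0=lambda0)

    factor, result = _search_min_sigma(
        evaluate, grid_spec.grid(1.0), kish_target, grid_spec, trace
    )
    log.info("sigma_reg_global = %.4g (final K = %.4f)", factor, result.kish)
    return factor, result, trace


def run_protocol(
    prior,
    dataset: ExperimentalDataset,
    kish_target: float = DEFAULT_KISH_TARGET,
    grid_spec: SigmaGridSpec | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    estimate_sigma_md: bool = True,
) -> CalibrationResult:
    """Run the full three-step protocol and return the calibrated ensemble.

    Blocks lacking ``sigma_md`` get it from blocking analysis of their
    per-frame prediction series (step 1).  ``kish_target=1.0`` is the exact
    no-reweighting boundary: only uniform weights have K=1, so the prior is
    returned untouched with all multipliers zero.
    """
    if not 0 < kish_target <= 1:
        raise ValueError("kish_target must be in (0, 1]")
    prior = normalize_weights(prior)
    if dataset.n_frames < 8:
        raise ValueError("protocol needs at least 8 frames")

    sigma_md_map: dict[str, np.ndarray] = {}
    blocks = []
    for block in dataset:
        if block.sigma_md is None and estimate_sigma_md:
            smd = np.array(
                [flyvbjerg_sigma(block.predictions[:, i])[0]
                 for i in range(block.n_observables)]
            )
            block = ObservableBlock(
                data_type=block.data_type,
                predictions=block.predictions,
                exp_values=block.exp_values,
                sigma_md=smd,
                sigma_reg=block.sigma_reg,
                observable_ids=block.observable_ids,
                exp_error=block.exp_error,
                units=block.units,
            )
        sigma_md_map[block.data_type] = (
            block.sigma_md if block.sigma_md is not None
            else np.zeros(block.n_observables)
        )
        blocks.append(block)
    dataset = ExperimentalDataset(blocks)

    if kish_target >= 1.0:
        # only the unperturbed ensemble attains K = 1
        lam = np.zeros(dataset.total_observables)
        from .ensemble import kish_ratio

        per_block_rmse = {}
        restrained = {}
        for b in dataset:
            avg = b.predictions.T @ prior
            restrained[b.data_type] = avg
            per_block_rmse[b.data_type] = float(
                np.sqrt(np.mean((avg - b.exp_values) ** 2))
            )
        final = ReweightResult(
            weights=prior,
            kish=kish_ratio(prior),
            lambda_state=LagrangeState(lam, 0.0, 0.0, 0, True),
            per_block_rmse=per_block_rmse,
            restrained_averages=restrained,
        )
        return CalibrationResult(
            kish_target=kish_target,
            per_type_sigma_reg={b.data_type: np.inf for b in dataset},
            sigma_reg_global=1.0,
            final=final,
            scan_trace=[],
            sigma_md=sigma_md_map,
        )

    per_type: dict[str, float] = {}
    for block in dataset:
        sigma, _ = calibrate_per_type(
            prior, block, kish_target, grid_spec, tolerance, max_iter
        )
        per_type[block.data_type] = sigma

    factor, final, trace = calibrate_global(
        prior, dataset, per_type, kish_target, grid_spec, tolerance, max_iter
    )
    return CalibrationResult(
        kish_target=kish_target,
        per_type_sigma_reg=per_type,
        sigma_reg_global=factor,
        final=final,
        scan_trace=trace,
        sigma_md=sigma_md_map,
    )
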