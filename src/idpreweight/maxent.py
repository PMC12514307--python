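"""Gaussian-error maximum-entropy reweighting.

Given prior weights w0 and restraints (ensemble-averaged observables that
should match experimental targets within Gaussian errors sigma_i), the
minimally perturbed posterior is the exponential-family reweighting

    w_j  propto  w0_j * exp(-sum_i lambda_i F_ij)

whose Lagrange multipliers lambda minimize the convex dual functional

    Gamma(lambda) = ln sum_j w0_j exp(-sum_i lambda_i F_ij)
                    + sum_i lambda_i O_i^exp
                    + 1/2 sum_i lambda_i^2 sigma_i^2 .

The quadratic term is the analytic marginalization of per-point Gaussian
error variables with standard deviation sigma_i: sigma_i = 0 enforces the
restraint exactly, sigma_i -> infinity switches it off and returns the
prior.  At the optimum the stationarity identity
<F_i> = O_i^exp + lambda_i sigma_i^2 holds.

Observables are not standardized: lambda carries inverse data units, so the
lambda*sigma^2 slack stays interpretable in data units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .ensemble import ExperimentalDataset, kish_ratio, normalize_weights

__all__ = [
    "LagrangeState",
    "ReweightResult",
    "InfeasibleRestraintError",
    "gamma",
    "gamma_gradient",
    "solve",
]

log = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 1e-7
DEFAULT_MAX_ITER = 5000


class InfeasibleRestraintError(ValueError):
    """Exact (sigma=0) restraints whose targets no weighting can reach."""


@dataclass
class LagrangeState:
    lambdas: np.ndarray
    gamma_value: float
    gradient_norm: float
    n_iterations: int
    converged: bool


@dataclass
class ReweightResult:
    weights: np.ndarray
    kish: float
    lambda_state: LagrangeState
    per_block_rmse: dict[str, float]
    restrained_averages: dict[str, np.ndarray]


def _stack(dataset: ExperimentalDataset):
    """Stack all blocks into (F, O, sigma) with F of shape (N, M_total)."""
    if len(dataset) == 0:
        raise ValueError("dataset has no blocks")
    F = np.hstack([b.predictions for b in dataset])
    O = np.concatenate([b.exp_values for b in dataset])
    sig = np.concatenate([b.sigma_total() for b in dataset])
    return F, O, sig


def gamma(lambdas, prior_weights, dataset: ExperimentalDataset) -> float:
    """Dual functional Gamma(lambda); convex, Gamma(0) = 0 for normalized prior."""
    lam = np.asarray(lambdas, dtype=float)
    w0 = np.asarray(prior_weights, dtype=float)
    F, O, sig = _stack(dataset)
    # zero-prior frames contribute -inf log-weight and never revive
    logz = logsumexp(_posterior_log_weights(lam, w0, F))
    return float(logz + lam @ O + 0.5 * np.sum(lam**2 * sig**2))


def _posterior_log_weights(lam, w0, F):
    with np.errstate(divide="ignore"):
        logw0 = np.where(w0 > 0, np.log(np.where(w0 > 0, w0, 1.0)), -np.inf)
    return logw0 - F @ lam


def gamma_gradient(lambdas, prior_weights, dataset: ExperimentalDataset) -> np.ndarray:
    """d Gamma / d lambda_i = O_i^exp - <F_i>_lambda + lambda_i sigma_i^2."""
    lam = np.asarray(lambdas, dtype=float)
    w0 = np.asarray(prior_weights, dtype=float)
    F, O, sig = _stack(dataset)
    w = softmax(_posterior_log_weights(lam, w0, F))
    return O - F.T @ w + lam * sig**2


def _check_feasible(dataset: ExperimentalDataset, w0: np.ndarray) -> None:
    """Exact restraints must lie inside the per-observable prediction range."""
    mask = w0 > 0
    bad: list[str] = []
    for block in dataset:
        sig = block.sigma_total()
        if not np.any(sig == 0):
            continue
        P = block.predictions[mask]
        lo, hi = P.min(axis=0), P.max(axis=0)
        for i in np.flatnonzero(sig == 0):
            if not (lo[i] <= block.exp_values[i] <= hi[i]):
                bad.append(block.observable_ids[i])
    if bad:
        raise InfeasibleRestraintError(
            "exact (sigma=0) restraints outside the range of per-frame "
            f"predictions: {bad}"
        )


def solve(
    prior_weights,
    dataset: ExperimentalDataset,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    lambda0: np.ndarray | None = None,
) -> ReweightResult:
    """Minimize Gamma over lambda and return the posterior reweighting.

    Parameters
    ----------
    prior_weights : array-like
        Prior weights w0 (renormalized on entry).
    dataset : ExperimentalDataset
        Restraint blocks; each block's sigma_reg must already be set.
    tolerance : float
        Convergence threshold on the max-norm of the dual gradient.
    max_iter : int
        Iteration cap for the quasi-Newton optimizer.
    lambda0 : array-like, optional
        Warm-start multipliers (default: zeros).
    """
    w0 = normalize_weights(prior_weights)
    F, O, sig = _stack(dataset)
    if F.shape[0] != w0.size:
        raise ValueError("prior weight length does not match dataset frame count")
    _check_feasible(dataset, w0)

    x0 = np.zeros(O.size) if lambda0 is None else np.asarray(lambda0, dtype=float)
    res = minimize(
        gamma,
        x0,
        args=(w0, dataset),
        jac=gamma_gradient,
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "maxfun": 10 * max_iter,
            "gtol": tolerance,
            "ftol": 1e-16,
        },
    )
    lam = res.x
    grad = gamma_gradient(lam, w0, dataset)
    gnorm = float(np.max(np.abs(grad)))
    converged = gnorm <= tolerance
    if not converged:
        log.debug(
            "maxent solve stopped at gradient max-norm %.3g (> %.3g) after %d iterations",
            gnorm,
            tolerance,
            res.nit,
        )
    state = LagrangeState(
        lambdas=lam,
        gamma_value=float(res.fun),
        gradient_norm=gnorm,
        n_iterations=int(res.nit),
        converged=converged,
    )
    w = softmax(_posterior_log_weights(lam, w0, F))
    w = normalize_weights(w)

    per_block_rmse: dict[str, float] = {}
    restrained_averages: dict[str, np.ndarray] = {}
    for block in dataset:
        avg = block.predictions.T @ w
        restrained_averages[block.data_type] = avg
        per_block_rmse[block.data_type] = float(
            np.sqrt(np.mean((avg - block.exp_values) ** 2))
        )
    return ReweightResult(
        weights=w,
        kish=kish_ratio(w),
        lambda_state=state,
        per_block_rmse=per_block_rmse,
        restrained_averages=restrained_averages,
    )
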