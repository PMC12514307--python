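"""Accuracy metrics and leave-one-out cross-validation.

RMSE is computed per data type between ensemble-averaged predictions and
experimental targets.  RMSE_N normalizes each data type's RMSE by the value
obtained in a named reference ensemble (typically the unbiased prior), and
the averaged RMSE_N over data types is a single global quality index.

Cross-validation withholds one data type at a time, recalibrates the full
protocol from scratch on the remaining types, and scores the withheld type
under the resulting weights — small withheld RMSE_N indicates transferable
improvement rather than overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate import DEFAULT_KISH_TARGET, run_protocol
from .ensemble import ExperimentalDataset, normalize_weights, weighted_average

__all__ = [
    "ValidationReport",
    "rmse",
    "rmse_normalized",
    "averaged_rmse_n",
    "dataset_rmse",
    "loo_crossval",
]


@dataclass
class ValidationReport:
    per_type_rmse: dict[str, float]
    per_type_rmse_n: dict[str, float]
    averaged_rmse_n: float
    reference_label: str = ""


def rmse(calc_averages, exp_values) -> float:
    """Root-mean-square error between calculated averages and targets."""
    a = np.asarray(calc_averages, dtype=float).ravel()
    b = np.asarray(exp_values, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValueError("empty vectors")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def rmse_normalized(rmse_value: float, reference_rmse: float) -> float:
    """RMSE_N = RMSE / RMSE_reference."""
    if reference_rmse <= 0:
        raise ValueError("reference RMSE must be positive for normalization")
    return float(rmse_value / reference_rmse)


def averaged_rmse_n(per_type_rmse_n: dict[str, float]) -> float:
    """Arithmetic mean of RMSE_N over data types."""
    if not per_type_rmse_n:
        raise ValueError("no data types to average")
    return float(np.mean(list(per_type_rmse_n.values())))


def dataset_rmse(dataset: ExperimentalDataset, weights) -> dict[str, float]:
    """Per-type RMSE of a dataset under given weights."""
    w = normalize_weights(weights)
    return {
        b.data_type: rmse(weighted_average(b, w), b.exp_values) for b in dataset
    }


def validation_report(
    dataset: ExperimentalDataset,
    weights,
    reference_weights,
    reference_label: str = "prior",
) -> ValidationReport:
    """Score weights against a reference ensemble's RMSE per data type."""
    cur = dataset_rmse(dataset, weights)
    ref = dataset_rmse(dataset, reference_weights)
    rn = {t: rmse_normalized(cur[t], ref[t]) for t in cur}
    return ValidationReport(
        per_type_rmse=cur,
        per_type_rmse_n=rn,
        averaged_rmse_n=averaged_rmse_n(rn),
        reference_label=reference_label,
    )


def loo_crossval(
    prior,
    dataset: ExperimentalDataset,
    kish_target: float = DEFAULT_KISH_TARGET,
    **protocol_kw,
) -> dict[str, dict[str, float]]:
    """Leave-one-data-type-out cross-validation.

    For each block b: recalibrate the protocol on the other blocks, then
    report b's RMSE under the resulting weights and its RMSE_N relative to
    the prior ensemble's RMSE on b.

    Returns ``{data_type: {"rmse": ..., "rmse_n": ..., "kish": ...}}``.
    """
    if len(dataset) < 2:
        raise ValueError("cross-validation needs at least 2 data types")
    prior = normalize_weights(prior)
    out: dict[str, dict[str, float]] = {}
    for block in dataset:
        reduced = dataset.drop(block.data_type)
        cal = run_protocol(prior, reduced, kish_target=kish_target, **protocol_kw)
        held_rmse = rmse(weighted_average(block, cal.final.weights), block.exp_values)
        prior_rmse = rmse(weighted_average(block, prior), block.exp_values)
        out[block.data_type] = {
            "rmse": held_rmse,
            "rmse_n": rmse_normalized(held_rmse, prior_rmse),
            "kish": cal.final.kish,
        }
    return out
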