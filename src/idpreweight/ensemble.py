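"""Core data model: weighted conformational ensembles and observable blocks.

A conformational ensemble is represented by N frames carrying normalized
statistical weights w_i.  Experimental information enters as *observable
blocks*: for one data type (e.g. Calpha chemical shifts, 3J_HNHA couplings,
SAXS intensities) a block holds the per-frame forward-model predictions
F_ij, the experimental targets O_i^exp, the per-point statistical errors
sigma_i,MD of the ensemble averages, and a single per-type regularization
scale sigma_reg.

The Kish ratio K = (1/N)(sum w_i)^2 / sum w_i^2 is the normalized effective
sample size of a weight vector: K = 1 for uniform weights, K -> 1/N when a
single frame carries all the mass.  K * N is the effective number of frames
with weight substantially above zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WeightedEnsemble",
    "ObservableBlock",
    "ExperimentalDataset",
    "InvalidWeightsError",
    "normalize_weights",
    "kish_ratio",
    "effective_size",
    "weighted_average",
]

#: normalization tolerance for stored weight vectors
_NORM_TOL = 1e-10


class InvalidWeightsError(ValueError):
    """Raised for weight vectors that are empty, negative, or all zero."""


def normalize_weights(raw) -> np.ndarray:
    """Normalize a vector of non-negative weights to unit sum.

    Parameters
    ----------
    raw : array-like of float
        Non-negative, with at least one positive entry.

    Returns
    -------
    numpy.ndarray
        Weights proportional to ``raw`` summing to 1.
    """
    w = np.asarray(raw, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise InvalidWeightsError("weights must be a non-empty 1-D vector")
    if np.any(~np.isfinite(w)):
        raise InvalidWeightsError("weights must be finite")
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise InvalidWeightsError("weights must have positive total mass")
    return w / total


def kish_ratio(weights) -> float:
    """Normalized Kish effective sample size K of a weight vector.

    K = (1/N) * (sum w_i)^2 / (sum w_i^2).  Scale-invariant, so the input
    need not be normalized.  K = 1 iff all weights are equal; a vector with
    m equal nonzero entries out of N has K = m/N exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise InvalidWeightsError("empty weight vector")
    if np.any(w < 0):
        raise InvalidWeightsError("weights must be non-negative")
    ssq = float(np.dot(w, w))
    if ssq == 0.0:
        raise InvalidWeightsError("all-zero weight vector")
    return float(w.sum() ** 2 / (w.size * ssq))


def effective_size(weights) -> float:
    """Effective ensemble size K * N (approximate frame count after reweighting)."""
    w = np.asarray(weights, dtype=float)
    return kish_ratio(w) * w.size


@dataclass
class WeightedEnsemble:
    """N frames with normalized statistical weights.

    Weights are stored normalized; the constructor renormalizes any valid
    non-negative input.  Zero-weight frames are retained, never dropped:
    reweighting discards frames only in the statistical sense.
    """

    weights: np.ndarray
    source_label: str = ""
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = normalize_weights(self.weights)
        if self.frame_ids is not None:
            self.frame_ids = np.asarray(self.frame_ids, dtype=int)
            if self.frame_ids.shape != self.weights.shape:
                raise ValueError("frame_ids length must equal n_frames")

    @classmethod
    def uniform(cls, n_frames: int, source_label: str = "") -> "WeightedEnsemble":
        if n_frames < 1:
            raise InvalidWeightsError("need at least one frame")
        return cls(np.full(n_frames, 1.0 / n_frames), source_label=source_label)

    @property
    def n_frames(self) -> int:
        return self.weights.size

    @property
    def kish(self) -> float:
        return kish_ratio(self.weights)

    @property
    def effective_size(self) -> float:
        return effective_size(self.weights)


@dataclass
class ObservableBlock:
    """One experimental data type as a restraint block.

    predictions has shape (N frames, M observables); exp_values, sigma_md,
    observable_ids all have length M.  sigma_reg is the single per-type
    regularization scale; the total error on point i is
    sqrt(sigma_md_i**2 + sigma_reg**2).
    """

    data_type: str
    predictions: np.ndarray
    exp_values: np.ndarray
    sigma_md: np.ndarray | None = None
    sigma_reg: float = 0.0
    observable_ids: list[str] | None = None
    exp_error: np.ndarray | None = None  # carried, excluded from sigma_i by default
    units: str = ""

    def __post_init__(self) -> None:
        self.predictions = np.atleast_2d(np.asarray(self.predictions, dtype=float))
        self.exp_values = np.asarray(self.exp_values, dtype=float).ravel()
        m = self.exp_values.size
        if self.predictions.shape[1] != m:
            raise ValueError(
                f"block {self.data_type!r}: predictions have "
                f"{self.predictions.shape[1]} columns but {m} exp_values"
            )
        if self.sigma_md is not None:
            self.sigma_md = np.asarray(self.sigma_md, dtype=float).ravel()
            if self.sigma_md.size != m:
                raise ValueError(f"block {self.data_type!r}: sigma_md length mismatch")
            if np.any(self.sigma_md < 0):
                raise ValueError("sigma_md must be non-negative")
        if self.sigma_reg < 0:
            raise ValueError("sigma_reg must be non-negative")
        if self.observable_ids is None:
            self.observable_ids = [f"{self.data_type}_{i}" for i in range(m)]
        elif len(self.observable_ids) != m:
            raise ValueError(f"block {self.data_type!r}: observable_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.predictions.shape[0]

    @property
    def n_observables(self) -> int:
        return self.predictions.shape[1]

    def sigma_total(self) -> np.ndarray:
        """Per-point sigma_i = sqrt(sigma_md^2 + sigma_reg^2)."""
        smd = self.sigma_md if self.sigma_md is not None else np.zeros(self.n_observables)
        return np.sqrt(smd**2 + self.sigma_reg**2)

    def with_sigma_reg(self, sigma_reg: float) -> "ObservableBlock":
        return replace(self, sigma_reg=float(sigma_reg))


@dataclass
class ExperimentalDataset:
    """Ordered collection of observable blocks sharing one frame set."""

    blocks: list[ObservableBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        tags = [b.data_type for b in self.blocks]
        if len(set(tags)) != len(tags):
            raise ValueError(f"duplicate data_type tags in dataset: {tags}")
        ns = {b.n_frames for b in self.blocks}
        if len(ns) > 1:
            raise ValueError(f"inconsistent frame counts across blocks: {sorted(ns)}")

    @property
    def n_frames(self) -> int:
        if not self.blocks:
            raise ValueError("empty dataset")
        return self.blocks[0].n_frames

    @property
    def total_observables(self) -> int:
        return sum(b.n_observables for b in self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __getitem__(self, data_type: str) -> ObservableBlock:
        for b in self.blocks:
            if b.data_type == data_type:
                return b
        raise KeyError(data_type)

    def drop(self, data_type: str) -> "ExperimentalDataset":
        """Dataset without one block (used by leave-one-out cross-validation)."""
        if data_type not in [b.data_type for b in self.blocks]:
            raise KeyError(data_type)
        return ExperimentalDataset([b for b in self.blocks if b.data_type != data_type])


def weighted_average(block: ObservableBlock, weights) -> np.ndarray:
    """Ensemble averages <F_i> = sum_j w_j F_ij for every observable in a block."""
    w = np.asarray(weights, dtype=float)
    if w.size != block.n_frames:
        raise ValueError(
            f"weights length {w.size} does not match block frame count {block.n_frames}"
        )
    return block.predictions.T @ w
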