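"""Synthetic ensembles with known ground truth for end-to-end testing.

Real inputs to the reweighting protocol are MD trajectories plus measured
NMR/SAXS data.  The generators here emulate that situation with full
control of the answer: frames are latent points drawn from a Gaussian
mixture (the "prior" force field), the "true" solution ensemble is the same
frame set under tilted component probabilities (so the ground-truth weights
and their Kish ratio are known exactly), per-frame observables are fixed
deterministic functions of the latent coordinate, and experimental targets
are true-ensemble averages plus Gaussian noise.

What this does not emulate: time correlation between frames (frames are
i.i.d., so blocking analysis reduces to the plain standard error), forward
model systematic error, and the geometric realism of protein chains (the
polymer generator below produces freely jointed chains, which have no
secondary structure or excluded volume).

All randomness flows from one integer seed through spawned child
generators, so every sub-product is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import ExperimentalDataset, ObservableBlock, normalize_weights
from .forward import CoordinateEnsemble

__all__ = [
    "SyntheticSpec",
    "gen_observable_ensemble",
    "gen_target_data",
    "gen_polymer_ensemble",
    "gen_correlated_series",
    "default_fixture",
]

#: default fixture size: large enough that a K = 0.10 calibration is
#: non-trivial, small enough for fast tests
DEFAULT_N_FRAMES = 2000
DEFAULT_N_BLOCKS = 3
DEFAULT_OBS_PER_BLOCK = 10


@dataclass
class SyntheticSpec:
    """Generative recipe for a ground-truth reweighting problem.

    mixture: list of (mean vector, covariance scale, prior probability);
    true_component_probs: tilted probabilities defining the true ensemble
    (the ground-truth weights are the per-frame probability ratios).
    """

    n_frames: int = DEFAULT_N_FRAMES
    n_blocks: int = DEFAULT_N_BLOCKS
    observables_per_block: int = DEFAULT_OBS_PER_BLOCK
    mixture: list[tuple[tuple[float, ...], float, float]] = field(
        default_factory=lambda: [
            ((-2.0, 0.0), 0.5, 0.6),
            ((0.0, 2.0), 0.5, 0.3),
            ((2.0, -1.0), 0.5, 0.1),
        ]
    )
    true_component_probs: tuple[float, ...] | None = (0.1, 0.3, 0.6)
    true_weights: np.ndarray | None = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.array([p for _, _, p in self.mixture])
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("mixture component probabilities must sum to 1")
        if np.any(probs <= 0):
            raise ValueError("degenerate mixture: component probabilities must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.true_component_probs is not None:
            q = np.asarray(self.true_component_probs)
            if q.size != len(self.mixture) or not np.isclose(q.sum(), 1.0):
                raise ValueError("true_component_probs must match mixture and sum to 1")


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_observable_ensemble(
    spec: SyntheticSpec,
) -> tuple[ExperimentalDataset, np.ndarray]:
    """Draw latent frames and per-frame observables; return (dataset, true weights).

    The dataset's exp_values are the noiseless true-ensemble averages (add
    measurement noise with :func:`gen_target_data`).  True weights are
    normalized ratios q_c/p_c of true to prior component probabilities of
    each frame's mixture component, unless explicit weights were supplied.
    """
    rng_comp, rng_frames, rng_maps = _spawn(spec.seed, 3)
    k = len(spec.mixture)
    probs = np.array([p for _, _, p in spec.mixture])
    means = np.array([m for m, _, _ in spec.mixture], dtype=float)
    scales = np.array([s for _, s, _ in spec.mixture], dtype=float)
    dim = means.shape[1]

    comp = rng_comp.choice(k, size=spec.n_frames, p=probs)
    z = means[comp] + rng_frames.standard_normal((spec.n_frames, dim)) * scales[comp, None]

    if spec.true_weights is not None:
        w_true = normalize_weights(spec.true_weights)
    elif spec.true_component_probs is not None:
        ratio = np.asarray(spec.true_component_probs) / probs
        w_true = normalize_weights(ratio[comp])
    else:
        w_true = np.full(spec.n_frames, 1.0 / spec.n_frames)

    blocks = []
    map_rngs = _spawn(int(rng_maps.integers(2**31)), spec.n_blocks)
    for b in range(spec.n_blocks):
        rng = map_rngs[b]
        m = spec.observables_per_block
        W = rng.standard_normal((m, dim))
        c = rng.standard_normal(m)
        V = rng.standard_normal((m, dim)) * 0.5
        # deterministic nonlinear map of the latent coordinate
        F = z @ W.T + np.tanh(z @ V.T) + c[None, :]
        exp_values = F.T @ w_true
        blocks.append(
            ObservableBlock(
                data_type=f"type_{b}",
                predictions=F,
                exp_values=exp_values,
            )
        )
    return ExperimentalDataset(blocks), w_true


def gen_target_data(
    dataset: ExperimentalDataset,
    true_weights,
    noise_sd: float,
    seed: int,
) -> ExperimentalDataset:
    """Replace targets with true-ensemble averages plus Gaussian noise."""
    w = normalize_weights(true_weights)
    rngs = _spawn(seed, len(dataset))
    blocks = []
    for rng, block in zip(rngs, dataset):
        truth = block.predictions.T @ w
        noisy = truth + rng.standard_normal(truth.size) * noise_sd
        blocks.append(
            ObservableBlock(
                data_type=block.data_type,
                predictions=block.predictions,
                exp_values=noisy,
                sigma_md=block.sigma_md,
                sigma_reg=block.sigma_reg,
                observable_ids=block.observable_ids,
                units=block.units,
            )
        )
    return ExperimentalDataset(blocks)


def default_fixture(seed: int = 0) -> tuple[ExperimentalDataset, np.ndarray]:
    """Standard seeded fixture: biased prior vs known tilted truth, noisy targets."""
    spec = SyntheticSpec(seed=seed)
    dataset, w_true = gen_observable_ensemble(spec)
    dataset = gen_target_data(dataset, w_true, spec.noise_sd, seed=seed + 1)
    return dataset, w_true


def gen_polymer_ensemble(
    n_res: int,
    n_frames: int,
    bond_length: float = 3.8,
    seed: int = 0,
) -> CoordinateEnsemble:
    """Freely jointed Calpha chains: fixed bond length, i.i.d. directions.

    A geometric stand-in for disordered-chain coordinates (no excluded
    volume or chain stiffness): mean squared end-to-end distance is
    (n_res-1) * b^2 and mean Rg^2 approaches n_res * b^2 / 6.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames, n_res - 1, 3))
    steps /= np.linalg.norm(steps, axis=2, keepdims=True)
    coords = np.zeros((n_frames, n_res, 3))
    coords[:, 1:] = np.cumsum(steps * bond_length, axis=1)
    return CoordinateEnsemble(
        coords,
        atom_labels=[(i + 1, "CA") for i in range(n_res)],
        source_label="freely-jointed-chain",
    )


def gen_correlated_series(n: int, rho: float, sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series with lag-1 autocorrelation rho and marginal sd."""
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for stationarity")
    rng = np.random.default_rng(seed)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x
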