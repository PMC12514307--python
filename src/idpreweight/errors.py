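"""Statistical error estimation for per-frame observable series.

The average of a forward-model prediction over a finite, time-correlated
trajectory carries a statistical error sigma_MD.  For uncorrelated frames
this is the plain standard error of the mean; for correlated frames we use
the blocking method (successive pairwise averaging of the series until the
standard-error estimate plateaus).

The total error assigned to data point i composes the statistical term with
the per-data-type regularization scale: sigma_i = sqrt(sigma_MD^2 + sigma_reg^2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockingCurve",
    "blocking_transform",
    "flyvbjerg_sigma",
    "sem_uncorrelated",
    "compose_sigma",
]

log = logging.getLogger(__name__)


@dataclass
class BlockingCurve:
    """Standard-error estimates across blocking levels for one series."""

    n_blocks: np.ndarray          # block count per level
    sigma_estimates: np.ndarray   # sigma-hat per level, units of the observable
    sigma_errors: np.ndarray      # error bar of each sigma-hat
    selected_level: int
    selected_sigma: float

    @property
    def n_levels(self) -> int:
        return self.n_blocks.size


def blocking_transform(series) -> np.ndarray:
    """One blocking step: average consecutive non-overlapping pairs.

    A trailing odd element is dropped.  Output length is floor(n/2).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("blocking transform needs at least 2 points")
    n2 = x.size // 2
    return 0.5 * (x[: 2 * n2 : 2] + x[1 : 2 * n2 : 2])


def sem_uncorrelated(series) -> float:
    """Standard error of the mean assuming uncorrelated samples: sd/sqrt(n)."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 points for a standard error")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def _level_sigma(x: np.ndarray) -> tuple[float, float]:
    """sigma-hat of the mean from block means x, and its own error bar.

    sigma^2 = c0/(n_b - 1) with c0 the biased sample variance of the block
    means; the error bar uses the Gaussian approximation sigma/sqrt(2(n_b-1)).
    """
    nb = x.size
    c0 = float(np.var(x))  # biased variance of block means
    s = np.sqrt(c0 / (nb - 1))
    return s, s / np.sqrt(2.0 * (nb - 1))


def flyvbjerg_sigma(series, min_blocks: int = 8) -> tuple[float, BlockingCurve]:
    """Blocking estimate of the standard error of a correlated series' mean.

    The series is repeatedly pair-averaged; at each level the standard error
    of the mean is estimated from the block means.  For correlated data the
    estimate grows with level until blocks become effectively independent
    and the curve plateaus.  The selected value is the first level whose
    estimate agrees with the next level within one error bar; if no plateau
    is reached before fewer than ``min_blocks`` blocks remain, the maximum
    estimate over levels is returned (conservative) with a warning.

    Series shorter than ``min_blocks`` fall back to the uncorrelated SEM.

    Returns
    -------
    (selected_sigma, BlockingCurve)
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < min_blocks:
        log.warning(
            "series of length %d too short for blocking; using uncorrelated SEM",
            x.size,
        )
        s = sem_uncorrelated(x)
        curve = BlockingCurve(
            n_blocks=np.array([x.size]),
            sigma_estimates=np.array([s]),
            sigma_errors=np.array([s / np.sqrt(2.0 * (x.size - 1))]),
            selected_level=0,
            selected_sigma=s,
        )
        return s, curve

    n_blocks, sigmas, errs = [], [], []
    cur = x
    while cur.size >= 2:
        s, e = _level_sigma(cur)
        n_blocks.append(cur.size)
        sigmas.append(s)
        errs.append(e)
        cur = blocking_transform(cur) if cur.size >= 4 else cur[:1]
    n_blocks = np.asarray(n_blocks)
    sigmas = np.asarray(sigmas)
    errs = np.asarray(errs)

    selected = None
    for lev in range(len(sigmas) - 1):
        if n_blocks[lev] < min_blocks:
            break
        if abs(sigmas[lev] - sigmas[lev + 1]) <= errs[lev]:
            selected = lev
            break
    if selected is None:
        selected = int(np.argmax(sigmas))
        if sigmas[selected] > 0:
            log.warning(
                "no blocking plateau before %d blocks; using maximum estimate "
                "(level %d, sigma=%.3g)",
                min_blocks,
                selected,
                sigmas[selected],
            )
    sel_sigma = float(sigmas[selected])
    curve = BlockingCurve(
        n_blocks=n_blocks,
        sigma_estimates=sigmas,
        sigma_errors=errs,
        selected_level=int(selected),
        selected_sigma=sel_sigma,
    )
    return sel_sigma, curve


def compose_sigma(sigma_md: float, sigma_reg: float) -> float:
    """Total per-point error sqrt(sigma_md^2 + sigma_reg^2)."""
    if sigma_md < 0 or sigma_reg < 0:
        raise ValueError("sigma components must be non-negative")
    return float(np.hypot(sigma_md, sigma_reg))
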