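"""Quantitative ensemble similarity in a shared 2D latent space.

Ensembles of the same protein are compared by (1) describing every frame by
its Calpha-Calpha contact pattern, (2) embedding the merged frames into a
2D latent space (PCA on distance features by default, or classical MDS on
the contact dissimilarity matrix), (3) estimating a weighted density for
each ensemble over a shared grid spanning the global extrema of the
embedding, and (4) scoring pairs of densities with the overlap integral

    S = <D1, D2> / (||D1|| ||D2||)

— the normalized inner product of the flattened density vectors, analogous
to the overlap of quantum-mechanical wave functions.  S = 1 for identical
densities, S = 0 for disjoint supports.  Because all ensembles share one
embedding, reweighting moves only the statistical weights of points, never
their latent coordinates.

For a reweighted ensemble compared against its uniform parent, S^2 computed
with histogram densities converges to the Kish ratio of the weights as the
number of bins grows; conversely, once bins far outnumber the frames of two
independently sampled ensembles, S decays to zero regardless of similarity,
so bin counts should stay comparable to the effective ensemble size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = [
    "EmbeddingResult",
    "DensityGrid",
    "dissimilarity_matrix",
    "embed_2d",
    "kde_on_grid",
    "histogram_density",
    "overlap_integral",
    "s_alpha",
    "compare_ensembles",
    "downsample_stride",
    "merged_extent",
]

log = logging.getLogger(__name__)

KDE_GRID_SIZE = 80
HISTOGRAM_BINS = 60


@dataclass
class EmbeddingResult:
    points: np.ndarray                     # (N, 2)
    method: str = "pca"
    hyperparameters: dict = field(default_factory=dict)
    source_partition: np.ndarray | None = None  # frame -> ensemble label

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("embedding points must have shape (N, 2)")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding points must be finite")


@dataclass
class DensityGrid:
    """Normalized non-negative density over a shared 2D grid."""

    grid_x1: np.ndarray
    grid_x2: np.ndarray
    values: np.ndarray
    kind: str = "kde"                       # "kde" | "histogram"
    bandwidths: tuple[float, float] | None = None
    weights_used: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    def same_grid(self, other: "DensityGrid") -> bool:
        return (
            self.grid_x1.shape == other.grid_x1.shape
            and self.grid_x2.shape == other.grid_x2.shape
            and np.allclose(self.grid_x1, other.grid_x1)
            and np.allclose(self.grid_x2, other.grid_x2)
        )


def downsample_stride(array, stride: int = 2) -> np.ndarray:
    """Thin a trajectory-indexed array by keeping every ``stride``-th frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return np.asarray(array)[::stride]


def _contact_populations(coords, sigma0: float, epsilon: float, d0: float | None = None):
    from scipy.spatial.distance import pdist

    x = np.asarray(coords, dtype=float)
    D = np.stack([pdist(f) for f in x])  # (N, n_pairs)
    if d0 is None:
        d0 = epsilon * float(D.max())
    return 1.0 / (1.0 + np.exp((D - d0) / sigma0)), d0


def dissimilarity_matrix(coords, sigma0: float = 1.0, epsilon: float = 0.15) -> np.ndarray:
    """Pairwise conformational dissimilarity from Calpha contact populations.

    Each frame's pairwise distances d_ij are mapped to soft contact
    populations q_ij = 1/(1+exp((d_ij - d0)/sigma0)) with d0 = epsilon times
    the largest Calpha-Calpha distance in the ensemble; frames a, b are
    compared by the mean absolute contact difference
    d(a,b) = (1/n_pairs) sum_{i<j} |q_ij(a) - q_ij(b)|.  Built from internal
    distances only, hence invariant to rigid motions of any frame.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 3 or x.shape[0] < 2:
        raise ValueError("need a (N>=2, n_ca, 3) coordinate stack")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 Calpha atoms")
    Q, _ = _contact_populations(x, sigma0, epsilon)
    from scipy.spatial.distance import squareform, pdist as _pdist

    d = squareform(_pdist(Q, metric="cityblock")) / Q.shape[1]
    return d


def _classical_mds(dissim: np.ndarray) -> np.ndarray:
    """Torgerson classical MDS to 2D (deterministic sign convention)."""
    n = dissim.shape[0]
    d2 = dissim**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[order], 0.0, None)
    pts = vecs[:, order] * np.sqrt(lam)
    # sign convention: largest-magnitude coordinate positive per axis
    for k in range(pts.shape[1]):
        i = np.argmax(np.abs(pts[:, k]))
        if pts[i, k] < 0:
            pts[:, k] = -pts[:, k]
    return pts


def embed_2d(
    data,
    method: str = "pca",
    sigma0: float = 1.0,
    epsilon: float = 0.15,
    source_partition=None,
) -> EmbeddingResult:
    """Project frames into a 2D latent space.

    method="pca": ``data`` is an (N, p) feature matrix (e.g. Calpha distance
    features); components ordered by decreasing explained variance with a
    deterministic sign convention.  method="elvim_like": ``data`` is an
    (N, N) dissimilarity matrix, embedded by classical MDS.
    method="external": ``data`` is already (N, 2) latent coordinates.
    """
    X = np.asarray(data, dtype=float)
    if method == "pca":
        from sklearn.decomposition import PCA

        if X.ndim != 2:
            raise ValueError("pca expects an (N, p) feature matrix")
        if np.allclose(X, X[0]):
            warnings.warn("all frames identical; zero-spread embedding")
            pts = np.zeros((X.shape[0], 2))
        else:
            pca = PCA(n_components=2, svd_solver="full", random_state=0)
            pts = pca.fit_transform(X)
            for k in range(2):
                i = np.argmax(np.abs(pts[:, k]))
                if pts[i, k] < 0:
                    pts[:, k] = -pts[:, k]
        hyper = {}
    elif method == "elvim_like":
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("elvim_like expects a square dissimilarity matrix")
        pts = _classical_mds(X)
        hyper = {"sigma0": sigma0, "epsilon": epsilon}
    elif method == "external":
        pts = X
        hyper = {}
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return EmbeddingResult(
        points=pts,
        method=method,
        hyperparameters=hyper,
        source_partition=None if source_partition is None else np.asarray(source_partition),
    )


def merged_extent(points, pad: float = 0.0) -> tuple[tuple[float, float], tuple[float, float]]:
    """Global extrema of 2D points per dimension, optionally padded."""
    p = np.asarray(points, dtype=float)
    (x1lo, x2lo), (x1hi, x2hi) = p.min(axis=0), p.max(axis=0)
    return (x1lo - pad, x1hi + pad), (x2lo - pad, x2hi + pad)


def kde_on_grid(
    points,
    weights=None,
    grid_size: int = KDE_GRID_SIZE,
    extent=None,
    pad_bandwidths: float = 0.0,
) -> DensityGrid:
    """Weighted Gaussian kernel density sampled on a regular 2D grid.

    Bandwidths follow Scott's rule with the effective sample size of the
    weights, n_eff = 1/sum(w_i^2) = K*N, in place of the frame count.  The
    grid spans ``extent`` (default: the data extrema), optionally padded by
    a multiple of the bandwidth for mass checks.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 2:
        raise ValueError("need at least 2 points of shape (N, 2)")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive mass")
        w = w / w.sum()
    else:
        w = None
    kde = gaussian_kde(p.T, weights=w)  # Scott's rule on n_eff by default
    bw = tuple(np.sqrt(np.diag(kde.covariance)))
    log.debug("KDE bandwidths (weighted Scott): %s", bw)

    if extent is None:
        extent = merged_extent(p)
    (x1lo, x1hi), (x2lo, x2hi) = extent
    if pad_bandwidths:
        x1lo -= pad_bandwidths * bw[0]
        x1hi += pad_bandwidths * bw[0]
        x2lo -= pad_bandwidths * bw[1]
        x2hi += pad_bandwidths * bw[1]
    g1 = np.linspace(x1lo, x1hi, grid_size)
    g2 = np.linspace(x2lo, x2hi, grid_size)
    G1, G2 = np.meshgrid(g1, g2, indexing="ij")
    vals = kde(np.vstack([G1.ravel(), G2.ravel()])).reshape(grid_size, grid_size)
    return DensityGrid(
        grid_x1=g1,
        grid_x2=g2,
        values=vals,
        kind="kde",
        bandwidths=bw,
        weights_used=weights is not None,
    )


def histogram_density(
    points,
    weights=None,
    bins: int = HISTOGRAM_BINS,
    extent=None,
) -> DensityGrid:
    """Weighted 2D histogram normalized to unit total mass.

    Ensembles being compared must share ``extent`` (the global extrema of
    the merged embedding) so that bin edges coincide.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must have shape (N, 2)")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive mass")
    else:
        w = None
    if extent is None:
        extent = merged_extent(p)
    H, e1, e2 = np.histogram2d(
        p[:, 0], p[:, 1], bins=bins, range=list(extent), weights=w
    )
    H = H / H.sum()
    return DensityGrid(
        grid_x1=e1,
        grid_x2=e2,
        values=H,
        kind="histogram",
        weights_used=weights is not None,
    )


def overlap_integral(d1: DensityGrid, d2: DensityGrid) -> float:
    """S = <D1,D2> / (||D1|| ||D2||) on a shared grid; S in [0, 1]."""
    if not d1.same_grid(d2):
        raise ValueError("density grids do not match")
    v1 = d1.values.ravel()
    v2 = d2.values.ravel()
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm density")
    return float(np.clip(v1 @ v2 / (n1 * n2), 0.0, 1.0))


# --- alpha-helical order parameter ---------------------------------------

def _ideal_helix(n_res: int, radius: float, rise: float, twist_deg: float) -> np.ndarray:
    t = np.arange(n_res) * np.deg2rad(twist_deg)
    return np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.arange(n_res) * rise]
    )


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    H = a.T @ b
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return float(np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1))))


def s_alpha(
    coords,
    window: int = 6,
    r0: float = 1.0,
    n_exp: int = 8,
    m_exp: int = 12,
    helix_radius: float = 2.3,
    helix_rise: float = 1.5,
    helix_twist: float = 100.0,
) -> np.ndarray | float:
    """Alpha-helical order parameter from Calpha coordinates.

    Sums, over all consecutive ``window``-residue fragments, a rational
    switching function f(r) = (1-(r/r0)^n)/(1-(r/r0)^m) of the fragment's
    best-superposition RMSD r to an ideal alpha-helical Calpha template
    (radius 2.3 A, rise 1.5 A/residue, twist 100 deg/residue).  Near-ideal
    fragments contribute ~1, extended fragments ~0, so a fully helical
    chain scores about n_res - window + 1.

    Accepts (n_res, 3) or (N, n_res, 3); returns a scalar or per-frame vector.
    """
    x = np.asarray(coords, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    n_res = x.shape[1]
    if n_res < window:
        raise ValueError(f"need at least {window} residues")
    template = _ideal_helix(window, helix_radius, helix_rise, helix_twist)

    def switch(r):
        ratio = r / r0
        if abs(ratio - 1.0) < 1e-8:
            return n_exp / m_exp  # limit of the rational form at r = r0
        return (1.0 - ratio**n_exp) / (1.0 - ratio**m_exp)

    out = np.empty(x.shape[0])
    for f in range(x.shape[0]):
        total = 0.0
        for start in range(n_res - window + 1):
            r = _kabsch_rmsd(x[f, start : start + window], template)
            total += switch(r)
        out[f] = total
    return float(out[0]) if single else out


def compare_ensembles(
    weights_list,
    embedding: EmbeddingResult,
    kind: str = "kde",
    grid_size: int | None = None,
    as_percent: bool = False,
) -> np.ndarray:
    """Pairwise overlap matrix S between ensembles sharing one embedding.

    ``weights_list`` holds one weight vector per ensemble over the same N
    embedded frames (uniform vectors for unbiased ensembles, posterior
    weights for reweighted ones).  Densities share the grid spanning the
    global extrema of the embedding.
    """
    pts = embedding.points
    n = pts.shape[0]
    ws = []
    for w in weights_list:
        w = np.asarray(w, dtype=float)
        if w.size != n:
            raise ValueError(
                f"weight vector length {w.size} does not match embedding size {n}"
            )
        ws.append(w)
    extent = merged_extent(pts)
    if kind == "kde":
        gs = grid_size or KDE_GRID_SIZE
        dens = [kde_on_grid(pts, w, grid_size=gs, extent=extent) for w in ws]
    elif kind == "histogram":
        gs = grid_size or HISTOGRAM_BINS
        dens = [histogram_density(pts, w, bins=gs, extent=extent) for w in ws]
    else:
        raise ValueError(f"unknown density kind {kind!r}")
    k = len(dens)
    S = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            S[i, j] = S[j, i] = overlap_integral(dens[i], dens[j])
    return S * 100.0 if as_percent else S
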