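"""Covariance-based niche representation (COVET) and the AOT metric.

A cell's niche is its ``k`` spatially nearest cells.  The niche is summarised
by a *shifted* gene-gene covariance matrix: the classical covariance formula
with the niche mean replaced by the dataset-wide mean expression, so that
every niche is referenced to the same point and the matrices are directly
comparable.  Shifted covariance matrices remain symmetric positive
semi-definite (PSD), so statistical divergences between Gaussians apply.

Distances between niches are computed with the closed-form 2-Wasserstein
(Frechet) distance between zero-mean Gaussians, or with its fast
approximation (AOT) obtained by swapping the matrix square root and the
product in the cross term:

    d_Frechet(S_i, S_j) = tr(S_i) + tr(S_j) - 2 tr((S_i S_j)^1/2)
    d_AOT(S_i, S_j)     = tr(S_i) + tr(S_j) - 2 tr(S_i^1/2 S_j^1/2)
                        = || S_i^1/2 - S_j^1/2 ||_F^2

The last identity means all pairwise AOT distances reduce to squared
Euclidean distances between flattened matrix square roots, so standard
k-NN / clustering / embedding machinery applies unchanged.  AOT equals the
Frechet distance exactly whenever the two matrices commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm
from sklearn.metrics import pairwise_distances
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "NicheIndex",
    "CovetTensor",
    "build_niche_index",
    "build_niche_tensor",
    "shifted_covariance",
    "compute_covet",
    "matrix_sqrt_psd",
    "frechet_distance",
    "aot_distance",
    "pairwise_aot",
    "bhattacharyya_distance",
    "covet_mean",
]

#: eigenvalues in [-PSD_TOL, 0) are treated as numerical noise and clipped
PSD_TOL = 1e-8


@dataclass
class NicheIndex:
    """Per-cell neighbour lists defining each cell's spatial niche."""

    neighbors: list[np.ndarray]
    mode: str  # "knn" | "radius"
    k_or_radius: float
    #: cells with an empty niche (possible in radius mode only)
    empty: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __len__(self) -> int:
        return len(self.neighbors)


@dataclass
class CovetTensor:
    """Shifted covariance matrices and their symmetric PSD square roots."""

    sigma: np.ndarray  # (n, g, g)
    sigma_sqrt: np.ndarray  # (n, g, g)
    global_mean: np.ndarray  # (g,)
    k: int
    gene_ids: list[str] | None = None

    @property
    def n_cells(self) -> int:
        return self.sigma.shape[0]

    @property
    def n_genes(self) -> int:
        return self.sigma.shape[1]

    def flat_sqrt(self) -> np.ndarray:
        """Flatten square roots to (n, g*g) vectors for Euclidean machinery."""
        n = self.sigma_sqrt.shape[0]
        return self.sigma_sqrt.reshape(n, -1)


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] not in (2, 3):
        raise ValueError(f"coordinates must be (n, 2) or (n, 3), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain non-finite values")
    return coords


def build_niche_index(
    coords: np.ndarray,
    k: int = 8,
    mode: str = "knn",
    radius: float | None = None,
) -> NicheIndex:
    """Find each cell's niche: its ``k`` nearest cells, or all cells within
    ``radius``.  The cell itself is always excluded.

    Ties at equal distance are broken by ascending cell index so the result
    is deterministic across platforms.
    """
    coords = _check_coords(coords)
    n = coords.shape[0]
    if mode == "knn":
        if k < 1:
            raise ValueError("k must be a positive integer")
        if n <= k:
            raise ValueError(f"knn mode needs at least k+1={k + 1} cells, got {n}")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        dist, idx = nn.kneighbors(coords)
        neighbors = []
        for i in range(n):
            d_i, nb_i = dist[i], idx[i]
            # stable sort on (distance, index): deterministic tie-break,
            # then drop self (distance 0, smallest index tie included)
            order = np.lexsort((nb_i, d_i))
            nb_sorted = nb_i[order]
            nb_sorted = nb_sorted[nb_sorted != i][:k]
            neighbors.append(nb_sorted)
        return NicheIndex(neighbors=neighbors, mode="knn", k_or_radius=k)
    elif mode == "radius":
        if radius is None or radius <= 0:
            raise ValueError("radius mode requires a positive radius")
        nn = NearestNeighbors(radius=radius).fit(coords)
        dist, idx = nn.radius_neighbors(coords, sort_results=False)
        neighbors = []
        empty = []
        for i in range(n):
            d_i, nb_i = dist[i], idx[i]
            keep = nb_i != i
            d_i, nb_i = d_i[keep], nb_i[keep]
            order = np.lexsort((nb_i, d_i))
            nb_sorted = nb_i[order]
            if nb_sorted.size == 0:
                empty.append(i)
            neighbors.append(nb_sorted)
        return NicheIndex(
            neighbors=neighbors,
            mode="radius",
            k_or_radius=radius,
            empty=np.asarray(empty, dtype=int),
        )
    raise ValueError(f"unknown mode {mode!r}")


def build_niche_tensor(
    expr: np.ndarray,
    niche: NicheIndex,
    gene_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Stack the expression vectors of each cell's neighbours.

    Returns an (n, k, g) tensor in knn mode (a list of (k_i, g) arrays in
    radius mode where niche sizes vary).
    """
    expr = np.asarray(expr, dtype=float)
    if gene_indices is not None:
        expr = expr[:, gene_indices]
    if niche.mode == "knn":
        idx = np.stack(niche.neighbors)
        return expr[idx]
    return [expr[nb] for nb in niche.neighbors]


def shifted_covariance(E_i: np.ndarray, global_mean: np.ndarray) -> np.ndarray:
    """Shifted covariance of one niche: (1/k) (E_i - mean)^T (E_i - mean),
    with the dataset-wide mean in place of the niche mean.

    Coincides with the classical (biased, 1/k) covariance when ``global_mean``
    equals the niche's own mean.  Always symmetric PSD.
    """
    E_i = np.atleast_2d(np.asarray(E_i, dtype=float))
    global_mean = np.asarray(global_mean, dtype=float)
    if E_i.shape[1] != global_mean.shape[0]:
        raise ValueError(
            f"gene dimension mismatch: niche has {E_i.shape[1]} genes, "
            f"mean has {global_mean.shape[0]}"
        )
    centered = E_i - global_mean
    return centered.T @ centered / E_i.shape[0]


def matrix_sqrt_psd(A: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Unique symmetric PSD square root of a symmetric PSD matrix, via
    eigendecomposition with square-rooted eigenvalues.

    Eigenvalues in [-tol, 0) are clipped to zero; anything more negative is
    rejected as genuinely non-PSD input.
    """
    A = np.asarray(A, dtype=float)
    w, V = np.linalg.eigh(A)
    # tolerance is relative to the spectral radius for badly scaled input
    tol_eff = tol * max(1.0, float(np.abs(w).max(initial=0.0)))
    if w.min(initial=0.0) < -tol_eff:
        raise ValueError(
            f"matrix is not PSD: min eigenvalue {w.min():.3g} < -{tol_eff:g}"
        )
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


def _batch_sqrt_psd(sigmas: np.ndarray, tol: float = PSD_TOL) -> np.ndarray:
    """Symmetric PSD square roots of a stack of PSD matrices (vectorised)."""
    w, V = np.linalg.eigh(sigmas)
    tol_eff = tol * max(1.0, float(np.abs(w).max(initial=0.0)))
    if w.min(initial=0.0) < -tol_eff:
        raise ValueError(f"non-PSD matrix in stack: min eigenvalue {w.min():.3g}")
    w = np.clip(w, 0.0, None)
    return np.einsum("nij,nj,nkj->nik", V, np.sqrt(w), V)


def compute_covet(
    expr: np.ndarray,
    coords: np.ndarray,
    k: int = 8,
    gene_indices: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    mode: str = "knn",
    radius: float | None = None,
    log1p: bool = False,
) -> CovetTensor:
    """Compute the full niche-covariance tensor for a spatial dataset.

    The dataset-wide mean is taken over all cells on the selected genes.
    In radius mode, cells with an empty niche get NaN matrices and are
    recorded in the returned index; they must be excluded downstream.
    """
    expr = np.asarray(expr, dtype=float)
    if np.any(expr < 0):
        raise ValueError("expression matrix has negative entries")
    if log1p:
        expr = np.log1p(expr)
    if gene_indices is not None:
        expr_sub = expr[:, gene_indices]
    else:
        expr_sub = expr
    niche = build_niche_index(coords, k=k, mode=mode, radius=radius)
    global_mean = expr_sub.mean(axis=0)
    n, g = expr_sub.shape
    if mode == "knn":
        E = build_niche_tensor(expr_sub, niche)  # (n, k, g)
        centered = E - global_mean
        sigma = np.einsum("nkg,nkh->ngh", centered, centered) / k
        sigma_sqrt = _batch_sqrt_psd(sigma)
        eff_k = k
    else:
        sigma = np.full((n, g, g), np.nan)
        sigma_sqrt = np.full((n, g, g), np.nan)
        for i, nb in enumerate(niche.neighbors):
            if nb.size == 0:
                continue
            sigma[i] = shifted_covariance(expr_sub[nb], global_mean)
            sigma_sqrt[i] = matrix_sqrt_psd(sigma[i])
        eff_k = 0
    tensor = CovetTensor(
        sigma=sigma, sigma_sqrt=sigma_sqrt, global_mean=global_mean,
        k=eff_k, gene_ids=gene_ids,
    )
    tensor.niche_index = niche
    return tensor


def frechet_distance(sigma_i: np.ndarray, sigma_j: np.ndarray) -> float:
    """Closed-form squared 2-Wasserstein distance between zero-mean Gaussians:
    tr(S_i) + tr(S_j) - 2 tr((S_i S_j)^1/2)."""
    sigma_i = np.asarray(sigma_i, dtype=float)
    sigma_j = np.asarray(sigma_j, dtype=float)
    for s in (sigma_i, sigma_j):
        w = np.linalg.eigvalsh(s)
        if w.min(initial=0.0) < -PSD_TOL:
            raise ValueError("inputs to frechet_distance must be PSD")
    cross = sqrtm(sigma_i @ sigma_j)
    if np.iscomplexobj(cross):
        cross = cross.real
    d = float(np.trace(sigma_i) + np.trace(sigma_j) - 2.0 * np.trace(cross))
    return max(d, 0.0)


def aot_distance(sqrt_i: np.ndarray, sqrt_j: np.ndarray) -> float:
    """Approximate-optimal-transport distance from the matrix square roots:
    the squared Frobenius norm of their difference.

    Exact Frechet distance whenever the underlying matrices commute.
    """
    sqrt_i = np.asarray(sqrt_i, dtype=float)
    sqrt_j = np.asarray(sqrt_j, dtype=float)
    if sqrt_i.shape != sqrt_j.shape:
        raise ValueError(f"shape mismatch: {sqrt_i.shape} vs {sqrt_j.shape}")
    diff = sqrt_i - sqrt_j
    return float(np.sum(diff * diff))


def pairwise_aot(covet: CovetTensor) -> np.ndarray:
    """All pairwise AOT distances, via the flatten-then-squared-Euclidean
    identity (O(n k^3 + n^2 k^2) instead of O(n^2 k^3))."""
    flat = covet.flat_sqrt()
    if np.any(np.isnan(flat)):
        raise ValueError(
            "COVET tensor contains undefined (empty-niche) entries; "
            "exclude flagged cells before computing distances"
        )
    d = pairwise_distances(flat, metric="sqeuclidean")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def bhattacharyya_distance(
    sigma_i: np.ndarray, sigma_j: np.ndarray, reg: float = PSD_TOL
) -> float:
    """Bhattacharyya distance between zero-mean Gaussians (benchmark oracle):
    (1/2) ln( det((S_i+S_j)/2) / sqrt(det S_i det S_j) ).

    Inputs are regularised by ``reg * I`` to keep determinants finite.
    """
    sigma_i = np.asarray(sigma_i, dtype=float) + reg * np.eye(sigma_i.shape[0])
    sigma_j = np.asarray(sigma_j, dtype=float) + reg * np.eye(sigma_j.shape[0])
    mid = (sigma_i + sigma_j) / 2.0
    sign_m, logdet_m = np.linalg.slogdet(mid)
    sign_i, logdet_i = np.linalg.slogdet(sigma_i)
    sign_j, logdet_j = np.linalg.slogdet(sigma_j)
    if min(sign_m, sign_i, sign_j) <= 0:
        raise FloatingPointError("singular covariance after regularisation")
    return float(0.5 * (logdet_m - 0.5 * (logdet_i + logdet_j)))


def covet_mean(sigmas: np.ndarray) -> np.ndarray:
    """AOT-geometry mean of a set of PSD matrices: the matrix square of the
    mean of their symmetric square roots."""
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.ndim == 2:
        sigmas = sigmas[None]
    if sigmas.shape[0] == 0:
        raise ValueError("cannot average an empty set of matrices")
    roots = _batch_sqrt_psd(sigmas)
    m = roots.mean(axis=0)
    return m @ m
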