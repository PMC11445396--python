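"""Downstream analyses in niche-covariance (AOT) space.

Because the AOT distance between niche covariances is the squared Euclidean
distance between their flattened matrix square roots, every routine here
simply operates on those flattened roots with ordinary Euclidean machinery:
diffusion components, k-NN label transfer, niche-composition regression,
expression-vs-environment concordance, and a batch-mixing silhouette score
for latent integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .covet import build_niche_index

__all__ = [
    "DiffusionResult",
    "diffusion_components",
    "aot_knn_label_transfer",
    "niche_composition",
    "expression_environment_concordance",
    "batch_asw",
]


@dataclass
class DiffusionResult:
    components: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,)


def _adaptive_affinity(
    features: np.ndarray, k: int, adaptive_k: int, width: float
) -> np.ndarray:
    """Adaptive-Gaussian-kernel affinity on the k-NN graph.

    The per-point bandwidth is the distance to the ``adaptive_k``-th
    neighbour, scaled by ``width / k_default``; affinities are symmetrised
    by averaging with the transpose.
    """
    n = features.shape[0]
    k = min(k, n - 1)
    adaptive_k = min(adaptive_k, k)
    nn = NearestNeighbors(n_neighbors=k).fit(features)
    dist, idx = nn.kneighbors(features)
    sigma = dist[:, adaptive_k - 1].copy()
    sigma[sigma == 0] = np.finfo(float).eps
    sigma = sigma * (width / 30.0)
    aff = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    aff[rows, idx.ravel()] = np.exp(
        -(dist.ravel() ** 2) / (sigma[rows] ** 2)
    )
    return (aff + aff.T) / 2.0


def diffusion_components(
    features: np.ndarray,
    k: int = 30,
    m: int = 5,
    adaptive_k: int = 10,
    width: float = 30.0,
) -> DiffusionResult:
    """Diffusion components of a feature matrix (e.g. flattened COVET roots).

    The affinity matrix (adaptive Gaussian kernel over the k-NN graph) is
    row-normalised by the inverse degree matrix; eigenvectors of that
    operator, ordered by eigenvalue magnitude and skipping the trivial
    constant one, are the diffusion components.  Each component's sign is
    fixed so that it correlates positively with the first input feature
    (falling back to a positive first loading when that correlation
    vanishes), making the output deterministic.

    If the graph is disconnected, a warning is raised and the components
    are computed on the largest connected component (other rows are NaN).
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n <= m:
        raise ValueError("need more observations than requested components")
    aff = _adaptive_affinity(features, k=k, adaptive_k=adaptive_k, width=width)

    n_comp, labels = connected_components(aff > 0, directed=False)
    mask = np.ones(n, dtype=bool)
    if n_comp > 1:
        warnings.warn(
            f"affinity graph has {n_comp} connected components; "
            "computing diffusion components on the largest"
        )
        biggest = np.argmax(np.bincount(labels))
        mask = labels == biggest
        aff = aff[np.ix_(mask, mask)]

    deg = aff.sum(axis=1)
    deg[deg == 0] = np.finfo(float).eps
    # symmetric conjugate of D^-1 A has the same spectrum and real vectors
    d_isqrt = 1.0 / np.sqrt(deg)
    sym = aff * d_isqrt[:, None] * d_isqrt[None, :]
    w, V = np.linalg.eigh(sym)
    order = np.argsort(-np.abs(w))
    w, V = w[order], V[:, order]
    comps = V * d_isqrt[:, None]  # right eigenvectors of D^-1 A
    # drop the trivial stationary component (eigenvalue 1, constant vector)
    comps, w = comps[:, 1 : m + 1], w[1 : m + 1]
    comps = comps / np.linalg.norm(comps, axis=0)

    f0 = features[mask, 0]
    for j in range(comps.shape[1]):
        c = np.corrcoef(f0, comps[:, j])[0, 1] if f0.std() > 0 else 0.0
        if (np.isfinite(c) and c < 0) or (
            (not np.isfinite(c) or c == 0) and comps[0, j] < 0
        ):
            comps[:, j] = -comps[:, j]

    if mask.all():
        return DiffusionResult(components=comps, eigenvalues=w)
    full = np.full((n, comps.shape[1]), np.nan)
    full[mask] = comps
    return DiffusionResult(components=full, eigenvalues=w)


def _flatten_roots(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    return x


def aot_knn_label_transfer(
    train_sqrt: np.ndarray,
    train_labels: np.ndarray,
    test_sqrt: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """Majority-vote k-NN classification in AOT space.

    Inputs are COVET square roots, (n, g, g) or already flattened; the AOT
    metric reduces to Euclidean distance on the flattened roots.  Vote ties
    are broken by the smallest summed distance to the tied classes' voting
    neighbours, then lexicographically — fully deterministic.
    """
    train_flat = _flatten_roots(train_sqrt)
    test_flat = _flatten_roots(test_sqrt)
    train_labels = np.asarray(train_labels)
    if train_labels.shape[0] != train_flat.shape[0] or train_labels.size == 0:
        raise ValueError("train labels must be nonempty and match train matrices")
    if k > train_flat.shape[0]:
        raise ValueError(f"k={k} exceeds the {train_flat.shape[0]} training niches")
    nn = NearestNeighbors(n_neighbors=k).fit(train_flat)
    dist, idx = nn.kneighbors(test_flat)
    preds = []
    for d_i, nb_i in zip(dist, idx):
        votes: dict = {}
        for d, j in zip(d_i, nb_i):
            lab = train_labels[j]
            cnt, tot = votes.get(lab, (0, 0.0))
            votes[lab] = (cnt + 1, tot + d)
        preds.append(
            min(votes, key=lambda lab: (-votes[lab][0], votes[lab][1], str(lab)))
        )
    return np.asarray(preds)


def niche_composition(
    st_labels: np.ndarray,
    coords: np.ndarray,
    covet_sqrt_st: np.ndarray,
    covet_sqrt_query: np.ndarray | None = None,
    k_niche: int = 8,
    k_reg: int = 5,
    normalize: bool = False,
) -> tuple[np.ndarray, list]:
    """Cell-type composition of each niche, with k-NN regression to queries.

    For every spatial cell, its k = 8 nearest spatial neighbours are counted
    per cell type (rows sum to the niche size, or to 1 if ``normalize``).
    If query COVET roots are given, each query receives the average of the
    ``k_reg`` AOT-nearest spatial cells' composition vectors.  Returns the
    composition matrix and the cell-type category order.
    """
    st_labels = np.asarray(st_labels)
    if st_labels.shape[0] != np.asarray(coords).shape[0]:
        raise ValueError("every spatial cell needs a label")
    categories = sorted(set(st_labels.tolist()), key=str)
    cat_pos = {c: i for i, c in enumerate(categories)}
    niche = build_niche_index(coords, k=k_niche)
    comp = np.zeros((len(st_labels), len(categories)))
    for i, nb in enumerate(niche.neighbors):
        for j in nb:
            comp[i, cat_pos[st_labels[j]]] += 1
    if normalize:
        comp = comp / comp.sum(axis=1, keepdims=True)
    if covet_sqrt_query is None:
        return comp, categories
    train_flat = _flatten_roots(covet_sqrt_st)
    query_flat = _flatten_roots(covet_sqrt_query)
    nn = NearestNeighbors(n_neighbors=min(k_reg, train_flat.shape[0])).fit(train_flat)
    _, idx = nn.kneighbors(query_flat)
    return comp[idx].mean(axis=1), categories


def expression_environment_concordance(
    expr: np.ndarray,
    covet_sqrt: np.ndarray,
    n_clusters: int = 5,
    restarts: int = 10,
    seed: int = 0,
) -> float:
    """Mean adjusted Rand index between k-means clusterings of (log)
    expression and of flattened COVET roots.

    Each side is clustered ``restarts`` times with seeds seed..seed+r-1 and
    the ARI is averaged over all restarts^2 pairings (100 values under the
    defaults), measuring how far a cell's expression predicts its
    microenvironment.
    """
    expr = np.asarray(expr, dtype=float)
    env = _flatten_roots(covet_sqrt)
    if expr.shape[0] < n_clusters:
        raise ValueError("fewer cells than clusters")
    log_expr = np.log1p(expr)
    labels_e, labels_v = [], []
    for r in range(restarts):
        km = KMeans(n_clusters=n_clusters, n_init=1, random_state=seed + r)
        labels_e.append(km.fit_predict(log_expr))
        km = KMeans(n_clusters=n_clusters, n_init=1, random_state=seed + r)
        labels_v.append(km.fit_predict(env))
    aris = [
        adjusted_rand_score(le, lv) for le in labels_e for lv in labels_v
    ]
    return float(np.mean(aris))


def batch_asw(
    latent: np.ndarray,
    modality: np.ndarray,
    cell_type: np.ndarray,
    n_pcs: int = 10,
) -> float:
    """Batch-mixing average silhouette width of a joint latent space.

    The latent is compressed to its top ``n_pcs`` principal components;
    within each cell type, the silhouette of the modality labels is
    computed and folded as 1 - |s| per cell (1 = perfectly mixed,
    0 = fully separated), then averaged within and across cell types.
    Cell types present in a single modality are excluded with a warning.
    """
    latent = np.asarray(latent, dtype=float)
    modality = np.asarray(modality)
    cell_type = np.asarray(cell_type)
    if len(set(modality.tolist())) < 2:
        raise ValueError("need at least two modalities")
    n_pcs = min(n_pcs, latent.shape[1], latent.shape[0] - 1)
    pcs = PCA(n_components=n_pcs, random_state=0).fit_transform(latent)
    scores = []
    for ct in sorted(set(cell_type.tolist()), key=str):
        mask = cell_type == ct
        mods = set(modality[mask].tolist())
        if len(mods) < 2 or mask.sum() <= len(mods):
            warnings.warn(f"cell type {ct!r} not present in both modalities; skipped")
            continue
        sil = silhouette_samples(pcs[mask], modality[mask])
        scores.append(np.mean(1.0 - np.abs(sil)))
    if not scores:
        raise ValueError("no cell type is shared across modalities")
    return float(np.mean(scores))
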