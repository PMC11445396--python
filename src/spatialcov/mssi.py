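"""Multiscale spatial similarity index (MSSI) on a segmented-cell graph.

MSSI scores how similar two per-cell expression profiles are *as spatial
patterns*, adapting the multiscale structural similarity index (MS-SSIM)
from computer vision to tissues: instead of downsampling pixel grids, a
spatial k-NN graph of segmented cells is iteratively coarsened (four times,
each by roughly a factor of two), expression signals are pooled down the
pyramid, and the SSIM luminance / contrast / structure terms are combined
across the five scales by a weighted geometric mean.

The score lives in [0, 1]: 1 for identical patterns, 0 as soon as the two
signals are anti-correlated at any scale (negative structure terms are
clipped to zero, which annihilates the geometric mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "SsimComponents",
    "GraphPyramid",
    "build_pyramid",
    "pool_signal",
    "ssim_components",
    "mssi",
    "MSSI_WEIGHTS",
]

#: scale weights, identical to MS-SSIM's standard five-level weights
MSSI_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])

N_SCALES = 5


@dataclass
class SsimComponents:
    """Luminance, contrast and structure terms of one SSIM evaluation."""

    l: float
    c: float
    s: float
    M: float


@dataclass
class GraphPyramid:
    """Spatial graph at five scales with fine-to-coarse pooling operators.

    ``operators[s]`` maps level s+1 signals to level s+2 signals; its rows
    are convex weights (uniform over the fine nodes merged into each coarse
    node), so constant signals are fixed points of pooling.
    """

    graphs: list[sparse.csr_matrix]
    operators: list[sparse.csr_matrix]

    @property
    def sizes(self) -> list[int]:
        return [g.shape[0] for g in self.graphs]


def _coarsen_once(adj: sparse.csr_matrix) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """One greedy heavy-edge coarsening step.

    Repeatedly contracts the heaviest remaining edge (ties broken by node
    index) until the number of supernodes is at most ceil(n/2) or no edges
    remain.  Disconnected components never merge with each other.
    """
    n = adj.shape[0]
    target = -(-n // 2)  # ceil(n/2)

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    coo = sparse.triu(adj, k=1).tocoo()
    # heaviest edge first; deterministic tie-break by (i, j)
    order = np.lexsort((coo.col, coo.row, -coo.data))
    edges = list(zip(coo.data[order], coo.row[order], coo.col[order]))

    n_groups = n
    # first pass: a matching (merge only untouched nodes) to keep groups
    # balanced, then keep contracting heaviest edges until the factor-2
    # target is met
    touched = np.zeros(n, dtype=bool)
    for _, i, j in edges:
        if n_groups <= target:
            break
        if not touched[i] and not touched[j]:
            parent[find(j)] = find(i)
            touched[i] = touched[j] = True
            n_groups -= 1
    if n_groups > target:
        for _, i, j in edges:
            if n_groups <= target:
                break
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri
                n_groups -= 1

    roots = np.array([find(i) for i in range(n)])
    _, group = np.unique(roots, return_inverse=True)
    m = group.max() + 1

    # pooling operator: uniform average within each group
    counts = np.bincount(group, minlength=m).astype(float)
    C = sparse.csr_matrix(
        (1.0 / counts[group], (group, np.arange(n))), shape=(m, n)
    )
    # coarse adjacency: sum of inter-group weights
    P = sparse.csr_matrix((np.ones(n), (np.arange(n), group)), shape=(n, m))
    coarse = (P.T @ adj @ P).tocsr()
    coarse.setdiag(0)
    coarse.eliminate_zeros()
    return coarse, C


def build_pyramid(coords: np.ndarray, k: int = 8) -> GraphPyramid:
    """Build the five-scale graph pyramid over the spatial k-NN graph.

    The finest graph connects each cell to its ``k`` nearest neighbours
    (symmetrised, edge weight = 2 for mutual neighbours).  Each of the four
    coarsening steps halves the node count (up to rounding) by greedy
    heavy-edge aggregation.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a spatial graph")
    k_eff = min(k, n - 1)
    adj = kneighbors_graph(coords, n_neighbors=k_eff, mode="connectivity")
    adj = (adj + adj.T).tocsr()  # weight 2 on mutual edges
    adj.setdiag(0)
    adj.eliminate_zeros()

    graphs = [adj]
    operators = []
    for _ in range(N_SCALES - 1):
        coarse, C = _coarsen_once(graphs[-1])
        graphs.append(coarse)
        operators.append(C)
    return GraphPyramid(graphs=graphs, operators=operators)


def pool_signal(C: sparse.spmatrix, x: np.ndarray) -> np.ndarray:
    """Pool a per-node signal one level down the pyramid (linear in x)."""
    x = np.asarray(x, dtype=float)
    if C.shape[1] != x.shape[0]:
        raise ValueError(
            f"operator expects {C.shape[1]} nodes, signal has {x.shape[0]}"
        )
    return C @ x


def ssim_components(
    x: np.ndarray,
    y: np.ndarray,
    luminance_constant: str = "standard",
) -> SsimComponents:
    """SSIM luminance / contrast / structure terms for two signals.

    ``M`` is the joint maximum of the two signals; the stabilising constants
    are (0.01*M)^2 and (0.03*M)^2 as in SSIM.  ``luminance_constant``
    selects the luminance denominator constant: ``"standard"`` uses
    (0.01*M)^2 (so l(x,x) = 1); ``"asymmetric"`` uses 0.01/M, an alternative
    form that breaks the identity property and is kept for cross-checking.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    M = float(max(x.max(initial=0.0), y.max(initial=0.0)))
    if M == 0.0:
        # both signals identically zero: limiting case of identical signals
        return SsimComponents(l=1.0, c=1.0, s=1.0, M=0.0)
    mu_x, mu_y = x.mean(), y.mean()
    sd_x, sd_y = x.std(), y.std()
    cov_xy = ((x - mu_x) * (y - mu_y)).mean()
    c1 = (0.01 * M) ** 2
    c2 = (0.03 * M) ** 2
    if luminance_constant == "standard":
        l_den = mu_x**2 + mu_y**2 + c1
    elif luminance_constant == "asymmetric":
        l_den = mu_x**2 + mu_y**2 + 0.01 / M
    else:
        raise ValueError(f"unknown luminance_constant {luminance_constant!r}")
    l = (2 * mu_x * mu_y + c1) / l_den
    c = (2 * sd_x * sd_y + c2) / (sd_x**2 + sd_y**2 + c2)
    s = (cov_xy + c2 / 2) / (sd_x * sd_y + c2 / 2)
    return SsimComponents(l=float(l), c=float(c), s=float(s), M=M)


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def mssi(
    x: np.ndarray,
    y: np.ndarray,
    coords: np.ndarray | None = None,
    k: int = 8,
    pyramid: GraphPyramid | None = None,
    luminance_constant: str = "standard",
) -> float:
    """Multiscale spatial similarity between two per-cell signals.

    Signals are min-max normalised to [0, 1] at the original scale only
    (pooled signals are not re-normalised).  Contrast and structure terms
    are evaluated at scales 1-4, luminance at the coarsest scale 5, and
    combined by a weighted geometric product; negative structure terms are
    clipped to 0.  A precomputed ``pyramid`` can be passed to amortise graph
    construction over many gene pairs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("signals must be nonnegative")
    if pyramid is None:
        if coords is None:
            raise ValueError("either coords or a prebuilt pyramid is required")
        pyramid = build_pyramid(coords, k=k)
    if x.shape[0] != pyramid.sizes[0]:
        raise ValueError("signal length does not match the pyramid's cell count")

    xs, ys = _minmax(x), _minmax(y)
    score = 1.0
    for s_level in range(N_SCALES):
        comp = ssim_components(xs, ys, luminance_constant=luminance_constant)
        w = MSSI_WEIGHTS[s_level]
        if s_level < N_SCALES - 1:
            if xs.shape[0] >= 2:  # c and s undefined on a single node
                factor = comp.c * max(comp.s, 0.0)
                score *= factor**w if factor > 0 else 0.0
            xs = pool_signal(pyramid.operators[s_level], xs)
            ys = pool_signal(pyramid.operators[s_level], ys)
        else:
            score *= max(comp.l, 0.0) ** w
    return float(np.clip(score, 0.0, 1.0))
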