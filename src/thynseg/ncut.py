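"""Normalized-cut spectral segmentation on an intensity + proximity graph.

Pixels are nodes of a weighted undirected graph; the edge weight between
pixels i and j combines gray-level similarity and spatial proximity,

    W_ij = exp(-(F_i - F_j)^2 / sigma_I^2) * exp(-||X_i - X_j||^2 / sigma_X^2)

for pixel distance <= r (in raw pixels) and 0 beyond.  Spatial coordinates
are normalized by max(height, width) so they live in [0, 1]; this makes the
conventional sigma_X = 0.1 consistent with a connection radius of tens of
pixels.  Each pixel is maximally similar to itself: W_ii = 1.

A bipartition (A, B) is scored by the normalized cut

    Ncut(A, B) = cut(A,B)/assoc(A,V) + cut(A,B)/assoc(B,V)

which, unlike the plain minimum cut, penalizes splitting off tiny regions.
Minimizing Ncut relaxes to the generalized eigenproblem
(D - W) y = lambda D y; the eigenvector with the second-smallest eigenvalue
(the Fiedler vector) is thresholded at the quantile that minimizes the true
Ncut, and the bipartition recurses until no split beats the Ncut threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla

from .image_io import as_gray

__all__ = [
    "AffinityParams",
    "AffinityGraph",
    "SegmentationResult",
    "build_weight_matrix",
    "ncut_value",
    "solve_fiedler",
    "discretize_fiedler",
    "recursive_ncut",
]

logger = logging.getLogger(__name__)

#: Largest pixel count accepted by build_weight_matrix (128 x 128).
DEFAULT_NODE_CAP = 16384

#: Below this node count the generalized eigenproblem is solved densely.
_DENSE_LIMIT = 1200


@dataclass(frozen=True)
class AffinityParams:
    """Scales of the affinity kernel.

    sigma_i
        Gray-similarity scale (intensities are in [0, 1]).
    sigma_x
        Spatial scale in normalized coordinates (pixel coordinates divided
        by max(height, width)).
    radius
        Connection radius in raw pixels; weights are exactly zero beyond it.
    """

    sigma_i: float = 0.3
    sigma_x: float = 0.1
    radius: float = 20.0

    def __post_init__(self) -> None:
        if not (self.sigma_i > 0 and self.sigma_x > 0):
            raise ValueError("sigma_i and sigma_x must be > 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


@dataclass(frozen=True)
class AffinityGraph:
    """Sparse symmetric affinity matrix with its degree vector.

    ``shape`` maps nodes to pixels row-major when the graph came from an
    image; it is None for abstract graphs.
    """

    weights: sp.csr_matrix = field(repr=False)
    degrees: np.ndarray = field(repr=False)
    shape: tuple[int, int] | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_matrix(
        cls, W, shape: tuple[int, int] | None = None
    ) -> "AffinityGraph":
        """Wrap an explicit (dense or sparse) symmetric weight matrix."""
        W = sp.csr_matrix(W)
        if W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if (abs(W - W.T) > 1e-12).nnz:
            raise ValueError("weight matrix must be symmetric")
        if W.nnz and W.data.min() < 0:
            raise ValueError("weights must be non-negative")
        d = np.asarray(W.sum(axis=1)).ravel()
        return cls(weights=W, degrees=d, shape=shape)

    def subgraph(self, nodes: np.ndarray) -> "AffinityGraph":
        """Restriction of W to ``nodes``, with degrees recomputed."""
        Wsub = self.weights[nodes][:, nodes].tocsr()
        d = np.asarray(Wsub.sum(axis=1)).ravel()
        return AffinityGraph(weights=Wsub, degrees=d, shape=None)


@dataclass
class SegmentationResult:
    """Label raster plus the Ncut trace of the recursion."""

    labels: np.ndarray
    split_ncuts: list[float]
    rejected_ncuts: list[float]

    @property
    def n_regions(self) -> int:
        return int(self.labels.max()) + 1


def build_weight_matrix(
    img: np.ndarray,
    params: AffinityParams | None = None,
    *,
    node_cap: int = DEFAULT_NODE_CAP,
) -> AffinityGraph:
    """Build the intensity+proximity affinity graph of a gray image.

    Edges connect pixel pairs within ``params.radius`` (Euclidean, raw
    pixels); the weight multiplies a gray-similarity Gaussian (scale
    sigma_i) and a spatial Gaussian over coordinates normalized by
    max(height, width) (scale sigma_x).  Self-loops W_ii = 1.
    """
    img = as_gray(img)
    params = params or AffinityParams()
    h, w = img.shape
    n = h * w
    if n > node_cap:
        raise ValueError(
            f"image has {n} pixels, above the cap of {node_cap}; "
            "downscale or crop before building the affinity graph"
        )
    r = params.radius
    scale = float(max(h, w))
    idx = np.arange(n).reshape(h, w)
    flat = img.ravel()

    rows_l, cols_l, vals_l = [], [], []
    ri = int(np.floor(r))
    for dy in range(0, ri + 1):
        for dx in range(-ri, ri + 1):
            if dy == 0 and dx <= 0:
                continue  # upper half-plane only; mirrored below
            d2_px = dy * dy + dx * dx
            if d2_px > r * r:
                continue
            r0, r1 = max(0, -dy), min(h, h - dy)
            c0, c1 = max(0, -dx), min(w, w - dx)
            if r0 >= r1 or c0 >= c1:
                continue
            src = idx[r0:r1, c0:c1].ravel()
            dst = idx[r0 + dy:r1 + dy, c0 + dx:c1 + dx].ravel()
            fi = img[r0:r1, c0:c1].ravel()
            fj = img[r0 + dy:r1 + dy, c0 + dx:c1 + dx].ravel()
            wgt = np.exp(-((fi - fj) ** 2) / params.sigma_i**2) * np.exp(
                -(d2_px / scale**2) / params.sigma_x**2
            )
            rows_l.append(src)
            cols_l.append(dst)
            vals_l.append(wgt)

    if rows_l:
        rows = np.concatenate(rows_l)
        cols = np.concatenate(cols_l)
        vals = np.concatenate(vals_l)
    else:  # radius smaller than any pixel pair distance
        rows = cols = np.empty(0, dtype=np.intp)
        vals = np.empty(0)
    loops = np.arange(n)
    W = sp.coo_matrix(
        (
            np.concatenate([vals, vals, np.ones(n)]),
            (
                np.concatenate([rows, cols, loops]),
                np.concatenate([cols, rows, loops]),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    d = np.asarray(W.sum(axis=1)).ravel()
    return AffinityGraph(weights=W, degrees=d, shape=(h, w))


def ncut_value(graph: AffinityGraph, mask: np.ndarray) -> float:
    """Normalized-cut value of the bipartition given by a boolean mask.

    cut(A, B) / assoc(A, V) + cut(A, B) / assoc(B, V), with self-loops
    included in the associations (they are entries of W).
    """
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.size != graph.n_nodes:
        raise ValueError("mask length must equal the node count")
    if not mask.any() or mask.all():
        raise ValueError("both sides of the partition must be non-empty")
    x = mask.astype(np.float64)
    assoc_a = float(graph.degrees @ x)
    assoc_b = float(graph.degrees.sum() - assoc_a)
    within_a = float(x @ (graph.weights @ x))
    cut = assoc_a - within_a
    return cut / assoc_a + cut / assoc_b


def _fix_sign(y: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(y) > 1e-12 * max(np.abs(y).max(), 1e-300))
    if nz.size and y[nz[0]] < 0:
        return -y
    return y


def solve_smallest(
    graph: AffinityGraph, k: int = 1, *, tol: float = 1e-10
) -> np.ndarray:
    """First ``k`` non-trivial eigenvectors of (D - W) y = lambda D y.

    Returns an (n, k) array whose columns are the generalized eigenvectors
    with the 2nd, 3rd, ... smallest eigenvalues (the first column is the
    Fiedler vector).  Solved through the symmetrically normalized
    Laplacian L_sym = I - D^{-1/2} W D^{-1/2} (whose eigenvector z maps
    back as y = D^{-1/2} z).  Small graphs use a dense solver; large
    graphs a Lanczos iteration on 2I - L_sym with a deterministic start
    vector, so runs are reproducible.  Sign convention per column: first
    nonzero entry positive.
    """
    n = graph.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    k = min(k, n - 1)
    d = graph.degrees
    if np.any(d <= 0):
        raise ValueError("graph has an isolated zero-degree node")
    dis = 1.0 / np.sqrt(d)
    W = graph.weights
    if n <= _DENSE_LIMIT:
        Lsym = np.eye(n) - (dis[:, None] * W.toarray()) * dis[None, :]
        vals, vecs = scipy.linalg.eigh(Lsym)
        Z = vecs[:, 1:k + 1]
    else:
        Lsym = sp.identity(n, format="csr") - (
            sp.diags(dis) @ W @ sp.diags(dis)
        )
        M = 2.0 * sp.identity(n, format="csr") - Lsym.tocsr()
        v0 = np.ones(n)
        try:
            vals, vecs = spla.eigsh(
                M, k=k + 1, which="LA", v0=v0, tol=tol, maxiter=50 * n
            )
        except spla.ArpackNoConvergence as exc:  # pragma: no cover
            raise FloatingPointError(
                f"Fiedler eigensolver failed to converge on {n} nodes: {exc}"
            ) from exc
        order = np.argsort(2.0 - vals)  # ascending Laplacian eigenvalue
        Z = vecs[:, order[1:k + 1]]
    Y = dis[:, None] * Z
    return np.column_stack([_fix_sign(Y[:, j]) for j in range(Y.shape[1])])


def solve_fiedler(graph: AffinityGraph, *, tol: float = 1e-10) -> np.ndarray:
    """Fiedler vector of the generalized problem (D - W) y = lambda D y.

    The eigenvector with the second-smallest eigenvalue; see
    :func:`solve_smallest` for the solver details and conventions.
    """
    return solve_smallest(graph, 1, tol=tol)[:, 0]


def discretize_fiedler(
    y: np.ndarray, graph: AffinityGraph, n_candidates: int = 32
) -> np.ndarray:
    """Threshold a Fiedler vector at the value minimizing the true Ncut.

    Candidate thresholds sit at ``n_candidates`` evenly spaced quantiles of
    y, augmented with midpoints of the ``n_candidates`` largest gaps in the
    sorted vector (a quantile grid alone can straddle the value gap that
    isolates a region holding only a few percent of the pixels).
    Thresholds that empty a side are skipped.  Ties break toward the more
    balanced split (larger smaller side), then the lower threshold.

    Returns the boolean mask of the side with y above the best threshold.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.size != graph.n_nodes:
        raise ValueError("vector length must equal the node count")
    qs = np.linspace(0.0, 1.0, n_candidates + 2)[1:-1]
    ys = np.sort(y)
    gaps = np.diff(ys)
    top = np.argsort(gaps)[::-1][:n_candidates]
    gap_mids = 0.5 * (ys[top] + ys[top + 1])
    thresholds = np.sort(np.concatenate([np.quantile(y, qs), gap_mids]))
    best = None  # (ncut, -min_side, threshold, mask)
    seen: set[int] = set()
    for thr in thresholds:
        mask = y > thr
        na = int(mask.sum())
        if na == 0 or na == y.size:
            continue
        # mask = y > thr is monotone in thr, so the side size identifies it
        if na in seen:
            continue
        seen.add(na)
        val = ncut_value(graph, mask)
        cand = (val, -min(na, y.size - na), thr)
        if best is None or cand < best[:3]:
            best = (*cand, mask)
    if best is None:
        raise ValueError("degenerate Fiedler vector: every split is empty-sided")
    return best[3]


def best_spectral_split(
    graph: AffinityGraph, *, n_candidates: int = 32, n_eigvecs: int = 4
) -> tuple[np.ndarray, float]:
    """Best discretized bipartition over the smallest few eigenvectors.

    The Fiedler vector of a large uniform region can be a smooth spatial
    mode whose every threshold split is expensive, while a compact
    salient structure only shows up in a slightly higher eigenvector; the
    segmentation therefore discretizes each of the ``n_eigvecs`` smallest
    non-trivial generalized eigenvectors and keeps the bipartition with
    the minimal true Ncut value.

    Returns ``(mask, ncut)``.
    """
    Y = solve_smallest(graph, n_eigvecs)
    best_mask = None
    best_val = np.inf
    for j in range(Y.shape[1]):
        try:
            mask = discretize_fiedler(Y[:, j], graph, n_candidates=n_candidates)
        except ValueError:
            continue
        val = ncut_value(graph, mask)
        if val < best_val:
            best_val = val
            best_mask = mask
    if best_mask is None:
        raise ValueError("no eigenvector produced a two-sided split")
    return best_mask, best_val


def recursive_ncut(
    img: np.ndarray,
    params: AffinityParams | None = None,
    threshold: float = 0.065,
    max_regions: int = 10,
    *,
    min_region_px: int = 16,
    n_candidates: int = 32,
    n_eigvecs: int = 4,
    node_cap: int = DEFAULT_NODE_CAP,
) -> SegmentationResult:
    """Recursive two-way normalized-cut segmentation of a gray image.

    The affinity graph is built once; regions are bipartitioned (largest
    region first) while the best split's Ncut stays below ``threshold``,
    the region count stays below ``max_regions`` and both sides keep at
    least ``min_region_px`` pixels.  Each split searches the
    ``n_eigvecs`` smallest non-trivial eigenvectors (see
    :func:`best_spectral_split`).  Disconnected regions are split along
    connected components first (an Ncut of exactly 0).
    """
    img = as_gray(img)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if max_regions < 2:
        raise ValueError("max_regions must be >= 2")
    graph = build_weight_matrix(img, params, node_cap=node_cap)
    n = graph.n_nodes

    final: list[np.ndarray] = []
    split_ncuts: list[float] = []
    rejected: list[float] = []
    active: list[np.ndarray] = [np.arange(n)]

    def n_regions() -> int:
        return len(final) + len(active)

    while active:
        # deterministic traversal: largest active region first
        k = max(range(len(active)), key=lambda i: (active[i].size, -active[i][0]))
        nodes = active.pop(k)
        if n_regions() + 2 > max_regions or nodes.size < 2 * min_region_px:
            final.append(nodes)
            continue
        sub = graph.subgraph(nodes)
        n_comp, comp = csgraph.connected_components(sub.weights, directed=False)
        if n_comp > 1:
            side = comp == 0
            if side.sum() >= min_region_px and (~side).sum() >= min_region_px:
                split_ncuts.append(0.0)
                active.append(nodes[side])
                active.append(nodes[~side])
                continue
            # tiny stray component: keep the region whole
            final.append(nodes)
            continue
        try:
            side, val = best_spectral_split(
                sub, n_candidates=n_candidates, n_eigvecs=n_eigvecs
            )
        except ValueError:
            final.append(nodes)
            continue
        if (
            val < threshold
            and side.sum() >= min_region_px
            and (~side).sum() >= min_region_px
        ):
            split_ncuts.append(val)
            active.append(nodes[side])
            active.append(nodes[~side])
            logger.info(
                "accepted split: ncut=%.5f sizes=(%d, %d)",
                val, int(side.sum()), int((~side).sum()),
            )
        else:
            rejected.append(val)
            final.append(nodes)
            logger.info("rejected split: ncut=%.5f >= %.5f", val, threshold)

    # deterministic label order: descending size, then first node index
    final.sort(key=lambda ids: (-ids.size, ids[0]))
    labels_flat = np.empty(n, dtype=np.intp)
    for lab, ids in enumerate(final):
        labels_flat[ids] = lab
    assert graph.shape is not None
    return SegmentationResult(
        labels=labels_flat.reshape(graph.shape),
        split_ncuts=split_ncuts,
        rejected_ncuts=rejected,
    )
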