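"""EMT pseudotime inference, cell ordering, and pseudo-stage binning.

The epithelial-to-mesenchymal transition (EMT) is treated as a linear
trajectory: every cell receives a score in [0, 1] placing it on the E -> M
axis. Two estimators are provided: a marker-based one (rank of the
mesenchymal marker VIM, "VIM-time") and a graph-based one ("W-time") that
averages randomized shortest-path trajectories over an ensemble of
l-out-of-k nearest-neighbor graphs. Both are oriented so the score
correlates non-negatively with the mesenchymal marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import dijkstra
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import ExpressionMatrix, ValidationError


@dataclass
class Pseudotime:
    """Per-cell trajectory score in [0, 1] (both endpoints attained)."""

    cell_ids: np.ndarray
    score: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=str)
        self.score = np.asarray(self.score, dtype=float)
        if len(self.cell_ids) != len(self.score):
            raise ValidationError("pseudotime ids and scores have different lengths")

    def __len__(self) -> int:
        return len(self.score)


@dataclass
class PseudotimeSeries:
    """Expression matrix with columns sorted by ascending pseudotime."""

    matrix: ExpressionMatrix
    pseudotime: np.ndarray


def _rescale01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValidationError("degenerate pseudotime: all scores identical")
    return (x - lo) / (hi - lo)


def _orient(score: np.ndarray, marker_expr: np.ndarray) -> np.ndarray:
    """Flip the score so its correlation with the mesenchymal marker is >= 0."""
    if np.std(marker_expr) == 0 or np.std(score) == 0:
        return score
    if np.corrcoef(score, marker_expr)[0, 1] < 0:
        return 1.0 - score
    return score


def vim_time(mat: ExpressionMatrix, marker_gene: str = "VIM") -> Pseudotime:
    """Marker-based pseudotime: rank the cells by the marker's expression.

    Ties share the mean of their ranks before min-max rescaling to [0, 1].
    """
    expr = mat.gene_values(marker_gene)
    if np.all(expr == expr[0]):
        raise ValidationError(
            f"marker {marker_gene!r} is constant; ordering undefined")
    score = _rescale01(rankdata(expr, method="average"))
    return Pseudotime(mat.cell_ids.copy(), score, "vim")


def wanderlust_time(mat: ExpressionMatrix,
                    k: int = 25,
                    l: int = 15,
                    n_graphs: int = 20,
                    start_cell: str | None = None,
                    seed: int = 0,
                    n_reps: int = 10,
                    n_pca: int = 20,
                    marker_gene: str = "VIM") -> Pseudotime:
    """Graph-ensemble pseudotime (W-time).

    Builds the k-nearest-neighbor graph on Euclidean distances in PC space,
    draws ``n_graphs`` subgraphs keeping ``l`` of each cell's k neighbors,
    and on each runs ``n_reps`` randomized shortest-path repetitions (edge
    weights jittered multiplicatively by U(0.5, 1.5)) from the start cell.
    Per-cell scores are averaged over repetitions and graphs, rescaled to
    [0, 1], and oriented against the mesenchymal marker.

    The default start cell is the cell with minimal marker expression — the
    epithelial end of the E -> M axis.
    """
    c = mat.n_cells
    if not l <= k < c:
        raise ValidationError(f"need l <= k < C (got l={l}, k={k}, C={c})")

    X = mat.values.T
    pcs = PCA(n_components=min(n_pca, min(X.shape)), svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    if start_cell is None:
        start = int(np.argmin(mat.gene_values(marker_gene)))
    else:
        hits = np.flatnonzero(mat.cell_ids == start_cell)
        if hits.size == 0:
            raise ValidationError(f"start cell {start_cell!r} not found")
        start = int(hits[0])

    rng = np.random.default_rng(seed)
    rows = np.repeat(np.arange(c), l)
    total = np.zeros(c)
    for _ in range(n_graphs):
        if l == k:
            pick = np.broadcast_to(np.arange(k), (c, k))
        else:
            pick = np.argsort(rng.random((c, k)), axis=1)[:, :l]
        cols = np.take_along_axis(idx, pick, axis=1).ravel()
        w = np.take_along_axis(dist, pick, axis=1).ravel()
        # zero distances (duplicate cells) would break the multiplicative jitter
        w = np.maximum(w, 1e-12)
        for _ in range(n_reps):
            jitter = rng.uniform(0.5, 1.5, size=w.shape)
            a = scipy.sparse.csr_matrix((w * jitter, (rows, cols)), shape=(c, c))
            a = a.maximum(a.T)  # undirected
            d = dijkstra(a, directed=False, indices=start)
            unreachable = int(np.isinf(d).sum())
            if unreachable:
                raise ValidationError(
                    f"k-NN subgraph disconnected: {unreachable} cell(s) "
                    f"unreachable from the start cell")
            total += d
    score = _rescale01(total / (n_graphs * n_reps))
    if marker_gene in mat.gene_ids:
        score = _orient(score, mat.gene_values(marker_gene))
    return Pseudotime(mat.cell_ids.copy(), score, "wanderlust")


def order_cells(mat: ExpressionMatrix, pt: Pseudotime) -> PseudotimeSeries:
    """Sort columns by ascending pseudotime (ties: lexicographic cell id)."""
    pos = {cid: i for i, cid in enumerate(pt.cell_ids)}
    try:
        scores = np.asarray([pt.score[pos[cid]] for cid in mat.cell_ids])
    except KeyError as exc:
        raise ValidationError(f"cell {exc.args[0]!r} missing from pseudotime") from None
    order = np.lexsort((mat.cell_ids, scores))
    return PseudotimeSeries(mat.subset_cells(order), scores[order])


def bin_pseudotime(series: PseudotimeSeries, n_bins: int = 10) -> np.ndarray:
    """Average expression over equal-width pseudotime bins.

    Bin ``b`` covers [(b-1)/n_bins, b/n_bins), with the last bin closed at 1.
    Returns a (G, n_bins) array; empty bins are NaN.
    """
    c = series.matrix.n_cells
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    if n_bins > c:
        raise ValidationError(f"n_bins ({n_bins}) exceeds the number of cells ({c})")
    which = np.minimum((series.pseudotime * n_bins).astype(int), n_bins - 1)
    out = np.full((series.matrix.n_genes, n_bins), np.nan)
    for b in range(n_bins):
        members = which == b
        if members.any():
            out[:, b] = series.matrix.values[:, members].mean(axis=1)
    return out
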