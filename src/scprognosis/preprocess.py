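"""Single-cell denoising/imputation and gene filtering.

Dropout (false zeros from failed transcript capture) biases every downstream
gene-gene statistic, so the first stage diffuses expression across
transcriptionally similar cells: PCA on cells, an adaptive Gaussian kernel on
the cell-cell distances, symmetrization, Markov row-normalization, and a
``t``-step diffusion of the raw matrix through the resulting transition
matrix. Low-coverage / low-expression genes are removed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .io_formats import ExpressionMatrix, ValidationError


@dataclass
class ImputationParams:
    """Diffusion-imputation parameters.

    n_pca : components of the cell-space PCA used for distances.
    k     : neighborhood size kept in the affinity kernel.
    ka    : adaptive-bandwidth index; per-cell bandwidth is the distance to
            the ka-th nearest neighbor (ka <= k).
    t     : diffusion time, i.e. the power of the Markov matrix.
    """

    n_pca: int = 20
    k: int = 30
    ka: int = 10
    t: int = 6

    def __post_init__(self) -> None:
        if self.ka > self.k:
            raise ValidationError(f"ka ({self.ka}) must be <= k ({self.k})")
        if min(self.n_pca, self.k, self.ka, self.t) < 1:
            raise ValidationError("imputation parameters must be positive integers")


def markov_matrix(mat: ExpressionMatrix, params: ImputationParams) -> np.ndarray:
    """Cell-cell Markov transition matrix of the diffusion operator.

    Affinity kernel: ``exp(-(d/sigma_i)^2)`` with ``sigma_i`` the distance to
    the ka-th neighbor; affinities beyond the k-th neighbor are zeroed, the
    matrix is symmetrized as ``(A + A^T)/2`` and row-normalized.
    """
    c = mat.n_cells
    if params.k >= c:
        raise ValidationError(f"k ({params.k}) must be smaller than the number of cells ({c})")
    zero_cells = np.flatnonzero(mat.values.sum(axis=0) == 0)
    if zero_cells.size:
        names = ", ".join(mat.cell_ids[zero_cells][:5])
        raise ValidationError(f"all-zero cell(s) cannot be imputed: {names}")

    X = mat.values.T  # cells x genes
    n_pca = min(params.n_pca, min(X.shape))
    pcs = PCA(n_components=n_pca, svd_solver="full").fit_transform(X)
    dist = cdist(pcs, pcs)

    order = np.argsort(dist, axis=1, kind="stable")  # self first (distance 0)
    sigma = np.take_along_axis(dist, order[:, params.ka:params.ka + 1], axis=1)
    # duplicate cells give sigma = 0; fall back to the nearest positive distance
    for i in np.flatnonzero(sigma[:, 0] == 0):
        positive = dist[i][dist[i] > 0]
        sigma[i, 0] = positive.min() if positive.size else 1.0

    affinity = np.exp(-((dist / sigma) ** 2))
    keep = np.zeros_like(affinity, dtype=bool)
    np.put_along_axis(keep, order[:, : params.k + 1], True, axis=1)  # self + k nearest
    affinity[~keep] = 0.0
    affinity = (affinity + affinity.T) / 2.0
    return affinity / affinity.sum(axis=1, keepdims=True)


def magic_impute(raw: ExpressionMatrix,
                 params: ImputationParams | None = None) -> ExpressionMatrix:
    """Diffusion-based imputation: ``M^t`` applied to the cell profiles.

    Returns a matrix of the same shape and ids; values stay non-negative
    because the diffusion operator is a convex combination of cell profiles.
    """
    params = params or ImputationParams()
    m = markov_matrix(raw, params)
    mt = np.linalg.matrix_power(m, params.t)
    imputed = (mt @ raw.values.T).T
    np.clip(imputed, 0.0, None, out=imputed)  # guard round-off only
    return ExpressionMatrix(imputed, raw.gene_ids.copy(), raw.cell_ids.copy())


def filter_genes(mat: ExpressionMatrix,
                 min_coverage: float = 0.1,
                 min_mean_expr: float | None = None) -> ExpressionMatrix:
    """Drop genes with low coverage or low mean expression.

    A gene survives when (fraction of cells with value > 0) >= ``min_coverage``
    and mean expression >= ``min_mean_expr``. When ``min_mean_expr`` is None it
    defaults to the 10th percentile of the per-gene means of ``mat`` (note this
    default is data-dependent; pass an explicit threshold for idempotent
    re-application). Gene order is preserved.
    """
    if not 0.0 <= min_coverage <= 1.0:
        raise ValidationError("min_coverage must be in [0, 1]")
    means = mat.values.mean(axis=1)
    if min_mean_expr is None:
        min_mean_expr = float(np.percentile(means, 10.0))
    coverage = (mat.values > 0).mean(axis=1)
    keep = (coverage >= min_coverage) & (means >= min_mean_expr)
    if not keep.any():
        raise ValidationError(
            "gene filter removed every gene; relax min_coverage/min_mean_expr")
    return ExpressionMatrix(mat.values[keep], mat.gene_ids[keep], mat.cell_ids.copy())
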