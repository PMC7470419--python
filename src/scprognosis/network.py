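"""Lag-based dynamic co-expression network from a pseudotime series.

With cells ordered along pseudotime, the association between two genes is
the maximum absolute Pearson correlation (MAC) over time lags
``l in {0..max_lag}``: the leading gene's first ``window`` values are
correlated with the lagging gene's values shifted forward by ``l``. A fixed
window of ``C - max_lag`` cells keeps every lag's correlation on an equal
sample size. Edges run from the leading gene to its lagged target; edge
significance comes from a cell-order permutation null pooled across gene
pairs, Benjamini-Hochberg adjusted over all tested ordered pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io_formats import ValidationError
from .pseudotime import PseudotimeSeries
from .ranking import mad_score


@dataclass
class CoexpressionNetwork:
    """Directed gene graph with MAC weights and permutation significance.

    ``edges`` columns: source, target, mac, best_lag, p, q. ``tested`` holds
    the full table of tested ordered pairs (before the significance cut),
    which downstream consumers can re-threshold.
    """

    nodes: np.ndarray
    edges: pd.DataFrame
    tested: pd.DataFrame | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def mac_lagged(x, y, max_lag: int | None = None, window: int | None = None):
    """Maximum absolute lagged Pearson correlation of two ordered series.

    For each lag ``l``, ``r_l = Pearson(x[0:window], y[l:l+window])``; returns
    ``(max_l |r_l|, argmax)`` with the smallest lag winning ties. Lags where
    either segment has zero variance are skipped; if every lag is skipped the
    MAC is undefined and ``(nan, -1)`` is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = len(x)
    if len(y) != c:
        raise ValidationError("series lengths differ")
    if max_lag is None:
        max_lag = c // 3
    if window is None:
        window = c - max_lag
    if window < 3:
        raise ValidationError(f"window ({window}) must be >= 3")
    if max_lag + window > c:
        raise ValidationError("max_lag + window exceeds series length")

    best, best_lag = -1.0, -1
    xs = x[:window]
    if np.std(xs) == 0:
        return float("nan"), -1
    for lag in range(max_lag + 1):
        ys = y[lag:lag + window]
        if np.std(ys) == 0:
            continue
        r = abs(float(np.corrcoef(xs, ys)[0, 1]))
        if r > best:
            best, best_lag = r, lag
    if best_lag < 0:
        return float("nan"), -1
    return min(best, 1.0), best_lag


def _windowed_moments(X: np.ndarray, window: int, max_lag: int):
    """Mean and population std of X[:, l:l+window] for every lag l."""
    g, c = X.shape
    cs = np.cumsum(X, axis=1)
    cs2 = np.cumsum(X * X, axis=1)
    cs = np.hstack([np.zeros((g, 1)), cs])
    cs2 = np.hstack([np.zeros((g, 1)), cs2])
    lags = np.arange(max_lag + 1)
    s = cs[:, lags + window] - cs[:, lags]        # (G, L+1)
    s2 = cs2[:, lags + window] - cs2[:, lags]
    mean = s / window
    var = np.maximum(s2 / window - mean ** 2, 0.0)
    return mean, np.sqrt(var)


def all_pairs_mac(X: np.ndarray, max_lag: int, window: int):
    """MAC and best lag for every ordered gene pair (rows of ``X`` lead).

    Returns ``(mac, best_lag, valid)`` arrays of shape (G, G); entry (i, j)
    is for the edge i -> j. Ties across lags keep the smallest lag.
    """
    g, c = X.shape
    mean, std = _windowed_moments(X, window, max_lag)
    x0 = X[:, :window]
    m0, s0 = mean[:, 0], std[:, 0]

    mac = np.full((g, g), -1.0)
    best = np.full((g, g), -1, dtype=int)
    for lag in range(max_lag + 1):
        sl = std[:, lag]
        ok = np.outer(s0 > 0, sl > 0)
        if not ok.any():
            continue
        cross = x0 @ X[:, lag:lag + window].T / window
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (cross - np.outer(m0, mean[:, lag])) / np.outer(s0, sl)
        r = np.abs(r)
        r[~ok] = -1.0
        upd = r > mac
        mac[upd] = r[upd]
        best[upd] = lag
    valid = best >= 0
    np.clip(mac, None, 1.0, out=mac)
    mac[~valid] = np.nan
    np.fill_diagonal(valid, False)
    return mac, best, valid


def build_network(series: PseudotimeSeries,
                  max_genes: int = 2000,
                  fdr: float = 0.05,
                  n_perm: int = 200,
                  seed: int = 0,
                  max_lag: int | None = None,
                  correction: str = "bh") -> CoexpressionNetwork:
    """Build the directed MAC network with permutation significance.

    Every ordered pair (g, tg) is tested with g as the leading series. The
    null distribution is built by shuffling the cell order ``n_perm`` times
    and recomputing all pairwise MACs; null values are pooled across pairs,
    so p-value resolution is ~1/(n_perm * G^2) rather than 1/n_perm. Pairs
    are kept as edges when the BH-adjusted q (or the raw p, for
    ``correction="none"``) is <= ``fdr``. When G exceeds ``max_genes`` only
    the top ``max_genes`` genes by MAD enter the quadratic test.
    """
    if not 0.0 < fdr <= 1.0:
        raise ValidationError("fdr must be in (0, 1]")
    if correction not in ("bh", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    if n_perm < 20:
        warnings.warn(f"n_perm={n_perm} < 20 gives unstable permutation p-values")

    mat = series.matrix
    X = mat.values
    names = mat.gene_ids
    if mat.n_genes > max_genes:
        mads = np.asarray([mad_score(row) for row in X])
        keep = np.argsort(-mads, kind="stable")[:max_genes]
        keep.sort()
        X, names = X[keep], names[keep]

    g, c = X.shape
    if max_lag is None:
        max_lag = c // 3
    window = c - max_lag
    if window < 3:
        raise ValidationError("too few cells for the requested max_lag")

    mac, best, valid = all_pairs_mac(X, max_lag, window)

    rng = np.random.default_rng(seed)
    null_chunks = []
    for _ in range(n_perm):
        # each gene's series is shuffled independently, breaking both the
        # cross-gene alignment and the lag structure
        pmac, _, pvalid = all_pairs_mac(rng.permuted(X, axis=1), max_lag, window)
        null_chunks.append(pmac[pvalid])
    null = np.sort(np.concatenate(null_chunks)) if null_chunks else np.array([])
    n_null = len(null)

    src, tgt = np.nonzero(valid)
    obs = mac[valid]
    if n_null:
        exceed = n_null - np.searchsorted(null, obs, side="left")
        p = (1.0 + exceed) / (n_null + 1.0)
    else:
        p = np.ones_like(obs)
    q = false_discovery_control(p, method="bh") if len(p) else p

    tested = pd.DataFrame({
        "source": names[src],
        "target": names[tgt],
        "mac": obs,
        "best_lag": best[valid],
        "p": p,
        "q": q,
    })
    crit = tested["q"] if correction == "bh" else tested["p"]
    edges = tested[crit <= fdr].reset_index(drop=True)
    return CoexpressionNetwork(names.copy(), edges, tested)
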