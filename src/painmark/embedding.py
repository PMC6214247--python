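"""Unsupervised comparison of the interpolated signals: PCA and MCE.

The 14 interpolated topological curves plus the behavioural curve form a
signal matrix (rows = signals, columns = hourly grid values).  Two
parameter-free dimensionality reductions are applied:

* **PCA** on the z-scored, sign-aligned matrix (linear analysis);
* **MCE** — Minimum Curvilinear Embedding — on the quantile-normalized
  matrix (nonlinear analysis).  Curvilinear distances between signals are
  estimated as pairwise path distances over the Euclidean minimum spanning
  tree; the resulting MC-kernel is factorized by singular value
  decomposition *without* centering, and the first coordinates (left
  singular vectors scaled by singular values) give the embedding.

Sign alignment multiplies by -1 every signal that is negatively correlated
with a reference row (the behavioural signal), so anti-correlated markers
map near their correlated counterparts rather than at the opposite extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

logger = logging.getLogger("painmark")


@dataclass(frozen=True)
class SignalMatrix:
    """Row-per-signal matrix with preprocessing provenance flags."""

    data: pd.DataFrame  # rows: signal labels; columns: grid hours
    zscored: bool = False
    sign_aligned: bool = False
    quantile_normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("signal matrix must have no missing entries")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate signal labels")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def labels(self) -> list[str]:
        return list(self.data.index)


def signal_matrix_from_signals(signals: dict[str, np.ndarray]) -> SignalMatrix:
    """Assemble a :class:`SignalMatrix` from equally long label -> values pairs."""
    lengths = {len(v) for v in signals.values()}
    if len(lengths) != 1:
        raise ValueError("all signals must share one grid")
    df = pd.DataFrame(
        {k: np.asarray(v, dtype=float) for k, v in signals.items()}
    ).T
    return SignalMatrix(df)


def zscore_rows(m: SignalMatrix) -> SignalMatrix:
    """Scale each row to mean 0, standard deviation 1."""
    x = m.values
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [m.labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant signal(s) cannot be z-scored: {bad}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(m, data=pd.DataFrame(z, index=m.data.index, columns=m.data.columns),
                   zscored=True)


def sign_align(m: SignalMatrix, reference_row: str) -> SignalMatrix:
    """Flip rows negatively correlated with the reference row.

    After alignment every row has non-negative Pearson correlation with the
    reference; rows with exactly zero correlation are left unflipped.  The
    set of flipped labels is logged.
    """
    if reference_row not in m.data.index:
        raise KeyError(f"reference row {reference_row!r} not present")
    x = m.values
    ref = m.data.loc[reference_row].to_numpy(dtype=float)
    refc = ref - ref.mean()
    rowc = x - x.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        corr = (rowc @ refc) / (np.linalg.norm(rowc, axis=1) * np.linalg.norm(refc))
    flip = corr < 0
    if flip.any():
        logger.info("sign-aligned (flipped): %s",
                    [m.labels[i] for i in np.nonzero(flip)[0]])
    out = x * np.where(flip, -1.0, 1.0)[:, None]
    return replace(m, data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                   sign_aligned=True)


def pca_embed(m: SignalMatrix, dims: int = 2) -> pd.DataFrame:
    """Project rows onto the top variance-maximizing orthogonal directions.

    Returns a DataFrame (signal label x dim1..dimk) with the explained
    variance per component stored in ``df.attrs['explained_variance']``.
    """
    x = m.values
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least three signals")
    if dims > min(x.shape[0] - 1, x.shape[1]):
        raise ValueError("dims exceeds the rank of the signal matrix")
    pca = PCA(n_components=dims, svd_solver="full")
    coords = pca.fit_transform(x)
    df = pd.DataFrame(coords, index=m.data.index,
                      columns=[f"dim{i+1}" for i in range(dims)])
    df.attrs["explained_variance"] = tuple(map(float, pca.explained_variance_))
    return df


def quantile_normalize_rows(m: SignalMatrix) -> SignalMatrix:
    """Give every row the identical value distribution (rank-mean profile).

    Each row's sorted values are replaced by the across-row mean of the
    sorted profiles; within-row rank order is preserved, ties receive the
    average of the corresponding reference values.
    """
    x = m.values
    order = np.sort(x, axis=1)
    reference = order.mean(axis=0)
    ranks = stats.rankdata(x, axis=1)  # average ties -> possibly fractional
    grid = np.arange(1, x.shape[1] + 1, dtype=float)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = np.interp(ranks[i], grid, reference)
    return replace(m, data=pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
                   quantile_normalized=True)


def mc_kernel(x: np.ndarray) -> np.ndarray:
    """Minimum-curvilinear kernel: pairwise path distances over the Euclidean MST.

    Symmetric, zero-diagonal, and additive along tree paths.  Kruskal tie
    handling inside the sparse MST routine is deterministic given row order.
    """
    d = squareform(pdist(x, metric="euclidean"))
    mst = minimum_spanning_tree(d).toarray()
    tree = mst + mst.T
    # zero-weight tree edges between duplicate rows must stay traversable
    mask = (mst + mst.T) > 0
    k = shortest_path(np.where(mask, tree, 0.0), method="D", directed=False)
    if np.isinf(k).any():
        # duplicates produced exact-zero MST edges dropped by the sparse
        # representation; fall back to a dense tree walk over the edge list
        k = _tree_distances_dense(d)
    return k


def _tree_distances_dense(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    edges = sorted(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            adj[i].append((j, w))
            adj[j].append((i, w))
    out = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for v, dv in dist.items():
            out[s, v] = dv
    return out


def mce_embed(m: SignalMatrix, dims: int = 2, skip_first: bool = False) -> pd.DataFrame:
    """Minimum Curvilinear Embedding of the signals.

    Requires a quantile-normalized matrix (flag enforced).  The MC-kernel is
    decomposed by SVD without centering; coordinates are left singular
    vectors scaled by singular values.  ``skip_first`` drops the leading
    component (a convention that differs between MCE variants; default off).
    Axis signs are arbitrary (SVD indeterminacy).
    """
    if not m.quantile_normalized:
        raise ValueError("MCE requires a quantile-normalized signal matrix")
    x = m.values
    if x.shape[0] < 3:
        raise ValueError("MCE needs at least three signals")
    k = mc_kernel(x)
    if np.all(k == 0):
        raise ValueError("degenerate embedding: all signals identical")
    u, s, _ = np.linalg.svd(k)
    start = 1 if skip_first else 0
    if start + dims > len(s):
        raise ValueError("dims exceeds available components")
    coords = u[:, start : start + dims] * s[start : start + dims]
    return pd.DataFrame(coords, index=m.data.index,
                        columns=[f"dim{i+1}" for i in range(dims)])
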