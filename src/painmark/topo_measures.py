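"""The 14 topological measures of a binary connectome, with their null models.

Nine deterministic measures
    AND   average node degree
    CPL   characteristic path length (mean shortest-path length, connected pairs)
    AE    average efficiency (mean inverse shortest-path length)
    ACC   average clustering coefficient
    ACCE  average closeness centrality
    ANBC  average node betweenness centrality (unordered pairs, endpoints excluded)
    AEBC  average edge betweenness centrality
    AR    average radiality
    LCPcorr  local-community-paradigm correlation: Pearson correlation between
             the number of common neighbours (CN) of each link and the number
             of links among those common neighbours (LCL), over links with
             CN > 1.

Five stochastic measures (null-model or resampling based)
    SWsigma   small-worldness sigma = (C/C_rand)/(L/L_rand)
    SWomega   small-worldness omega = L_rand/L - C/C_latt, in [-1, 1]
    PLpvalue  bootstrap goodness-of-fit p-value for a discrete power-law
              degree distribution (power law accepted when p >= 0.1)
    Q         modularity of the best partition found by a seeded heuristic
    SC        structural consistency (link predictability via first-order
              eigen-perturbation), in [0, 1]

All measures are defined on binarized connectomes only; calling any of them
on a weighted connectome raises.  Results that are mathematically undefined
(radiality on diameter <= 1, LCP-corr with fewer than two qualifying links or
zero variance, ...) are returned as ``None`` — never silently 0.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Optional

import networkx as nx
import numpy as np
from scipy import optimize, special
from scipy.sparse.csgraph import connected_components, shortest_path

from .graph_core import Connectome

logger = logging.getLogger("painmark")

MEASURE_NAMES = (
    "AND", "CPL", "AE", "ACC", "ACCE", "ANBC", "AEBC", "AR", "LCPcorr",
    "SWsigma", "SWomega", "PLpvalue", "Q", "SC",
)

DETERMINISTIC_MEASURES = MEASURE_NAMES[:9]
STOCHASTIC_MEASURES = MEASURE_NAMES[9:]


@dataclass(frozen=True)
class GraphMetrics:
    """One named value per topological measure; ``None`` marks undefined."""

    AND: Optional[float] = None
    CPL: Optional[float] = None
    AE: Optional[float] = None
    ACC: Optional[float] = None
    ACCE: Optional[float] = None
    ANBC: Optional[float] = None
    AEBC: Optional[float] = None
    AR: Optional[float] = None
    LCPcorr: Optional[float] = None
    SWsigma: Optional[float] = None
    SWomega: Optional[float] = None
    PLpvalue: Optional[float] = None
    Q: Optional[float] = None
    SC: Optional[float] = None

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_csv_row(self) -> str:
        """One CSV row, undefined values as empty cells."""
        return ",".join(
            "" if v is None else repr(float(v)) for v in self.as_dict().values()
        )


@dataclass(frozen=True)
class NullEnsembleConfig:
    """Configuration of degree-preserving null-network ensembles."""

    n_realizations: int = 10
    swap_multiplier: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass(frozen=True)
class MeasureConfig:
    """Settings for the stochastic measures (defaults are study-scale)."""

    null: NullEnsembleConfig = field(default_factory=NullEnsembleConfig)
    n_bootstrap: int = 1000
    perturb_fraction: float = 0.1
    sc_repeats: int = 10
    seed: int = 0


def _require_binary(c: Connectome) -> None:
    if not c.binary:
        raise ValueError("topological measures require a binarized connectome")


def _require_nonempty(c: Connectome) -> None:
    _require_binary(c)
    if c.n_nodes == 0:
        raise ValueError("measure undefined on the empty graph")


def _pairwise_distances(c: Connectome) -> np.ndarray:
    """Dense unweighted shortest-path matrix; inf for disconnected pairs."""
    return shortest_path(c.adjacency, method="D", unweighted=True, directed=False)


# ---------------------------------------------------------------------------
# Deterministic measures
# ---------------------------------------------------------------------------

def average_node_degree(c: Connectome) -> float:
    """AND: mean node degree, sum_i d_i / n."""
    _require_nonempty(c)
    return float(c.adjacency.sum(axis=1).mean())


def characteristic_path_length(c: Connectome) -> float:
    """CPL: mean shortest-path length over unordered connected pairs.

    Infinite distances (disconnected pairs) are excluded from the mean, so
    transiently disconnected ensemble members still yield a defined value.
    """
    _require_nonempty(c)
    d = _pairwise_distances(c)
    iu = np.triu_indices(c.n_nodes, k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("no connected node pair: CPL undefined")
    return float(finite.mean())


def average_efficiency(c: Connectome) -> float:
    """AE: mean inverse shortest-path length; disconnected pairs contribute 0."""
    _require_nonempty(c)
    if c.n_nodes < 2:
        raise ValueError("efficiency needs at least two nodes")
    d = _pairwise_distances(c)
    iu = np.triu_indices(c.n_nodes, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def average_clustering_coefficient(c: Connectome) -> float:
    """ACC: mean local clustering; nodes with degree < 2 contribute 0."""
    _require_nonempty(c)
    return float(nx.average_clustering(c.to_networkx()))


def average_closeness_centrality(c: Connectome) -> float:
    """ACCE: mean of (n-1)/sum_j sp_ij over nodes.

    On disconnected graphs each node's closeness is computed within its own
    component (isolated nodes contribute 0).
    """
    _require_nonempty(c)
    cc = nx.closeness_centrality(c.to_networkx(), wf_improved=False)
    return float(np.mean(list(cc.values())))


def average_node_betweenness(c: Connectome) -> float:
    """ANBC: mean over nodes of shortest-path betweenness.

    Betweenness is summed over unordered pairs {j, k}, endpoints excluded,
    with no normalization beyond the final 1/n.
    """
    _require_nonempty(c)
    bc = nx.betweenness_centrality(c.to_networkx(), normalized=False)
    return float(np.mean(list(bc.values())))


def average_edge_betweenness(c: Connectome) -> float:
    """AEBC: mean over edges of shortest-path load over unordered pairs."""
    _require_nonempty(c)
    if c.n_edges == 0:
        raise ValueError("edge betweenness undefined on an edgeless graph")
    eb = nx.edge_betweenness_centrality(c.to_networkx(), normalized=False)
    return float(np.mean(list(eb.values())))


def average_radiality(c: Connectome) -> Optional[float]:
    """AR: mean over nodes of sum_j (D + 1 - sp_ij) / (D - 1).

    ``None`` (undefined) when the diameter D <= 1 (complete graphs) or the
    graph is disconnected (infinite diameter).
    """
    _require_nonempty(c)
    d = _pairwise_distances(c)
    if not np.all(np.isfinite(d)):
        return None
    diam = float(d.max())
    if diam <= 1:
        return None
    n = c.n_nodes
    node_sums = (diam + 1 - d).sum(axis=1) - (diam + 1)  # drop the j = i term
    return float((node_sums / (diam - 1)).mean())


def _cn_lcl_from_adjacency(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = a.astype(bool)
    common = a.astype(np.int64) @ a.astype(np.int64)
    ii, jj = np.nonzero(np.triu(a, k=1))
    cn_list, lcl_list = [], []
    for i, j in zip(ii, jj):
        cn = int(common[i, j])
        if cn > 1:
            cohort = a[i] & a[j]
            lcl = int(a[np.ix_(cohort, cohort)].sum() // 2)
            cn_list.append(cn)
            lcl_list.append(lcl)
    return np.array(cn_list, dtype=int), np.array(lcl_list, dtype=int)


def _lcp_from_adjacency(a: np.ndarray) -> Optional[float]:
    cn, lcl = _cn_lcl_from_adjacency(a)
    if cn.size < 2 or cn.std() == 0 or lcl.std() == 0:
        return None
    return float(np.corrcoef(cn, lcl)[0, 1])


def cn_lcl_arrays(c: Connectome) -> tuple[np.ndarray, np.ndarray]:
    """Per-link common-neighbour (CN) and local-community-link (LCL) counts.

    One entry per network link whose endpoints share more than one common
    neighbour (CN > 1).  CN is the number of shared first neighbours; LCL is
    the number of links among that cohort (the local community).  The two
    arrays are index-aligned (edges in upper-triangular order).
    """
    _require_binary(c)
    return _cn_lcl_from_adjacency(c.adjacency)


def lcp_correlation(c: Connectome) -> Optional[float]:
    """LCP-corr: Pearson correlation of the CN and LCL arrays.

    Undefined (``None``) with fewer than two qualifying links or when either
    array has zero variance.
    """
    _require_binary(c)
    return _lcp_from_adjacency(c.adjacency)


# ---------------------------------------------------------------------------
# Null networks (degree-preserving rewiring)
# ---------------------------------------------------------------------------

def _is_connected(a: np.ndarray) -> bool:
    return connected_components(a, directed=False, return_labels=False) == 1


def _double_edge_swaps(
    a: np.ndarray,
    rng: np.random.Generator,
    n_attempts: int,
    accept: Callable[[np.ndarray, tuple, tuple, tuple, tuple], bool],
) -> tuple[np.ndarray, int]:
    """Attempt degree-preserving double-edge swaps on a copy of ``a``.

    A proposed swap replaces edges (u,v),(x,y) with (u,y),(x,v); it is applied
    only when it creates no self-loop or multi-edge and ``accept`` returns
    True on the post-swap matrix.  Returns the rewired matrix and the number
    of accepted swaps.
    """
    a = a.copy()
    edges = [tuple(e) for e in np.column_stack(np.nonzero(np.triu(a, k=1)))]
    if len(edges) < 2:
        return a, 0
    accepted = 0
    for _ in range(n_attempts):
        ei, ej = rng.choice(len(edges), size=2, replace=False)
        u, v = edges[ei]
        x, y = edges[ej]
        if rng.random() < 0.5:
            x, y = y, x
        if len({u, v, x, y}) < 4:
            continue
        if a[u, y] or a[x, v]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, y] = a[y, u] = 1
        a[x, v] = a[v, x] = 1
        if accept(a, (u, v), (x, y), (u, y), (x, v)):
            edges[ei] = (min(u, y), max(u, y))
            edges[ej] = (min(x, v), max(x, v))
            accepted += 1
        else:  # revert
            a[u, y] = a[y, u] = 0
            a[x, v] = a[v, x] = 0
            a[u, v] = a[v, u] = 1
            a[x, y] = a[y, x] = 1
    return a, accepted


def random_equivalent(c: Connectome, cfg: NullEnsembleConfig) -> Connectome:
    """Degree-preserving randomization (double-edge swaps).

    ``swap_multiplier * |E|`` swaps are attempted.  If the input is connected,
    connectedness is preserved: accepted swaps are verified in adaptive
    windows and any window that disconnects the graph is rolled back and
    resampled.
    """
    _require_binary(c)
    rng = np.random.default_rng(cfg.seed)
    keep_connected = c.n_nodes > 0 and _is_connected(c.adjacency)
    a = c.adjacency.copy()
    edges = [tuple(e) for e in np.column_stack(np.nonzero(np.triu(a, k=1)))]
    n_attempts = cfg.swap_multiplier * max(c.n_edges, 1)
    accepted = 0
    window, in_window = 1, 0
    undo: list[tuple] = []  # (ei, old_edge_i, ej, old_edge_j)
    if len(edges) >= 2:
        for _ in range(n_attempts):
            ei, ej = rng.choice(len(edges), size=2, replace=False)
            u, v = edges[ei]
            x, y = edges[ej]
            if rng.random() < 0.5:
                x, y = y, x
            if len({u, v, x, y}) < 4 or a[u, y] or a[x, v]:
                continue
            a[u, v] = a[v, u] = 0
            a[x, y] = a[y, x] = 0
            a[u, y] = a[y, u] = 1
            a[x, v] = a[v, x] = 1
            undo.append((ei, edges[ei], ej, edges[ej]))
            edges[ei] = (min(u, y), max(u, y))
            edges[ej] = (min(x, v), max(x, v))
            accepted += 1
            if not keep_connected:
                undo.clear()
                continue
            in_window += 1
            if in_window >= window:
                if _is_connected(a):
                    undo.clear()
                    window = min(window * 2, 64)
                else:
                    accepted -= _rollback(a, edges, undo)
                    window = max(window // 2, 1)
                in_window = 0
        if keep_connected and undo and not _is_connected(a):
            accepted -= _rollback(a, edges, undo)
    if accepted == 0:
        warnings.warn("no admissible degree-preserving swap; graph returned unchanged")
    return replace(c, adjacency=a)


def _rollback(a: np.ndarray, edges: list, undo: list[tuple]) -> int:
    """Revert a window of accepted swaps (in reverse order); return its size."""
    count = len(undo)
    while undo:
        ei, old_i, ej, old_j = undo.pop()
        new_i, new_j = edges[ei], edges[ej]
        for (p, q) in (new_i, new_j):
            a[p, q] = a[q, p] = 0
        for (p, q) in (old_i, old_j):
            a[p, q] = a[q, p] = 1
        edges[ei], edges[ej] = old_i, old_j
    return count


def _band_cost(a: np.ndarray) -> float:
    """Total circular band distance of the edges from the matrix diagonal.

    The circular distance min(|i-j|, n-|i-j|) treats the node ordering as a
    ring, so a ring lattice is already at minimum cost and is left unchanged
    by latticization.
    """
    n = a.shape[0]
    i, j = np.nonzero(np.triu(a, k=1))
    d = np.abs(i - j)
    return float(np.minimum(d, n - d).sum())


def lattice_equivalent(c: Connectome, cfg: NullEnsembleConfig) -> Connectome:
    """Degree-preserving latticization by greedy band compaction.

    Double-edge swaps are accepted only when they strictly reduce the total
    circular band distance of the edge set from the diagonal, rearranging
    edges into a lattice-like band while preserving every node degree.
    """
    _require_binary(c)
    rng = np.random.default_rng(cfg.seed)
    n = c.n_nodes
    cost = _band_cost(c.adjacency)
    state = {"cost": cost}

    def accept(a, old1, old2, new1, new2) -> bool:
        def cdist(e):
            d = abs(e[0] - e[1])
            return min(d, n - d)

        new_cost = state["cost"] - cdist(old1) - cdist(old2) + cdist(new1) + cdist(new2)
        if new_cost < state["cost"]:
            state["cost"] = new_cost
            return True
        return False

    a, accepted = _double_edge_swaps(
        c.adjacency, rng, cfg.swap_multiplier * max(c.n_edges, 1), accept
    )
    return replace(c, adjacency=a)


def smallworldness_sigma(c: Connectome, cfg: NullEnsembleConfig) -> Optional[float]:
    """Small-worldness sigma = (C/C_rand) / (L/L_rand); > 1 for small worlds.

    C_rand and L_rand are averaged over ``cfg.n_realizations`` degree-
    preserving random equivalents.  ``None`` if C_rand is zero.
    """
    _require_binary(c)
    C = average_clustering_coefficient(c)
    L = characteristic_path_length(c)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_realizations)
    c_rand, l_rand = [], []
    for s in seeds:
        r = random_equivalent(c, NullEnsembleConfig(1, cfg.swap_multiplier, int(s) % (2**31)))
        c_rand.append(average_clustering_coefficient(r))
        l_rand.append(characteristic_path_length(r))
    c_bar, l_bar = float(np.mean(c_rand)), float(np.mean(l_rand))
    if c_bar == 0:
        return None
    return (C / c_bar) / (L / l_bar)


def smallworldness_omega(c: Connectome, cfg: NullEnsembleConfig) -> Optional[float]:
    """Small-worldness omega = L_rand/L - C/C_latt, in [-1, 1].

    Near 0 for small-world networks; positive leans random, negative leans
    lattice.  ``None`` if C_latt is zero.
    """
    _require_binary(c)
    C = average_clustering_coefficient(c)
    L = characteristic_path_length(c)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(2 * cfg.n_realizations)
    l_rand, c_latt = [], []
    for s in seeds[: cfg.n_realizations]:
        r = random_equivalent(c, NullEnsembleConfig(1, cfg.swap_multiplier, int(s) % (2**31)))
        l_rand.append(characteristic_path_length(r))
    for s in seeds[cfg.n_realizations :]:
        lat = lattice_equivalent(c, NullEnsembleConfig(1, cfg.swap_multiplier, int(s) % (2**31)))
        c_latt.append(average_clustering_coefficient(lat))
    c_bar = float(np.mean(c_latt))
    if c_bar == 0:
        return None
    return float(np.mean(l_rand)) / L - C / c_bar


# ---------------------------------------------------------------------------
# Power-lawness (discrete power-law goodness of fit)
# ---------------------------------------------------------------------------

def _discrete_pl_loglik(alpha: float, tail: np.ndarray, xmin: int) -> float:
    return -tail.size * math.log(special.zeta(alpha, xmin)) - alpha * float(
        np.log(tail).sum()
    )


def _fit_alpha(tail: np.ndarray, xmin: int) -> float:
    res = optimize.minimize_scalar(
        lambda a: -_discrete_pl_loglik(a, tail, xmin),
        bounds=(1.01, 12.0),
        method="bounded",
    )
    return float(res.x)


def _ks_discrete(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, tail.max() + 1)
    z = special.zeta(alpha, xmin)
    pmf = xs.astype(float) ** (-alpha) / z
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(tail), xs, side="right") / tail.size
    return float(np.max(np.abs(emp - cdf)))


def fit_discrete_power_law(values: np.ndarray) -> tuple[float, int, float]:
    """Fit a discrete power law p(x) ~ x^-alpha for x >= x_min.

    x_min is chosen to minimize the Kolmogorov-Smirnov distance between the
    fitted model and the empirical tail; alpha by maximum likelihood.
    Returns (alpha, x_min, KS distance).
    """
    values = np.asarray(values, dtype=int)
    values = values[values >= 1]
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("degenerate sequence: power-law fit undefined")
    candidates = np.unique(values)[:-1]  # need >= 2 tail values
    best = None
    for xmin in candidates:
        tail = values[values >= xmin]
        if tail.size < 2:
            continue
        alpha = _fit_alpha(tail, int(xmin))
        ks = _ks_discrete(tail, alpha, int(xmin))
        if best is None or ks < best[2]:
            best = (alpha, int(xmin), ks)
    if best is None:
        raise ValueError("degenerate sequence: power-law fit undefined")
    return best


def _sample_discrete_pl(
    rng: np.random.Generator, alpha: float, xmin: int, size: int
) -> np.ndarray:
    # continuous-approximation sampler (Clauset et al., App. D)
    u = rng.random(size)
    return np.floor((xmin - 0.5) * (1.0 - u) ** (-1.0 / (alpha - 1.0)) + 0.5).astype(int)


def power_law_pvalue(values: np.ndarray, n_bootstrap: int = 1000, seed: int = 0) -> float:
    """Goodness-of-fit p for the discrete power-law hypothesis on a sequence.

    Semi-parametric bootstrap: each replicate draws n values, taking tail
    values from the fitted power law (probability n_tail/n) and head values
    uniformly from the observed below-x_min data, then refits from scratch.
    p is the fraction of replicates whose KS distance is at least the
    observed one; the hypothesis is accepted when p >= 0.1.
    """
    values = np.asarray(values, dtype=int)
    values = values[values >= 1]
    alpha, xmin, ks_obs = fit_discrete_power_law(values)
    head = values[values < xmin]
    n = values.size
    p_tail = (n - head.size) / n
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_bootstrap):
        take_tail = rng.random(n) < p_tail
        n_tail = int(take_tail.sum())
        parts = []
        if n_tail:
            parts.append(_sample_discrete_pl(rng, alpha, xmin, n_tail))
        if n - n_tail:
            parts.append(rng.choice(head, size=n - n_tail, replace=True))
        synth = np.concatenate(parts)
        try:
            _, _, ks_synth = fit_discrete_power_law(synth)
        except ValueError:
            continue  # degenerate replicate carries no evidence either way
        if ks_synth >= ks_obs:
            exceed += 1
    return exceed / n_bootstrap


def power_lawness(c: Connectome, n_bootstrap: int = 1000, seed: int = 0) -> Optional[float]:
    """PLpvalue: power-law goodness-of-fit p for the degree sequence.

    Zero-degree nodes are excluded (x_min >= 1).  ``None`` on degenerate
    degree sequences (fewer than two distinct positive degrees).
    """
    _require_nonempty(c)
    degrees = c.adjacency.sum(axis=1).astype(int)
    try:
        return power_law_pvalue(degrees, n_bootstrap=n_bootstrap, seed=seed)
    except ValueError:
        return None


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity_of_partition(c: Connectome, communities: list[set[int]]) -> float:
    """Q = sum_u [e_uu - (sum_v e_uv)^2] for a given node partition."""
    _require_binary(c)
    a = c.adjacency
    m = c.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    q = 0.0
    deg = a.sum(axis=1)
    for comm in communities:
        idx = np.fromiter(comm, dtype=int)
        e_uu = a[np.ix_(idx, idx)].sum() / 2.0 / m
        a_u = deg[idx].sum() / (2.0 * m)
        q += e_uu - a_u**2
    return float(q)


def _modularity_exact(a: np.ndarray, m: int) -> float:
    """Best Q over all node partitions (restricted-growth-string enumeration)."""
    n = a.shape[0]
    deg = a.sum(axis=1)
    best = -0.5

    def q_of_labels(labels: np.ndarray) -> float:
        q = 0.0
        for l in range(labels.max() + 1):
            idx = np.nonzero(labels == l)[0]
            e_uu = a[np.ix_(idx, idx)].sum() / 2.0 / m
            a_u = deg[idx].sum() / (2.0 * m)
            q += e_uu - a_u**2
        return q

    labels = np.zeros(n, dtype=int)

    def grow(i: int, maxlab: int) -> None:
        nonlocal best
        if i == n:
            best = max(best, q_of_labels(labels))
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            grow(i + 1, max(maxlab, lab))

    grow(1, 0)
    return float(best)


def modularity(c: Connectome, seed: int = 0, exact_threshold: int = 8) -> float:
    """Q of the best node partition, in [-1/2, 1).

    Graphs with at most ``exact_threshold`` nodes are solved exactly by
    enumerating every partition; larger graphs use seeded greedy
    agglomeration (merge the pair with the largest modularity gain, random
    tie-breaking) followed by single-node-move refinement.
    """
    _require_binary(c)
    a = c.adjacency
    m = c.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    if c.n_nodes <= exact_threshold:
        return _modularity_exact(a, m)
    rng = np.random.default_rng(seed)
    n = c.n_nodes
    deg = a.sum(axis=1)
    label = np.arange(n)

    def q_of(labels: np.ndarray) -> float:
        comms = [set(np.nonzero(labels == l)[0]) for l in np.unique(labels)]
        return modularity_of_partition(c, comms)

    # greedy agglomeration
    improved = True
    while improved:
        improved = False
        uniq = np.unique(label)
        if uniq.size == 1:
            break
        base_q = q_of(label)
        best_gain, best_pairs = 0.0, []
        for la, lb in itertools.combinations(uniq, 2):
            ia, ib = label == la, label == lb
            # merging changes Q by 2*(e_ab - a_a*a_b)
            e_ab = a[np.ix_(np.nonzero(ia)[0], np.nonzero(ib)[0])].sum() / m
            a_a = deg[ia].sum() / (2.0 * m)
            a_b = deg[ib].sum() / (2.0 * m)
            gain = e_ab - 2.0 * a_a * a_b
            if gain > best_gain + 1e-12:
                best_gain, best_pairs = gain, [(la, lb)]
            elif best_pairs and abs(gain - best_gain) <= 1e-12:
                best_pairs.append((la, lb))
        if best_pairs and best_gain > 1e-12:
            la, lb = best_pairs[rng.integers(len(best_pairs))]
            label[label == lb] = la
            improved = True

    # local node-moving refinement
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for i in order:
            current = label[i]
            targets = set(np.unique(label)) - {current}
            targets.add(n + i)  # allow splitting off into a fresh singleton
            best_q = q_of(label)
            best_target = None
            for t in sorted(targets):
                trial = label.copy()
                trial[i] = t
                qt = q_of(trial)
                if qt > best_q + 1e-12:
                    best_q, best_target = qt, t
            if best_target is not None:
                label[i] = best_target
                improved = True
    return q_of(label)


# ---------------------------------------------------------------------------
# Structural consistency
# ---------------------------------------------------------------------------

def structural_consistency(
    c: Connectome,
    perturb_fraction: float = 0.1,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """SC: link predictability via first-order eigen-perturbation, in [0, 1].

    Per repeat a random fraction of the edges (the perturbation set dE) is
    removed; the remainder A^R is eigendecomposed, the removed edges supply a
    first-order eigenvalue correction, and the perturbed reconstruction ranks
    all entries unobserved in A^R.  SC is the fraction of removed edges among
    the top-|dE| ranked entries, averaged over ``n_repeats`` repeats.
    """
    _require_binary(c)
    if not (0 < perturb_fraction < 1):
        raise ValueError("perturb_fraction must be in (0, 1)")
    edges = c.edge_index_pairs()
    m = len(edges)
    k = max(1, int(round(perturb_fraction * m)))
    if m < math.ceil(1.0 / perturb_fraction):
        raise ValueError("too few edges for the requested perturbation fraction")
    rng = np.random.default_rng(seed)
    n = c.n_nodes
    iu = np.triu_indices(n, k=1)
    scores = []
    for _ in range(n_repeats):
        removed = rng.choice(m, size=k, replace=False)
        delta = np.zeros_like(c.adjacency)
        for i, j in edges[removed]:
            delta[i, j] = delta[j, i] = 1.0
        a_r = c.adjacency - delta
        lam, x = np.linalg.eigh(a_r)
        dlam = np.einsum("ij,jk,ki->i", x.T, delta, x)  # x_k' dA x_k (x_k normalized)
        a_tilde = (x * (lam + dlam)) @ x.T
        candidate = (a_r[iu] == 0)  # unobserved entries of A^R
        vals = a_tilde[iu][candidate]
        is_removed = (delta[iu][candidate] == 1)
        top = np.argsort(-vals, kind="stable")[:k]
        scores.append(is_removed[top].sum() / k)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def measure_all(c: Connectome, cfg: MeasureConfig | None = None) -> GraphMetrics:
    """Evaluate all 14 measures; per-measure failures become ``None`` markers."""
    _require_binary(c)
    cfg = cfg or MeasureConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(5)
    seeds = [int(s) % (2**31) for s in seeds]
    null = lambda s: NullEnsembleConfig(
        cfg.null.n_realizations, cfg.null.swap_multiplier, s
    )
    jobs: dict[str, Callable[[], Optional[float]]] = {
        "AND": lambda: average_node_degree(c),
        "CPL": lambda: characteristic_path_length(c),
        "AE": lambda: average_efficiency(c),
        "ACC": lambda: average_clustering_coefficient(c),
        "ACCE": lambda: average_closeness_centrality(c),
        "ANBC": lambda: average_node_betweenness(c),
        "AEBC": lambda: average_edge_betweenness(c),
        "AR": lambda: average_radiality(c),
        "LCPcorr": lambda: lcp_correlation(c),
        "SWsigma": lambda: smallworldness_sigma(c, null(seeds[0])),
        "SWomega": lambda: smallworldness_omega(c, null(seeds[1])),
        "PLpvalue": lambda: power_lawness(c, cfg.n_bootstrap, seeds[2]),
        "Q": lambda: modularity(c, seeds[3]),
        "SC": lambda: structural_consistency(
            c, cfg.perturb_fraction, cfg.sc_repeats, seeds[4]
        ),
    }
    out: dict[str, Optional[float]] = {}
    for name, fn in jobs.items():
        try:
            out[name] = fn()
        except ValueError as exc:
            logger.info("measure %s undefined: %s", name, exc)
            out[name] = None
    return GraphMetrics(**out)


def compute_measure(
    c: Connectome, name: str, cfg: MeasureConfig | None = None, seed: int | None = None
) -> Optional[float]:
    """Evaluate one named measure (seed overrides cfg.seed for stochastic ones)."""
    cfg = cfg or MeasureConfig()
    s = cfg.seed if seed is None else seed
    dispatch: dict[str, Callable[[], Optional[float]]] = {
        "AND": lambda: average_node_degree(c),
        "CPL": lambda: characteristic_path_length(c),
        "AE": lambda: average_efficiency(c),
        "ACC": lambda: average_clustering_coefficient(c),
        "ACCE": lambda: average_closeness_centrality(c),
        "ANBC": lambda: average_node_betweenness(c),
        "AEBC": lambda: average_edge_betweenness(c),
        "AR": lambda: average_radiality(c),
        "LCPcorr": lambda: lcp_correlation(c),
        "SWsigma": lambda: smallworldness_sigma(
            c, NullEnsembleConfig(cfg.null.n_realizations, cfg.null.swap_multiplier, s)
        ),
        "SWomega": lambda: smallworldness_omega(
            c, NullEnsembleConfig(cfg.null.n_realizations, cfg.null.swap_multiplier, s)
        ),
        "PLpvalue": lambda: power_lawness(c, cfg.n_bootstrap, s),
        "Q": lambda: modularity(c, s),
        "SC": lambda: structural_consistency(
            c, cfg.perturb_fraction, cfg.sc_repeats, s
        ),
    }
    if name not in dispatch:
        raise KeyError(f"unknown measure {name!r}; known: {MEASURE_NAMES}")
    return dispatch[name]()


def stability_check(
    measure_fn: Callable[[Connectome, int], Optional[float]],
    c: Connectome,
    k: int,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and standard error of a (stochastic) measure over k seeded runs."""
    if k < 2:
        raise ValueError("stability check needs k >= 2 evaluations")
    seeds = np.random.SeedSequence(seed).generate_state(k)
    vals = []
    for s in seeds:
        v = measure_fn(c, int(s) % (2**31))
        if v is None:
            raise ValueError("measure undefined on this connectome")
        vals.append(v)
    arr = np.array(vals, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    return float(arr.mean()), se
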