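"""Synthetic study generator: connectome ensembles driven by a latent pain level.

The generator emulates the structure of the chronic-constriction-injury
study so that the whole analysis pipeline can be exercised end to end with
known ground truth:

* 8 recording steps (3 h, then days 4/6/9/11/12/15/16 post surgery);
* per step 1000 connectomes over 31 nodes (15 in S1, 16 in VPL), of which
  the middle 400 are kept for analysis;
* a Von-Frey-like behavioural value per step (grams; lower = more pain).

A latent pain level in [0, 1] per step drives both sides.  Behaviour is a
monotone decreasing map of the latent plus Gaussian noise.  Topology starts
from a community-rich template (region-aligned near-cliques bridged across
regions, giving high LCP-corr) and is rewired by *targeted* degree-
preserving double-edge swaps until its LCP-corr reaches a target that is
affine in the latent: acute pain erodes the local-community organization,
so LCP-corr is the planted behavioural-coupled marker.  Because swaps never
change any node degree, the average degree is a planted negative control.
Within a study the per-step base graphs form a chain — each step's graph is
annealed from the previous step's graph — so steps with equal latent have
identical base connectivity (the planted stable chronic phase seen by the
engram analysis) while large latent jumps rewire many links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .graph_core import Connectome, ConnectomeSeries, middle_window_filter
from .timeseries_stats import DEFAULT_STEP_LABELS, step_hours_from_labels

logger = logging.getLogger("painmark")

#: default per-step latent pain level: acute spike at step 2 (day 4),
#: chronic rise and plateau from day 11 onward
DEFAULT_LATENT = (0.2, 0.9, 0.5, 0.45, 0.6, 0.65, 0.7, 0.7)


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and planted structure of a synthetic study."""

    n_nodes: int = 31
    region_split: tuple[int, int] = (15, 16)
    region_names: tuple[str, str] = ("S1", "VPL")
    step_labels: tuple[str, ...] = DEFAULT_STEP_LABELS
    n_matrices_per_step: int = 1000
    keep_middle: int = 400
    latent_trajectory: tuple[float, ...] = DEFAULT_LATENT
    coupling: tuple[str, ...] = ("LCPcorr",)
    control: tuple[str, ...] = ("AND",)
    noise_flip_prob: float = 0.02
    scale_grams: float = 26.0
    behav_noise_sd: float = 0.5
    lcp_target_high: float = 0.9  # LCP-corr target at latent 0
    lcp_target_low: float = 0.35  # LCP-corr target at latent 1
    anneal_tol: float = 0.02
    anneal_max_proposals: int = 4000
    community_edge_prob: float = 0.95
    intra_region_edge_prob: float = 0.15
    inter_region_edge_prob: float = 0.15
    seed: int = 0

    def lcp_target(self, latent_value: float) -> float:
        return self.lcp_target_high - (self.lcp_target_high - self.lcp_target_low) * latent_value

    def __post_init__(self) -> None:
        if sum(self.region_split) != self.n_nodes:
            raise ValueError("region_split must sum to n_nodes")
        if self.keep_middle > self.n_matrices_per_step:
            raise ValueError("keep_middle cannot exceed n_matrices_per_step")
        if len(self.latent_trajectory) != len(self.step_labels):
            raise ValueError("one latent value per step required")
        if any(not (0 <= v <= 1) for v in self.latent_trajectory):
            raise ValueError("latent values must lie in [0, 1]")
        if not (0 <= self.noise_flip_prob < 0.5):
            raise ValueError("noise_flip_prob must be in [0, 0.5)")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted (acceptance surface for recovery tests)."""

    latent: tuple[float, ...]
    scale_grams: float
    behav_noise_sd: float
    coupled_measures: tuple[str, ...]
    control_measures: tuple[str, ...]
    lcp_targets: tuple[float, ...]
    swap_counts: tuple[int, ...]
    base_graphs: tuple[Connectome, ...]
    seed: int


# ---------------------------------------------------------------------------
# Behaviour
# ---------------------------------------------------------------------------

def behavioral_from_latent(
    latent: Sequence[float],
    scale_grams: float = 26.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Von-Frey-like thresholds: grams = scale * (1 - latent) + noise.

    Monotone decreasing in the latent pain level: the lower the threshold,
    the higher the pain sensitivity.
    """
    lat = np.asarray(latent, dtype=float)
    if np.any((lat < 0) | (lat > 1)):
        raise ValueError("latent values must lie in [0, 1]")
    if scale_grams < 0:
        raise ValueError("scale_grams must be non-negative")
    rng = np.random.default_rng(seed)
    return scale_grams * (1.0 - lat) + noise_sd * rng.standard_normal(lat.size)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def _community_sizes(region_size: int) -> list[int]:
    """Split a region into communities of varying size (4..7 nodes)."""
    sizes = []
    remaining = region_size
    cycle = (4, 5, 6, 7)
    i = 0
    while remaining > 0:
        s = min(cycle[i % len(cycle)], remaining)
        if remaining - s in (1, 2) and s > 4:  # avoid leftover fragments
            s -= 1
        sizes.append(s)
        remaining -= s
        i += 1
    return sizes


def _node_labels(cfg: SyntheticConfig) -> tuple[tuple[str, ...], dict[str, str]]:
    labels, region_of = [], {}
    for region, size in zip(cfg.region_names, cfg.region_split):
        for k in range(size):
            lab = f"{region}_{k:02d}"
            labels.append(lab)
            region_of[lab] = region
    return tuple(labels), region_of


def _template_adjacency(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Community-rich template: near-cliques inside regions, sparse bridges."""
    n = cfg.n_nodes
    a = np.zeros((n, n))
    offset = 0
    blocks = []
    for size in cfg.region_split:
        comms = _community_sizes(size)
        start = offset
        for s in comms:
            blocks.append((start, start + s))
            start += s
        offset += size
    comm_of = np.empty(n, dtype=int)
    for bi, (lo, hi) in enumerate(blocks):
        comm_of[lo:hi] = bi
    region_of_idx = np.repeat(np.arange(2), cfg.region_split)
    for i in range(n):
        for j in range(i + 1, n):
            if comm_of[i] == comm_of[j]:
                p = cfg.community_edge_prob
            elif region_of_idx[i] == region_of_idx[j]:
                p = cfg.intra_region_edge_prob
            else:
                p = cfg.inter_region_edge_prob
            if rng.random() < p:
                a[i, j] = a[j, i] = 1.0
    return a


def _anneal_to_lcp_target(
    a: np.ndarray,
    target: float,
    rng: np.random.Generator,
    tol: float = 0.02,
    max_proposals: int = 4000,
    stall_limit: int = 500,
) -> tuple[np.ndarray, int]:
    """Degree-preserving rewiring of ``a`` toward an LCP-corr target.

    Random double-edge swaps are proposed and accepted only when they move
    LCP-corr strictly closer to the target (a blind swap count would give a
    noisy, non-monotone response on graphs this small).  Stops inside
    ``tol`` of the target, after ``max_proposals`` proposals, or after
    ``stall_limit`` consecutive rejections.  Returns the rewired matrix and
    the number of accepted swaps.
    """
    from .topo_measures import _lcp_from_adjacency

    a = a.copy()
    edges = [tuple(e) for e in np.column_stack(np.nonzero(np.triu(a, k=1)))]
    cur = _lcp_from_adjacency(a)
    cur = 0.0 if cur is None else cur
    accepted = 0
    stall = 0
    for _ in range(max_proposals):
        if abs(cur - target) <= tol or stall >= stall_limit:
            break
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
        cand = _lcp_from_adjacency(a)
        if cand is not None and abs(cand - target) < abs(cur - target):
            edges[ei] = (min(u, y), max(u, y))
            edges[ej] = (min(x, v), max(x, v))
            cur = cand
            accepted += 1
            stall = 0
        else:  # revert
            a[u, y] = a[y, u] = 0
            a[x, v] = a[v, x] = 0
            a[u, v] = a[v, u] = 1
            a[x, y] = a[y, x] = 1
            stall += 1
    return a, accepted


def base_graph(latent_value: float, cfg: SyntheticConfig, seed: int = 0) -> Connectome:
    """Base connectome at one latent pain level.

    The seeded community template (high LCP-corr) is rewired by targeted
    degree-preserving double-edge swaps until its LCP-corr reaches
    ``cfg.lcp_target(latent_value)``: latent 0 keeps the high-LCP local-
    community organization, latent 1 erodes it toward ``lcp_target_low``.
    The degree sequence is identical across latent values for a fixed seed.
    """
    if not (0 <= latent_value <= 1):
        raise ValueError("latent value must lie in [0, 1]")
    labels, region_of = _node_labels(cfg)
    ss = np.random.SeedSequence((seed, 101))
    rng_template, rng_swaps = (np.random.default_rng(s) for s in ss.spawn(2))
    a = _template_adjacency(cfg, rng_template)
    a, _ = _anneal_to_lcp_target(
        a, cfg.lcp_target(latent_value), rng_swaps,
        tol=cfg.anneal_tol, max_proposals=cfg.anneal_max_proposals,
    )
    return Connectome(a, labels, region_of, binary=True)


def step_ensemble(
    base: Connectome, n: int, flip_prob: float, seed: int = 0
) -> list[Connectome]:
    """``n`` noisy copies of a base graph: i.i.d. per-pair edge flips.

    Each node pair flips state (edge <-> non-edge) independently with
    probability ``flip_prob``; symmetry and zero diagonal are preserved.
    """
    if n < 1:
        raise ValueError("need n >= 1 matrices")
    if not (0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    nn = base.n_nodes
    iu = np.triu_indices(nn, k=1)
    base_vec = base.adjacency[iu].astype(bool)
    flips = rng.random((n, base_vec.size)) < flip_prob
    out = []
    for row in flips:
        vec = np.logical_xor(base_vec, row)
        a = np.zeros((nn, nn))
        a[iu] = vec
        a += a.T
        out.append(replace(base, adjacency=a, binary=True))
    return out


def generate_study(cfg: SyntheticConfig | None = None) -> tuple[ConnectomeSeries, GroundTruth]:
    """Generate a full synthetic study (series + ground truth).

    Per step, ``n_matrices_per_step`` matrices are generated and the middle
    ``keep_middle`` retained (head/tail discarded symmetrically), matching
    the recording-reliability filter of the study design.  All randomness
    cascades from ``cfg.seed``.
    """
    cfg = cfg or SyntheticConfig()
    hours = step_hours_from_labels(cfg.step_labels)
    ss = np.random.SeedSequence((cfg.seed, 202))
    behav_seed, *step_seeds = [int(s.generate_state(1)[0]) % (2**31) for s in ss.spawn(1 + len(hours))]
    behavioral = behavioral_from_latent(
        cfg.latent_trajectory, cfg.scale_grams, cfg.behav_noise_sd, behav_seed
    )
    discard = cfg.n_matrices_per_step - cfg.keep_middle
    head = discard // 2
    tail = discard - head
    labels, region_of = _node_labels(cfg)
    ss2 = np.random.SeedSequence((cfg.seed, 101))
    rng_template, rng_swaps = (np.random.default_rng(s) for s in ss2.spawn(2))
    current = _template_adjacency(cfg, rng_template)
    ensembles = []
    bases = []
    swap_counts = []
    for latent, sseed in zip(cfg.latent_trajectory, step_seeds):
        # chain: each step's base is annealed from the previous step's base,
        # so equal latents leave the connectivity untouched (stable phase)
        current, n_swaps = _anneal_to_lcp_target(
            current, cfg.lcp_target(latent), rng_swaps,
            tol=cfg.anneal_tol, max_proposals=cfg.anneal_max_proposals,
        )
        base = Connectome(current, labels, region_of, binary=True)
        bases.append(base)
        swap_counts.append(n_swaps)
        ens = step_ensemble(base, cfg.n_matrices_per_step, cfg.noise_flip_prob, sseed)
        if discard:
            ens = middle_window_filter(ens, head, tail)
        ensembles.append(tuple(ens))
    series = ConnectomeSeries(tuple(hours), tuple(ensembles), tuple(map(float, behavioral)))
    truth = GroundTruth(
        latent=cfg.latent_trajectory,
        scale_grams=cfg.scale_grams,
        behav_noise_sd=cfg.behav_noise_sd,
        coupled_measures=cfg.coupling,
        control_measures=cfg.control,
        lcp_targets=tuple(cfg.lcp_target(l) for l in cfg.latent_trajectory),
        swap_counts=tuple(swap_counts),
        base_graphs=tuple(bases),
        seed=cfg.seed,
    )
    return series, truth
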