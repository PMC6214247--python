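"""Region-resolved connectivity dynamics: representative connectomes,
intra/inter-region link counts, and links retained across time steps.

A persistent connectivity pattern maintained over consecutive recording
steps is read as an engram (topological memory trace).  Per step the
*representative* connectome is the ensemble member whose LCP-corr is closest
to the step's mean LCP-corr; its edge set is partitioned into intra-S1,
intra-VPL and inter-regional links, and edge-set intersections between
consecutive representatives give the retained links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .graph_core import Connectome, ConnectomeSeries
from .topo_measures import lcp_correlation

logger = logging.getLogger("painmark")


@dataclass(frozen=True)
class RegionLinkCounts:
    """Per-step link counts of the representative connectomes."""

    step_hours: tuple[int, ...]
    intra_first: tuple[int, ...]
    intra_second: tuple[int, ...]
    inter: tuple[int, ...]
    region_names: tuple[str, str]

    def totals(self) -> tuple[int, ...]:
        return tuple(
            a + b + c
            for a, b, c in zip(self.intra_first, self.intra_second, self.inter)
        )


@dataclass(frozen=True)
class RetainedLinks:
    """Edges common to two consecutive representative connectomes."""

    interval: str
    edges: frozenset[tuple[int, int]]
    count_full: int
    count_intra_first: int
    count_intra_second: int
    count_inter: int
    region_names: tuple[str, str]


def representative_connectome(
    ensemble: Sequence[Connectome], lcp_values: Sequence[Optional[float]]
) -> Connectome:
    """Member whose LCP-corr is closest to the ensemble mean LCP-corr.

    Undefined LCP values are excluded from the mean and from candidacy.
    Ties go to the lowest ensemble index.
    """
    if len(ensemble) != len(lcp_values):
        raise ValueError("ensemble and lcp_values must be aligned")
    defined = [(i, v) for i, v in enumerate(lcp_values) if v is not None]
    if not defined:
        raise ValueError("no defined LCP-corr value in the ensemble")
    mean = float(np.mean([v for _, v in defined]))
    best_i = min(defined, key=lambda iv: (abs(iv[1] - mean), iv[0]))[0]
    if len(defined) > 1:
        dists = sorted(abs(v - mean) for _, v in defined)
        if len(dists) > 1 and dists[0] == dists[1]:
            logger.info("representative tie at step; lowest index %d chosen", best_i)
    return ensemble[best_i]


def _region_pair_names(c: Connectome) -> tuple[str, str]:
    names = sorted(set(c.regions), key=lambda r: c.regions.index(r))
    if len(names) != 2:
        raise ValueError(f"expected exactly two regions, got {names}")
    return names[0], names[1]


def region_link_counts(c: Connectome) -> tuple[int, int, int]:
    """(intra_first, intra_second, inter) edge counts by endpoint regions.

    Regions are taken in order of first appearance along the node list (in
    the default study: S1 then VPL).  The three counts sum to |E|.
    """
    if not c.binary:
        raise ValueError("region link counts require a binarized connectome")
    first, second = _region_pair_names(c)
    regions = c.regions
    counts = {"first": 0, "second": 0, "inter": 0}
    for i, j in c.edge_index_pairs():
        ri, rj = regions[i], regions[j]
        if ri == rj:
            counts["first" if ri == first else "second"] += 1
        else:
            counts["inter"] += 1
    return counts["first"], counts["second"], counts["inter"]


def _hours_label(hours: int) -> str:
    return f"{hours} h" if hours < 24 else f"{hours // 24}d"


def retained_links(c_t: Connectome, c_next: Connectome, interval: str = "") -> RetainedLinks:
    """Edge-set intersection of two connectomes, classified by region."""
    if c_t.node_ids != c_next.node_ids or c_t.regions != c_next.regions:
        raise ValueError("connectomes have different node sets or partitions")
    if not (c_t.binary and c_next.binary):
        raise ValueError("retained links require binarized connectomes")
    e_t = {tuple(e) for e in c_t.edge_index_pairs()}
    e_n = {tuple(e) for e in c_next.edge_index_pairs()}
    common = frozenset(e_t & e_n)
    first, second = _region_pair_names(c_t)
    regions = c_t.regions
    n_first = n_second = n_inter = 0
    for i, j in common:
        ri, rj = regions[i], regions[j]
        if ri == rj:
            if ri == first:
                n_first += 1
            else:
                n_second += 1
        else:
            n_inter += 1
    return RetainedLinks(
        interval=interval,
        edges=common,
        count_full=len(common),
        count_intra_first=n_first,
        count_intra_second=n_second,
        count_inter=n_inter,
        region_names=(first, second),
    )


def engram_timecourse(
    series: ConnectomeSeries,
    lcp_values_per_step: Sequence[Sequence[Optional[float]]] | None = None,
) -> tuple[RegionLinkCounts, list[RetainedLinks]]:
    """Representative-connectome link counts per step and retained links per interval.

    ``lcp_values_per_step`` may carry precomputed per-member LCP-corr values;
    otherwise they are computed here.  Interval labels follow the
    "3 h/4d" convention.
    """
    if series.n_steps < 2:
        raise ValueError("engram analysis needs at least two time steps")
    reps = []
    for si, ens in enumerate(series.ensembles):
        if lcp_values_per_step is not None:
            lcps = list(lcp_values_per_step[si])
        else:
            lcps = [lcp_correlation(c) for c in ens]
        reps.append(representative_connectome(ens, lcps))
    first, second = _region_pair_names(reps[0])
    intra_first, intra_second, inter = [], [], []
    for rep in reps:
        a, b, x = region_link_counts(rep)
        intra_first.append(a)
        intra_second.append(b)
        inter.append(x)
    counts = RegionLinkCounts(
        step_hours=series.step_hours,
        intra_first=tuple(intra_first),
        intra_second=tuple(intra_second),
        inter=tuple(inter),
        region_names=(first, second),
    )
    retained = []
    for (h0, r0), (h1, r1) in zip(
        zip(series.step_hours, reps), zip(series.step_hours[1:], reps[1:])
    ):
        label = f"{_hours_label(h0)}/{_hours_label(h1)}"
        retained.append(retained_links(r0, r1, interval=label))
    return counts, retained
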