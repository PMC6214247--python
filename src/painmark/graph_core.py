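"""Connectome data model, binarization, ensemble filtering and plain-text I/O.

A connectome is a symmetric, non-negative, zero-diagonal weighted adjacency
matrix over a labelled node set, each node assigned to a brain region (in the
default study: primary somatosensory cortex ``S1`` and ventral posterolateral
thalamus ``VPL``).  A study is a :class:`ConnectomeSeries`: at each recording
time step an *ensemble* of connectomes (short-time-varying functional
networks sampled inside a narrow window) plus one behavioural scalar
(Von Frey mechanical threshold, grams).

On disk a series is a JSON manifest plus one plain-text matrix file per
connectome.  The matrix dialect is whitespace- or comma-delimited ``n x n``
real numbers with no header; all metadata (node labels, regions, time stamps,
behavioural values) lives in the manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("painmark")

#: tolerance used when checking matrix symmetry (checking, never symmetrizing)
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class Connectome:
    """A single (weighted or binarized) functional connectome.

    Parameters
    ----------
    adjacency:
        Symmetric ``n x n`` non-negative matrix with zero diagonal.
    node_ids:
        Ordered node labels (external indexing never leaks in; internally
        nodes are the 0-based row indices).
    region_of:
        Map from node label to region tag; must cover every node.
    binary:
        Whether entries are restricted to {0, 1}.
    """

    adjacency: np.ndarray
    node_ids: tuple[str, ...]
    region_of: Mapping[str, str]
    binary: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "node_ids", tuple(str(x) for x in self.node_ids))
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        n = a.shape[0]
        if len(self.node_ids) != n:
            raise ValueError(
                f"{len(self.node_ids)} node labels for a {n}x{n} matrix"
            )
        if len(set(self.node_ids)) != n:
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite weight in adjacency")
        if np.any(a < 0):
            raise ValueError("negative weight in adjacency")
        if n and np.max(np.abs(a - a.T)) > SYMMETRY_TOL:
            raise ValueError(
                f"adjacency not symmetric within tolerance {SYMMETRY_TOL:g}"
            )
        if n and np.any(np.diagonal(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        missing = [v for v in self.node_ids if v not in self.region_of]
        if missing:
            raise ValueError(f"nodes without region label: {missing}")
        if self.binary and not np.all(np.isin(a, (0.0, 1.0))):
            raise ValueError("binary connectome has entries outside {0, 1}")

    # -- convenience ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def regions(self) -> tuple[str, ...]:
        """Region tag per node, in node order."""
        return tuple(self.region_of[v] for v in self.node_ids)

    def edge_index_pairs(self) -> np.ndarray:
        """``(m, 2)`` array of 0-based upper-triangular edge index pairs."""
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([i, j])

    def to_networkx(self):
        """Integer-indexed :class:`networkx.Graph` view (0..n-1)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edge_index_pairs()))
        return g


@dataclass(frozen=True)
class ConnectomeSeries:
    """Time-stamped connectome ensembles with one behavioural value per step."""

    step_hours: tuple[int, ...]
    ensembles: tuple[tuple[Connectome, ...], ...]
    behavioral: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "step_hours", tuple(int(h) for h in self.step_hours))
        object.__setattr__(
            self, "ensembles", tuple(tuple(e) for e in self.ensembles)
        )
        object.__setattr__(
            self, "behavioral", tuple(float(b) for b in self.behavioral)
        )
        if not (len(self.step_hours) == len(self.ensembles) == len(self.behavioral)):
            raise ValueError("step_hours, ensembles and behavioral lengths differ")
        if any(b <= a for a, b in zip(self.step_hours, self.step_hours[1:])):
            raise ValueError("step_hours must be strictly increasing")
        if any(len(e) == 0 for e in self.ensembles):
            raise ValueError("empty ensemble at some time step")
        ref = self.ensembles[0][0]
        for ens in self.ensembles:
            for c in ens:
                if c.node_ids != ref.node_ids:
                    raise ValueError("node labels differ across connectomes")
                if c.regions != ref.regions:
                    raise ValueError("region partition differs across connectomes")

    @property
    def n_steps(self) -> int:
        return len(self.step_hours)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return self.ensembles[0][0].node_ids

    @property
    def region_of(self) -> Mapping[str, str]:
        return self.ensembles[0][0].region_of


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> np.ndarray:
    # whitespace- or comma-delimited plain text, no header
    text = path.read_text().replace(",", " ")
    rows = [line.split() for line in text.splitlines() if line.strip()]
    try:
        return np.array(rows, dtype=float)
    except ValueError as exc:  # ragged or non-numeric
        raise ValueError(f"malformed matrix file {path}: {exc}") from None


def read_series(manifest_path: str | Path) -> ConnectomeSeries:
    """Load a :class:`ConnectomeSeries` from a JSON manifest.

    Manifest schema::

        {"steps": [{"hours": int, "behavioral": float, "matrices": [file, ...]},
                   ...],
         "nodes": [{"id": str, "region": str}, ...]}

    Matrix file paths are resolved relative to the manifest.  Every matrix is
    validated (shape, symmetry within 1e-9, non-negativity, zero diagonal).
    """
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    nodes = doc["nodes"]
    node_ids = tuple(str(nd["id"]) for nd in nodes)
    region_of = {str(nd["id"]): str(nd["region"]) for nd in nodes}
    base = manifest_path.parent
    n = len(node_ids)
    hours, behavioral, ensembles = [], [], []
    for step in doc["steps"]:
        hours.append(int(step["hours"]))
        behavioral.append(float(step["behavioral"]))
        ens = []
        for fname in step["matrices"]:
            path = base / fname
            if not path.is_file():
                raise FileNotFoundError(f"matrix file missing: {path}")
            a = _read_matrix(path)
            if a.shape != (n, n):
                raise ValueError(
                    f"{path}: shape {a.shape} does not match {n} declared nodes"
                )
            binary = bool(np.all(np.isin(a, (0.0, 1.0))))
            ens.append(Connectome(a, node_ids, region_of, binary=binary))
        ensembles.append(tuple(ens))
    return ConnectomeSeries(tuple(hours), tuple(ensembles), tuple(behavioral))


def write_series(series: ConnectomeSeries, out_dir: str | Path) -> Path:
    """Write a series to ``out_dir`` (matrix files + manifest); return manifest path.

    Weights are printed with 17 significant digits so the read/write round
    trip is bit-exact.  The behavioural trajectory is additionally exported as
    a two-column CSV (hours, grams).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    steps = []
    for si, (hours, ens, behav) in enumerate(
        zip(series.step_hours, series.ensembles, series.behavioral)
    ):
        fnames = []
        for mi, c in enumerate(ens):
            fname = f"step{si:02d}_mat{mi:04d}.txt"
            np.savetxt(out_dir / fname, c.adjacency, fmt="%.17g")
            fnames.append(fname)
        steps.append({"hours": hours, "behavioral": behav, "matrices": fnames})
    manifest = {
        "steps": steps,
        "nodes": [
            {"id": v, "region": series.region_of[v]} for v in series.node_ids
        ],
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    behav_csv = out_dir / "behavioral.csv"
    behav_csv.write_text(
        "hours,grams\n"
        + "".join(f"{h},{b:.17g}\n" for h, b in zip(series.step_hours, series.behavioral))
    )
    return manifest_path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def binarize(c: Connectome, threshold: float = 0.0) -> Connectome:
    """Binarize a weighted connectome: edge iff weight strictly above threshold.

    The default threshold 0 turns every positive coherence weight into an
    edge, which is the convention used throughout the unweighted topological
    analysis.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    a = (c.adjacency > threshold).astype(float)
    return replace(c, adjacency=a, binary=True)


def middle_window_filter(
    matrices: Sequence, discard_head: int, discard_tail: int
) -> list:
    """Keep the middle of an ordered ensemble, dropping unreliable ends.

    In the default study 1000 short-time-varying matrices are recorded per
    step and the first and last 300 are discarded, keeping the middle 400.
    """
    if discard_head < 0 or discard_tail < 0:
        raise ValueError("discard counts must be non-negative")
    if len(matrices) <= discard_head + discard_tail:
        raise ValueError(
            f"cannot discard {discard_head}+{discard_tail} from "
            f"{len(matrices)} matrices"
        )
    end = len(matrices) - discard_tail
    return list(matrices[discard_head:end])
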