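"""Whole-brain graph measures on static connectivity.

Four measures are implemented, all evaluated against a *fixed* canonical
seven-network partition (no community detection):

* Newman–Girvan modularity Q of the fixed partition on a binarized graph;
* system segregation, (mean within-network z − mean between-network z) /
  mean within-network z, on the full Fisher-z matrix;
* weighted characteristic path length with edge lengths 1 − r (negative-r
  edges excluded from the length graph);
* binarized characteristic path length (mean hop-count distance), with an
  explicit exclusion list for parcels that disconnect at sparse thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from cycleconn.static_fc import BinaryAdjacency, FCMatrix, ZMatrix


class GraphMetricError(ValueError):
    pass


def _as_partition(partition: Sequence[int]) -> np.ndarray:
    part = np.asarray(partition)
    if part.ndim != 1:
        raise GraphMetricError("partition must be a 1-D assignment vector")
    return part


def modularity_q(g: BinaryAdjacency, partition: Sequence[int]) -> float:
    """Newman–Girvan modularity of the fixed partition.

    Q = Σ_c [ e_c/m − (d_c/2m)² ] with m the edge count, e_c the number of
    within-community edges and d_c the community degree sum. The partition is
    not optimized, so Q may be negative.
    """
    adj = np.asarray(g.adjacency)
    part = _as_partition(partition)
    if part.size != adj.shape[0]:
        raise GraphMetricError("partition length must equal node count")
    m = adj.sum() / 2.0
    if m == 0:
        raise GraphMetricError("modularity undefined on an empty graph")
    degrees = adj.sum(axis=1)
    q = 0.0
    for c in np.unique(part):
        idx = part == c
        e_c = adj[np.ix_(idx, idx)].sum() / 2.0
        d_c = degrees[idx].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


def system_segregation(z: ZMatrix, partition: Sequence[int]) -> float:
    """(Z̄_within − Z̄_between) / Z̄_within over off-diagonal parcel pairs."""
    values = np.asarray(z.values, dtype=float)
    part = _as_partition(partition)
    p = values.shape[0]
    if part.size != p:
        raise GraphMetricError("partition length must equal parcel count")
    iu, ju = np.triu_indices(p, k=1)
    within = part[iu] == part[ju]
    if not within.any() or within.all():
        raise GraphMetricError(
            "need at least one within-system and one between-system pair"
        )
    z_w = values[iu, ju][within].mean()
    z_b = values[iu, ju][~within].mean()
    if z_w == 0:
        raise GraphMetricError("mean within-system z is zero; segregation undefined")
    return float((z_w - z_b) / z_w)


@dataclass
class CPLResult:
    """Characteristic path length plus bookkeeping on unreachable pairs."""

    value: float
    n_pairs: int
    n_excluded_pairs: int = 0

    def __float__(self) -> float:
        return self.value


def weighted_cpl(fc: FCMatrix, length_map: str = "one_minus_r") -> CPLResult:
    """Mean shortest-path distance on the weighted length graph.

    Edge lengths are ``1 − r`` (default) or ``1/r``; edges with r <= 0 are
    removed from the length graph. Unreachable pairs are excluded from the
    mean and counted in the result.
    """
    r = np.asarray(fc.values, dtype=float).copy()
    np.fill_diagonal(r, 0.0)
    pos = r > 0
    lengths = np.zeros_like(r)
    if length_map == "one_minus_r":
        lengths[pos] = 1.0 - r[pos]
    elif length_map == "inverse":
        lengths[pos] = 1.0 / r[pos]
    else:
        raise GraphMetricError(f"unknown length_map {length_map!r}")
    # explicit sparse structure: zero-length edges would otherwise be
    # dropped by the dense-to-csgraph conversion
    lengths[pos] = np.maximum(lengths[pos], 1e-12)
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    p = r.shape[0]
    off = ~np.eye(p, dtype=bool)
    finite = np.isfinite(dist) & off
    n_pairs = int(finite.sum())
    if n_pairs == 0:
        raise GraphMetricError("no finite pairwise distances")
    return CPLResult(
        value=float(dist[finite].mean()),
        n_pairs=n_pairs,
        n_excluded_pairs=int(off.sum()) - n_pairs,
    )


def binary_cpl(g: BinaryAdjacency, exclude: Iterable[int] = ()) -> float:
    """Mean breadth-first hop-count distance over ordered node pairs.

    ``exclude`` lists parcel indices removed before the computation (parcels
    known to disconnect at sparse densities). Raises if the retained graph is
    disconnected, naming the offending nodes.
    """
    adj = np.asarray(g.adjacency)
    p = adj.shape[0]
    exclude = sorted(set(int(i) for i in exclude))
    keep = np.setdiff1d(np.arange(p), exclude)
    if keep.size < 2:
        raise GraphMetricError("fewer than 2 nodes retained")
    sub = adj[np.ix_(keep, keep)]
    n_comp, labels = connected_components(sub, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        stray = keep[labels != np.argmax(sizes)]
        raise GraphMetricError(
            f"graph disconnected after exclusion; unreachable nodes {stray.tolist()}"
        )
    dist = shortest_path(sub, method="D", directed=False, unweighted=True)
    off = ~np.eye(keep.size, dtype=bool)
    return float(dist[off].mean())


@dataclass
class UnreachableReport:
    """Where each parcel fell off the largest connected component."""

    parcels: list[int]
    occurrences: dict[int, list[str]] = field(default_factory=dict)


def find_unreachable_nodes(
    graphs: Sequence[BinaryAdjacency],
    labels: Sequence[str] | None = None,
    exclude: Iterable[int] = (),
) -> UnreachableReport:
    """Parcels disconnected from the largest component in ANY input graph.

    ``labels`` annotates each graph (e.g. "session03@0.10") so the report
    records where each exclusion-worthy parcel occurred. ``exclude`` removes
    parcels before the component analysis; because removing a parcel can
    itself strand further parcels, callers building an exclusion list should
    iterate to a fixed point (see :func:`exclusion_fixed_point`).
    """
    if labels is None:
        labels = [f"graph{i}" for i in range(len(graphs))]
    occurrences: dict[int, list[str]] = {}
    excluded = sorted(set(int(i) for i in exclude))
    for g, lab in zip(graphs, labels):
        adj = np.asarray(g.adjacency)
        keep = np.setdiff1d(np.arange(adj.shape[0]), excluded)
        n_comp, comp = connected_components(adj[np.ix_(keep, keep)], directed=False)
        if n_comp == 1:
            continue
        main = np.argmax(np.bincount(comp))
        for node in keep[comp != main]:
            occurrences.setdefault(int(node), []).append(str(lab))
    return UnreachableReport(parcels=sorted(occurrences), occurrences=occurrences)


def exclusion_fixed_point(
    graphs: Sequence[BinaryAdjacency],
    labels: Sequence[str] | None = None,
    exclude: Iterable[int] = (),
) -> tuple[list[int], dict[int, list[str]]]:
    """Smallest exclusion set (greedy) leaving every graph's retained
    subgraph connected: iterate find_unreachable_nodes until stable."""
    excluded = set(int(i) for i in exclude)
    occurrences: dict[int, list[str]] = {}
    for _ in range(len(graphs[0].adjacency) if graphs else 1):
        report = find_unreachable_nodes(graphs, labels, exclude=excluded)
        if not report.parcels:
            break
        excluded.update(report.parcels)
        for node, where in report.occurrences.items():
            occurrences.setdefault(node, []).extend(where)
    return sorted(excluded), occurrences
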