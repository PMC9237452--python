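"""Static functional connectivity: Pearson FC, Fisher r-to-z, and
proportional-threshold binarization over a sparsity sweep.

"Sparsity threshold" follows the standard connectome convention of
proportional edge density: a density of 0.1 keeps the 10% strongest
off-diagonal edges by signed value. An absolute-cutoff alternative is
available via :func:`binarize_by_threshold`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cycleconn.io_sessions import SessionRecord

#: default density sweep matching a 0.1–0.25 sparsity range
DEFAULT_DENSITY_GRID = (0.10, 0.15, 0.20, 0.25)


@dataclass
class FCMatrix:
    """P×P Pearson correlation matrix; parcel order follows the session."""

    values: np.ndarray
    parcel_names: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FCMatrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FCMatrix must be symmetric")
        self.values = v

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class ZMatrix:
    """Fisher-transformed FC; the diagonal is set to 0 and is excluded from
    all downstream statistics."""

    values: np.ndarray
    parcel_names: list[str] | None = None

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryAdjacency:
    """Thresholded binary graph with its target and realized edge density."""

    adjacency: np.ndarray
    density: float
    density_actual: float
    parcel_names: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def pearson_fc(session: SessionRecord) -> FCMatrix:
    """Full-session Pearson correlation between all parcel pairs."""
    data = session.data
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [session.parcel_names[i] for i in dead[:5]]
            if session.parcel_names
            else dead[:5].tolist()
        )
        raise ValueError(
            f"session {session.session_id!r}: zero-variance parcel(s) {names}"
        )
    r = np.corrcoef(data, rowvar=False)
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return FCMatrix(r, session.parcel_names)


def fisher_r2z(fc: FCMatrix, clip: float = 1.0 - 1e-7) -> ZMatrix:
    """Elementwise atanh off-diagonal; |r| >= clip is clipped first so the
    transform stays finite."""
    if not 0.0 < clip < 1.0:
        raise ValueError("clip must be in (0, 1)")
    r = np.clip(fc.values, -clip, clip)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ZMatrix(z, fc.parcel_names)


def _upper_edges(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(p, k=1)


def binarize_by_density(
    m: FCMatrix | ZMatrix, density: float
) -> BinaryAdjacency:
    """Keep the round(density·E) strongest off-diagonal edges by signed value.

    E = P(P−1)/2. Ties are broken by stable edge index order (upper-triangle
    row-major), which makes the edge set at a lower density a subset of the
    edge set at any higher density.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    values = np.asarray(m.values, dtype=float)
    p = values.shape[0]
    iu, ju = _upper_edges(p)
    weights = values[iu, ju]
    n_edges = weights.size
    keep = int(np.floor(density * n_edges + 0.5))
    if keep < 1:
        raise ValueError(
            f"density {density} retains no edges (E={n_edges}); need density·E >= 1"
        )
    # stable sort on -w: descending by weight, ties by edge index
    order = np.argsort(-weights, kind="stable")[:keep]
    adj = np.zeros((p, p), dtype=np.int8)
    adj[iu[order], ju[order]] = 1
    adj |= adj.T
    return BinaryAdjacency(
        adjacency=adj,
        density=density,
        density_actual=keep / n_edges,
        parcel_names=getattr(m, "parcel_names", None),
    )


def binarize_by_threshold(m: FCMatrix | ZMatrix, cutoff: float) -> BinaryAdjacency:
    """Absolute-value-threshold alternative: keep edges with value > cutoff."""
    values = np.asarray(m.values, dtype=float)
    p = values.shape[0]
    adj = (values > cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)
    n_edges = p * (p - 1) // 2
    return BinaryAdjacency(
        adjacency=adj,
        density=float("nan"),
        density_actual=adj.sum() / 2 / n_edges,
        parcel_names=getattr(m, "parcel_names", None),
    )
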