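"""Diametrical clustering of leading eigenvectors into brain states.

Diametrical clustering is a k-means-type algorithm on *axes*: unit vectors
identified with their negation. Each sample is assigned to the centroid
maximizing the squared cosine similarity (x·μ)², and each centroid is updated
to the leading eigenvector of its cluster's scatter matrix Σ x xᵀ — the unit
vector maximizing the within-cluster sum of squared cosines. Both steps are
invariant to flipping the sign of any sample, which is exactly the ambiguity
carried by eigenvectors.

The objective, mean over samples of max_j (x·μ_j)², is non-decreasing across
iterations (alternating maximization); the best of several seeded restarts is
returned. Centroid updates run power iteration through the data matrix
(μ ← Xᵀ(Xμ), normalized), which has the same fixed point as an explicit
eigendecomposition of the P×P scatter but costs O(N·P) per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class StateModel:
    """A fitted set of k brain-state centroids on the sign-invariant sphere."""

    k: int
    centroids: np.ndarray  # k×P, unit rows
    objective: float  # mean max_j (x·μ_j)², in [0, 1]
    n_iter: int
    restart_index: int
    seed: int | None = None
    objective_history: list[float] = field(default_factory=list)
    all_restart_histories: list[list[float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        norms = np.linalg.norm(self.centroids, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("centroid rows must have unit norm")


def _check_unit_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("samples must be an N×P matrix")
    norms = np.linalg.norm(x, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("sample rows must have unit norm")
    return x


def _sq_cos(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """N×k squared cosines to each centroid."""
    return (x @ centroids.T) ** 2


def _plusplus_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Diametrical k-means++: greedy seeding by squared-cosine distance 1−(x·μ)²."""
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    dist = np.clip(1.0 - (x @ centroids[0]) ** 2, 0.0, None)
    for j in range(1, k):
        total = dist.sum()
        if total <= 0:
            centroids[j] = x[rng.integers(n)]
        else:
            centroids[j] = x[rng.choice(n, p=dist / total)]
        dist = np.minimum(dist, np.clip(1.0 - (x @ centroids[j]) ** 2, 0.0, None))
    return centroids


def _scatter_leading(x_j: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Leading eigenvector of x_jᵀx_j by power iteration warm-started at mu.

    The scatter is PSD, so each sweep is non-decreasing in the Rayleigh
    quotient; the alternating objective therefore stays monotone even when
    the iteration is stopped early.
    """
    v = mu
    prev = -np.inf
    for _ in range(100):
        w = x_j.T @ (x_j @ v)
        norm = np.linalg.norm(w)
        if norm == 0:  # mu orthogonal to the cluster span; restart randomly
            w = x_j[0]
            norm = np.linalg.norm(w)
        v = w / norm
        rayleigh = float(v @ (x_j.T @ (x_j @ v)))
        if rayleigh - prev <= 1e-12 * max(1.0, rayleigh):
            break
        prev = rayleigh
    return v


def _single_run(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    centroids = _plusplus_init(x, k, rng)
    history: list[float] = []
    labels = np.zeros(x.shape[0], dtype=int)
    objective = -np.inf
    for iteration in range(1, max_iter + 1):
        scores = _sq_cos(x, centroids)
        labels = np.argmax(scores, axis=1)  # ties -> lowest index
        new_objective = float(scores[np.arange(x.shape[0]), labels].mean())
        history.append(new_objective)
        if new_objective - objective < tol and iteration > 1:
            objective = new_objective
            break
        objective = new_objective
        best = scores[np.arange(x.shape[0]), labels]
        for j in range(k):
            members = labels == j
            if not members.any():
                # re-seed an empty cluster from the worst-fit sample
                centroids[j] = x[np.argmin(best)]
                continue
            centroids[j] = _scatter_leading(x[members], centroids[j])
    return centroids, labels, objective, len(history), history


def diametrical_fit(
    x: np.ndarray,
    k: int,
    restarts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-10,
    seed: int | None = None,
) -> StateModel:
    """Fit k diametrical clusters to pooled unit-norm eigenvectors.

    Runs ``restarts`` independent k-means++-seeded alternating maximizations
    and returns the restart with the highest objective.
    """
    x = _check_unit_rows(x)
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"need 1 <= k <= N; got k={k}, N={n}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    all_histories: list[list[float]] = []
    for restart in range(restarts):
        centroids, _, objective, n_iter, history = _single_run(
            x, k, rng, max_iter, tol
        )
        all_histories.append(history)
        if best is None or objective > best[1]:
            best = (centroids, objective, n_iter, restart, history)
    centroids, objective, n_iter, restart_index, history = best
    return StateModel(
        k=k,
        centroids=centroids,
        objective=objective,
        n_iter=n_iter,
        restart_index=restart_index,
        seed=seed,
        objective_history=history,
        all_restart_histories=all_histories,
    )


def diametrical_assign(x: np.ndarray, model: StateModel) -> np.ndarray:
    """Label each sample with argmax_j (x·μ_j)²; ties go to the lowest index."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(
            f"dimension mismatch: samples have P={x.shape[1]}, "
            f"model has P={model.centroids.shape[1]}"
        )
    return np.argmax(_sq_cos(x, model.centroids), axis=1)


def state_proportions(labels: Sequence[int], k: int) -> np.ndarray:
    """Per-state label proportions for one session (labels in 0..k−1)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= k):
        raise ValueError(f"labels must lie in 0..{k - 1}")
    counts = np.bincount(labels, minlength=k)
    return counts / labels.size


def fractional_occurrence(
    labels_by_session: Mapping[tuple[str, str, int], Sequence[int]],
    k: int,
) -> pd.DataFrame:
    """Occupancy table: one row per session, one column per state.

    ``labels_by_session`` maps (session_id, condition, day_index) to that
    session's label sequence. Row values are label proportions and sum to 1.
    """
    rows = []
    for (session_id, condition, day_index), labels in labels_by_session.items():
        props = state_proportions(labels, k)
        row = {"session_id": session_id, "condition": condition, "day_index": day_index}
        row.update({f"state_{j + 1}": props[j] for j in range(k)})
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["condition", "day_index"], kind="stable").reset_index(
        drop=True
    )


def match_centroids(
    model_a: StateModel, model_b: StateModel
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Optimal one-to-one centroid pairing maximizing total |cosine|.

    Returns ``(pairs, similarities)`` for min(k_a, k_b) pairs; similarity is
    |cos| so the pairing ignores centroid sign.
    """
    a, b = model_a.centroids, model_b.centroids
    if a.shape[1] != b.shape[1]:
        raise ValueError("models must share the parcel dimension P")
    sim = np.abs(a @ b.T)
    row, col = linear_sum_assignment(-sim)
    return list(zip(row.tolist(), col.tolist())), sim[row, col]
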