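"""Synthetic two-condition cohorts with known ground truth.

Two generators emulate the dense-sampling paired design (30 scan sessions per
condition, paired by day):

* the *static* generator draws each session's time series from a planted
  block correlation matrix — within-network correlation fixed, between-network
  correlation differing by condition and fluctuating day-to-day through a
  shared-variance AR(1) day effect, so paired metric differences carry known
  lag-1 serial correlation;
* the *dynamic* generator produces piecewise-stationary oscillatory sessions:
  a hidden Markov chain (per-condition transition matrix) selects one of
  K planted ±1 sign patterns per volume, parcels oscillate at f0 with the two
  sign groups offset by π plus phase noise. The phase-coherence matrix of a
  noise-free volume is exactly uuᵀ for the active pattern u, whose leading
  eigenvector is u/√P — so LEiDA and the clustering stage have analytically
  known targets.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, hadamard

from cycleconn.io_sessions import (
    SEVEN_NETWORKS,
    AtlasDefinition,
    SessionManifest,
    SessionRecord,
)


class SimulationError(ValueError):
    pass


def gen_ar1_series(
    phi: float, n: int, sd: float = 1.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Stationary AR(1) draw: x_t = φ·x_{t−1} + ε_t, ε ~ N(0, sd²).

    The first value is drawn from the stationary distribution
    N(0, sd²/(1−φ²)) so the series is stationary from t=0.
    """
    if not -1.0 < phi < 1.0:
        raise SimulationError(f"|phi| must be < 1, got {phi}")
    if n < 1:
        raise SimulationError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    innovations = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innovations[t - 1]
    return x


def plant_block_fc(
    p: int, partition_sizes: list[int], r_within: float, r_between: float
) -> np.ndarray:
    """Block correlation matrix: 1 on the diagonal, r_within inside blocks,
    r_between across blocks. Raises if the combination is not positive
    definite."""
    if sum(partition_sizes) != p:
        raise SimulationError(f"partition sizes {partition_sizes} must sum to P={p}")
    if not (-1.0 < r_within < 1.0 and -1.0 < r_between < 1.0):
        raise SimulationError("|r| values must be < 1")
    sigma = np.full((p, p), r_between)
    start = 0
    for size in partition_sizes:
        sigma[start : start + size, start : start + size] = r_within
        start += size
    np.fill_diagonal(sigma, 1.0)
    try:
        cholesky(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SimulationError(
            f"r_within={r_within}, r_between={r_between} gives a non-positive-"
            "definite matrix; bring r_between closer to r_within or shrink |r|"
        ) from exc
    return sigma


def _equal_sizes(p: int, m: int) -> list[int]:
    base, extra = divmod(p, m)
    return [base + (i < extra) for i in range(m)]


def _atlas_for(partition_sizes: list[int]) -> AtlasDefinition:
    m = len(partition_sizes)
    labels = (
        list(SEVEN_NETWORKS) if m == 7 else [f"network_{i + 1}" for i in range(m)]
    )
    parcel_names, network_of = [], {}
    for label, size in zip(labels, partition_sizes):
        for j in range(size):
            name = f"{label.replace(' ', '_')}_{j + 1}"
            parcel_names.append(name)
            network_of[name] = label
    return AtlasDefinition(parcel_names, network_of, labels)


@dataclass
class StaticSimParams:
    """Study conditions for the static-cohort simulation.

    Defaults plant a between-network coupling contrast (natural 0.10 vs oc
    0.20 — lower between-network coupling means higher segregation in the
    natural condition) on a seven-network brain of 100 parcels, with a
    moderate AR(1) day effect on the between-network level.

    ``edge_hetero`` is the variance of a rank-``hetero_rank`` random
    component giving every parcel pair its own coupling offset (fixed parcel
    identities across sessions). Zero gives the exact three-valued block
    structure of :func:`plant_block_fc`; the positive default makes edge
    strengths heterogeneous and overlapping the way real connectomes are, so
    proportional thresholding at 10% density yields connected graphs instead
    of isolated network cliques.
    """

    p: int = 100
    partition_sizes: list[int] | None = None
    r_within: float = 0.35
    r_between_natural: float = 0.10
    r_between_oc: float = 0.20
    edge_hetero: float = 0.30
    hetero_rank: int = 5
    t: int = 400
    tr: float = 2.0
    day_ar1_phi: float = 0.5
    day_sd: float = 0.02
    noise_sd: float = 0.2
    n_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition_sizes is None:
            self.partition_sizes = _equal_sizes(self.p, 7)
        if not 0.0 < self.r_between_natural < self.r_within < 1.0:
            raise SimulationError("need 0 < r_between_natural < r_within < 1")
        if not 0.0 < self.r_between_oc < self.r_within < 1.0:
            raise SimulationError("need 0 < r_between_oc < r_within < 1")


@dataclass
class GroundTruth:
    """Planted quantities for recovery tests."""

    labels: dict[str, np.ndarray] = field(default_factory=dict)
    fractional_occurrence: dict[str, np.ndarray] = field(default_factory=dict)
    r_between: dict[tuple[str, int], float] = field(default_factory=dict)
    state_patterns: np.ndarray | None = None
    stationary: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    manifest: SessionManifest
    atlas: AtlasDefinition
    truth: GroundTruth


def gen_static_cohort(params: StaticSimParams) -> Cohort:
    """Two-condition static cohort from a planted factor covariance.

    The population correlation of a session on day d of condition c is

        r_ij = a_c²·1[same network] + r_b(c, d) + (b²/q)·w_i·w_j

    with a_c² = r_within − r_between_c (network factors), r_b(c, d) the
    between-network level perturbed by an independent AR(1) day series per
    condition, and w_i ∈ R^q fixed random parcel identities providing the
    per-edge heterogeneity (variance b² = edge_hetero). Mean within-network
    correlation is r_within, mean between-network correlation r_b(c, d), so
    daily paired differences of segregation-type metrics inherit lag-1
    autocorrelation ≈ day_ar1_phi. Observation noise is added i.i.d.
    """
    rng = np.random.default_rng(params.seed)
    atlas = _atlas_for(params.partition_sizes)
    partition = atlas.partition_vector()
    n_networks = len(params.partition_sizes)
    truth = GroundTruth()
    records = []
    base = {"natural": params.r_between_natural, "oc": params.r_between_oc}
    day_effects = {
        cond: gen_ar1_series(params.day_ar1_phi, params.n_days, params.day_sd, rng)
        for cond in ("natural", "oc")
    }
    # per-edge coupling identities, fixed across all sessions
    q = max(1, params.hetero_rank)
    w = (
        np.sqrt(params.edge_hetero / q) * rng.standard_normal((params.p, q))
        if params.edge_hetero > 0
        else np.zeros((params.p, 1))
    )
    for cond in ("natural", "oc"):
        a_net = np.sqrt(params.r_within - base[cond])
        for day in range(1, params.n_days + 1):
            r_b = base[cond] + day_effects[cond][day - 1]
            r_b = float(np.clip(r_b, 0.01, params.r_within - 0.05))
            glob_load = np.full(params.p, np.sqrt(r_b))
            net_load = np.full(params.p, a_net)
            # keep unique variance positive (factor model stays a correlation)
            total = net_load**2 + glob_load**2 + (w**2).sum(axis=1)
            shrink = np.sqrt(np.minimum(1.0, 0.95 / total))
            net_load *= shrink
            glob_load *= shrink
            w_day = w * shrink[:, None]
            psi = 1.0 - net_load**2 - glob_load**2 - (w_day**2).sum(axis=1)
            factors = rng.standard_normal((params.t, n_networks + 1))
            hetero = rng.standard_normal((params.t, q)) @ w_day.T
            signal = (
                factors[:, partition] * net_load
                + factors[:, [n_networks]] * glob_load
                + hetero
                + np.sqrt(psi) * rng.standard_normal((params.t, params.p))
            )
            noise = params.noise_sd * rng.standard_normal((params.t, params.p))
            records.append(
                SessionRecord(
                    session_id=f"{cond}{day:02d}",
                    condition=cond,
                    day_index=day,
                    tr=params.tr,
                    data=signal + noise,
                    parcel_names=atlas.parcel_names,
                )
            )
            truth.r_between[(cond, day)] = r_b
    return Cohort(SessionManifest(records), atlas, truth)


def default_state_patterns(p: int, k: int) -> np.ndarray:
    """K mutually orthogonal ±1 block sign patterns (Hadamard rows over
    equal parcel blocks)."""
    m = 1
    while m < k:
        m *= 2
    rows = hadamard(m)[:k]
    sizes = _equal_sizes(p, m)
    patterns = np.empty((k, p), dtype=float)
    for i in range(k):
        patterns[i] = np.repeat(rows[i], sizes)
    return patterns


def stationary_transition_matrix(pi: np.ndarray, stay: float = 0.8) -> np.ndarray:
    """Row-stochastic matrix T = stay·I + (1−stay)·1πᵀ with stationary
    distribution π and expected dwell time 1/(1−stay) volumes."""
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0) or (pi < 0).any():
        raise SimulationError("pi must be a probability vector")
    if not 0.0 <= stay < 1.0:
        raise SimulationError("stay must be in [0, 1)")
    k = pi.size
    return stay * np.eye(k) + (1.0 - stay) * np.tile(pi, (k, 1))


def shifted_stationary(k: int, shift: float, state: int = 0) -> np.ndarray:
    """Uniform stationary distribution with ``shift`` added to one state and
    removed evenly from the rest."""
    pi = np.full(k, 1.0 / k)
    if k == 1:
        if shift:
            raise SimulationError("cannot shift occupancy with a single state")
        return pi
    pi[state] += shift
    others = [j for j in range(k) if j != state]
    pi[others] -= shift / (k - 1)
    if (pi < 0).any():
        raise SimulationError(f"shift {shift} makes the distribution negative")
    return pi


@dataclass
class DynamicSimParams:
    """Study conditions for the dynamic-cohort simulation.

    Defaults plant K_true = 4 orthogonal sign-pattern states on 100 parcels,
    switching with expected dwell 5 volumes; the oc condition's stationary
    distribution shifts 0.08 of fractional occurrence onto state 1 relative
    to the natural condition's uniform distribution. Parcels oscillate at
    0.05 Hz (inside the 0.01–0.1 Hz analysis band at TR = 2 s).
    """

    p: int = 100
    k_true: int = 4
    state_patterns: np.ndarray | None = None
    transition_natural: np.ndarray | None = None
    transition_oc: np.ndarray | None = None
    fo_shift: float = 0.08
    shifted_state: int = 0
    stay: float = 0.8
    f0: float = 0.05
    tr: float = 2.0
    t: int = 250
    phase_noise_sd: float = 0.3
    n_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 >= 1.0 / (2.0 * self.tr):
            raise SimulationError(
                f"f0={self.f0} Hz at or above Nyquist ({1.0 / (2.0 * self.tr)} Hz)"
            )
        if self.state_patterns is None:
            self.state_patterns = default_state_patterns(self.p, self.k_true)
        self.state_patterns = np.asarray(self.state_patterns, dtype=float)
        if self.state_patterns.shape != (self.k_true, self.p):
            raise SimulationError("state_patterns must be K_true×P")
        if self.transition_natural is None:
            self.transition_natural = stationary_transition_matrix(
                np.full(self.k_true, 1.0 / self.k_true), self.stay
            )
        if self.transition_oc is None:
            shift = self.fo_shift if self.k_true > 1 else 0.0
            self.transition_oc = stationary_transition_matrix(
                shifted_stationary(self.k_true, shift, self.shifted_state),
                self.stay,
            )
        for name, mat in (
            ("transition_natural", self.transition_natural),
            ("transition_oc", self.transition_oc),
        ):
            mat = np.asarray(mat, dtype=float)
            if not np.allclose(mat.sum(axis=1), 1.0):
                raise SimulationError(f"rows of {name} must sum to 1")


def _stationary_of(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    idx = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, idx])
    return pi / pi.sum()


def _markov_labels(
    transition: np.ndarray, t: int, rng: np.random.Generator
) -> np.ndarray:
    pi = _stationary_of(transition)
    labels = np.empty(t, dtype=int)
    labels[0] = rng.choice(pi.size, p=pi)
    for step in range(1, t):
        labels[step] = rng.choice(pi.size, p=transition[labels[step - 1]])
    return labels


def gen_dynamic_cohort(params: DynamicSimParams) -> Cohort:
    """Two-condition dynamic cohort of phase-locked oscillatory sessions.

    For each volume the active state's ±1 pattern splits parcels into two
    groups oscillating in antiphase:
    x[t, p] = cos(2π·f0·t·TR + φ_session + π·1[u_p = −1] + ε) with
    ε ~ N(0, phase_noise_sd²) drawn per volume and parcel.
    """
    rng = np.random.default_rng(params.seed)
    atlas = _atlas_for(_equal_sizes(params.p, 7))
    truth = GroundTruth(
        state_patterns=params.state_patterns,
        stationary={
            "natural": _stationary_of(np.asarray(params.transition_natural)),
            "oc": _stationary_of(np.asarray(params.transition_oc)),
        },
    )
    transitions = {
        "natural": np.asarray(params.transition_natural, dtype=float),
        "oc": np.asarray(params.transition_oc, dtype=float),
    }
    group_offset = np.pi * (params.state_patterns < 0)  # K×P phase offsets
    times = 2.0 * np.pi * params.f0 * params.tr * np.arange(params.t)
    records = []
    for cond in ("natural", "oc"):
        for day in range(1, params.n_days + 1):
            labels = _markov_labels(transitions[cond], params.t, rng)
            phase0 = rng.uniform(0.0, 2.0 * np.pi)
            noise = rng.normal(0.0, params.phase_noise_sd, size=(params.t, params.p))
            phases = times[:, None] + phase0 + group_offset[labels] + noise
            sid = f"{cond}{day:02d}"
            records.append(
                SessionRecord(
                    session_id=sid,
                    condition=cond,
                    day_index=day,
                    tr=params.tr,
                    data=np.cos(phases),
                    parcel_names=atlas.parcel_names,
                )
            )
            truth.labels[sid] = labels
            truth.fractional_occurrence[sid] = (
                np.bincount(labels, minlength=params.k_true) / params.t
            )
    return Cohort(SessionManifest(records), atlas, truth)
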