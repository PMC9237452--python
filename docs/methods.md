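# Methods

This note documents the models and procedures implemented in `cycleconn`,
the defaults they use, and the reasoning behind the choices that were
genuinely open.

## Design and data model

The target design is a dense-sampling single-subject study: one resting-state
scan per day for 30 consecutive days under each of two conditions
("natural" and "oc"), compared pairwise by day index. Inputs are
already-parcellated BOLD time series (T timepoints × P parcels, TSV with a
parcel-name header) plus a session manifest (condition, day index, TR).
Preprocessing and parcellation are upstream concerns; the package starts at
the parcel series. Sessions are paired by *experiment day* (day n with
day n); pairing by aligned cycle day is possible by relabeling `day_index`
in the manifest.

Parcels are allocated to the seven canonical resting-state networks
(visual, somatomotor, dorsal attention, ventral attention, limbic, default
mode, executive control), parsed either from Schaefer-style
`7Networks_<Hemi>_<Network>_<idx>` names or from an explicit two-column
table.

## Static stage

**Connectivity.** Whole-session Pearson correlation per parcel pair;
Fisher z = atanh(r) with |r| clipped at 1 − 1e−7 so the transform stays
finite. The z diagonal is zeroed and excluded everywhere.

**Thresholding.** "Sparsity" is proportional edge density: density d keeps
the ⌊d·E⌉ strongest of the E = P(P−1)/2 off-diagonal edges by signed value,
ties broken by stable edge-index order (making edge sets nest across
densities). Default sweep {0.10, 0.15, 0.20, 0.25}. An absolute-cutoff
binarization exists behind `binarize_by_threshold`. Ranking is done on the
z matrix; since atanh is strictly increasing, r- and z-ranked binary graphs
are identical.

**Measures.**

* Modularity Q of the *fixed* seven-network partition (no community
  detection): Q = Σ_c [e_c/m − (d_c/2m)²]. With a non-optimized partition Q
  can be negative at sparse densities.
* System segregation SS = (Z̄_w − Z̄_b)/Z̄_w over off-diagonal pairs.
* Weighted CPL: Dijkstra shortest paths with edge length 1 − r
  (configurable to 1/r); negative-r edges are excluded from the length
  graph; unreachable pairs are dropped from the mean and counted. The
  1 − r map is the default because it keeps path lengths on the scale of
  the observed correlations.
* Binarized CPL: mean hop-count distance over ordered pairs of retained
  nodes. Parcels that fall off the largest connected component in *any*
  session/density graph are excluded from bCPL (only) at all densities and
  in both conditions — mirroring how a single temporal-pole parcel behaves
  in real Schaefer-400 data. The exclusion set is computed to a fixed point
  (excluding a parcel can strand another) and logged; a manual exclusion
  list can be supplied in the config.

## Dynamic stage (LEiDA + diametrical clustering)

Each session is demeaned and band-pass filtered (zero-phase Butterworth,
order 2, 0.01–0.1 Hz by default — the conventional resting-state band; the
order/band are config entries). Instantaneous phases come from the Hilbert
transform; for every volume t the P×P phase-coherence matrix
cos(θ_i(t) − θ_j(t)) is summarized by its leading eigenvector (unit norm).
Three volumes are trimmed at each end against filter/Hilbert transients
(configurable). Eigenvector sign is fixed cosmetically (majority of
elements negative; ties resolved by the first element) — the downstream
clustering is sign-invariant, so this only makes outputs byte-reproducible.
A (near-)degenerate top eigenvalue is flagged and counted; with real or
noisy synthetic data it is measure-zero.

**Diametrical clustering.** Eigenvectors from all sessions are pooled
(per-condition fitting is a non-default option) and clustered on the
sign-invariant unit sphere: assignment maximizes (xᵀμ_j)², the update sets
μ_j to the leading eigenvector of the cluster scatter Σ xxᵀ. The update is
computed by power iteration *through the data matrix* (μ ← Xᵀ(Xμ),
normalized) — the same fixed point as an explicit P×P eigendecomposition,
monotone in the Rayleigh quotient, and O(N·P) per sweep, which keeps the
full k = 2..20 sweep fast. The objective (mean best squared cosine) is
non-decreasing across iterations; each fit runs 50 k-means++-style seeded
restarts by default (greedy seeding by 1 − (xᵀμ)² distance) and returns the
best restart. Empty clusters are re-seeded from the worst-fit sample rather
than silently reducing k. Tolerance 1e−10 on the objective, max 1000
iterations.

Per session and k, fractional occurrence is the proportion of volumes
assigned to each state; rows sum to 1 by construction. `match_centroids`
aligns state models across k (or across runs) by maximum-|cosine| optimal
assignment.

## Statistics

All comparisons are on the 30 day-paired differences (natural − oc, ordered
by day).

* **Paired t** for system segregation, weighted CPL and fractional
  occurrence.
* **AR(1) GLS** for modularity and binarized CPL, whose day-ordered paired
  differences show lag-1 serial correlation (see
  `analysis/04_serial_correlation_checks.py` for the correlograms). The
  model is an intercept-only regression with AR(1) error correlation,
  estimated by exact restricted maximum likelihood: the AR(1) covariance is
  whitened analytically and the likelihood concentrated to a 1-D search
  over φ. Inference uses t with n − 1 df. Likelihood estimates of φ are
  biased toward zero at n ≈ 30, which makes the naive plug-in test
  anti-conservative (empirical type-I error ≈ 0.10 at φ = 0.5, n = 30 — we
  verified our fit is numerically identical to `nlme::gls`, which shares the
  problem). The default therefore applies a Kendall–Orcutt-type bias
  correction, φ̃ = φ̂ + (1 + 3φ̂)/n, before forming the standard error; this
  holds the measured type-I error at 0.05–0.07 across φ ∈ [0, 0.7] and
  vanishes as 1/n, so the test still agrees with the paired t on white-noise
  differences at large n. Plain ML and the uncorrected plug-in remain
  available (`method="ml"`, `bias_correct=False`).
* The metric→test routing is fixed configuration (mirroring inspection of
  the correlograms); an automatic router switching to GLS when |acf(1)|
  exceeds a cutoff exists but is off by default, since a data-driven switch
  changes the test's operating characteristics.
* **Effect sizes** are pooled-SD Cohen's d (independent-groups form,
  s_p = √((s_a² + s_b²)/2) at equal n) — the convention that matches
  condition-summary reporting — with confidence intervals by noncentral-t
  inversion. The paired-difference form would give systematically smaller
  values.
* **Multiplicity.** Occupancy tests are corrected within each k by
  Bonferroni (p_fwer = min(1, k·p)); the k = 2..20 sweep yields Σk = 209
  tests. No correction is applied across k, which asks a different question
  (the same underlying contrast re-expressed at every resolution).

## Synthetic cohorts

The generators exist to give every stage a known truth; both are pure
functions of their seed.

**Static.** Sessions are drawn from a factor model whose population
correlation is r_within (default 0.35) inside networks and r_b(c, d)
across, where r_b is 0.10 (natural) vs 0.20 (oc) perturbed by an
independent stationary AR(1) day series per condition (φ = 0.5, innovation
sd 0.02) — so the planted contrast is purely between-network coupling, its
direction forces higher segregation/modularity in the natural condition,
and daily paired metric differences inherit lag-1 autocorrelation. A
low-rank random component (variance 0.30, rank 5, fixed per cohort) gives
every parcel pair its own coupling offset: without it, proportional
thresholding of a clean block matrix at 10% density returns seven
disconnected network cliques, whereas real connectomes stay connected
because per-edge spread is comparable to the within/between mean gap. With
it, sparse graphs behave like real data: connected up to a handful of
straggler parcels, which exercises the bCPL exclusion machinery. The exact
three-valued block construction remains available as `plant_block_fc`.
Defaults: P = 100, seven equal networks, T = 400, TR = 2 s, 30 days,
observation noise sd 0.2.

**Dynamic.** A hidden Markov chain per session selects one of K_true = 4
planted ±1 sign patterns per volume (mutually orthogonal Hadamard block
patterns by default); parcels oscillate at f0 = 0.05 Hz with the two sign
groups in antiphase plus N(0, 0.3²) phase noise. A noise-free volume's
coherence matrix is exactly uuᵀ with leading eigenvector u/√P, so LEiDA's
output is analytically known. Transition matrices are
stay·I + (1 − stay)·1πᵀ (stay = 0.8, expected dwell 5 volumes); the oc
condition's stationary distribution shifts 0.08 of occupancy onto state 1.
Defaults: P = 100, T = 250, TR = 2 s, 30 days per condition.

**What the generators do not emulate:** hemodynamic convolution and
low-pass structure, motion and physiological artifacts, spatial
autocorrelation within parcels, amplitude (as opposed to phase) dynamics,
and session-level nonstationarity. Passing recovery tests therefore shows
the pipeline is correct under its own signal model, not that real scans
satisfy that model.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] before atanh; zero-variance parcels
  are an error naming the parcel.
* Binarization requires density·E ≥ 1; tie-breaks are stable and
  documented above.
* Zero-length weighted edges are floored at 1e−12 so sparse shortest-path
  routines keep them.
* Constant difference series: the ACF returns flagged zeros with a warning;
  tests raise on zero variance.
* Clustering label ties go to the lowest state index; sample rows must be
  unit-norm within 1e−6.
* One config seed drives all stochastic stages through derived substreams
  (`SeedSequence([seed, k])`), so stages can be rerun independently with
  bit-identical results.

## Problem sizes in the test suite

The suite validates properties, not scale: unit tests run on small graphs
and short sessions; the end-to-end dynamic power check runs the full study
size (P = 100, T = 250, 30 paired days, k = 4); the null-pipeline
calibration runs 50 replicate cohorts at a reduced size (P = 32, T = 140,
k = 2..5, 3 restarts) — the calibration property being checked does not
depend on scale. `scripts/acceptance.py` runs the complete k = 2..20 sweep
at full study size with 5 restarts per k.

## Known limitations

* The AR(1) GLS covers lag-1 structure only; longer-memory errors would
  need an ARMA extension.
* Modularity is evaluated on binarized graphs per density (matching how Q
  is reported per threshold); a weighted-Q variant is not implemented.
* Dwell times, transition probabilities and Markov modeling of the label
  sequences are out of scope — only fractional occurrence is tested.
* With compositional occupancies, within-k tests are not independent
  (states' occupancies sum to 1); Bonferroni is conservative here, which is
  the intended direction.
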