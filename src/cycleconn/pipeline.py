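"""End-to-end orchestration: static metrics, dynamic states, paired tests.

``run_static`` computes per-session system segregation and weighted CPL on
the full matrices, and modularity / binarized CPL over the density sweep,
then routes each metric to its paired test (t-test for SS and weighted CPL;
AR(1) GLS for modularity and binarized CPL, whose day-ordered differences
show lag-1 serial structure). ``run_dynamic`` runs LEiDA per session, pools
eigenvectors across all sessions, fits diametrical clustering for every k in
the sweep, and tests per-state fractional occurrence with within-k
Bonferroni correction.

One seed governs all stochastic stages through per-stage derived substreams,
so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from cycleconn.clustering import (
    StateModel,
    diametrical_assign,
    diametrical_fit,
    fractional_occurrence,
)
from cycleconn.graph_metrics import (
    binary_cpl,
    exclusion_fixed_point,
    modularity_q,
    system_segregation,
    weighted_cpl,
)
from cycleconn.io_sessions import AtlasDefinition, SessionManifest
from cycleconn.leida import session_eigenvectors
from cycleconn.static_fc import binarize_by_density, fisher_r2z, pearson_fc
from cycleconn.stats import acf, compare_conditions, full_test_matrix, paired_diffs

logger = logging.getLogger("cycleconn")

DEFAULT_ROUTING = {
    "system_segregation": "paired_t",
    "weighted_cpl": "paired_t",
    "modularity": "gls_ar1",
    "binary_cpl": "gls_ar1",
}


@dataclass
class PipelineConfig:
    """All tunables for one end-to-end run; round-trips through YAML."""

    # static block
    density_grid: list[float] = field(default_factory=lambda: [0.10, 0.15, 0.20, 0.25])
    length_map: str = "one_minus_r"
    clip: float = 1.0 - 1e-7
    exclude_parcels: list[int] = field(default_factory=list)
    auto_exclude: bool = True
    # dynamic block
    band_low: float = 0.01
    band_high: float = 0.1
    filter_order: int = 2
    edge_trim: int = 3
    kmin: int = 2
    kmax: int = 20
    restarts: int = 50
    seed: int = 0
    # stats block
    alpha: float = 0.05
    routing: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROUTING))
    auto_route: bool = False
    acf_route_cutoff: float = 0.3

    def __post_init__(self) -> None:
        if self.kmin < 2 or self.kmax < self.kmin:
            raise ValueError("need 2 <= kmin <= kmax")
        if not all(0.0 < d <= 1.0 for d in self.density_grid):
            raise ValueError("density grid values must lie in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def substream_seed(self, *key: int) -> int:
        """Derived substream seed for an independent stage (stable, < 2³¹)."""
        return int(
            np.random.SeedSequence([self.seed, *key]).generate_state(1)[0] % (2**31)
        )


@dataclass
class StaticResults:
    metrics: pd.DataFrame
    tests: pd.DataFrame
    excluded_parcels: list[int]


@dataclass
class DynamicResults:
    models: dict[int, StateModel]
    occupancy: dict[int, pd.DataFrame]
    tests: pd.DataFrame


def _route(metric: str, diffs_series, config: PipelineConfig) -> str:
    method = config.routing.get(metric, "paired_t")
    if config.auto_route:
        lag1 = acf(diffs_series, 1)[0]
        method = "gls_ar1" if abs(lag1) > config.acf_route_cutoff else "paired_t"
    return method


def run_static(
    manifest: SessionManifest,
    atlas: AtlasDefinition,
    config: PipelineConfig | None = None,
) -> StaticResults:
    """Static metrics per session plus routed paired tests."""
    config = config or PipelineConfig()
    partition = atlas.partition_vector()
    rows = []
    graphs, graph_labels = [], []
    per_session_graphs: dict[tuple[str, float], object] = {}
    for rec in manifest.records:
        fc = pearson_fc(rec)
        z = fisher_r2z(fc, config.clip)
        meta = {
            "session_id": rec.session_id,
            "condition": rec.condition,
            "day_index": rec.day_index,
        }
        rows.append(
            dict(meta, metric="system_segregation", parameter="weighted",
                 value=system_segregation(z, partition))
        )
        rows.append(
            dict(meta, metric="weighted_cpl", parameter="weighted",
                 value=weighted_cpl(fc, config.length_map).value)
        )
        for density in config.density_grid:
            g = binarize_by_density(z, density)
            per_session_graphs[(rec.session_id, density)] = g
            graphs.append(g)
            graph_labels.append(f"{rec.session_id}@{density:g}")
            rows.append(
                dict(meta, metric="modularity", parameter=f"{density:g}",
                     value=modularity_q(g, partition))
            )
    excluded = sorted(set(config.exclude_parcels))
    if config.auto_exclude:
        excluded, occurrences = exclusion_fixed_point(
            graphs, graph_labels, exclude=excluded
        )
        if occurrences:
            logger.info("auto-excluding parcels from bCPL: %s", occurrences)
    for rec in manifest.records:
        meta = {
            "session_id": rec.session_id,
            "condition": rec.condition,
            "day_index": rec.day_index,
        }
        for density in config.density_grid:
            g = per_session_graphs[(rec.session_id, density)]
            rows.append(
                dict(meta, metric="binary_cpl", parameter=f"{density:g}",
                     value=binary_cpl(g, exclude=excluded))
            )
    metrics = pd.DataFrame(rows)

    test_rows = []
    for (metric, parameter), block in metrics.groupby(["metric", "parameter"]):
        nat = dict(
            zip(block.loc[block.condition == "natural", "day_index"],
                block.loc[block.condition == "natural", "value"])
        )
        oc = dict(
            zip(block.loc[block.condition == "oc", "day_index"],
                block.loc[block.condition == "oc", "value"])
        )
        method = _route(metric, paired_diffs(nat, oc, metric), config)
        res = compare_conditions(nat, oc, metric, method, config.alpha)
        test_rows.append(
            {
                "metric": metric,
                "parameter": parameter,
                "estimate": res.estimate,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "t": res.t_stat,
                "df": res.df,
                "p": res.p,
                "d": res.d,
                "d_ci_low": res.d_ci_low,
                "d_ci_high": res.d_ci_high,
                "method": res.method,
                "phi_hat": res.phi_hat,
            }
        )
    tests = pd.DataFrame(test_rows).sort_values(
        ["metric", "parameter"], kind="stable"
    ).reset_index(drop=True)
    return StaticResults(metrics=metrics, tests=tests, excluded_parcels=excluded)


def run_dynamic(
    manifest: SessionManifest,
    config: PipelineConfig | None = None,
) -> DynamicResults:
    """LEiDA → pooled diametrical clustering per k → occupancy → test matrix."""
    config = config or PipelineConfig()
    eigensets = [
        session_eigenvectors(
            rec,
            edge_trim=config.edge_trim,
            band=(config.band_low, config.band_high),
            filter_order=config.filter_order,
        )
        for rec in manifest.records
    ]
    pooled = np.vstack([es.vectors for es in eigensets])
    slices = []
    start = 0
    for es in eigensets:
        slices.append((es, slice(start, start + es.n_volumes)))
        start += es.n_volumes
    models: dict[int, StateModel] = {}
    occupancy: dict[int, pd.DataFrame] = {}
    for k in range(config.kmin, config.kmax + 1):
        model = diametrical_fit(
            pooled,
            k,
            restarts=config.restarts,
            seed=config.substream_seed(k),
        )
        labels = diametrical_assign(pooled, model)
        logger.info("k=%d: objective=%.6f (restart %d)", k, model.objective,
                    model.restart_index)
        models[k] = model
        occupancy[k] = fractional_occurrence(
            {
                (es.session_id, es.condition, es.day_index): labels[sl]
                for es, sl in slices
            },
            k,
        )
    tests = full_test_matrix(occupancy, alpha=config.alpha)
    return DynamicResults(models=models, occupancy=occupancy, tests=tests)


# ---------------------------------------------------------------------------
# reporting


def notch_half_width(values: Sequence[float]) -> float:
    """Tukey boxplot notch half-width, 1.58·IQR/√n (95% CI for the median)."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    return float(1.58 * (q3 - q1) / np.sqrt(values.size))


def centroid_loading_summary(
    centroid: np.ndarray,
    parcel_names: Sequence[str] | None = None,
    fraction_of_max: float = 0.5,
) -> list[tuple[str, float]]:
    """Parcels whose |loading| is at least ``fraction_of_max`` of the
    centroid's maximum |loading| (the visualization rule for brain states)."""
    centroid = np.asarray(centroid, dtype=float)
    cutoff = fraction_of_max * np.abs(centroid).max()
    if parcel_names is None:
        parcel_names = [f"parcel_{i + 1}" for i in range(centroid.size)]
    return [
        (parcel_names[i], float(centroid[i]))
        for i in np.flatnonzero(np.abs(centroid) >= cutoff)
    ]


def report(
    static: StaticResults | None = None,
    dynamic: DynamicResults | None = None,
    config: PipelineConfig | None = None,
    parcel_names: Sequence[str] | None = None,
) -> str:
    """Human-readable summary of an end-to-end run."""
    config = config or PipelineConfig()
    lines = ["# cycleconn run summary", ""]
    if static is not None:
        lines.append("## Static metrics (median notches, 1.58·IQR/√n)")
        for (metric, parameter), block in static.metrics.groupby(
            ["metric", "parameter"]
        ):
            for cond in ("natural", "oc"):
                vals = block.loc[block.condition == cond, "value"]
                lines.append(
                    f"  {metric}[{parameter}] {cond}: median {vals.median():.4f} "
                    f"± notch {notch_half_width(vals):.4f}"
                )
        lines.append("")
        lines.append("## Static paired tests (natural − oc)")
        sig = static.tests[static.tests.p < config.alpha]
        if sig.empty:
            lines.append("  none significant")
        for row in sig.itertuples(index=False):
            lines.append(
                f"  {row.metric}[{row.parameter}]: diff {row.estimate:+.4f} "
                f"(95% CI {row.ci_low:.4f}..{row.ci_high:.4f}), p={row.p:.2e}, "
                f"d={row.d:.2f} [{row.method}]"
            )
        if static.excluded_parcels:
            lines.append(
                f"  parcels excluded from binarized CPL: {static.excluded_parcels}"
            )
        lines.append("")
    if dynamic is not None:
        lines.append(
            f"## Dynamic states (k {min(dynamic.models)}..{max(dynamic.models)}, "
            f"{len(dynamic.tests)} tests, within-k Bonferroni at α={config.alpha})"
        )
        sig = dynamic.tests[dynamic.tests.p_fwer < config.alpha]
        if sig.empty:
            lines.append("  none significant")
        for row in sig.itertuples(index=False):
            lines.append(
                f"  k={row.k} state {row.state}: FO diff {row.estimate:+.4f} "
                f"(95% CI {row.ci_low:.4f}..{row.ci_high:.4f}), "
                f"p={row.p:.2e}, p_FWER={row.p_fwer:.4f}, d={row.d:.2f}"
            )
        for k, model in sorted(dynamic.models.items()):
            hits = dynamic.tests[
                (dynamic.tests.k == k) & (dynamic.tests.p_fwer < config.alpha)
            ]
            for row in hits.itertuples(index=False):
                strong = centroid_loading_summary(
                    model.centroids[row.state - 1], parcel_names
                )
                names = ", ".join(name for name, _ in strong[:12])
                lines.append(f"    k={k} state {row.state} strong loadings: {names}")
    return "\n".join(lines) + "\n"
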