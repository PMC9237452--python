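"""Session, manifest and atlas I/O.

Inputs are already-parcellated BOLD time series: one tab-separated table per
scan session (rows = timepoints, columns = parcels, header row = parcel
names), plus a manifest describing condition ("natural" or "oc"), day index
and repetition time, and an atlas label file mapping parcels to the seven
canonical resting-state networks.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("natural", "oc")

#: canonical seven-network vocabulary (Yeo/Schaefer order)
SEVEN_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "ventral attention",
    "limbic",
    "default mode",
    "executive control",
)

# Schaefer "7Networks_<Hemi>_<Network>_<idx>" tokens -> canonical labels
_SCHAEFER_TOKENS = {
    "Vis": "visual",
    "SomMot": "somatomotor",
    "DorsAttn": "dorsal attention",
    "SalVentAttn": "ventral attention",
    "VentAttn": "ventral attention",
    "Limbic": "limbic",
    "Default": "default mode",
    "Cont": "executive control",
}

_CANONICAL = {name.lower(): name for name in SEVEN_NETWORKS}
_CANONICAL.update(
    {
        "salience": "ventral attention",
        "salience/ventral attention": "ventral attention",
        "dmn": "default mode",
        "control": "executive control",
        "frontoparietal": "executive control",
    }
)


class SessionIOError(ValueError):
    """Raised for malformed session tables, manifests or atlas files."""


@dataclass
class SessionRecord:
    """One scan session: a T×P time-series matrix plus metadata."""

    session_id: str
    condition: str
    day_index: int
    tr: float
    data: np.ndarray
    parcel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise SessionIOError(
                f"session {self.session_id!r}: need a T×P matrix with T >= 2, "
                f"got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise SessionIOError(f"session {self.session_id!r}: non-finite values")
        if self.condition not in CONDITIONS:
            raise SessionIOError(
                f"session {self.session_id!r}: condition must be one of "
                f"{CONDITIONS}, got {self.condition!r}"
            )
        if self.tr <= 0:
            raise SessionIOError(f"session {self.session_id!r}: tr must be > 0")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class SessionManifest:
    """Ordered collection of sessions with natural↔oc pairing by day index."""

    records: list[SessionRecord]

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            days = [r.day_index for r in self.records if r.condition == cond]
            if len(days) != len(set(days)):
                raise SessionIOError(f"duplicate day_index within condition {cond!r}")

    def by_condition(self, condition: str) -> list[SessionRecord]:
        return [r for r in self.records if r.condition == condition]

    @property
    def pairing(self) -> dict[int, tuple[SessionRecord, SessionRecord]]:
        """day_index -> (natural session, oc session), complete pairs only."""
        nat = {r.day_index: r for r in self.by_condition("natural")}
        oc = {r.day_index: r for r in self.by_condition("oc")}
        return {d: (nat[d], oc[d]) for d in sorted(nat.keys() & oc.keys())}

    def paired_days(self) -> list[int]:
        return sorted(self.pairing)


@dataclass
class AtlasDefinition:
    """Parcel names and their allocation to resting-state networks."""

    parcel_names: list[str]
    network_of: dict[str, str]
    networks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [p for p in self.parcel_names if p not in self.network_of]
        if missing:
            raise SessionIOError(f"parcels without a network: {missing[:5]}")
        if not self.networks:
            self.networks = sorted(set(self.network_of.values()))

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_names)

    def partition_vector(self) -> np.ndarray:
        """Integer network index (0..M-1) per parcel, in parcel order."""
        index = {n: i for i, n in enumerate(self.networks)}
        return np.array([index[self.network_of[p]] for p in self.parcel_names])


def normalize_network_label(token: str) -> str:
    """Map a Schaefer token or free-form network name to the canonical label."""
    if token in _SCHAEFER_TOKENS:
        return _SCHAEFER_TOKENS[token]
    low = token.strip().lower()
    if low in _CANONICAL:
        return _CANONICAL[low]
    raise SessionIOError(f"unknown network token {token!r}")


_SCHAEFER_RE = re.compile(r"^7Networks_(LH|RH)_([A-Za-z]+)_\d+$")


def parse_schaefer_name(parcel_name: str) -> str:
    """Network label from a ``7Networks_<Hemi>_<Network>_<idx>`` parcel name."""
    m = _SCHAEFER_RE.match(parcel_name)
    if not m:
        raise SessionIOError(f"parcel name {parcel_name!r} does not follow the "
                             "7Networks_<Hemi>_<Network>_<idx> convention")
    return normalize_network_label(m.group(2))


def read_timeseries_table(
    path: str | Path,
    session_id: str,
    condition: str,
    day_index: int,
    tr: float,
) -> SessionRecord:
    """Read one session's tab-separated time-series table.

    The file has a header row of parcel names and one numeric row per
    timepoint. Column order is preserved exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering
            raise SessionIOError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} at "
                f"file row {bad[0] + 2}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return SessionRecord(
        session_id=session_id,
        condition=condition,
        day_index=day_index,
        tr=tr,
        data=values,
        parcel_names=list(df.columns),
    )


def read_manifest(path: str | Path) -> SessionManifest:
    """Read a manifest TSV (session_id, condition, day_index, tr, path) and
    load every referenced time-series table."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = {"session_id", "condition", "day_index", "tr", "path"}
    if not required.issubset(table.columns):
        raise SessionIOError(
            f"{path}: manifest needs columns {sorted(required)}, "
            f"found {list(table.columns)}"
        )
    records = []
    for row in table.itertuples(index=False):
        ts_path = Path(row.path)
        if not ts_path.is_absolute():
            ts_path = path.parent / ts_path
        records.append(
            read_timeseries_table(
                ts_path,
                session_id=str(row.session_id),
                condition=str(row.condition),
                day_index=int(row.day_index),
                tr=float(row.tr),
            )
        )
    return SessionManifest(records)


def write_manifest(manifest: SessionManifest, out_dir: str | Path) -> Path:
    """Write each session as a TSV table plus a manifest TSV; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in manifest.records:
        fname = f"{rec.session_id}.tsv"
        names = rec.parcel_names or [f"parcel_{i + 1}" for i in range(rec.n_parcels)]
        pd.DataFrame(rec.data, columns=names).to_csv(
            out_dir / fname, sep="\t", index=False
        )
        rows.append(
            {
                "session_id": rec.session_id,
                "condition": rec.condition,
                "day_index": rec.day_index,
                "tr": rec.tr,
                "path": fname,
            }
        )
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    return manifest_path


def read_atlas_labels(path: str | Path) -> AtlasDefinition:
    """Read an atlas label file.

    Two layouts are accepted:

    * FreeSurfer-style Schaefer labels — one ``7Networks_<Hemi>_<Network>_<idx>``
      name per line, optionally preceded by a numeric index column;
    * an explicit two-column ``parcel<TAB>network`` table (no header), with
      network names from the seven-network vocabulary.
    """
    path = Path(path)
    parcel_names: list[str] = []
    network_of: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) >= 2 and not fields[0].isdigit():
            name, network = fields[0], fields[1]
            network_of[name] = normalize_network_label(network)
        else:
            name = fields[1] if fields[0].isdigit() and len(fields) >= 2 else fields[0]
            network_of[name] = parse_schaefer_name(name)
        parcel_names.append(name)
    networks = [n for n in SEVEN_NETWORKS if n in set(network_of.values())]
    extra = sorted(set(network_of.values()) - set(networks))
    return AtlasDefinition(parcel_names, network_of, networks + extra)


def write_metric_table(results: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write per-session metric values as a deterministic TSV.

    Rows are sorted by (condition, day, metric, parameter); re-reading with
    :func:`read_metric_table` reproduces values to full float precision.
    """
    df = pd.DataFrame(results)
    expected = ["session_id", "condition", "day_index", "metric", "parameter", "value"]
    if df.empty:
        df = pd.DataFrame(columns=expected)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SessionIOError(f"metric table missing columns {missing}")
    df = df[expected].sort_values(
        ["condition", "day_index", "metric", "parameter"], kind="stable"
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_metric_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"parameter": str})


def write_state_model_json(model, path: str | Path) -> None:
    """Serialize a fitted state model (centroids as nested lists)."""
    payload = {
        "k": int(model.k),
        "centroids": np.asarray(model.centroids).tolist(),
        "objective": float(model.objective),
        "n_iter": int(model.n_iter),
        "restart_index": int(model.restart_index),
        "seed": int(model.seed) if model.seed is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def default_atlas(parcel_names: Sequence[str]) -> AtlasDefinition:
    """Atlas inferred from Schaefer-style parcel names."""
    network_of = {p: parse_schaefer_name(p) for p in parcel_names}
    networks = [n for n in SEVEN_NETWORKS if n in set(network_of.values())]
    return AtlasDefinition(list(parcel_names), network_of, networks)
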