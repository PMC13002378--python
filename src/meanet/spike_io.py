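"""Spike-train containers, delimited-text interchange, raster binning and graph export.

Time is expressed in milliseconds end to end.  The interchange format is a tidy
delimited table (CSV or TSV, autodetected) with one spike per row and columns
``unit_id, time_ms, kind[, ttp_ms]``; recording-level metadata travels in ``#``
comment lines at the top of the file.  Rasters use half-open bins
``[t0 + b*bin_ms, t0 + (b+1)*bin_ms)`` so a spike on a bin edge belongs to the
later bin and no spike is ever counted twice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

VALID_KINDS = ("SUA", "MUA")


@dataclass
class Unit:
    """A sorted unit: ascending spike timestamps plus sorting metadata."""

    unit_id: str
    kind: str
    timestamps_ms: np.ndarray
    trough_to_peak_ms: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown unit kind {self.kind!r} (expected SUA or MUA)")
        ts = np.asarray(self.timestamps_ms, dtype=float)
        if ts.size and ts[0] < 0:
            raise ValueError(f"unit {self.unit_id}: negative timestamp {ts[0]}")
        if ts.size > 1 and np.any(np.diff(ts) < 0):
            logger.warning("unit %s: timestamps not sorted; sorting", self.unit_id)
            ts = np.sort(ts)
        if ts.size > 1 and np.any(np.diff(ts) == 0):
            logger.warning("unit %s: duplicate timestamps collapsed", self.unit_id)
            ts = np.unique(ts)
        self.timestamps_ms = ts

    @property
    def n_spikes(self) -> int:
        return int(self.timestamps_ms.size)

    def rate_hz(self, duration_ms: float) -> float:
        return self.n_spikes / (duration_ms / 1000.0)


@dataclass
class SpikeTrainSet:
    """All sorted units of one slice under one experimental condition."""

    slice_id: str
    condition: str
    units: list[Unit]
    duration_ms: float

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit_id in SpikeTrainSet")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def sua_units(self) -> list[Unit]:
        return [u for u in self.units if u.kind == "SUA"]

    def rates_hz(self) -> dict[str, float]:
        return {u.unit_id: u.rate_hz(self.duration_ms) for u in self.units}


@dataclass
class Raster:
    """Binary unit x bin occupancy matrix at a stated bin width."""

    bin_ms: float
    t0_ms: float
    occupancy: np.ndarray  # shape (n_units, n_bins), values in {0, 1}
    unit_ids: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return int(self.occupancy.shape[1])


@dataclass
class LfpTrace:
    """A local-field-potential trace: voltages (mV) at a fixed sample rate."""

    fs: float
    samples: np.ndarray
    channel_id: str = "ch0"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")


# ---------------------------------------------------------------------------
# Delimited spike-table interchange


def write_spike_trains(sts: SpikeTrainSet, path: str | Path, sep: str = ",") -> None:
    """Write one spike per row with ``#``-prefixed metadata header lines."""
    path = Path(path)
    rows = []
    for u in sts.units:
        for t in u.timestamps_ms:
            rows.append((u.unit_id, t, u.kind,
                         "" if u.trough_to_peak_ms is None else u.trough_to_peak_ms))
    df = pd.DataFrame(rows, columns=["unit_id", "time_ms", "kind", "ttp_ms"])
    with open(path, "w") as fh:
        fh.write(f"# slice_id={sts.slice_id}\n")
        fh.write(f"# condition={sts.condition}\n")
        fh.write(f"# duration_ms={sts.duration_ms!r}\n")
        # units with zero spikes still need to exist after a round trip
        for u in sts.units:
            ttp = "" if u.trough_to_peak_ms is None else repr(u.trough_to_peak_ms)
            fh.write(f"# unit={u.unit_id},{u.kind},{ttp}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_spike_trains(path: str | Path, dialect: str | None = None) -> SpikeTrainSet:
    """Read a delimited spike table written by :func:`write_spike_trains`.

    ``dialect`` forces the separator (``"csv"`` or ``"tsv"``); by default it is
    autodetected from the header line.  Malformed records are rejected with the
    offending line number rather than silently coerced.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    declared_units: list[tuple[str, str, float | None]] = []
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n")
                break
            header_lines += 1
            body = line[1:].strip()
            if body.startswith("unit="):
                uid, kind, ttp = body[len("unit="):].split(",")
                declared_units.append((uid, kind, float(ttp) if ttp else None))
            elif "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        else:
            raise ValueError(f"{path}: no table header found")
    if dialect == "tsv":
        sep = "\t"
    elif dialect == "csv":
        sep = ","
    else:
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, comment="#",
                     dtype={"unit_id": str, "kind": str})
    required = {"unit_id", "time_ms", "kind"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: header must declare columns {sorted(required)}")
    # validate with line numbers (1-based, counting metadata and header lines)
    offset = header_lines + 2
    bad_t = np.where(df["time_ms"].to_numpy() < 0)[0]
    if bad_t.size:
        raise ValueError(f"{path}, line {bad_t[0] + offset}: negative time_ms")
    bad_k = np.where(~df["kind"].isin(VALID_KINDS).to_numpy())[0]
    if bad_k.size:
        raise ValueError(
            f"{path}, line {bad_k[0] + offset}: unknown kind "
            f"{df['kind'].iloc[bad_k[0]]!r}")

    units: list[Unit] = []
    seen: dict[str, int] = {}
    for uid, kind, ttp in declared_units:
        seen[uid] = len(units)
        units.append(Unit(uid, kind, np.array([]), ttp))
    for uid, grp in df.groupby("unit_id", sort=True):
        kind = grp["kind"].iloc[0]
        ttp = None
        if "ttp_ms" in grp.columns and grp["ttp_ms"].notna().any():
            ttp = float(grp["ttp_ms"].dropna().iloc[0])
        unit = Unit(str(uid), kind, grp["time_ms"].to_numpy(float), ttp)
        if uid in seen:
            units[seen[uid]] = unit
        else:
            units.append(unit)
    duration = float(meta.get("duration_ms",
                              max((u.timestamps_ms[-1] for u in units if u.n_spikes),
                                  default=1.0)))
    return SpikeTrainSet(meta.get("slice_id", path.stem),
                         meta.get("condition", "unknown"), units, duration)


# ---------------------------------------------------------------------------
# Raster binning


def bin_raster(sts: SpikeTrainSet, bin_ms: float = 1.0, t0_ms: float = 0.0) -> Raster:
    """Discretize spikes into a binary occupancy matrix.

    Entry ``(u, b)`` is 1 iff unit ``u`` has at least one spike in
    ``[t0 + b*bin_ms, t0 + (b+1)*bin_ms)``; multiple spikes in one bin still
    yield 1, so a row sum never exceeds the unit's spike count.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    span = sts.duration_ms - t0_ms
    n_bins = max(int(math.ceil(span / bin_ms)), 1)
    occ = np.zeros((sts.n_units, n_bins), dtype=np.uint8)
    for i, u in enumerate(sts.units):
        if not u.n_spikes:
            continue
        b = np.floor((u.timestamps_ms - t0_ms) / bin_ms).astype(int)
        b = b[(b >= 0) & (b < n_bins)]
        occ[i, b] = 1
    return Raster(bin_ms=bin_ms, t0_ms=t0_ms, occupancy=occ, unit_ids=sts.unit_ids)


# ---------------------------------------------------------------------------
# Matrices and graph export


def write_matrix(M: np.ndarray, path: str | Path, labels: list[str] | None = None,
                 precision: int = 10) -> None:
    M = np.asarray(M, dtype=float)
    idx = labels if labels is not None else [str(i) for i in range(M.shape[0])]
    pd.DataFrame(M, index=idx, columns=idx).to_csv(
        path, float_format=f"%.{precision}g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), [str(c) for c in df.index]


def _check_square_symmetric(M: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"matrix must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol):
        raise ValueError("matrix is not symmetric within tolerance")
    return M


def export_graph(M: np.ndarray, path: str | Path,
                 node_attributes: pd.DataFrame | None = None,
                 labels: list[str] | None = None) -> nx.Graph:
    """Export a symmetric (weighted) matrix as a GEXF graph.

    Each undirected edge is listed once with its weight; node attributes
    (degree, topological class, cell type, ...) are attached from the optional
    ``node_attributes`` table keyed by node label.
    """
    M = _check_square_symmetric(M)
    n = M.shape[0]
    names = labels if labels is not None else [str(i) for i in range(n)]
    G = nx.Graph()
    G.add_nodes_from(names)
    ii, jj = np.nonzero(np.triu(M, k=1))
    for i, j in zip(ii, jj):
        G.add_edge(names[i], names[j], weight=float(M[i, j]))
    if node_attributes is not None:
        for node, row in node_attributes.iterrows():
            if str(node) in G.nodes:
                for k, v in row.items():
                    G.nodes[str(node)][str(k)] = v if not pd.isna(v) else ""
    nx.write_gexf(G, path, version="1.2draft")
    return G
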