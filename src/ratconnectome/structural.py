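"""Structural connectome construction from tractography streamline records.

Each streamline is reduced to its endpoint regions, its length l(s) in mm
and the mean fractional anisotropy (FA) sampled along it.  A pair of
regions (I, J) is connected when at least one streamline joins them;
streamlines have no anatomical direction, so the unordered pair is used
and the matrix is symmetric by construction.  Three edge weightings are
supported:

``binary``
    1 where any streamline joins the pair, else 0.
``fa_weighted``
    arithmetic mean of per-streamline FA over the connecting set.
``fd_weighted``
    fiber density,  FD = (1 / (V_i * V_j)) * sum_{s in S_ij} 1 / l(s),
    where V_i, V_j are the endpoint region volumes (mm^3).  FD rewards
    many short streamlines between small regions and is the
    volume-normalised analogue of a streamline count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome, ConnectomeError
from .regions import NodeSet, RegionTable, structural_nodes

__all__ = [
    "StreamlineRecord",
    "fiber_density",
    "mean_edge_fa",
    "build_structural_connectome",
    "read_streamlines",
    "write_streamlines",
]

STREAMLINE_COLUMNS = ("subject_id", "start_index", "end_index", "length_mm", "mean_fa")


@dataclass(frozen=True)
class StreamlineRecord:
    """One streamline: endpoint node_ids (0-based), length in mm, mean FA."""

    start_region: int
    end_region: int
    length_mm: float
    mean_fa: float

    def __post_init__(self):
        if not self.length_mm > 0:
            raise ValueError(f"streamline length must be > 0, got {self.length_mm}")
        if not 0.0 <= self.mean_fa <= 1.0:
            raise ValueError(f"mean FA must be in [0, 1], got {self.mean_fa}")


def fiber_density(
    streamlines_ij: Iterable[StreamlineRecord], vol_i: float, vol_j: float
) -> float:
    """Fiber density of one connection: volume-normalised sum of 1/length.

    Returns 0.0 for an empty streamline set (no connection).
    """
    if not vol_i > 0 or not vol_j > 0:
        raise ValueError(f"region volumes must be > 0, got {vol_i}, {vol_j}")
    inv_lengths = []
    for s in streamlines_ij:
        if not s.length_mm > 0:
            raise ValueError("streamline length must be > 0")
        inv_lengths.append(1.0 / s.length_mm)
    return float(sum(inv_lengths)) / (vol_i * vol_j)


def mean_edge_fa(streamlines_ij: Sequence[StreamlineRecord]) -> float:
    """Unweighted mean FA over the streamlines connecting one region pair."""
    streamlines_ij = list(streamlines_ij)
    if not streamlines_ij:
        raise ValueError("cannot average FA over an empty streamline set: no edge exists")
    return float(np.mean([s.mean_fa for s in streamlines_ij]))


def build_structural_connectome(
    streamlines: Iterable[StreamlineRecord],
    table: RegionTable,
    kind: str,
    subject_id: str | None = None,
) -> Connectome:
    """Accumulate streamlines into a symmetric structural connectome.

    Self-loops (both endpoints in the same region) are dropped; an
    endpoint outside the structural node set is an error.
    """
    if kind not in ("binary", "fa_weighted", "fd_weighted"):
        raise ConnectomeError(f"unknown structural connectome kind {kind!r}")
    nodes = structural_nodes(table)
    n = len(nodes)
    volumes = table.volumes_by_structural_id()

    inv_len_sum = np.zeros((n, n))
    fa_sum = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for s in streamlines:
        i, j = s.start_region, s.end_region
        if not (0 <= i < n and 0 <= j < n):
            raise ConnectomeError(
                f"streamline endpoint ({i}, {j}) outside node set of size {n}"
            )
        if i == j:
            continue
        a, b = (i, j) if i < j else (j, i)
        count[a, b] += 1
        inv_len_sum[a, b] += 1.0 / s.length_mm
        fa_sum[a, b] += s.mean_fa

    if kind == "binary":
        w = (count > 0).astype(float)
    elif kind == "fa_weighted":
        w = np.divide(fa_sum, count, out=np.zeros_like(fa_sum), where=count > 0)
    else:  # fd_weighted
        vol_prod = np.outer(volumes, volumes)
        w = inv_len_sum / vol_prod
    w = w + w.T  # upper-triangular accumulation -> symmetric
    return Connectome(nodes, w, kind, subject_id)


# ---------------------------------------------------------------------- I/O


def read_streamlines(path: str | Path, nodes: NodeSet) -> list[StreamlineRecord]:
    """Read a streamline TSV, mapping 1-based indexes to 0-based node_ids.

    Endpoints outside the node set are rejected (a parcellation or
    tractography mismatch should surface, not be dropped silently).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STREAMLINE_COLUMNS if c not in df.columns]
    if missing:
        raise ConnectomeError(f"streamline file {path} missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            StreamlineRecord(
                start_region=nodes.node_id_for_source(int(row.start_index)),
                end_region=nodes.node_id_for_source(int(row.end_index)),
                length_mm=float(row.length_mm),
                mean_fa=float(row.mean_fa),
            )
        )
    return records


def write_streamlines(
    path: str | Path,
    streamlines: Iterable[StreamlineRecord],
    nodes: NodeSet,
    subject_id: str,
) -> None:
    rows = [
        {
            "subject_id": subject_id,
            "start_index": nodes[s.start_region].source_index,
            "end_index": nodes[s.end_region].source_index,
            "length_mm": s.length_mm,
            "mean_fa": s.mean_fa,
        }
        for s in streamlines
    ]
    pd.DataFrame(rows, columns=list(STREAMLINE_COLUMNS)).to_csv(path, sep="\t", index=False)
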