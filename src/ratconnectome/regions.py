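"""Region catalogue and network node definitions.

A parcellation of the rat brain defines the nodes of both connectomes.
Each region row carries a 1-based index into the structural network
(all 76 parcels) and, for grey-matter-containing parcels only, a 1-based
index into the functional network (54 parcels; pure white-matter tracts
carry no BOLD signal and are excluded).  Region volumes (mm^3) enter the
fiber-density edge weight, which normalises streamline counts by the
product of endpoint volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RegionTable",
    "NodeSet",
    "RegionTableError",
    "load_region_table",
    "packaged_region_table",
    "structural_nodes",
    "functional_nodes",
]

HEMISPHERES = frozenset({"right", "left", "midline"})
TISSUE_CLASSES = frozenset({"GM", "WM", "mixed"})
REQUIRED_COLUMNS = (
    "region_name",
    "hemisphere",
    "structural_index",
    "functional_index",
    "tissue_class",
    "volume_mm3",
)


class RegionTableError(ValueError):
    """Raised when a region table violates its schema or invariants."""


@dataclass(frozen=True)
class Node:
    """One network node: 0-based matrix position plus provenance."""

    node_id: int
    region_name: str
    hemisphere: str
    source_index: int  # the table's 1-based index

    @property
    def label(self) -> str:
        return f"{self.region_name} ({self.hemisphere})"


class NodeSet:
    """Ordered node list fixing the adjacency-matrix row/column convention.

    Nodes are ordered by ascending 1-based source index and assigned
    contiguous 0-based ``node_id`` values.
    """

    def __init__(self, nodes: Iterable[Node]):
        self.nodes = list(nodes)
        for i, node in enumerate(self.nodes):
            if node.node_id != i:
                raise RegionTableError(
                    f"node_ids must be contiguous from 0; got {node.node_id} at position {i}"
                )
        self._by_source = {n.source_index: n for n in self.nodes}

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __getitem__(self, node_id: int) -> Node:
        return self.nodes[node_id]

    def __eq__(self, other) -> bool:
        return isinstance(other, NodeSet) and self.nodes == other.nodes

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    @property
    def region_names(self) -> set[str]:
        return {n.region_name for n in self.nodes}

    def node_id_for_source(self, source_index: int) -> int:
        """Map a file-facing 1-based index to the 0-based matrix position."""
        try:
            return self._by_source[source_index].node_id
        except KeyError:
            raise KeyError(
                f"source index {source_index} not in node set (valid: "
                f"1..{len(self)})"
            ) from None


class RegionTable:
    """Validated catalogue of brain regions (one row per hemisphere-region)."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise RegionTableError(f"missing required columns: {missing}")

        bad_hemi = df.loc[~df["hemisphere"].isin(HEMISPHERES)]
        if not bad_hemi.empty:
            raise RegionTableError(
                f"invalid hemisphere value(s) at row(s) {list(bad_hemi.index)}: "
                f"{sorted(set(bad_hemi['hemisphere']))}"
            )
        bad_tissue = df.loc[~df["tissue_class"].isin(TISSUE_CLASSES)]
        if not bad_tissue.empty:
            raise RegionTableError(
                f"invalid tissue_class at row(s) {list(bad_tissue.index)}"
            )

        vols = pd.to_numeric(df["volume_mm3"], errors="coerce")
        bad_vol = df.loc[~(vols > 0) | vols.isna()]
        if not bad_vol.empty:
            raise RegionTableError(
                f"non-positive or missing volume at row(s) {list(bad_vol.index)}"
            )

        for col, n_name in (("structural_index", "structural"), ("functional_index", "functional")):
            idx = pd.to_numeric(df[col], errors="coerce").dropna()
            if (idx <= 0).any() or (idx != idx.astype(int)).any():
                raise RegionTableError(f"{n_name} indexes must be positive integers")
            dup = idx[idx.duplicated()]
            if not dup.empty:
                raise RegionTableError(
                    f"duplicate {n_name} index {sorted(set(dup.astype(int)))}"
                )
            if len(idx) and sorted(idx.astype(int)) != list(range(1, len(idx) + 1)):
                raise RegionTableError(
                    f"{n_name} indexes must form a contiguous 1..N range"
                )

        has_f = df["functional_index"].notna()
        has_s = df["structural_index"].notna()
        orphan = df.loc[has_f & ~has_s]
        if not orphan.empty:
            raise RegionTableError(
                f"row(s) {list(orphan.index)} have a functional index but no "
                "structural index"
            )
        wm_func = df.loc[has_f & (df["tissue_class"] == "WM")]
        if not wm_func.empty:
            names = list(wm_func["region_name"])
            raise RegionTableError(
                f"white-matter region(s) cannot be functional nodes: {names}"
            )

    @property
    def n_structural(self) -> int:
        return int(self.frame["structural_index"].notna().sum())

    @property
    def n_functional(self) -> int:
        return int(self.frame["functional_index"].notna().sum())

    def volumes_by_structural_id(self) -> np.ndarray:
        """Region volumes (mm^3) ordered by 0-based structural node_id."""
        df = self.frame.loc[self.frame["structural_index"].notna()]
        df = df.sort_values("structural_index")
        return df["volume_mm3"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def load_region_table(path: str | Path) -> RegionTable:
    """Read and validate a region table from TSV/CSV.

    Empty cells in the index columns mean the region has no node in that
    network.  The file must carry the header
    ``region_name, hemisphere, structural_index, functional_index,
    tissue_class, volume_mm3``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"region_name": str, "hemisphere": str, "tissue_class": str})
    for col in ("structural_index", "functional_index"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return RegionTable(df)


def packaged_region_table() -> RegionTable:
    """The packaged 76-region parcellation fixture.

    Region names, hemispheres and node indexes follow the published atlas
    parcellation; the volumes are synthetic placeholders (the source table
    prints none) and real analyses must supply their own.
    """
    ref = resources.files("ratconnectome.data") / "regions_table1.tsv"
    with resources.as_file(ref) as path:
        return load_region_table(path)


def _nodes_from(table: RegionTable, index_col: str) -> NodeSet:
    df = table.frame.loc[table.frame[index_col].notna()].copy()
    if df.empty:
        raise RegionTableError(f"no rows carry a {index_col}; node set would be empty")
    df = df.sort_values(index_col)
    nodes = [
        Node(
            node_id=i,
            region_name=row.region_name,
            hemisphere=row.hemisphere,
            source_index=int(getattr(row, index_col)),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    return NodeSet(nodes)


def structural_nodes(table: RegionTable) -> NodeSet:
    """Node set of the structural (tractography) network, one per parcel."""
    return _nodes_from(table, "structural_index")


def functional_nodes(table: RegionTable) -> NodeSet:
    """Node set of the functional (BOLD) network: GM/mixed parcels only."""
    return _nodes_from(table, "functional_index")
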