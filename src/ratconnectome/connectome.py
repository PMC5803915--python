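"""Connectome container: a symmetric weighted/binary adjacency over a node set."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import Node, NodeSet

__all__ = ["Connectome", "ConnectomeError", "KINDS"]

KINDS = ("binary", "fa_weighted", "fd_weighted", "func_weighted", "func_binary")
BINARY_KINDS = ("binary", "func_binary")


class ConnectomeError(ValueError):
    pass


@dataclass
class Connectome:
    """Symmetric non-negative adjacency matrix over a declared node set.

    The diagonal is zero (no self-connections) and binary kinds contain
    only 0/1 entries.  ``weights[i, j]`` is the connection weight between
    nodes ``i`` and ``j`` in the node set's 0-based order.
    """

    nodes: NodeSet
    weights: np.ndarray
    kind: str
    subject_id: str | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.kind not in KINDS:
            raise ConnectomeError(f"unknown connectome kind {self.kind!r}; expected one of {KINDS}")
        if self.weights.shape != (n, n):
            raise ConnectomeError(
                f"weight matrix shape {self.weights.shape} does not match node count {n}"
            )
        if not np.allclose(self.weights, self.weights.T):
            raise ConnectomeError("weight matrix must be symmetric")
        if np.any(np.diagonal(self.weights) != 0):
            raise ConnectomeError("diagonal must be zero (self-connections are excluded)")
        if np.any(self.weights < 0):
            raise ConnectomeError("weights must be non-negative")
        if self.kind in BINARY_KINDS and not np.isin(self.weights, (0.0, 1.0)).all():
            raise ConnectomeError(f"{self.kind} connectome must contain only 0/1 entries")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def is_binary(self) -> bool:
        return self.kind in BINARY_KINDS

    def binarized(self) -> "Connectome":
        """0/1 twin: 1 wherever the weight is strictly positive."""
        kind = "func_binary" if self.kind.startswith("func") else "binary"
        return Connectome(self.nodes, (self.weights > 0).astype(float), kind, self.subject_id)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as labelled CSV plus a JSON sidecar."""
        path = Path(path)
        labels = self.nodes.labels
        pd.DataFrame(self.weights, index=labels, columns=labels).to_csv(path)
        sidecar = {
            "kind": self.kind,
            "node_count": self.n_nodes,
            "subject_id": self.subject_id,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, nodes: NodeSet | None = None) -> "Connectome":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        if nodes is None:
            # reconstruct a minimal node set from the stored labels
            nodes = NodeSet(
                Node(
                    node_id=i,
                    region_name=lbl.rsplit(" (", 1)[0],
                    hemisphere=lbl.rsplit(" (", 1)[1].rstrip(")"),
                    source_index=i + 1,
                )
                for i, lbl in enumerate(df.index)
            )
        return cls(nodes, df.to_numpy(dtype=float), sidecar["kind"], sidecar.get("subject_id"))
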