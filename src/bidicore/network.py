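"""Weighted directed network container with delimited-text I/O.

Nodes keep a fixed, serialized order so that outputs are deterministic and
diffs across runs are stable.  Absent edges are weight 0; self-loops are
never stored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclasses.dataclass
class DirectedNetwork:
    """Directed graph G(V, E) with nonnegative edge weights.

    Parameters
    ----------
    nodes : ordered list of labels
    edges : mapping (u, v) -> weight, u != v, weight >= 0
    """

    nodes: list[str]
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node labels")
        node_set = set(self.nodes)
        clean: dict[tuple[str, str], float] = {}
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            w = float(w)
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"edge ({u!r}, {v!r}) has invalid weight {w}")
            if w > 0:
                clean[(u, v)] = w
        self.edges = clean

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, u: str, v: str) -> float:
        return self.edges.get((u, v), 0.0)

    def to_matrix(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        W = np.zeros((self.n_nodes, self.n_nodes))
        for (u, v), w in self.edges.items():
            W[idx[u], idx[v]] = w
        return W

    @classmethod
    def from_matrix(cls, W: np.ndarray, nodes: Iterable[str]) -> "DirectedNetwork":
        nodes = [str(n) for n in nodes]
        W = np.asarray(W, float)
        edges = {
            (nodes[i], nodes[j]): W[i, j]
            for i in range(len(nodes))
            for j in range(len(nodes))
            if i != j and W[i, j] != 0.0
        }
        return cls(nodes=nodes, edges=edges)

    def subgraph(self, members: Iterable[str]) -> "DirectedNetwork":
        keep = set(members)
        return DirectedNetwork(
            nodes=[n for n in self.nodes if n in keep],
            edges={(u, v): w for (u, v), w in self.edges.items() if u in keep and v in keep},
        )

    def symmetrized(self) -> "DirectedNetwork":
        """Bidirectionality-ignored variant with weight matrix (W + W')/2."""
        W = self.to_matrix()
        return DirectedNetwork.from_matrix((W + W.T) / 2.0, self.nodes)

    # -- text serialization (lossless: 17 significant digits) ---------------

    def write_adjacency(self, path: str | Path, sep: str = "\t") -> None:
        df = pd.DataFrame(self.to_matrix(), index=self.nodes, columns=self.nodes)
        df.to_csv(path, sep=sep, float_format="%.17g", index_label="node")

    def write_edge_list(
        self, path: str | Path, p_values: Mapping[tuple[str, str], float] | None = None,
        sep: str = "\t",
    ) -> None:
        rows = []
        for u in self.nodes:
            for v in self.nodes:
                if (u, v) in self.edges:
                    row = {"source": u, "target": v, "weight": self.edges[(u, v)]}
                    if p_values is not None:
                        row["p_value"] = p_values.get((u, v), np.nan)
                    rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str | Path, sep: str = "\t", fmt: str = "auto") -> "DirectedNetwork":
        """Read either a labeled square adjacency matrix or an edge list.

        ``fmt`` is one of "auto", "adjacency", "edgelist"; auto-detection is
        by column layout.
        """
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        cols = [str(c) for c in df.columns]
        if fmt == "auto":
            fmt = "edgelist" if cols[:3] == ["source", "target", "weight"] else "adjacency"
        if fmt == "edgelist":
            nodes = list(dict.fromkeys([*df["source"].astype(str), *df["target"].astype(str)]))
            edges = {
                (str(r.source), str(r.target)): float(r.weight) for r in df.itertuples()
            }
            return cls(nodes=nodes, edges=edges)
        df = df.set_index(cols[0])
        nodes = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != nodes:
            raise ValueError("adjacency matrix row labels do not match column labels")
        return cls.from_matrix(df.to_numpy(float), nodes)
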