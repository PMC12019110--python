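"""Model/Results objects tying the estimation and core-extraction stages together.

``NdteNetwork`` is built from a multi-trial time-series container (or a
long-format DataFrame) and its :meth:`fit` estimates the significance-
filtered, density-thresholded directed network.  ``BidirectionalCores`` is
built from a directed network and its :meth:`fit` runs the exact complex
decomposition.  Both results objects expose tabular views and summaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import cores as _cores
from .estimation import build_directed_network
from .network import DirectedNetwork
from .timeseries import RoiTimeSeriesSet, preprocess_timeseries
from .var import EdgeEstimate, EstimationParams


class NdteNetwork:
    """Directed functional network model over multi-trial time series."""

    def __init__(self, data: RoiTimeSeriesSet, params: EstimationParams | None = None):
        self.data = data
        self.params = params or EstimationParams()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sampling_interval: float,
        trial_column: str = "trial",
        params: EstimationParams | None = None,
    ) -> "NdteNetwork":
        """Build from a long-format frame: one row per frame, node columns plus a trial column."""
        labels = [c for c in df.columns if c != trial_column]
        trials = [g[labels].to_numpy(float) for _, g in df.groupby(trial_column, sort=True)]
        ts = RoiTimeSeriesSet(
            values=np.stack(trials), node_labels=[str(c) for c in labels],
            sampling_interval=sampling_interval,
        )
        return cls(ts, params=params)

    def fit(self, preprocess: bool = False, **band) -> "NdteNetworkResults":
        data = self.data
        if preprocess and not data.preprocessed:
            data = preprocess_timeseries(data, **band)
        net, estimates = build_directed_network(data, self.params, return_estimates=True)
        return NdteNetworkResults(model=self, network=net, estimates=estimates)


@dataclasses.dataclass
class NdteNetworkResults:
    model: NdteNetwork
    network: DirectedNetwork
    estimates: list[EdgeEstimate]

    @property
    def edges(self) -> pd.DataFrame:
        """All ordered-pair estimates: te, norm_factor, ndte, p_value, retained flag."""
        rows = [
            {
                "source": e.source, "target": e.target, "te": e.te,
                "norm_factor": e.norm_factor, "ndte": e.ndte, "p_value": e.p_value,
                "retained": (e.source, e.target) in self.network.edges,
            }
            for e in self.estimates
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        p = self.model.params
        df = self.edges
        lines = [
            "NDTE directed network estimate",
            "==============================",
            f"nodes: {self.network.n_nodes}   ordered pairs: {len(df)}",
            f"lag order: {p.lag_order}   surrogates: {p.n_surrogates} (block {p.block_size})",
            f"alpha: {p.alpha} ({p.correction})   density: {p.density}   seed: {p.seed}",
            f"edges retained: {len(self.network.edges)}",
        ]
        if len(self.network.edges):
            w = np.array(list(self.network.edges.values()))
            lines.append(
                f"edge weight (NDTE): min {w.min():.4f}  median {np.median(w):.4f}  max {w.max():.4f}"
            )
        return "\n".join(lines)


class BidirectionalCores:
    """Exact complex decomposition model over a weighted directed network."""

    def __init__(
        self,
        network: DirectedNetwork,
        mode: str = "bidirectional",
        brute_force_limit: int = _cores.BRUTE_FORCE_LIMIT,
    ):
        if mode not in ("bidirectional", "symmetrized"):
            raise ValueError("mode must be 'bidirectional' or 'symmetrized'")
        self.network = network
        self.mode = mode
        self.brute_force_limit = brute_force_limit

    @classmethod
    def from_dataframe(cls, adjacency: pd.DataFrame, **kw) -> "BidirectionalCores":
        """Build from a labeled square adjacency DataFrame."""
        nodes = [str(c) for c in adjacency.columns]
        return cls(DirectedNetwork.from_matrix(adjacency.to_numpy(float), nodes), **kw)

    def fit(self) -> "BidirectionalCoresResults":
        net = self.network if self.mode == "bidirectional" else _cores.symmetrize(self.network)
        decomp = _cores.list_complexes(net, brute_force_limit=self.brute_force_limit)
        cness = _cores.coreness(net, decomposition=decomp)
        return BidirectionalCoresResults(
            model=self, analyzed_network=net, decomposition=decomp, coreness_map=cness
        )


@dataclasses.dataclass
class BidirectionalCoresResults:
    model: BidirectionalCores
    analyzed_network: DirectedNetwork
    decomposition: _cores.ComplexDecomposition
    coreness_map: _cores.CorenessMap

    @property
    def complexes(self) -> pd.DataFrame:
        rows = []
        ids = {c.members: f"c{i}" for i, c in enumerate(self.decomposition.complexes)}
        for c in self.decomposition.complexes:
            par = self.decomposition.parent[c.members]
            rows.append(
                {
                    "complex_id": ids[c.members],
                    "mc_weight": c.mc_weight,
                    "parent_id": ids[par] if par is not None else "",
                    "members": ",".join(sorted(c.members)),
                }
            )
        return pd.DataFrame(rows, columns=["complex_id", "mc_weight", "parent_id", "members"])

    @property
    def node_table(self) -> pd.DataFrame:
        net = self.analyzed_network
        deg = _cores.weighted_degree(net).values
        sym = net if self.model.mode == "symmetrized" else _cores.symmetrize(net)
        s = _cores.s_core(sym).values
        k = self.coreness_map.values
        kn = _cores.normalize_map(k)
        return pd.DataFrame(
            {
                "node": net.nodes,
                "coreness": [k[v] for v in net.nodes],
                "normalized_coreness": [kn[v] for v in net.nodes],
                "weighted_degree": [deg[v] for v in net.nodes],
                "s_coreness": [s[v] for v in net.nodes],
            }
        )

    def summary(self) -> str:
        lines = [
            f"Bidirectional core decomposition ({self.model.mode})",
            "===============================================",
            f"nodes: {self.analyzed_network.n_nodes}   edges: {len(self.analyzed_network.edges)}",
            f"complexes found: {len(self.decomposition.complexes)}",
        ]
        for _, row in self.complexes.iterrows():
            lines.append(
                f"  {row.complex_id}: w^mc = {row.mc_weight:.6g}  members = {{{row.members}}}"
            )
        top = sorted(self.coreness_map.values.items(), key=lambda kv: -kv[1])[:5]
        lines.append("top coreness: " + ", ".join(f"{v}={k:.6g}" for v, k in top))
        return "\n".join(lines)

    def plot_coreness(self, ax=None):
        """Bar plot of per-node coreness (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        nodes = self.analyzed_network.nodes
        ax.bar(nodes, [self.coreness_map.values[v] for v in nodes])
        ax.set_ylabel("coreness $k_v$")
        ax.set_xlabel("node")
        return ax
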