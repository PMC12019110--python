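"""Synthetic networks and VAR time series with planted bidirectional cores.

Every generator is a pure, seeded function of its spec, so all downstream
modules can be exercised without any external dataset.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .network import DirectedNetwork
from .timeseries import RoiTimeSeriesSet

#: ten toy-network node labels; {E,F,I,J} form the planted bidirectional core
TOY_NODES = list("ABCDEFGHIJ")
TOY_CORE = frozenset("EFIJ")
TOY_ATTACHED = "B"
TOY_FEEDFORWARD = frozenset("ACDGH")


@dataclasses.dataclass
class ToyNetworkSpec:
    """Specification of a deterministic or seeded toy directed network."""

    pattern: str = "fig1d_like"
    n_nodes: int = 10
    w_bidirectional: float = 3.0
    w_attachment: float = 2.0
    w_feedforward: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w_bidirectional, self.w_attachment, self.w_feedforward) < 0:
            raise ValueError("weights must be nonnegative")
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")


def _fig1d_like(spec: ToyNetworkSpec) -> DirectedNetwork:
    """Ten-node toy graph: a reciprocal quartet core, a weakly attached node,
    and feedforward-only periphery.

    Structure (defaults w_bidirectional=3, w_attachment=2, w_feedforward=3):

    * reciprocal clique on {E, F, I, J} at ``w_bidirectional`` — the
      strongest complex, w^mc = 3 * w_bidirectional;
    * B reciprocally attached to each core node at ``w_attachment`` — the
      second complex {B, E, F, I, J}, w^mc = 4 * w_attachment;
    * feedforward ring A->C->D->G->H->A at ``w_feedforward`` plus one-way
      links between periphery and core/B (A and C are heavy receivers; D, G
      and H are heavy senders), so the whole graph is bidirectionally
      connected only weakly (w^mc = w_feedforward) yet, once directions are
      ignored, the periphery is wired strongly enough to join the top core.
    """
    wb, wa, wf = spec.w_bidirectional, spec.w_attachment, spec.w_feedforward
    edges: dict[tuple[str, str], float] = {}
    core = sorted(TOY_CORE)
    for u, v in itertools.permutations(core, 2):
        edges[(u, v)] = wb
    for v in core:
        edges[(TOY_ATTACHED, v)] = wa
        edges[(v, TOY_ATTACHED)] = wa
    ring = ["A", "C", "D", "G", "H"]
    for u, v in zip(ring, ring[1:] + ring[:1]):
        edges[(u, v)] = wf
    receivers, senders = ["A", "C"], ["D", "G", "H"]
    for v in receivers:
        for u in core + [TOY_ATTACHED]:
            edges[(u, v)] = wf
    for u in senders:
        for v in core + [TOY_ATTACHED]:
            edges[(u, v)] = wf
    return DirectedNetwork(nodes=list(TOY_NODES), edges=edges)


def _two_modules(spec: ToyNetworkSpec) -> DirectedNetwork:
    """Two reciprocal triangles joined by one reciprocal bridge (all weights equal)."""
    w = spec.w_bidirectional
    nodes = list("ABCDEF")
    edges: dict[tuple[str, str], float] = {}
    for module in ("ABC", "DEF"):
        for u, v in itertools.permutations(module, 2):
            edges[(u, v)] = w
    edges[("C", "D")] = w
    edges[("D", "C")] = w
    return DirectedNetwork(nodes=nodes, edges=edges)


def _reciprocal_pair(spec: ToyNetworkSpec) -> DirectedNetwork:
    return DirectedNetwork(
        nodes=["a", "b"],
        edges={("a", "b"): spec.w_bidirectional, ("b", "a"): spec.w_feedforward},
    )


def _random_digraph(spec: ToyNetworkSpec) -> DirectedNetwork:
    """Seeded random digraph with weights on the {0, 0.1, ..., 1.0} grid.

    The coarse grid deliberately produces exact weight ties so that
    tie-handling paths are exercised.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    W = rng.integers(0, 11, size=(n, n)) / 10.0
    W *= rng.random((n, n)) < 0.7
    np.fill_diagonal(W, 0.0)
    labels = [f"n{i}" for i in range(n)]
    return DirectedNetwork.from_matrix(W, labels)


_PATTERNS = {
    "fig1d_like": _fig1d_like,
    "two_modules": _two_modules,
    "reciprocal_pair": _reciprocal_pair,
    "random_digraph": _random_digraph,
}


def make_toy_network(spec: ToyNetworkSpec) -> DirectedNetwork:
    """Build the toy network described by ``spec`` (deterministic given spec)."""
    try:
        builder = _PATTERNS[spec.pattern]
    except KeyError:
        raise ValueError(
            f"unknown pattern {spec.pattern!r}; choose from {sorted(_PATTERNS)}"
        ) from None
    return builder(spec)


@dataclasses.dataclass
class VarSimulationSpec:
    """Ground truth for a lag-1 VAR simulation with a planted core.

    ``coupling`` is the node-by-node lag-1 coefficient matrix A (entry
    A[i, j] couples node j's past into node i's present); ``noise_cov`` is
    the innovation covariance.  The process must be stationary (spectral
    radius of A below 1).
    """

    coupling: np.ndarray
    noise_cov: np.ndarray | None = None
    n_trials: int = 20
    n_time: int = 500
    seed: int = 0
    ground_truth_core: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, float)
        n = self.coupling.shape[0]
        if self.coupling.shape != (n, n):
            raise ValueError("coupling must be square")
        if self.noise_cov is None:
            self.noise_cov = np.eye(n)
        self.noise_cov = np.asarray(self.noise_cov, float)
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise covariance must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise covariance must be positive definite")
        radius = float(np.abs(np.linalg.eigvals(self.coupling)).max())
        if radius >= 1.0:
            raise ValueError(f"unstable coupling: spectral radius {radius:.4f} >= 1")


def planted_pair_spec(
    coupling_strength: float = 0.4,
    n_nodes: int = 5,
    n_trials: int = 20,
    n_time: int = 500,
    seed: int = 0,
) -> VarSimulationSpec:
    """Reciprocal pair {n0, n1} plus a feedforward chain over the remaining nodes.

    Emulates the planted-core benchmark: nodes 0 and 1 drive each other at
    ``coupling_strength``; nodes 2..n form a one-way chain at the same
    strength; innovations are unit-variance white noise.
    """
    A = np.zeros((n_nodes, n_nodes))
    A[0, 1] = A[1, 0] = coupling_strength
    for i in range(3, n_nodes):
        A[i, i - 1] = coupling_strength
    return VarSimulationSpec(
        coupling=A, n_trials=n_trials, n_time=n_time, seed=seed,
        ground_truth_core=frozenset({"n0", "n1"}),
    )


def simulate_var_timeseries(spec: VarSimulationSpec, burn_in: int | None = None) -> RoiTimeSeriesSet:
    """Simulate Z_t = A Z_{t-1} + eps_t per trial, discarding a burn-in.

    The burn-in defaults to ten times the lag span (minimum 50 frames) so
    trials start near stationarity.
    """
    n = spec.coupling.shape[0]
    if burn_in is None:
        burn_in = max(50, 10)
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(spec.noise_cov)
    total = spec.n_time + burn_in
    out = np.empty((spec.n_trials, spec.n_time, n))
    for tr in range(spec.n_trials):
        eps = rng.standard_normal((total, n)) @ chol.T
        z = np.zeros((total, n))
        z[0] = eps[0]
        for t in range(1, total):
            z[t] = spec.coupling @ z[t - 1] + eps[t]
        out[tr] = z[burn_in:]
    return RoiTimeSeriesSet(
        values=out, node_labels=[f"n{i}" for i in range(n)],
        sampling_interval=1.0, preprocessed=True,
    )
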