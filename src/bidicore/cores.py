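"""Exact extraction of bidirectionally interacting cores ("complexes").

The strength of bidirectional connections across a bipartition (V_L, V_R)
is min(w(V_L -> V_R), w(V_R -> V_L)); the min-cut weight w^mc of a
(sub)graph is the minimum of that strength over all bipartitions.  A
complex is an induced subgraph whose w^mc is positive and strictly exceeds
the w^mc of every induced strict supergraph; complexes are nested or
disjoint, and a node's coreness is the largest w^mc among complexes that
contain it.

Exactness.  Because min(fwd, bwd) over all bipartitions equals the minimum
plain *directed* cut weight min_S w(S -> V\\S) over proper subsets (each
bipartition contributes both of its directed cuts), the min-cut is found
exactly in polynomial time with 2(n-1) max-flow computations.  Exhaustive
bipartition enumeration is used below ``brute_force_limit`` nodes.  The
hierarchical decomposition is exact: an induced subgraph that straddles a
min-cut of its parent has w^mc no larger than the parent's, so every
complex is a node of the recursive min-cut bisection tree.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .network import DirectedNetwork

logger = logging.getLogger(__name__)

#: default node count below which min-cuts are found by exhaustive enumeration
BRUTE_FORCE_LIMIT = 15

_REL_TOL = 1e-9


def _strictly_greater(a: float, b: float) -> bool:
    """Strict comparison with relative tolerance; ties do not count as greater."""
    return a > b + _REL_TOL * max(1.0, abs(a), abs(b))


@dataclasses.dataclass
class Bipartition:
    """A two-way split (V_L, V_R) of a node set."""

    left: frozenset[str]
    right: frozenset[str]

    def __post_init__(self) -> None:
        self.left = frozenset(self.left)
        self.right = frozenset(self.right)
        if not self.left or not self.right:
            raise ValueError("both sides of a bipartition must be nonempty")
        if self.left & self.right:
            raise ValueError("bipartition sides overlap")


@dataclasses.dataclass
class CutResult:
    """Directed crossing weights and bidirectional strength of one bipartition."""

    partition: Bipartition | None
    forward_weight: float
    backward_weight: float

    @property
    def strength(self) -> float:
        return min(self.forward_weight, self.backward_weight)


@dataclasses.dataclass
class Complex:
    """An inseparable induced subgraph with its min-cut weight."""

    members: frozenset[str]
    mc_weight: float


@dataclasses.dataclass
class ComplexDecomposition:
    """All complexes of a network, sorted by descending min-cut weight.

    ``parent`` maps each complex's member set to the member set of its
    smallest strict superset complex (or None for the outermost one).
    """

    complexes: list[Complex]
    parent: dict[frozenset[str], frozenset[str] | None]

    def strongest(self) -> Complex | None:
        return self.complexes[0] if self.complexes else None


@dataclasses.dataclass
class CorenessMap:
    """Per-node coreness k_v, optionally normalized by the maximum."""

    values: dict[str, float]
    normalized: dict[str, float] | None = None
    condition_label: str = ""


@dataclasses.dataclass
class NodeMetricMap:
    """Per-node comparison metric (weighted degree, s-coreness, ...)."""

    values: dict[str, float]
    metric_kind: str


# ---------------------------------------------------------------------------
# cut strength and exact min-cut
# ---------------------------------------------------------------------------

def bidirectional_strength(net: DirectedNetwork, part: Bipartition) -> CutResult:
    """Sum crossing weights in each direction; strength is their minimum."""
    covered = part.left | part.right
    if covered != set(net.nodes):
        raise ValueError("bipartition must cover exactly the network's nodes")
    fwd = sum(w for (u, v), w in net.edges.items() if u in part.left and v in part.right)
    bwd = sum(w for (u, v), w in net.edges.items() if u in part.right and v in part.left)
    return CutResult(partition=part, forward_weight=fwd, backward_weight=bwd)


def _cut_weights(W: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    return float(W[mask][:, ~mask].sum()), float(W[~mask][:, mask].sum())


def _min_cut_brute(W: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exhaustive enumeration over all 2^(n-1) - 1 bipartitions."""
    n = W.shape[0]
    best = None
    for bits in range(0, 2 ** (n - 1) - 1):
        mask = np.zeros(n, bool)
        mask[0] = True
        for i in range(n - 1):
            if bits >> i & 1:
                mask[i + 1] = True
        fwd, bwd = _cut_weights(W, mask)
        key = min(fwd, bwd)
        if best is None or key < best[0]:
            best = (key, mask.copy(), fwd, bwd)
    _, mask, fwd, bwd = best
    return mask, fwd, bwd


def _min_cut_flow(W: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Global minimum directed cut via max-flows from/to a fixed source."""
    n = W.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i, j in zip(*np.nonzero(W)):
        G.add_edge(int(i), int(j), capacity=float(W[i, j]))
    best: tuple[float, np.ndarray] | None = None
    s = 0
    for t in range(1, n):
        for a, b in ((s, t), (t, s)):
            value, (side_a, _) = nx.minimum_cut(G, a, b)
            if best is None or value < best[0]:
                mask = np.zeros(n, bool)
                mask[list(side_a)] = True
                best = (value, mask)
    _, mask = best
    fwd, bwd = _cut_weights(W, mask)
    return mask, fwd, bwd


def min_cut(
    net: DirectedNetwork,
    node_subset: Iterable[str] | None = None,
    brute_force_limit: int = BRUTE_FORCE_LIMIT,
) -> CutResult:
    """Exact minimum bidirectional cut of the induced subgraph on ``node_subset``.

    A single node has w^mc = 0 by convention (no partitions exist) and is
    returned with an empty partition marker.
    """
    subset = list(net.nodes) if node_subset is None else [n for n in net.nodes if n in set(node_subset)]
    if not subset:
        raise ValueError("node subset must be nonempty")
    if len(subset) == 1:
        return CutResult(partition=None, forward_weight=0.0, backward_weight=0.0)
    sub = net.subgraph(subset)
    W = sub.to_matrix()
    if len(subset) <= brute_force_limit:
        mask, fwd, bwd = _min_cut_brute(W)
    else:
        mask, fwd, bwd = _min_cut_flow(W)
    labels = np.array(sub.nodes)
    part = Bipartition(left=frozenset(labels[mask]), right=frozenset(labels[~mask]))
    return CutResult(partition=part, forward_weight=fwd, backward_weight=bwd)


# ---------------------------------------------------------------------------
# hierarchical complex extraction and coreness
# ---------------------------------------------------------------------------

def list_complexes(
    net: DirectedNetwork, brute_force_limit: int = BRUTE_FORCE_LIMIT
) -> ComplexDecomposition:
    """Exactly enumerate all complexes by recursive min-cut bisection.

    The recursion tree's node sets are the only candidates for complexes; a
    candidate qualifies iff its w^mc is positive and strictly greater (with
    relative tolerance) than the w^mc of every ancestor.
    """
    if net.n_nodes == 0:
        raise ValueError("network must be nonempty")
    found: list[Complex] = []

    def recurse(subset: tuple[str, ...], ancestor_max: float) -> None:
        cut = min_cut(net, subset, brute_force_limit=brute_force_limit)
        wmc = cut.strength
        if _strictly_greater(wmc, 0.0) and _strictly_greater(wmc, ancestor_max):
            found.append(Complex(members=frozenset(subset), mc_weight=wmc))
        if cut.partition is None:
            return
        bound = max(ancestor_max, wmc)
        order = {n: i for i, n in enumerate(net.nodes)}
        for side in (cut.partition.left, cut.partition.right):
            if len(side) >= 1:
                recurse(tuple(sorted(side, key=order.__getitem__)), bound)

    recurse(tuple(net.nodes), 0.0)
    found.sort(key=lambda c: (-c.mc_weight, -len(c.members), sorted(c.members)))
    parent: dict[frozenset[str], frozenset[str] | None] = {}
    for c in found:
        supersets = [d for d in found if d.members > c.members]
        parent[c.members] = min(supersets, key=lambda d: len(d.members)).members if supersets else None
    return ComplexDecomposition(complexes=found, parent=parent)


def coreness(
    net: DirectedNetwork,
    decomposition: ComplexDecomposition | None = None,
    brute_force_limit: int = BRUTE_FORCE_LIMIT,
    condition_label: str = "",
) -> CorenessMap:
    """Coreness k_v: the largest w^mc among complexes containing v (0 if none)."""
    if decomposition is None:
        decomposition = list_complexes(net, brute_force_limit=brute_force_limit)
    values = {v: 0.0 for v in net.nodes}
    for c in decomposition.complexes:
        for v in c.members:
            values[v] = max(values[v], c.mc_weight)
    return CorenessMap(values=values, condition_label=condition_label)


def normalize_map(values: Mapping[str, float]) -> dict[str, float]:
    """Divide by the maximum value; an all-zero map stays zero (logged)."""
    top = max(values.values(), default=0.0)
    if top <= 0.0:
        logger.warning("all-zero metric map; normalization left as zeros")
        return dict(values)
    return {v: k / top for v, k in values.items()}


def normalize_average_coreness(
    maps: Sequence[CorenessMap], weights: Sequence[float] | None = None,
    condition_label: str = "average",
) -> CorenessMap:
    """Per-map max-normalization followed by a (weighted) per-node mean.

    Weights support conventions such as pre-averaging two resting-state
    sessions into a single condition before averaging across conditions.
    """
    if not maps:
        raise ValueError("need at least one coreness map")
    nodes = set(maps[0].values)
    for m in maps[1:]:
        if set(m.values) != nodes:
            raise ValueError("coreness maps must share the same node set")
    if weights is None:
        weights = [1.0] * len(maps)
    if len(weights) != len(maps):
        raise ValueError("weights must match the number of maps")
    total = float(sum(weights))
    normed = [normalize_map(m.values) for m in maps]
    avg = {
        v: sum(w * nm[v] for w, nm in zip(weights, normed)) / total for v in nodes
    }
    return CorenessMap(values=avg, normalized=normalize_map(avg), condition_label=condition_label)


def symmetrize(net: DirectedNetwork) -> DirectedNetwork:
    """Bidirectionality-ignored network with weight matrix (W + W')/2.

    Running :func:`list_complexes` on the result extracts cores regardless
    of edge direction.
    """
    return net.symmetrized()


# ---------------------------------------------------------------------------
# comparison metrics: weighted degree, s-core, functional rich club
# ---------------------------------------------------------------------------

def weighted_degree(net: DirectedNetwork) -> NodeMetricMap:
    """deg(v): sum of weights of all edges touching v, directions ignored."""
    values = {v: 0.0 for v in net.nodes}
    for (u, v), w in net.edges.items():
        values[u] += w
        values[v] += w
    return NodeMetricMap(values=values, metric_kind="weighted_degree")


def s_core(net_undirected: DirectedNetwork) -> NodeMetricMap:
    """Weighted-core decomposition of a symmetric network.

    Nodes are iteratively peeled at increasing strength levels; a node's
    s-coreness is the largest level at which it still belongs to the
    surviving subgraph.  Levels are the distinct node strengths encountered
    during peeling (parameter-free).
    """
    W = net_undirected.to_matrix()
    if not np.allclose(W, W.T, atol=1e-9):
        raise ValueError("s-core requires symmetric weights; symmetrize the network first")
    nodes = list(net_undirected.nodes)
    alive = np.ones(len(nodes), bool)
    level = 0.0
    out: dict[str, float] = {}
    while alive.any():
        strengths = (W * alive[None, :]).sum(axis=1)
        current = strengths[alive]
        m = current.min()
        level = max(level, float(m))
        peel = alive & (strengths <= m + 1e-12)
        for i in np.nonzero(peel)[0]:
            out[nodes[i]] = level
        alive &= ~peel
    return NodeMetricMap(values=out, metric_kind="s_coreness")


def fric_score(net: DirectedNetwork, subset: Iterable[str]) -> float:
    """Functional rich-club score of a node subset.

    G_FRIC(k) = sum_{i,j in k} W_ij + sum_{i in k, j} W_ij - sum_{i, j in k} W_ij,
    i.e. within-subset weight plus total out-strength minus total in-strength
    of the subset.  For a symmetric network the last two terms cancel.
    """
    members = [v for v in net.nodes if v in set(subset)]
    if not members:
        raise ValueError("subset must be nonempty")
    W = net.to_matrix()
    idx = [net.nodes.index(v) for v in members]
    within = W[np.ix_(idx, idx)].sum()
    out_strength = W[idx, :].sum()
    in_strength = W[:, idx].sum()
    return float(within + out_strength - in_strength)


def fric_top_core(net: DirectedNetwork, top_fraction: float = 0.05) -> frozenset[str]:
    """Demo identification of the functional rich club by exhaustive enumeration.

    Returns the largest subnetwork among those whose G_FRIC score falls
    within the top ``top_fraction`` of subnetworks of the same size.
    Intended for small graphs only (all subsets are enumerated).
    """
    n = net.n_nodes
    if n > 16:
        raise ValueError("exhaustive rich-club demo limited to 16 nodes")
    qualifying: list[tuple[int, float, tuple[str, ...]]] = []
    for size in range(1, n + 1):
        scored = [
            (fric_score(net, c), c) for c in itertools.combinations(net.nodes, size)
        ]
        scores = np.array([s for s, _ in scored])
        cutoff = np.quantile(scores, 1.0 - top_fraction)
        for s, c in scored:
            if s >= cutoff:
                qualifying.append((size, s, c))
    size, score, members = max(qualifying, key=lambda t: (t[0], t[1], tuple(reversed(t[2]))))
    return frozenset(members)
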