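"""Shared fixtures and independent brute-force oracles.

The oracles enumerate every bipartition / every induced subgraph directly
from the definitions, independent of the package's recursive search path.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from bidicore import DirectedNetwork, ToyNetworkSpec, make_toy_network
from bidicore.cores import _strictly_greater


def brute_min_cut_weight(W: np.ndarray) -> float:
    """Minimum bidirectional cut strength by enumerating all bipartitions."""
    n = W.shape[0]
    if n <= 1:
        return 0.0
    best = np.inf
    for bits in range(0, 2 ** (n - 1) - 1):
        mask = np.zeros(n, bool)
        mask[0] = True
        for i in range(n - 1):
            if bits >> i & 1:
                mask[i + 1] = True
        best = min(best, min(W[mask][:, ~mask].sum(), W[~mask][:, mask].sum()))
    return float(best)


def brute_all_subset_wmc(net: DirectedNetwork) -> dict[frozenset, float]:
    """w^mc of every nonempty induced subgraph, by exhaustive enumeration."""
    W = net.to_matrix()
    n = len(net.nodes)
    out = {}
    for r in range(1, n + 1):
        for S in itertools.combinations(range(n), r):
            sub = W[np.ix_(S, S)]
            out[frozenset(net.nodes[i] for i in S)] = brute_min_cut_weight(sub)
    return out


def brute_complexes(net: DirectedNetwork) -> list[tuple[frozenset, float]]:
    """Complexes straight from the definition: positive w^mc strictly above
    the w^mc of every strict superset."""
    wmc = brute_all_subset_wmc(net)
    out = []
    for S, w in wmc.items():
        if not _strictly_greater(w, 0.0):
            continue
        if all(_strictly_greater(w, wT) for T, wT in wmc.items() if T > S):
            out.append((S, w))
    return sorted(out, key=lambda t: (-t[1], sorted(t[0])))


def brute_coreness(net: DirectedNetwork) -> dict[str, float]:
    """Coreness as the max w^mc over *all* subsets containing each node."""
    wmc = brute_all_subset_wmc(net)
    return {
        v: max((w for S, w in wmc.items() if v in S), default=0.0)
        for v in net.nodes
    }


@pytest.fixture(scope="session")
def fig1d_net() -> DirectedNetwork:
    return make_toy_network(ToyNetworkSpec(pattern="fig1d_like"))


@pytest.fixture(scope="session")
def two_modules_net() -> DirectedNetwork:
    return make_toy_network(ToyNetworkSpec(pattern="two_modules", w_bidirectional=1.0))


def random_net(seed: int, n: int) -> DirectedNetwork:
    return make_toy_network(
        ToyNetworkSpec(pattern="random_digraph", n_nodes=n, seed=seed)
    )
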