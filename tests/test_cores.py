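"""Exact complex extraction, coreness, and the comparison metrics.

The deep checks compare the package's recursive min-cut path against
independent brute-force enumeration of every bipartition / induced
subgraph (see conftest oracles).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bidicore import (
    Bipartition,
    CorenessMap,
    DirectedNetwork,
    bidirectional_strength,
    coreness,
    fric_score,
    fric_top_core,
    list_complexes,
    min_cut,
    normalize_average_coreness,
    s_core,
    symmetrize,
    weighted_degree,
)
from conftest import (
    brute_all_subset_wmc,
    brute_complexes,
    brute_coreness,
    brute_min_cut_weight,
    random_net,
)


def simple_net(edges, nodes=None):
    if nodes is None:
        nodes = sorted({n for e in edges for n in e})
    return DirectedNetwork(nodes=list(nodes), edges=dict(edges))


# ---------------------------------------------------------------------- cuts

def test_unidirectional_cut_has_zero_strength():
    net = simple_net({("a", "c"): 1.0, ("a", "d"): 1.0, ("b", "d"): 1.0})
    cut = bidirectional_strength(net, Bipartition(left={"a", "b"}, right={"c", "d"}))
    assert cut.forward_weight == 3.0 and cut.backward_weight == 0.0
    assert cut.strength == 0.0


def test_asymmetric_cut_strength_is_smaller_direction():
    net = simple_net(
        {("a", "c"): 2.0, ("b", "c"): 1.0, ("c", "a"): 1.0},
        nodes=["a", "b", "c"],
    )
    cut = bidirectional_strength(net, Bipartition(left={"a", "b"}, right={"c"}))
    assert (cut.forward_weight, cut.backward_weight, cut.strength) == (3.0, 1.0, 1.0)


def test_balanced_cut_strength():
    net = simple_net(
        {("a", "c"): 2.0, ("b", "d"): 1.0, ("c", "a"): 1.5, ("d", "b"): 1.5}
    )
    cut = bidirectional_strength(net, Bipartition(left={"a", "b"}, right={"c", "d"}))
    assert cut.strength == 3.0 == cut.forward_weight == cut.backward_weight


def test_strength_symmetric_under_side_swap():
    for seed in range(10):
        net = random_net(seed, 6)
        rng = np.random.default_rng(seed)
        k = rng.integers(1, 5)
        left = set(rng.choice(net.nodes, size=k, replace=False))
        right = set(net.nodes) - left
        a = bidirectional_strength(net, Bipartition(left=left, right=right)).strength
        b = bidirectional_strength(net, Bipartition(left=right, right=left)).strength
        assert a == b


def test_partition_must_cover_nodes():
    net = simple_net({("a", "b"): 1.0}, nodes=["a", "b", "c"])
    with pytest.raises(ValueError):
        bidirectional_strength(net, Bipartition(left={"a"}, right={"b"}))


def test_single_node_min_cut_is_zero():
    net = simple_net({("a", "b"): 1.0})
    cut = min_cut(net, ["a"])
    assert cut.strength == 0.0 and cut.partition is None


def test_two_node_min_cut_is_weaker_reciprocal_weight():
    net = simple_net({("a", "b"): 2.0, ("b", "a"): 5.0})
    assert min_cut(net).strength == 2.0


def test_min_cut_lower_bounds_every_bipartition():
    for seed in range(5):
        net = random_net(seed, 7)
        wmc = min_cut(net).strength
        rng = np.random.default_rng(seed)
        for _ in range(10):
            k = rng.integers(1, 6)
            left = set(rng.choice(net.nodes, size=k, replace=False))
            part = Bipartition(left=left, right=set(net.nodes) - left)
            assert bidirectional_strength(net, part).strength >= wmc - 1e-12


def test_flow_min_cut_equals_brute_force():
    """The polynomial max-flow path agrees with bipartition enumeration."""
    for seed in range(100):
        net = random_net(seed, 4 + seed % 5)
        fast = min_cut(net, brute_force_limit=1).strength  # force the flow path
        brute = brute_min_cut_weight(net.to_matrix())
        assert fast == pytest.approx(brute, abs=1e-9)


# ----------------------------------------------------------------- complexes

def test_edgeless_graph_has_no_complexes():
    net = DirectedNetwork(nodes=["a", "b", "c"], edges={})
    assert list_complexes(net).complexes == []


def test_fig1d_complex_hierarchy(fig1d_net):
    decomp = list_complexes(fig1d_net)
    members = [set(c.members) for c in decomp.complexes]
    assert members[0] == set("EFIJ")
    assert members[1] == set("BEFIJ")
    feedforward = set("ACDGH")
    for m in members[:-1]:
        assert not (m & feedforward)
    # feedforward nodes appear only at the whole-graph level, if at all
    assert members[-1] == set(fig1d_net.nodes)


def test_two_modules_are_both_strongest_complexes(two_modules_net):
    decomp = list_complexes(two_modules_net)
    top_w = decomp.complexes[0].mc_weight
    strongest = {frozenset(c.members) for c in decomp.complexes
                 if c.mc_weight == pytest.approx(top_w)}
    assert strongest == {frozenset("ABC"), frozenset("DEF")}


def test_complexes_match_brute_force_on_random_digraphs():
    for seed in range(40):
        net = random_net(seed, 4 + seed % 5)
        fast = sorted(
            ((c.members, c.mc_weight) for c in list_complexes(net).complexes),
            key=lambda t: (-t[1], sorted(t[0])),
        )
        oracle = brute_complexes(net)
        assert [m for m, _ in fast] == [m for m, _ in oracle]
        np.testing.assert_allclose(
            [w for _, w in fast], [w for _, w in oracle], atol=1e-9
        )


def test_complexes_nested_or_disjoint_with_decreasing_weight():
    for seed in range(30):
        decomp = list_complexes(random_net(seed + 100, 7))
        cs = decomp.complexes
        for i, a in enumerate(cs):
            for b in cs[i + 1 :]:
                inter = a.members & b.members
                assert inter in (frozenset(), a.members, b.members)
                if a.members > b.members:
                    assert a.mc_weight < b.mc_weight
                if b.members > a.members:
                    assert b.mc_weight < a.mc_weight


def test_parent_links_point_to_smallest_strict_superset(fig1d_net):
    decomp = list_complexes(fig1d_net)
    by_members = {c.members: c for c in decomp.complexes}
    for c in decomp.complexes:
        parent = decomp.parent[c.members]
        if parent is None:
            assert all(not (o.members > c.members) for o in decomp.complexes)
        else:
            assert parent > c.members and parent in by_members


@given(seed=st.integers(0, 500), scale=st.floats(0.1, 10.0))
@settings(max_examples=25, derandomize=True, deadline=None)
def test_scale_covariance(seed, scale):
    """Scaling all weights by c scales every w^mc and coreness by c."""
    net = random_net(seed, 6)
    scaled = DirectedNetwork(
        nodes=net.nodes, edges={e: w * scale for e, w in net.edges.items()}
    )
    d1, d2 = list_complexes(net), list_complexes(scaled)
    assert [c.members for c in d1.complexes] == [c.members for c in d2.complexes]
    np.testing.assert_allclose(
        [c.mc_weight * scale for c in d1.complexes],
        [c.mc_weight for c in d2.complexes], rtol=1e-9,
    )
    k1, k2 = coreness(net, d1).values, coreness(scaled, d2).values
    np.testing.assert_allclose(
        [k1[v] * scale for v in net.nodes], [k2[v] for v in net.nodes], rtol=1e-9
    )


def test_relabeling_permutes_outputs():
    net = random_net(17, 6)
    mapping = {n: f"x_{n}" for n in net.nodes}
    relabeled = DirectedNetwork(
        nodes=[mapping[n] for n in net.nodes],
        edges={(mapping[u], mapping[v]): w for (u, v), w in net.edges.items()},
    )
    d1 = list_complexes(net)
    d2 = list_complexes(relabeled)
    sets1 = {frozenset(mapping[v] for v in c.members): c.mc_weight for c in d1.complexes}
    sets2 = {c.members: c.mc_weight for c in d2.complexes}
    assert sets1.keys() == sets2.keys()
    for k in sets1:
        assert sets1[k] == pytest.approx(sets2[k], rel=1e-12)


# ------------------------------------------------------------------ coreness

def test_edgeless_coreness_zero():
    net = DirectedNetwork(nodes=["a", "b"], edges={})
    assert coreness(net).values == {"a": 0.0, "b": 0.0}


def test_fig1d_coreness_ordering(fig1d_net):
    k = coreness(fig1d_net).values
    core_val = {k[v] for v in "EFIJ"}
    assert len(core_val) == 1
    assert k["E"] > k["B"] > k["A"]
    assert all(k[v] == k["A"] for v in "ACDGH")


def test_coreness_via_complexes_equals_all_subsets_definition():
    """Max over complexes equals max over all containing subnetworks."""
    for seed in range(10):
        net = random_net(seed + 300, 7)
        fast = coreness(net).values
        oracle = brute_coreness(net)
        for v in net.nodes:
            assert fast[v] == pytest.approx(oracle[v], abs=1e-9)


def test_normalize_average_coreness():
    m1 = CorenessMap(values={"a": 2.0, "b": 0.0})
    m2 = CorenessMap(values={"a": 0.0, "b": 3.0})
    avg = normalize_average_coreness([m1, m2])
    assert avg.values == {"a": 0.5, "b": 0.5}
    single = normalize_average_coreness([CorenessMap(values={"a": 4.0, "b": 1.0})])
    assert single.values == {"a": 1.0, "b": 0.25}
    rep = normalize_average_coreness([m1] * 8)
    assert rep.values == {"a": 1.0, "b": 0.0}


def test_normalize_average_supports_condition_weights():
    """Half-weighted duplicate sessions reproduce pre-averaging them."""
    rest1 = CorenessMap(values={"a": 1.0, "b": 0.5})
    rest2 = CorenessMap(values={"a": 0.5, "b": 1.0})
    task = CorenessMap(values={"a": 1.0, "b": 0.0})
    out = normalize_average_coreness([rest1, rest2, task], weights=[0.5, 0.5, 1.0])
    assert out.values["a"] == pytest.approx((0.5 * 1.0 + 0.5 * 0.5 + 1.0) / 2)
    assert out.values["b"] == pytest.approx((0.5 * 0.5 + 0.5 * 1.0) / 2)


def test_mismatched_node_sets_rejected():
    with pytest.raises(ValueError):
        normalize_average_coreness(
            [CorenessMap(values={"a": 1.0}), CorenessMap(values={"b": 1.0})]
        )


# ------------------------------------------------- symmetrize / degree / s-core

def test_symmetrize_fixed_point_and_halving():
    sym = simple_net({("a", "b"): 2.0, ("b", "a"): 2.0})
    assert symmetrize(sym).edges == sym.edges
    single = simple_net({("u", "v"): 4.0})
    out = symmetrize(single)
    assert out.edges == {("u", "v"): 2.0, ("v", "u"): 2.0}


def test_symmetrization_admits_feedforward_nodes(fig1d_net):
    """Ignoring direction pulls feedforward-only nodes into the top core."""
    top_bidir = list_complexes(fig1d_net).complexes[0].members
    top_sym = list_complexes(symmetrize(fig1d_net)).complexes[0].members
    assert not (top_bidir & set("ACDGH"))
    assert top_sym & set("ACDGH")


def test_weighted_degree_hand_example():
    net = simple_net({("a", "b"): 2.0, ("b", "a"): 3.0, ("b", "c"): 1.0})
    deg = weighted_degree(net).values
    assert deg == {"a": 5.0, "b": 6.0, "c": 1.0}
    assert sum(deg.values()) == pytest.approx(2 * sum(net.edges.values()))


def test_weighted_degree_isolated_node_zero():
    net = DirectedNetwork(nodes=["a", "b", "z"], edges={("a", "b"): 1.0})
    assert weighted_degree(net).values["z"] == 0.0


def test_s_core_uniform_clique_single_level():
    n = 5
    net = DirectedNetwork.from_matrix(
        np.ones((n, n)) - np.eye(n), [f"n{i}" for i in range(n)]
    )
    values = set(s_core(net).values.values())
    assert len(values) == 1


def test_s_core_star_leaves_never_outlast_hub():
    edges = {}
    for i in range(4):
        edges[("hub", f"leaf{i}")] = 1.0
        edges[(f"leaf{i}", "hub")] = 1.0
    net = DirectedNetwork(nodes=["hub"] + [f"leaf{i}" for i in range(4)], edges=edges)
    s = s_core(net).values
    assert all(s[f"leaf{i}"] <= s["hub"] for i in range(4))


def naive_s_core(net):
    """Oracle: recompute strengths from scratch at every candidate level."""
    W = net.to_matrix()
    nodes = list(net.nodes)
    result = {v: 0.0 for v in nodes}
    # candidate levels: the minima encountered while peeling
    candidates = set()
    alive = np.ones(len(nodes), bool)
    while alive.any():
        strengths = (W * alive[None, :]).sum(axis=1)
        m = strengths[alive].min()
        candidates.add(float(m))
        alive &= ~(strengths <= m + 1e-12)
    for s in sorted(candidates):
        alive = np.ones(len(nodes), bool)
        while True:
            strengths = (W * alive[None, :]).sum(axis=1)
            drop = alive & (strengths < s - 1e-12)
            if not drop.any():
                break
            alive &= ~drop
        for i in np.nonzero(alive)[0]:
            result[nodes[i]] = max(result[nodes[i]], s)
    return result


def test_s_core_matches_naive_recomputation_oracle():
    for seed in range(20):
        net = symmetrize(random_net(seed + 50, 8))
        fast = s_core(net).values
        oracle = naive_s_core(net)
        for v in net.nodes:
            assert fast[v] == pytest.approx(oracle[v], abs=1e-9)


def test_s_core_rejects_asymmetric_weights():
    with pytest.raises(ValueError):
        s_core(simple_net({("a", "b"): 1.0}))


# ----------------------------------------------------------------- rich club

def test_fric_reduces_to_within_weight_on_symmetric_nets():
    net = symmetrize(random_net(9, 6))
    W = net.to_matrix()
    rng = np.random.default_rng(0)
    for _ in range(5):
        k = rng.integers(1, 6)
        subset = list(rng.choice(net.nodes, size=k, replace=False))
        idx = [net.nodes.index(v) for v in subset]
        assert fric_score(net, subset) == pytest.approx(W[np.ix_(idx, idx)].sum())


def test_fric_single_node_out_minus_in():
    net = simple_net({("u", "v"): 3.0, ("w", "u"): 1.0})
    assert fric_score(net, ["u"]) == pytest.approx(2.0)


def test_fric_top_core_includes_feedforward_nodes(fig1d_net):
    """The rich-club contrast method absorbs unidirectionally wired nodes."""
    top = fric_top_core(fig1d_net)
    assert top & set("ACDGH")
    assert top != frozenset("EFIJ")
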