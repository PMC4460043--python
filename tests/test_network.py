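"""Median-joining construction, parsimony pruning and cycle resolution,
checked against exhaustive small-instance oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mtroute.errors import ContractViolation, RootingError
from mtroute.network import (
    PhyloNetwork,
    build_mj_network,
    contract_unary_medians,
    mp_prune,
    resolve_reticulations,
)
from mtroute.seqio import MtHaplotype, Variant
from oracles import (
    assert_is_perfect_phylogeny,
    edges_as_vector_pairs,
    hap,
    node_vectors,
    random_perfect_phylogeny,
    tvar,
)


# ---------------------------------------------------------------------------
# construction basics


def test_single_haplotype_single_node():
    net = build_mj_network([hap("a", [100]), hap("b", [100])])
    assert net.n_nodes == 1
    assert net.graph.number_of_edges() == 0
    assert net.sample_size() == 2


def test_two_haplotypes_one_edge_with_all_separating_variants():
    net = build_mj_network([hap("a", []), hap("b", [100, 200, 300])])
    assert net.n_nodes == 2
    (label,) = [d["label"] for _, _, d in net.graph.edges(data=True)]
    assert label == {tvar(100), tvar(200), tvar(300)}


def test_inconsistent_coverage_rejected():
    a = MtHaplotype("a", (), region=((1, 16569),))
    b = MtHaplotype("b", (), region=((57, 372),))
    with pytest.raises(ContractViolation):
        build_mj_network([a, b])
    with pytest.raises(ContractViolation):
        build_mj_network([])


def test_star_data_gains_central_median():
    net = build_mj_network([hap("a", [1]), hap("b", [2]), hap("c", [3])])
    vecs = set(node_vectors(net).values())
    assert frozenset() in vecs  # inferred ancestral median
    assert net.n_nodes == 4
    assert net.reticulation_count == 0
    medians = [n for n, d in net.graph.nodes(data=True) if not d["observed"]]
    assert len(medians) == 1
    assert net.graph.nodes[medians[0]]["multiplicity"] == 0


def _conflict_haps():
    a, b = 100, 200
    return [hap("h0", []), hap("h1", [a]), hap("h2", [b]), hap("h3", [a, b])]


def test_canonical_conflict_square_is_a_four_cycle():
    net = build_mj_network(_conflict_haps(), epsilon=0)
    assert net.n_nodes == 4
    assert net.graph.number_of_edges() == 4
    assert net.reticulation_count == 1
    # the two-mutation diagonals are absent
    vec = node_vectors(net)
    for u, v in net.graph.edges:
        assert len(vec[u] ^ vec[v]) == 1


def test_conflict_square_prune_matches_union_of_minimum_spanning_trees():
    """Exhaustive oracle: union of all minimum-length spanning trees of the
    observed haplotypes equals the pruned network (cycle kept, diagonals out)."""
    haps = _conflict_haps()
    vectors = [h.variant_set() for h in haps]
    complete = nx.Graph()
    for i, j in itertools.combinations(range(4), 2):
        complete.add_edge(i, j, weight=len(vectors[i] ^ vectors[j]))
    best = None
    union = set()
    for tree_edges in itertools.combinations(complete.edges, 3):
        t = nx.Graph(tree_edges)
        if t.number_of_nodes() != 4 or not nx.is_connected(t):
            continue
        w = sum(complete.edges[e]["weight"] for e in tree_edges)
        if best is None or w < best:
            best, union = w, set(tree_edges)
        elif w == best:
            union |= set(tree_edges)
    oracle_edges = {frozenset((vectors[u], vectors[v])) for u, v in union}
    pruned = mp_prune(build_mj_network(haps, epsilon=0))
    assert edges_as_vector_pairs(pruned) == oracle_edges
    assert pruned.reticulation_count == 1


# ---------------------------------------------------------------------------
# conflict-free recovery: the network must be the unique perfect phylogeny


def test_conflict_free_instances_recover_perfect_phylogeny():
    rng = np.random.default_rng(11)
    for _ in range(60):
        haps = random_perfect_phylogeny(rng)
        net = mp_prune(build_mj_network(haps, epsilon=0))
        assert_is_perfect_phylogeny(contract_unary_medians(net), haps)


# ---------------------------------------------------------------------------
# parsimony pruning


def test_prune_leaves_tree_input_unchanged():
    haps = [hap("a", []), hap("b", [100]), hap("c", [100, 200])]
    net = build_mj_network(haps)
    pruned = mp_prune(net)
    assert edges_as_vector_pairs(pruned) == edges_as_vector_pairs(net)


def test_prune_removes_degree_one_median():
    g = nx.Graph()
    g.add_node(0, variants=frozenset(), samples=("a",), multiplicity=1, observed=True, outgroup=False)
    g.add_node(1, variants=frozenset({tvar(100)}), samples=("b",), multiplicity=1, observed=True, outgroup=False)
    g.add_node(2, variants=frozenset({tvar(200)}), samples=(), multiplicity=0, observed=False, outgroup=False)
    g.add_edge(0, 1, label=frozenset({tvar(100)}), weight=1)
    g.add_edge(0, 2, label=frozenset({tvar(200)}), weight=1)
    pruned = mp_prune(PhyloNetwork(graph=g))
    assert set(pruned.graph.nodes) == {0, 1}


def test_prune_never_increases_length():
    rng = np.random.default_rng(23)
    for _ in range(30):
        haps = _random_conflicted_haps(rng)
        net = build_mj_network(haps)
        assert mp_prune(net).total_length <= net.total_length


def _random_conflicted_haps(rng, n_haps=6, n_sites=6):
    seen = {}
    for k in range(n_haps):
        row = frozenset(100 + s for s in range(n_sites) if rng.random() < 0.4)
        seen.setdefault(row, f"h{k}")
    return [hap(sid, sorted(row)) for row, sid in seen.items()]


# ---------------------------------------------------------------------------
# reticulation resolution


def test_resolve_acyclic_input_is_identity_up_to_rooting():
    haps = [hap("a", []), hap("b", [100]), hap("c", [100, 200])]
    net = mp_prune(build_mj_network(haps))
    tree = resolve_reticulations(net, outgroup=())
    assert tree.sample_size == 3
    assert sum(tree.edge_length.values()) == net.total_length
    assert tree.variants[tree.root] == frozenset()


def test_resolve_cuts_the_transversion_edge():
    """Policy definition: in a cycle with exactly one transversion-bearing
    link, that link is the one removed."""
    g = nx.Graph()
    labels = [
        frozenset({tvar(100)}),
        frozenset({tvar(200)}),
        frozenset({tvar(300)}),
        frozenset({Variant(400, "transversion", "A")}),
    ]
    vecs = [frozenset(), frozenset({tvar(100)}), frozenset({tvar(100), tvar(200)}), frozenset({tvar(300)})]
    for i, vec in enumerate(vecs):
        g.add_node(i, variants=vec, samples=(f"s{i}",), multiplicity=1, observed=True, outgroup=i == 0)
    cycle = [(0, 1), (1, 2), (2, 3), (3, 0)]
    for (u, v), lab in zip(cycle, labels):
        g.add_edge(u, v, label=lab, weight=len(lab))
    tree = resolve_reticulations(PhyloNetwork(graph=g))
    kept = {(min(u, v), max(u, v)) for u, v in zip(tree.parent.values(), tree.parent.keys())}
    kept = {(min(c, p), max(c, p)) for c, p in tree.parent.items()}
    assert (0, 3) not in kept  # the transversion link went


def test_resolution_reaches_minimum_over_all_cycle_resolutions():
    """Exhaustive oracle: resolving must match the best spanning tree of
    the network (dangling medians trimmed) for transition-only data."""
    rng = np.random.default_rng(31)
    checked = 0
    for _ in range(40):
        haps = _random_conflicted_haps(rng)
        if len(haps) < 3:
            continue
        net = mp_prune(build_mj_network(haps, outgroup=()))
        if net.reticulation_count == 0:
            continue
        if any(len(c) > 16 for c in nx.biconnected_component_edges(net.graph)):
            continue  # beyond the documented exact-resolution bound
        checked += 1
        tree = resolve_reticulations(net, outgroup=())
        resolved_length = sum(tree.edge_length.values())
        best = None
        for st_edges in nx.SpanningTreeIterator(net.graph, weight="weight"):
            t = nx.Graph(st_edges.edges(data=True))
            while True:
                leaves = [
                    n
                    for n in t.nodes
                    if t.degree(n) <= 1 and not net.graph.nodes[n]["observed"]
                ]
                if not leaves:
                    break
                t.remove_nodes_from(leaves)
            w = sum(d["weight"] for _, _, d in t.edges(data=True))
            best = w if best is None else min(best, w)
        assert resolved_length == best
    assert checked >= 5


def test_resolution_invariant_under_input_permutation():
    rng = np.random.default_rng(47)
    haps = _random_conflicted_haps(rng, n_haps=7)
    trees = []
    for order in (haps, haps[::-1], haps[2:] + haps[:2]):
        net = mp_prune(build_mj_network(order, outgroup=()))
        tree = resolve_reticulations(net, outgroup=())
        profile = sorted(
            (tree.node_name(n), tree.depth(n)) for n in tree.nodes if tree.observed[n]
        )
        trees.append((profile, sum(tree.edge_length.values())))
    assert trees[0] == trees[1] == trees[2]


def test_resolve_without_outgroup_raises():
    net = build_mj_network([hap("a", []), hap("b", [100])])
    with pytest.raises(RootingError):
        resolve_reticulations(net, outgroup=[tvar(999)])
    with pytest.raises(RootingError):
        resolve_reticulations(net)  # no outgroup designated at build time


def test_newick_export_contains_tips_and_lengths():
    net = build_mj_network([hap("a", []), hap("b", [100, 200])], outgroup=())
    tree = resolve_reticulations(net)
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    assert "b:2" in nwk
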