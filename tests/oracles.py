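"""Independent brute-force oracles shared across the test suite.

Everything here deliberately avoids the code paths it checks: rho/sigma
are recomputed by naive parent-pointer walks and recursive subtree
counts, and network correctness is characterised directly from the data
(each polymorphic site changes exactly once across a split separating
carriers from non-carriers, which pins down the unique minimum-length
solution for conflict-free input).
"""

import math

import networkx as nx
import numpy as np

from mtroute.network import RootedCladeTree
from mtroute.seqio import MtHaplotype, Variant


def tvar(pos):
    return Variant(pos, "transition")


def hap(sid, positions):
    return MtHaplotype(sid, tuple(Variant(p, "transition") for p in positions))


def node_vectors(net):
    return {n: d["variants"] for n, d in net.graph.nodes(data=True)}


def edges_as_vector_pairs(net):
    vec = node_vectors(net)
    return {frozenset((vec[u], vec[v])) for u, v in net.graph.edges}


# --- dating oracles --------------------------------------------------------


def random_tree(rng, max_tips=12):
    """Random topology, random integer branch lengths and multiplicities."""
    n_nodes = int(rng.integers(2, 2 * max_tips))
    edges = []
    for child in range(1, n_nodes):
        parent = int(rng.integers(0, child))
        edges.append((parent, child, int(rng.integers(0, 6))))
    mult = {i: int(rng.integers(0, 3)) for i in range(n_nodes)}
    if sum(mult.values()) == 0:
        mult[n_nodes - 1] = 1
    return RootedCladeTree.from_edges(0, edges, multiplicity=mult)


def brute_force_rho(tree):
    """Path-sum enumeration via parent pointers."""
    total = 0.0
    n = 0
    for node in tree.nodes:
        m = tree.multiplicity[node]
        if m == 0:
            continue
        depth = 0
        cur = node
        while cur != tree.root:
            depth += tree.edge_length[cur]
            cur = tree.parent[cur]
        total += m * depth
        n += m
    return total / n


def brute_force_sigma(tree):
    """Per-edge enumeration with subtree tip counts recomputed recursively."""
    n = sum(tree.multiplicity.values())

    def tips_below(node):
        out = tree.multiplicity[node]
        for c in tree.children[node]:
            out += tips_below(c)
        return out

    var = sum(
        (tips_below(child) / n) ** 2 * length
        for child, length in tree.edge_length.items()
    )
    return math.sqrt(var)


# --- network oracles -------------------------------------------------------


def random_perfect_phylogeny(rng, max_haps=8, n_sites=10):
    """Random conflict-free instance: vectors grown by unique-site additions."""
    vectors = [frozenset()]
    for site in range(n_sites):
        base = vectors[rng.integers(len(vectors))]
        vectors.append(base | {100 + site})
    idx = rng.choice(len(vectors), size=min(max_haps, len(vectors)), replace=False)
    chosen = {vectors[i] for i in idx}
    return [hap(f"h{k}", sorted(v)) for k, v in enumerate(sorted(chosen, key=sorted))]


def assert_is_perfect_phylogeny(net, haps):
    """The unique minimum-length solution for conflict-free data: a tree in
    which every polymorphic site changes on exactly one link whose removal
    splits the sample into carriers and non-carriers."""
    observed = [h.variant_set() for h in haps]
    polymorphic = {
        v
        for v in set().union(*observed)
        if any(v in o for o in observed) and any(v not in o for o in observed)
    }
    assert net.reticulation_count == 0
    assert nx.is_connected(net.graph)
    assert net.total_length == len(polymorphic)
    vec = node_vectors(net)
    appearances = {}
    for u, v, d in net.graph.edges(data=True):
        for var in d["label"]:
            appearances.setdefault(var, []).append((u, v))
    assert set(appearances) == polymorphic
    for var, edge_list in appearances.items():
        assert len(edge_list) == 1
        g2 = net.graph.copy()
        g2.remove_edge(*edge_list[0])
        sides = list(nx.connected_components(g2))
        assert len(sides) == 2
        carriers = {n for n in net.graph if var in vec[n]}
        assert carriers in (set(sides[0]), set(sides[1]))
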