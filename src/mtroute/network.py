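"""Median-joining networks and their resolution into rooted trees.

Haplotypes are encoded as presence/absence vectors over the union of
observed variants.  The median-joining construction iteratively inserts
median (Steiner) vectors of triplets of nodes that are mutually close
under an epsilon-relaxed minimum-spanning criterion, until no median
improves the network; character conflict (homoplasy) survives as
reticulation cycles.  A maximum-parsimony pruning step then deletes
median vectors and links that no minimum-length spanning structure of the
observed haplotypes uses, and a deterministic weight policy cuts the
remaining cycles so the network becomes a rooted tree suitable for
rho/sigma coalescence dating.

The cycle-cutting policy replaces the by-hand resolution step of classic
network workflows with a reproducible rule: within each cycle the most
weight-penalised link is removed first (transversions and indels outweigh
transitions, then links through hypermutable sites, then the highest
position, with a final canonical-label tie-break), which is exactly a
reverse-delete pass and therefore leaves a minimum-weight spanning tree
of the network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

from .errors import ContractViolation, RootingError
from .seqio import MtHaplotype, Variant, format_variant

logger = logging.getLogger(__name__)

#: default mutation-class weights for the cycle-cutting policy
DEFAULT_POLICY: Mapping[str, int] = {
    "transition": 1,
    "transversion": 3,
    "insertion": 3,
    "deletion": 3,
}


@dataclass
class PhyloNetwork:
    """Mutation-labelled haplotype network.

    Node attributes: ``variants`` (frozenset of Variant), ``samples``
    (tuple of sample ids), ``multiplicity`` (observed copies; 0 for
    median vectors), ``observed`` (bool), ``outgroup`` (bool).
    Edge attributes: ``label`` (frozenset of Variant separating the two
    nodes) and ``weight`` (its size).
    """

    graph: nx.Graph
    epsilon: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def total_length(self) -> int:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    @property
    def reticulation_count(self) -> int:
        """Cyclomatic number: independent cycles in the network."""
        return (
            self.graph.number_of_edges()
            - self.graph.number_of_nodes()
            + nx.number_connected_components(self.graph)
        )

    def observed_nodes(self) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    def sample_size(self) -> int:
        return sum(d["multiplicity"] for _, d in self.graph.nodes(data=True))


def _as_variant_set(
    item: MtHaplotype | Iterable[Variant], exclude_hypermutable: bool
) -> frozenset[Variant]:
    if isinstance(item, MtHaplotype):
        return item.variant_set(exclude_hypermutable=exclude_hypermutable)
    vs = frozenset(item)
    if exclude_hypermutable:
        vs = frozenset(v for v in vs if not v.is_hypermutable())
    return vs


def _feasible_links(D: np.ndarray, epsilon: int) -> np.ndarray:
    """Boolean matrix of epsilon-relaxed minimum-spanning links.

    A link (u, v) is feasible iff its length exceeds the bottleneck
    (minimax-path) distance between u and v by at most epsilon; with
    epsilon 0 these are exactly the links lying on some minimum spanning
    tree of the current node set.
    """
    k = D.shape[0]
    if k == 1:
        return np.zeros((1, 1), dtype=bool)
    mst = minimum_spanning_tree(D.astype(float)).tocoo()
    adj: list[list[tuple[int, int]]] = [[] for _ in range(k)]
    for i, j, w in zip(mst.row, mst.col, mst.data):
        adj[i].append((j, int(round(w))))
        adj[j].append((i, int(round(w))))
    bottleneck = np.zeros((k, k), dtype=np.int64)
    for src in range(k):
        seen = {src}
        stack = [(src, 0)]
        while stack:
            node, mx = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    b = max(mx, w)
                    bottleneck[src, nxt] = b
                    stack.append((nxt, b))
    feasible = D <= bottleneck + epsilon
    np.fill_diagonal(feasible, False)
    return feasible


def _pairwise_hamming(M: np.ndarray) -> np.ndarray:
    Mi = M.astype(np.int16)
    # (k x c) boolean matrix; symmetric-difference counts via dot products
    ones = Mi.sum(axis=1)
    inter = Mi @ Mi.T
    return ones[:, None] + ones[None, :] - 2 * inter


def build_mj_network(
    haps: Sequence[MtHaplotype],
    epsilon: int = 0,
    outgroup: MtHaplotype | Iterable[Variant] | None = None,
    exclude_hypermutable: bool = True,
    max_rounds: int = 40,
) -> PhyloNetwork:
    """Build the median-joining network of *haps*.

    All haplotypes must share the same covered region.  An optional
    *outgroup* (a haplotype or an ancestral motif, e.g. the root state of
    the clade being dated) is inserted as an observed node with
    multiplicity 0 so the network can later be rooted on it.
    """
    if not haps:
        raise ContractViolation("need at least one haplotype")
    regions = {h.region for h in haps}
    if len(regions) > 1:
        raise ContractViolation(
            "haplotypes cover inconsistent regions; restrict them to a common interval first"
        )

    vec_info: dict[frozenset[Variant], dict] = {}
    for h in haps:
        vec = _as_variant_set(h, exclude_hypermutable)
        rec = vec_info.setdefault(vec, {"samples": [], "multiplicity": 0, "outgroup": False})
        rec["samples"].append(h.sample_id)
        rec["multiplicity"] += 1
    if outgroup is not None:
        vec = _as_variant_set(outgroup, exclude_hypermutable)
        rec = vec_info.setdefault(vec, {"samples": [], "multiplicity": 0, "outgroup": False})
        rec["outgroup"] = True

    characters = sorted(set().union(*vec_info.keys())) if any(vec_info) else []
    char_index = {v: i for i, v in enumerate(characters)}
    observed_rows: list[np.ndarray] = []
    for vec in vec_info:
        row = np.zeros(len(characters), dtype=bool)
        for v in vec:
            row[char_index[v]] = True
        observed_rows.append(row)
    vec_keys = list(vec_info.keys())

    if len(characters) == 0:
        M = np.zeros((len(vec_keys), 0), dtype=bool)
    else:
        M = np.vstack(observed_rows)
    n_observed = M.shape[0]
    is_median = np.zeros(n_observed, dtype=bool)

    def row_key(row: np.ndarray) -> bytes:
        return np.packbits(row).tobytes()

    known = {row_key(M[i]): i for i in range(M.shape[0])}

    for _ in range(max_rounds):
        D = _pairwise_hamming(M)
        feasible = _feasible_links(D, epsilon)
        # drop median vectors that no longer touch a feasible link
        degrees = feasible.sum(axis=1)
        drop = is_median & (degrees <= 1)
        if drop.any():
            keep = ~drop
            M = M[keep]
            is_median = is_median[keep]
            known = {row_key(M[i]): i for i in range(M.shape[0])}
            continue
        if M.shape[0] < 3:
            break
        neighbors = [np.flatnonzero(feasible[u]) for u in range(M.shape[0])]
        candidates: dict[bytes, tuple[int, np.ndarray]] = {}
        for u in range(M.shape[0]):
            for v, w in itertools.combinations(neighbors[u], 2):
                med = (
                    M[u].astype(np.int8) + M[v].astype(np.int8) + M[w].astype(np.int8)
                ) >= 2
                key = row_key(med)
                if key in known:
                    continue
                cost = int(
                    np.count_nonzero(M[u] != med)
                    + np.count_nonzero(M[v] != med)
                    + np.count_nonzero(M[w] != med)
                )
                if key not in candidates or cost < candidates[key][0]:
                    candidates[key] = (cost, med)
        if not candidates:
            break
        lam = min(cost for cost, _ in candidates.values())
        new_rows = [med for cost, med in candidates.values() if cost <= lam + epsilon]
        for med in new_rows:
            known[row_key(med)] = M.shape[0]
            M = np.vstack([M, med])
            is_median = np.append(is_median, True)
    else:
        logger.warning("median-joining did not converge in %d rounds", max_rounds)

    # final feasible links over the converged node set
    D = _pairwise_hamming(M)
    feasible = _feasible_links(D, epsilon)

    g = nx.Graph()
    node_vecs: list[frozenset[Variant]] = []
    for i in range(M.shape[0]):
        vec = frozenset(characters[j] for j in np.flatnonzero(M[i]))
        node_vecs.append(vec)
        if not is_median[i]:
            rec = vec_info[vec_keys[i]] if i < n_observed else None
            g.add_node(
                i,
                variants=vec,
                samples=tuple(rec["samples"]),
                multiplicity=rec["multiplicity"],
                observed=True,
                outgroup=rec["outgroup"],
            )
        else:
            g.add_node(
                i, variants=vec, samples=(), multiplicity=0, observed=False, outgroup=False
            )
    for i in range(M.shape[0]):
        for j in range(i + 1, M.shape[0]):
            if feasible[i, j]:
                label = node_vecs[i] ^ node_vecs[j]
                g.add_edge(i, j, label=label, weight=len(label))
    return PhyloNetwork(graph=g, epsilon=epsilon)


# ---------------------------------------------------------------------------
# maximum-parsimony pruning


def _drop_dangling_medians(g: nx.Graph) -> None:
    """Iteratively delete unobserved nodes of degree <= 1."""
    while True:
        victims = [
            n for n, d in g.nodes(data=True) if not d["observed"] and g.degree(n) <= 1
        ]
        if not victims:
            return
        g.remove_nodes_from(victims)


def _required_vertices(g: nx.Graph, comp_edges: list[tuple[int, int]]) -> set[int]:
    """Vertices of a biconnected component that any Steiner tree must touch:
    observed members plus attachment points behind which observed nodes lie."""
    comp_vertices = {v for e in comp_edges for v in e}
    required = {v for v in comp_vertices if g.nodes[v]["observed"]}
    outside = g.copy()
    outside.remove_edges_from(comp_edges)
    for v in comp_vertices - required:
        reachable = nx.node_connected_component(outside, v)
        if any(g.nodes[u]["observed"] for u in reachable if u != v):
            required.add(v)
    return required


def _iter_steiner_masks(comp_edges: list[tuple[int, int]], required: set[int]):
    """Yield edge-subset bitmasks forming a tree that connects *required*.

    Subsets touching extra vertices are allowed (Steiner points); subsets
    with cycles or disconnected pieces are rejected, so every yielded
    mask is a candidate resolution of the component.
    """
    verts = sorted({v for e in comp_edges for v in e} | set(required))
    vid = {v: i for i, v in enumerate(verts)}
    ea = [vid[u] for u, _ in comp_edges]
    eb = [vid[v] for _, v in comp_edges]
    req = [vid[v] for v in required]
    n_e = len(comp_edges)
    n_v = len(verts)
    for mask in range(1, 1 << n_e):
        parent = list(range(n_v))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        touched: set[int] = set()
        acyclic = True
        n_kept = 0
        m, i = mask, 0
        while m:
            if m & 1:
                a, b = find(ea[i]), find(eb[i])
                if a == b:
                    acyclic = False
                    break
                parent[a] = b
                touched.add(ea[i])
                touched.add(eb[i])
                n_kept += 1
            m >>= 1
            i += 1
        if not acyclic or not set(req) <= touched:
            continue
        r0 = find(req[0])
        if any(find(r) != r0 for r in req[1:]):
            continue
        if n_kept != len(touched) - 1:
            continue
        yield mask


def mp_prune(net: PhyloNetwork, max_component_edges: int = 16) -> PhyloNetwork:
    """Delete medians and links no minimum-length spanning structure uses.

    Within each biconnected component the minimum-weight edge subsets
    connecting all required vertices are enumerated exactly; the union of
    those minimal solutions is kept, so equally parsimonious alternatives
    survive as reticulations.  Observed nodes are never deleted.
    """
    g = net.graph.copy()
    _drop_dangling_medians(g)
    doomed_edges: list[tuple[int, int]] = []
    for comp_edges in nx.biconnected_component_edges(g):
        comp_edges = [tuple(e) for e in comp_edges]
        if len(comp_edges) == 1:
            u, v = comp_edges[0]
            required = _required_vertices(g, comp_edges)
            if not ({u, v} <= required):
                doomed_edges.append((u, v))
            continue
        if len(comp_edges) > max_component_edges:
            logger.warning(
                "biconnected component with %d links too large for exact pruning; kept as-is",
                len(comp_edges),
            )
            continue
        required = _required_vertices(g, comp_edges)
        if len(required) <= 1:
            doomed_edges.extend(comp_edges)
            continue
        weights = [g.edges[e]["weight"] for e in comp_edges]
        best_weight = None
        best_masks: list[int] = []
        n_e = len(comp_edges)
        for mask in _iter_steiner_masks(comp_edges, required):
            w = sum(weights[i] for i in range(n_e) if mask >> i & 1)
            if best_weight is None or w < best_weight:
                best_weight = w
                best_masks = [mask]
            elif w == best_weight:
                best_masks.append(mask)
        union_mask = 0
        for mask in best_masks:
            union_mask |= mask
        for i in range(n_e):
            if not union_mask >> i & 1:
                doomed_edges.append(comp_edges[i])
    g.remove_edges_from(doomed_edges)
    _drop_dangling_medians(g)
    return PhyloNetwork(graph=g, epsilon=net.epsilon)


# ---------------------------------------------------------------------------
# reticulation resolution and rooting


def _edge_penalty(
    g: nx.Graph, edge: tuple[int, int], policy: Mapping[str, int]
) -> tuple:
    label: frozenset[Variant] = g.edges[edge]["label"]
    class_weight = sum(policy[v.kind] for v in label)
    flagged = sum(1 for v in label if v.is_hypermutable())
    max_position = max((v.position for v in label), default=0)
    canonical = tuple(sorted(format_variant(v) for v in label))
    endpoints = tuple(
        sorted(tuple(sorted(format_variant(v) for v in g.nodes[n]["variants"])) for n in edge)
    )
    return (class_weight, flagged, max_position, canonical, endpoints)


@dataclass
class RootedCladeTree:
    """Resolved, rooted mutation-labelled tree ready for dating.

    ``parent``/``children`` encode the topology; ``edge_length[child]`` is
    the mutation count on the branch above *child*; ``multiplicity`` holds
    sampled copies per node (0 for medians and a pure outgroup).
    """

    root: int
    parent: dict[int, int]
    children: dict[int, list[int]]
    edge_length: dict[int, int]
    multiplicity: dict[int, int]
    samples: dict[int, tuple[str, ...]]
    observed: dict[int, bool]
    variants: dict[int, frozenset[Variant]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[int]:
        return list(self.children)

    @property
    def sample_size(self) -> int:
        return sum(self.multiplicity.values())

    def depth(self, node: int) -> int:
        d = 0
        while node != self.root:
            d += self.edge_length[node]
            node = self.parent[node]
        return d

    def subtree_multiplicity(self, node: int) -> int:
        total = self.multiplicity[node]
        for child in self.children[node]:
            total += self.subtree_multiplicity(child)
        return total

    def postorder(self) -> list[int]:
        out: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                out.append(node)
            else:
                stack.append((node, True))
                for child in self.children[node]:
                    stack.append((child, False))
        return out

    def node_name(self, node: int) -> str:
        names = self.samples.get(node, ())
        if names:
            return "|".join(names)
        return f"mv{node}"

    def to_newick(self) -> str:
        def render(node: int) -> str:
            kids = self.children[node]
            name = self.node_name(node)
            if not kids:
                return name
            inner = ",".join(
                f"{render(c)}:{self.edge_length[c]}"
                for c in sorted(kids, key=self.node_name)
            )
            return f"({inner}){name}"

        return render(self.root) + ";"

    @classmethod
    def from_edges(
        cls,
        root: int,
        edges: Sequence[tuple[int, int, int]],
        multiplicity: Mapping[int, int] | None = None,
    ) -> "RootedCladeTree":
        """Convenience constructor: edges are (parent, child, mutations)."""
        parent: dict[int, int] = {}
        children: dict[int, list[int]] = {root: []}
        edge_length: dict[int, int] = {}
        for p, c, w in edges:
            parent[c] = p
            children.setdefault(p, [])
            children.setdefault(c, [])
            children[p].append(c)
            edge_length[c] = w
        mult = {}
        for node in children:
            if multiplicity is not None:
                mult[node] = multiplicity.get(node, 0)
            else:
                mult[node] = 1 if not children[node] else 0
        return cls(
            root=root,
            parent=parent,
            children=children,
            edge_length=edge_length,
            multiplicity=mult,
            samples={n: () for n in children},
            observed={n: mult[n] > 0 for n in children},
        )


def resolve_reticulations(
    net: PhyloNetwork,
    outgroup: MtHaplotype | Iterable[Variant] | None = None,
    policy: Mapping[str, int] | None = None,
    exclude_hypermutable: bool = True,
) -> RootedCladeTree:
    """Cut cycles deterministically and root the network on its outgroup.

    Cycle edges are removed in decreasing penalty order (reverse-delete),
    so the surviving tree has minimum total penalty over all resolutions;
    with transition-only data that is exactly the minimum mutation count.
    The root is the node flagged as outgroup at network construction, or
    the node matching the *outgroup* haplotype/motif passed here.
    """
    policy = dict(DEFAULT_POLICY if policy is None else policy)
    g = net.graph.copy()

    root = None
    if outgroup is not None:
        target = _as_variant_set(outgroup, exclude_hypermutable)
        for n, d in g.nodes(data=True):
            if d["variants"] == target:
                root = n
                break
        if root is None:
            raise RootingError("no network node matches the designated outgroup")
    else:
        flagged = [n for n, d in g.nodes(data=True) if d.get("outgroup")]
        if not flagged:
            raise RootingError("network has no outgroup node; pass one explicitly")
        root = flagged[0]

    if not nx.is_connected(g):
        keep = nx.node_connected_component(g, root)
        orphan_obs = [
            n for n, d in g.nodes(data=True) if d["observed"] and n not in keep
        ]
        if orphan_obs:
            raise RootingError(
                f"{len(orphan_obs)} observed node(s) unreachable from the outgroup"
            )
        g = g.subgraph(keep).copy()

    _cut_cycles(g, root, policy)
    _drop_dangling_medians_keeping(g, root)

    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {n: [] for n in g.nodes}
    edge_length: dict[int, int] = {}
    for u, v in nx.bfs_edges(g, root):
        parent[v] = u
        children[u].append(v)
        edge_length[v] = g.edges[u, v]["weight"]
    return RootedCladeTree(
        root=root,
        parent=parent,
        children=children,
        edge_length=edge_length,
        multiplicity={n: g.nodes[n]["multiplicity"] for n in g.nodes},
        samples={n: g.nodes[n]["samples"] for n in g.nodes},
        observed={n: g.nodes[n]["observed"] for n in g.nodes},
        variants={n: g.nodes[n]["variants"] for n in g.nodes},
    )


def _cut_cycles(
    g: nx.Graph, root: int, policy: Mapping[str, int], max_component_edges: int = 16
) -> None:
    """Reduce every biconnected component to its best resolution.

    Within a component the connecting edge subsets over the required
    vertices (observed nodes, attachment points, the root) are enumerated
    exactly; the kept subset minimises total policy penalty — i.e. the
    most weight-penalised links are the ones cut — with a canonical
    label tie-break so the outcome is independent of node numbering.
    Components too large to enumerate fall back to a greedy
    reverse-delete that preserves observed connectivity.
    """
    doomed: list[tuple[int, int]] = []
    for comp_edges in nx.biconnected_component_edges(g):
        comp_edges = [tuple(e) for e in comp_edges]
        if len(comp_edges) == 1:
            continue
        required = _required_vertices(g, comp_edges)
        comp_vertices = {v for e in comp_edges for v in e}
        if root in comp_vertices:
            required.add(root)
        if len(required) <= 1:
            doomed.extend(comp_edges)
            continue
        penalties = {e: _edge_penalty(g, e, policy) for e in comp_edges}
        if len(comp_edges) > max_component_edges:
            logger.warning(
                "component with %d links too large for exact resolution; using greedy cuts",
                len(comp_edges),
            )
            sub = g.edge_subgraph(comp_edges).copy()
            for e in sorted(comp_edges, key=penalties.__getitem__, reverse=True):
                data = sub.edges[e]
                sub.remove_edge(*e)
                still = all(
                    nx.has_path(sub, a, b)
                    for a, b in itertools.pairwise(sorted(required))
                ) if len(required) > 1 else True
                if still:
                    doomed.append(e)
                else:
                    sub.add_edge(*e, **data)
            continue
        n_e = len(comp_edges)
        best_key = None
        best_mask = 0
        for mask in _iter_steiner_masks(comp_edges, required):
            kept = [comp_edges[i] for i in range(n_e) if mask >> i & 1]
            key = (
                sum(penalties[e][0] for e in kept),
                tuple(sorted(penalties[e] for e in kept)),
            )
            if best_key is None or key < best_key:
                best_key = key
                best_mask = mask
        if best_key is None:
            continue  # nothing to do; component kept as-is
        for i in range(n_e):
            if not best_mask >> i & 1:
                doomed.append(comp_edges[i])
    g.remove_edges_from(doomed)


def _drop_dangling_medians_keeping(g: nx.Graph, keep: int) -> None:
    while True:
        victims = [
            n
            for n, d in g.nodes(data=True)
            if n != keep and not d["observed"] and g.degree(n) <= 1
        ]
        if not victims:
            return
        g.remove_nodes_from(victims)


# ---------------------------------------------------------------------------
# canonical form and exports


def contract_unary_medians(net: PhyloNetwork) -> PhyloNetwork:
    """Suppress unobserved degree-2 nodes, concatenating edge labels.

    Useful for comparing networks up to the placement of intermediate
    median vectors along multi-mutation branches.
    """
    g = net.graph.copy()
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            d = g.nodes[n]
            if d["observed"] or g.degree(n) != 2:
                continue
            u, v = list(g.neighbors(n))
            if g.has_edge(u, v):
                continue  # contraction would merge parallel paths of a cycle
            label = g.edges[n, u]["label"] | g.edges[n, v]["label"]
            g.remove_node(n)
            g.add_edge(u, v, label=label, weight=len(label))
            changed = True
    return PhyloNetwork(graph=g, epsilon=net.epsilon)


def write_gml(net: PhyloNetwork, path) -> None:
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(
            n,
            label="|".join(d["samples"]) if d["samples"] else f"mv{n}",
            variants=" ".join(sorted(format_variant(v) for v in d["variants"])),
            multiplicity=d["multiplicity"],
            observed=int(d["observed"]),
        )
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(
            u,
            v,
            label=" ".join(sorted(format_variant(x) for x in d["label"])),
            weight=d["weight"],
        )
    nx.write_gml(g, str(path))


def write_edge_table(net: PhyloNetwork, path) -> None:
    import pandas as pd

    rows = []
    for u, v, d in sorted(net.graph.edges(data=True)):
        rows.append(
            {
                "node_a": u,
                "node_b": v,
                "mutations": " ".join(sorted(format_variant(x) for x in d["label"])),
                "n_mutations": d["weight"],
            }
        )
    pd.DataFrame(rows, columns=["node_a", "node_b", "mutations", "n_mutations"]).to_csv(
        path, sep="\t", index=False
    )
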