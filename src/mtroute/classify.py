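"""Motif-based haplogroup classification.

A haplogroup tree is a rooted tree of named clades; each branch carries a
motif, the set of mutations acquired on the branch leading to that clade,
written in rCRS-relative notation.  A back-mutation is encoded as a
reversion variant (``16223!``): the branch restores the rCRS state at a
site some ancestor had changed.  The cumulative expected state of a clade
is the union of motifs along its root path with reversions cancelling the
earlier variant.

Classification scores a sample against every clade: over the sample's
covered region, each diagnostic site of the clade's cumulative state
either matches (expected variant present, or reverted site clean) or
mismatches; uncovered sites are neutral.  The sample is assigned to the
clade maximising matched minus mismatched; ties are reported as ambiguous
at the lowest common ancestor of the tied clades.  Hypermutable sites are
excluded by default, following standard practice for mtDNA trees.

The N(xR) predicate singles out lineages inside macrohaplogroup N but
outside its R subclade — the clades whose phylogeography carries the
signal for the dispersal-route analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ContractViolation, StructureError, ValidationError
from .seqio import MtHaplotype, Variant, format_variant, parse_variant_string


@dataclass(frozen=True)
class HaplogroupNode:
    """Named clade: parent link plus the motif acquired on its branch."""

    name: str
    parent: str | None
    motif: tuple[Variant, ...]


class HaplogroupTree:
    """Validated classification tree with cumulative per-clade states."""

    def __init__(self, nodes: list[HaplogroupNode]):
        self.nodes: dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise StructureError(f"duplicate haplogroup name {node.name!r}")
            self.nodes[node.name] = node
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].name
        self._children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for node in nodes:
            if node.parent is None:
                continue
            if node.parent not in self.nodes:
                raise StructureError(f"orphan node {node.name!r}: parent {node.parent!r} missing")
            if not node.motif:
                raise StructureError(f"non-root node {node.name!r} has an empty motif")
            self._children[node.parent].append(node.name)
        # cycle check doubles as depth computation
        self.depth: dict[str, int] = {}
        self._cumulative: dict[str, dict[tuple[int, int], Variant | None]] = {}
        stack = [self.root]
        self.depth[self.root] = 0
        order = []
        while stack:
            name = stack.pop()
            order.append(name)
            for child in self._children[name]:
                if child in self.depth:
                    raise StructureError(f"cycle through node {child!r}")
                self.depth[child] = self.depth[name] + 1
                stack.append(child)
        if len(order) != len(self.nodes):
            unreached = set(self.nodes) - set(order)
            raise StructureError(f"unreachable node(s): {', '.join(sorted(unreached))}")
        for name in order:
            node = self.nodes[name]
            state: dict[tuple[int, int], Variant | None] = (
                dict(self._cumulative[node.parent]) if node.parent else {}
            )
            for v in node.motif:
                key = (v.position, v.suffix_index)
                if v.back:
                    if state.get(key) is None:
                        raise StructureError(
                            f"{name}: reversion {format_variant(v)} cancels nothing"
                        )
                    state[key] = None  # site restored to the rCRS state
                else:
                    state[key] = v
            self._cumulative[name] = state

    def children(self, name: str) -> list[str]:
        return list(self._children[name])

    def cumulative_state(self, name: str) -> dict[tuple[int, int], Variant | None]:
        """Expected rCRS-relative state at every diagnostic site of *name*.

        Maps (position, suffix) to the expected Variant, or None where the
        root path touched the site but the clade has reverted to rCRS.
        """
        if name not in self._cumulative:
            raise ValidationError(f"haplogroup {name!r} not in tree")
        return dict(self._cumulative[name])

    def cumulative_motif(self, name: str) -> frozenset[Variant]:
        """The variants a clean full-coverage member of *name* carries."""
        return frozenset(v for v in self.cumulative_state(name).values() if v is not None)

    def ancestors(self, name: str) -> list[str]:
        """Root path including *name* itself, root first."""
        if name not in self.nodes:
            raise ValidationError(f"haplogroup {name!r} not in tree")
        path = []
        cur: str | None = name
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def is_descendant(self, name: str, ancestor: str) -> bool:
        """True iff *name* equals or descends from *ancestor*."""
        return ancestor in self.ancestors(name)

    def lca(self, names: list[str]) -> str:
        paths = [self.ancestors(n) for n in names]
        lca = self.root
        for level in range(min(len(p) for p in paths)):
            step = {p[level] for p in paths}
            if len(step) != 1:
                break
            lca = step.pop()
        return lca


@dataclass(frozen=True)
class ClassificationResult:
    haplogroup: str
    score: int  # matched diagnostic sites
    mismatches: int
    ambiguous: bool


def load_haplogroup_tree(path: str | Path | None = None) -> HaplogroupTree:
    """Load a haplogroup tree from JSON (list of name/parent/motif records).

    With no *path* the packaged fixture is used: real nomenclature and
    topology for L3, M, N, R and the N(xR) clades of the route analysis,
    with partly synthetic motif positions (see the data file header).
    """
    if path is None:
        source = resources.files("mtroute.data") / "haplogroups_synthetic.json"
        with resources.as_file(source) as p:
            payload = json.loads(Path(p).read_text())
    else:
        payload = json.loads(Path(path).read_text())
    records = payload["haplogroups"] if isinstance(payload, dict) else payload
    nodes = []
    for rec in records:
        motif = tuple(parse_variant_string(tok) for tok in rec.get("motif", []))
        nodes.append(HaplogroupNode(rec["name"], rec.get("parent"), motif))
    return HaplogroupTree(nodes)


def _variant_matches(got: Variant, expected: Variant) -> bool:
    """Same mutational change, tolerating bare-transition notation."""
    if got.kind != expected.kind:
        return False
    if expected.derived_state and got.derived_state:
        return got.derived_state == expected.derived_state
    return True


def classify_haplotype(
    h: MtHaplotype,
    tree: HaplogroupTree,
    exclude_hypermutable: bool = True,
) -> ClassificationResult:
    """Assign *h* to the best-scoring clade of *tree*.

    Scoring counts matched minus mismatched diagnostic sites restricted to
    the sample's covered region; sites outside coverage are neutral, so
    HVR-only data can still be placed.  Ties return ambiguous=True with
    the lowest common ancestor of the tied clades.
    """
    if not tree.nodes:
        raise ContractViolation("empty haplogroup tree")
    if not h.region:
        raise ContractViolation(f"{h.sample_id}: empty coverage")
    observed = {
        (v.position, v.suffix_index): v
        for v in h.variant_set(exclude_hypermutable=exclude_hypermutable)
    }
    scores: dict[str, tuple[int, int]] = {}
    for name in tree.nodes:
        matched = mismatched = 0
        for (pos, suffix), expected in tree.cumulative_state(name).items():
            if expected is not None and exclude_hypermutable and expected.is_hypermutable():
                continue
            if not h.covers(pos):
                continue
            got = observed.get((pos, suffix))
            if expected is None:
                if got is None:
                    matched += 1
                else:
                    mismatched += 1
            else:
                if got is not None and _variant_matches(got, expected):
                    matched += 1
                else:
                    mismatched += 1
        scores[name] = (matched, mismatched)
    best = max(m - mm for m, mm in scores.values())
    candidates = sorted(
        (name for name, (m, mm) in scores.items() if m - mm == best),
        key=lambda n: (tree.depth[n], n),
    )
    if len(candidates) == 1:
        winner = candidates[0]
        matched, mismatched = scores[winner]
        return ClassificationResult(winner, matched, mismatched, ambiguous=False)
    winner = tree.lca(candidates)
    matched, mismatched = scores[winner]
    return ClassificationResult(winner, matched, mismatched, ambiguous=True)


def is_NxR(result: ClassificationResult, tree: HaplogroupTree, n: str = "N", r: str = "R") -> bool:
    """True iff the assigned clade lies inside N but outside its R subclade."""
    if result.haplogroup not in tree.nodes:
        raise ValidationError(f"haplogroup {result.haplogroup!r} not in tree")
    return tree.is_descendant(result.haplogroup, n) and not tree.is_descendant(
        result.haplogroup, r
    )


def haplogroup_frequencies(
    haplotypes: list[MtHaplotype],
    tree: HaplogroupTree,
    level: int | None = None,
    exclude_hypermutable: bool = True,
) -> dict[str, float]:
    """Per-haplogroup sample frequencies (fractions summing to 1).

    With *level* set, calls are rolled up to the ancestor at that depth
    (e.g. level=1 aggregates to the clades directly under the root), the
    way population surveys report major-clade frequencies.
    """
    if not haplotypes:
        raise ContractViolation("no haplotypes to aggregate")
    counts: dict[str, int] = {}
    for h in haplotypes:
        call = classify_haplotype(h, tree, exclude_hypermutable=exclude_hypermutable)
        name = call.haplogroup
        if level is not None:
            path = tree.ancestors(name)
            name = path[min(level, len(path) - 1)]
        counts[name] = counts.get(name, 0) + 1
    total = sum(counts.values())
    return {name: counts[name] / total for name in sorted(counts)}
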