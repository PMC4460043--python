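"""Clade-structured synthetic haplotype data with known ground truth.

Every pipeline stage is testable without downloads: a Yule (pure-birth)
topology is scaled so the root age equals a known TMRCA, mutations
accumulate along branches as a Poisson process on rCRS coordinates at a
fixed rate in years per substitution, and tips receive geographic labels
arranged along a west-to-east longitude gradient that either follows the
route model (older clades west) or is shuffled into a null arrangement.

The mutation model is two-state per site: a repeat hit at an already
mutated site reverts it, so recurrent mutation and the reticulations it
causes are exercised, while transitions outnumber transversions according
to the configured bias as in real mtDNA.  All randomness flows from the
single mandatory seed; each operation draws from its own child stream so
no generator state is shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ContractViolation, ValidationError
from .network import RootedCladeTree
from .phylogeo import Anchor, RouteModel, RouteObservation
from .seqio import (
    GeoPoint,
    MtHaplotype,
    PLACEHOLDER_POSITION,
    TRANSITIONS,
    Variant,
    load_reference,
)

#: route geometry used for geographic placement: the Djibouti and Darwin
#: anchor longitudes with the published anchor ages in ky
DEFAULT_ANCHORS = ((43.35, 70.8), (130.8333, 46.8))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated clade."""

    seed: int
    n_tips: int = 30
    tmrca_years: float = 50_000.0
    rate: float = 3624.0
    seq_interval: tuple[int, int] = (1, 16569)
    transition_bias: float = 22.0
    anchors: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ContractViolation("n_tips must be >= 1")
        if self.tmrca_years <= 0 or self.rate <= 0:
            raise ValidationError("tmrca_years and rate must be positive")
        if self.transition_bias < 0:
            raise ValidationError("transition_bias must be >= 0")
        lo, hi = self.seq_interval
        if not 1 <= lo <= hi <= 16569:
            raise ValidationError("seq_interval outside rCRS coordinates")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent child stream for one pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stage,)))


def simulate_tree(cfg: SimConfig) -> RootedCladeTree:
    """Yule topology conditioned on n_tips, root age scaled to tmrca_years.

    Branch lengths are in years and the tree is ultrametric: every tip
    sits exactly tmrca_years below the root.
    """
    rng = cfg.rng(0)
    n = cfg.n_tips
    root = 0
    if n == 1:
        tree = RootedCladeTree.from_edges(root, [(0, 1, cfg.tmrca_years)])
        return tree
    # split times: with k lineages the epoch lasts Exp(k); rescale to tmrca
    epochs = np.array([rng.exponential(1.0 / k) for k in range(2, n + 1)])
    epochs *= cfg.tmrca_years / epochs.sum()
    split_times = np.concatenate([[0.0], np.cumsum(epochs)[:-1]])  # time of k-th split
    node_time = {root: 0.0}
    parent: dict[int, int] = {}
    leaves = [root]
    next_id = 1
    for k in range(n - 1):  # k-th split happens at split_times[k]
        t = split_times[k]
        idx = rng.integers(len(leaves))
        target = leaves.pop(int(idx))
        # the split node materialises at time t; its branch began at its parent
        for _ in range(2):
            node_time[next_id] = t
            parent[next_id] = target
            leaves.append(next_id)
            next_id += 1
        node_time[target] = t
    edges = []
    for child, par in parent.items():
        length = node_time[child] - node_time[par]
        edges.append((par, child, length))
    # extend every leaf to the present (tmrca below the root)
    final_edges = []
    leaf_set = set(leaves)
    for par, child, length in edges:
        if child in leaf_set:
            length = cfg.tmrca_years - node_time[parent[child]]
        final_edges.append((par, child, length))
    tree = RootedCladeTree.from_edges(root, final_edges)
    return tree


def evolve_haplotypes(
    tree: RootedCladeTree,
    cfg: SimConfig,
    ref: str | None = None,
) -> tuple[list[MtHaplotype], dict]:
    """Drop Poisson mutations on the tree and read haplotypes off the tips.

    Per branch the mutation count is Poisson(branch_years / rate); sites
    are uniform on the configured interval, transitions outnumber
    transversions by the configured bias, and a repeat hit reverts the
    site (recurrent mutation allowed).  Returns the tip haplotypes plus a
    ground-truth record with per-tip mutation-event counts.
    """
    rng = cfg.rng(1)
    if ref is None:
        ref = load_reference()
    lo, hi = cfg.seq_interval
    p_transition = cfg.transition_bias / (cfg.transition_bias + 1.0)

    tips: list[MtHaplotype] = []
    tip_events: dict[str, int] = {}
    n_events_total = 0
    n_recurrent = 0

    state_stack: dict[int, dict[int, Variant]] = {tree.root: {}}
    events_stack: dict[int, int] = {tree.root: 0}
    order = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        order.append(node)
        for child in tree.children[node]:
            stack.append(child)
    tip_counter = 0
    for node in order:
        if node != tree.root:
            par = tree.parent[node]
            state = dict(state_stack[par])
            events = events_stack[par]
            branch_years = tree.edge_length[node]
            k = int(rng.poisson(branch_years / cfg.rate))
            for _ in range(k):
                pos = int(rng.integers(lo, hi + 1))
                while pos == PLACEHOLDER_POSITION:
                    pos = int(rng.integers(lo, hi + 1))
                if pos in state:
                    del state[pos]  # repeat hit reverts the site
                    n_recurrent += 1
                elif rng.random() < p_transition:
                    state[pos] = Variant(pos, "transition")
                else:
                    base = ref[pos - 1]
                    choices = [
                        b for b in "ACGT" if b != base and b != TRANSITIONS.get(base)
                    ]
                    state[pos] = Variant(pos, "transversion", str(rng.choice(choices)))
                events += 1
                n_events_total += 1
            state_stack[node] = state
            events_stack[node] = events
        if not tree.children[node]:
            tip_counter += 1
            sample_id = f"T{tip_counter:04d}"
            tips.append(
                MtHaplotype(
                    sample_id=sample_id,
                    variants=tuple(state_stack[node].values()),
                    region=(cfg.seq_interval,),
                    population="sim",
                )
            )
            tip_events[sample_id] = events_stack[node]
    truth = {
        "tmrca_years": cfg.tmrca_years,
        "rate": cfg.rate,
        "expected_rho": cfg.tmrca_years / cfg.rate,
        "tip_mutation_events": tip_events,
        "mean_tip_mutation_events": float(np.mean(list(tip_events.values()))),
        "n_events_total": n_events_total,
        "n_recurrent_hits": n_recurrent,
        "seed": cfg.seed,
    }
    return tips, truth


GradientMode = Literal["concordant", "null"]


def assign_geography(
    tips: Sequence[MtHaplotype],
    cfg: SimConfig,
    gradient: GradientMode = "concordant",
    clade_of: dict[str, int] | None = None,
    clade_age: dict[int, float] | None = None,
) -> dict[str, GeoPoint]:
    """Place tips along the route's longitude gradient.

    Tips are grouped into clades (by the provided mapping, else one clade
    per tip); concordant mode orders clade centers west to east by
    decreasing clade age so the serial-founder expectation holds, null
    mode shuffles the clade-to-longitude assignment.  Returns a mapping
    from sample id to GeoPoint; permuting tip ids permutes but never
    changes the multiset of assigned points.
    """
    rng = cfg.rng(2)
    ids = [t.sample_id for t in tips]
    if clade_of is None:
        clade_of = {sid: i for i, sid in enumerate(sorted(ids))}
    clades = sorted(set(clade_of.values()))
    if clade_age is None:
        clade_age = {c: float(len(clades) - i) for i, c in enumerate(clades)}
    (lon_w, _), (lon_e, _) = cfg.anchors
    # oldest clade sits at the western anchor, youngest at the eastern one
    by_age = sorted(clades, key=lambda c: (-clade_age[c], c))
    lons = np.linspace(lon_w, lon_e, num=len(clades))
    if gradient == "null":
        lons = rng.permutation(lons)
    elif gradient != "concordant":
        raise ValidationError(f"unknown gradient mode {gradient!r}")
    clade_lon = {c: float(lon) for c, lon in zip(by_age, lons)}
    points: dict[str, GeoPoint] = {}
    for sid in sorted(ids):
        lon = clade_lon[clade_of[sid]]
        jitter = float(rng.normal(0.0, 0.5))
        points[sid] = GeoPoint(
            latitude=float(np.clip(10.0 + rng.normal(0.0, 2.0), -89.0, 89.0)),
            longitude=float(np.clip(lon + jitter, -179.9, 179.9)),
        )
    return points


# ---------------------------------------------------------------------------
# route-concordance fixtures


def route_fixture_model(
    anchors: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_ANCHORS,
    band_halfwidth: float = 5.0,
) -> RouteModel:
    """Route model whose CI band has a constant half-width in ky."""
    (lon_w, age_w), (lon_e, age_e) = anchors
    return RouteModel(
        anchor_west=Anchor("W", lon_w, age_w, (age_w - band_halfwidth, age_w + band_halfwidth)),
        anchor_east=Anchor("E", lon_e, age_e, (age_e - band_halfwidth, age_e + band_halfwidth)),
    )


def make_route_fixture(
    n_clades: int,
    seed: int,
    mode: GradientMode = "concordant",
    obs_halfwidth: float = 2.0,
    band_halfwidth: float = 5.0,
    anchors: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_ANCHORS,
) -> tuple[list[RouteObservation], RouteModel]:
    """Observations on (concordant) or shuffled off (null) the model line.

    Clade ages sit exactly on the interpolation line at their true
    longitudes with tight +/- obs_halfwidth CIs; null mode permutes the
    longitudes so age and geography decouple.  The half-widths are chosen
    so that under the null the probability of CI overlap at a random
    longitude is ~1/2, centring tau at 0 (see the methods note).
    """
    if n_clades < 2:
        raise ContractViolation("need at least two clades")
    rng = np.random.default_rng(seed)
    model = route_fixture_model(anchors, band_halfwidth)
    (lon_w, age_w), (lon_e, age_e) = anchors
    true_lons = rng.uniform(lon_w, lon_e, size=n_clades)
    slope = (age_e - age_w) / (lon_e - lon_w)
    ages = age_w + slope * (true_lons - lon_w)
    lons = rng.permutation(true_lons) if mode == "null" else true_lons
    observations = [
        RouteObservation(
            haplogroup=f"C{i:02d}",
            longitude=float(lons[i]),
            age=float(ages[i]),
            ci95=(float(ages[i] - obs_halfwidth), float(ages[i] + obs_halfwidth)),
        )
        for i in range(n_clades)
    ]
    return observations, model


def shuffle_longitudes(
    observations: Sequence[RouteObservation], rng: np.random.Generator
) -> list[RouteObservation]:
    """Permute longitudes across observations (one draw from the null)."""
    lons = rng.permutation([o.longitude for o in observations])
    return [
        RouteObservation(
            haplogroup=o.haplogroup,
            longitude=float(lon),
            age=o.age,
            ci95=o.ci95,
            place=o.place,
            latitude=o.latitude,
        )
        for o, lon in zip(observations, lons)
    ]
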