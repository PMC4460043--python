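# Methods

This note documents the models, conventions and numerical choices behind
mtroute, in the spirit of the methods documentation of simulation and
statistics packages: what each stage assumes, which knobs matter, and
what the synthetic-data checks do and do not establish about real data.

## Coordinates and notation

All positions are 1-based rCRS coordinates (1..16569). The historical
placeholder at position 3107 is retained in the reference so printed
positions match the literature; it is written `N` and never penalised in
alignment. Variant tokens follow the field's compact notation: a bare
position (`16223`) is a transition, an explicit base (`95C`) a
transversion, `16189.1C` an insertion, `8281d` a deletion, and a
trailing `!` in haplogroup motifs marks a back-mutation to the rCRS
state. When a reference is supplied to the parser, an explicit base is
reclassified as transition or transversion by comparison with the
reference base; without one, the notation convention decides.

Degree-minute coordinates (`11°00´N-104°00´E`) are converted to decimal
degrees at parse time, south/west negative. This rounding is why the
expected-age checks carry a ±0.2 ky tolerance.

Hypermutable sites — 16182, 16183, 16519, and indels in the 16184–16193
poly-C tract — are flagged and excluded from classification and network
building by default (configurable). Substitutions inside the tract are
kept; only length variation there is conventionally uninterpretable.

## Sequence ↔ haplotype conversion

Conversion to and from sequences uses banded global alignment against
the reference slice with substitution cost 1 and gap cost 2, so
substitutions are always preferred over indel pairs. Equal-cost indel
placements are resolved during traceback toward the *rightmost* position
of a homopolymer run, a deterministic stand-in for the unstated manual
convention of alignment editors. The band half-width (default 32)
bounds the tolerated edit distance; inputs outside it raise an
alignment error rather than silently truncating.

## Haplogroup classification

The classification tree stores per-branch motifs; the cumulative state
of a clade is the union of motifs along its root path with reversions
cancelling earlier variants. In the rCRS frame the deep topology is
encoded with the real key events: the five-site motif separating N from
L3 (8701, 9540, 10398, 10873, 15301 as reversions, because the rCRS
itself sits inside R), and R defined by the 12705 change plus the 16223
reversion. Scoring counts matched minus mismatched diagnostic sites
restricted to the sample's covered region — uncovered diagnostics are
neutral, which is what makes HVR-only surveys classifiable — and the
best-scoring clade wins. Tied candidates are reported as ambiguous at
their lowest common ancestor: for a sample with no informative coverage
every clade ties and the call degrades gracefully to the root. (The
alternative reading, "shallowest common ancestor", would always return
the root and carry no information.) The packaged tree fixture follows
the published per-clade counts of defining mutations with synthetic
placeholder positions where the literature's motifs are not shipped;
its file header says so, and real analyses should load a
PhyloTree-derived JSON instead.

## Median-joining networks

Haplotypes are binary presence/absence vectors over the union of
observed variants; distances are symmetric-difference counts. A link is
*feasible* when its length exceeds the bottleneck (minimax-path)
distance between its endpoints by at most ε — for ε = 0 exactly the
links on some minimum spanning tree. Each round forms majority medians
of triplets joined by feasible links and adds every new median whose
connection cost is within ε of the round's minimum; medians that lose
all feasible links are discarded; iteration stops at a fixed point.
ε defaults to 0, the conventional default of median-network software,
and is exposed on the CLI. A separate reduced-median preprocessing pass
is deliberately omitted: in this binary encoding the median-joining
step already generates the reduced-median vectors, and the historical
RM pass is a data-reduction heuristic rather than a different estimator.

Maximum-parsimony pruning deletes median vectors and links that no
minimum-length spanning structure of the observed nodes uses. Within
each biconnected component the connecting edge subsets over the
required vertices (observed members plus attachment points, Steiner
points allowed) are enumerated exactly and the union of all minimal
solutions is kept, so equally parsimonious alternatives survive as
reticulations; observed nodes are never deleted. Exact enumeration is
bounded at 16 links per component — beyond that the component is kept
as-is with a warning. On the data scales this pipeline targets
(tens of haplotypes, homoplasy at a handful of sites) components are
far smaller; the bound exists so pathological inputs degrade loudly,
not wrongly.

Reticulation cutting replaces the traditional manual step with a
deterministic policy. Within each component the kept resolution
minimises total policy penalty — mutation classes weighted
transition 1, transversion 3, indel 3, then hypermutable-site count,
then highest position, then a canonical label key — which is exactly
"cut the most penalised links first" and is independent of input order
and node numbering. For transition-only data the penalty is the
mutation count, so the resolved tree attains the minimum length over
all cycle resolutions (verified against exhaustive enumeration in the
tests). Components over the same 16-link bound fall back to a greedy
reverse-delete that preserves observed connectivity. Rooting uses a
designated outgroup: either a haplotype or a haplogroup's ancestral
motif (e.g. the L3 state for N-clade trees).

## Dating

ρ is the multiplicity-weighted mean root-to-tip mutation count; σ is
Saillard's standard error, σ² = Σₑ (nₑ/n)² ℓₑ. Sampled haplotypes that
sit at internal nodes (including the root) count as tips at their own
depth. Calibration is linear by default at 3624 years per substitution
for complete mitogenomes; a polynomial-in-ρ correction (for
purifying-selection-adjusted clocks) can be supplied through
configuration rather than hard-coded coefficients. CIs are
(ρ ± 1.96σ) × rate with the lower bound clamped at 0 and the clamp
logged. Age comparisons use z = |ρ₁−ρ₂|/√(σ₁²+σ₂²) against the normal
reference distribution, treating the σ's as known standard errors; the
literature's "t-test" phrasing never states degrees of freedom, so the
normal reference is the documented choice here.

## Route model and concordance

The route model is linear in longitude only — latitude is ignored by
construction, matching how the west-to-east dispersal axis is framed —
between the Djibouti L3 anchor (43°21´E, 70.8 ky, CI 52.7–88.1) and the
Darwin S anchor (130°50´E, 46.8 ky, CI 37.0–56.9); anchor CI bounds are
interpolated into the model band. One tested haplogroup is one
"pair" (model versus observation at one longitude): concordant iff the
closed CI intervals overlap; τ is normalised by the number tested.
Pearson r and its two-sided p relate longitude to the observed point
ages. The center of gravity of a haplogroup's presence/absence range is
the crossing of its extreme-latitude and extreme-longitude segments,
with a logged bounding-box-center fallback when they do not cross
(degenerate ranges, e.g. collinear points).

Recomputing τ and r from the packaged route tables gives values that
differ from the correlation coefficients printed alongside those tables
(whose exact point sets and pairing are unstated);
this package reports its own statistics and treats only the expected-age
column — pure anchor interpolation — as reproducible, within ±0.2 ky.
Two rows of the northern table (X and A) deviate from pure longitude
interpolation by more than that and are excluded from the checks.

## Synthetic data

The generator emulates the statistical structure the dating and route
stages assume, with known ground truth:

* **Topology.** Yule (pure-birth) trees conditioned on the tip count,
  epoch durations Exp(k) with k lineages, rescaled so the root age
  equals the configured TMRCA exactly — the tree is ultrametric, so the
  expected ρ is TMRCA/rate by construction. No demographic model is
  implied beyond that; real clades under growth or structure have
  different coalescent-time profiles.
* **Mutation.** Per-branch Poisson(branch-years/rate) events, sites
  uniform on the configured rCRS interval, transition:transversion odds
  22:1 (a realistic mtDNA bias), and a repeat hit at a mutated site
  reverts it — a two-state site model that deliberately allows
  recurrent mutation so reticulation handling is exercised. Rate
  heterogeneity across sites (real hotspots) is not modelled.
* **Geography.** Clades are placed along the Djibouti–Darwin longitude
  span, oldest westmost in concordant mode or permuted in null mode.
* **Seeding.** One mandatory seed; each stage draws from its own child
  stream of the seed sequence, so no generator state is shared between
  operations and runs are reproducible bit-for-bit.

The defaults (30 tips, 50-ky TMRCA, 3624 y/sub, full-genome interval)
are the conditions of the recovery checks: 500 replicates of the full
simulate → evolve → network → resolve → date chain must cover the true
TMRCA in 90–99% of the 95% CIs and put mean ρ within 3 Monte-Carlo
standard errors of TMRCA/rate. Passing shows the chain is unbiased and
correctly calibrated *under its own assumptions*; it does not validate
the clock calibration, the Yule assumption, or motif quality on real
data.

The null-geography fixture is calibrated analytically, not by trial:
with observed ages on the model line at their true longitudes, a
shuffled clade is concordant iff |Δage| ≤ w_obs + w_band, and for
uniform longitudes P(|ΔU| ≤ t) = 2t − t² over the unit span; setting
this to ½ gives w_obs + w_band ≈ 0.293 × (age span) ≈ 7.0 ky for the
24-ky anchor drop, split as ±2 ky observed CIs and a ±5 ky model band.
That closed form is why τ averages near zero over longitude shuffles.

## Degenerate inputs and edge cases

Empty haplotype sets, inconsistent coverage, unreachable outgroups,
empty classification trees and sub-minimal route tables raise typed
errors rather than returning partial results; the CLI maps validation
failures to exit code 1 and runtime failures to 2. Zero-width CIs are
legal in the concordance test (closed-interval overlap); constant ages
make the Pearson correlation undefined and are reported as NaN rather
than warned from inside scipy. Identical haplotypes condense into one
network node carrying their multiplicity, and a clade whose members all
equal the root haplotype dates to age 0 with a zero-width CI.

## Known limitations

* The packaged reference and haplogroup fixtures are synthetic
  stand-ins (true coordinates and topology, placeholder content); real
  analyses must supply the genuine rCRS and motif set.
* Exact network pruning/resolution is bounded at 16 links per
  biconnected component; beyond that the greedy fallback is
  order-deterministic but not guaranteed minimal.
* The two-state mutation model ignores site-rate heterogeneity, so
  synthetic homoplasy is rarer and more uniform than in real
  control-region data.
* The route model is one-dimensional in longitude; great-circle or
  least-cost-path geography is out of scope.
* Classification is deterministic motif counting, not probabilistic
  placement; samples typed only at a few coding SNPs in the wet lab
  cannot be re-derived computationally.
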