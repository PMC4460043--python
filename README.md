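# mtroute

A tested, reusable pipeline for mtDNA haplogroup phylogeography: it takes
rCRS-relative haplotypes (or sequences), assigns them to haplogroups by
diagnostic motifs, builds median-joining networks per clade, dates clades
with the rho statistic, and tests whether clade ages decrease along a
geographic route — the workflow used to weigh dispersal-route hypotheses
such as the southern-coastal versus northern-Asian routes of the modern
human expansion out of Africa, as read from macrohaplogroup N(xR)
lineages.

## Who it is for

Population geneticists and students working with mtDNA control-region or
mitogenome surveys who want the classic founder-analysis toolchain —
HaploSearch-style haplotype/sequence conversion, PhyloTree-style motif
classification, Network-style median-joining graphs, rho/sigma dating —
as one scriptable, reproducible Python package instead of a chain of GUI
tools and by-hand steps.

## The statistics at the core

* **rho dating.** For a clade with root haplotype *r* and *n* sampled
  tips, ρ = (1/n) Σᵢ mᵢ dᵢ, the mean number of mutations from root to
  tip (tips weighted by multiplicity mᵢ). Its standard error follows
  Saillard's estimator, σ² = Σₑ (nₑ/n)² ℓₑ over edges *e* with ℓₑ
  mutations and nₑ sample lineages below. A molecular clock converts
  mutations to years; the default linear calibration for complete
  mitogenomes is 3624 years per substitution, and age CIs are
  (ρ ± 1.96σ) × rate, floored at zero.
* **Median-joining networks.** Haplotypes are binary vectors over
  observed variants; median (Steiner) vectors of close triplets are
  added under an ε-relaxed minimum-spanning criterion until stable, and
  a maximum-parsimony pass prunes links no minimum-length solution uses.
  Homoplasy survives as reticulation cycles, which a deterministic
  weight policy (transversions/indels over transitions, then
  hypermutable sites, then position) cuts into a rooted tree — a
  reproducible replacement for the traditional by-hand resolution.
* **Route concordance.** A route model interpolates clade age linearly
  in longitude between a western anchor (L3 at Djibouti, 70.8 ky) and an
  eastern anchor (S at Darwin, 46.8 ky), with the anchors' 95% CIs
  interpolated into a band. A clade at its center-of-gravity longitude
  is *concordant* when its age CI overlaps the band; τ =
  (concordant − discordant)/tested, reported with a Pearson correlation
  of longitude versus age.

## Worked example

```python
import mtroute as mt
from mtroute.pipeline import simulate_and_date

# simulate a 30-tip clade with a known 50-ky TMRCA, then recover it
cfg = mt.SimConfig(seed=42, n_tips=30, tmrca_years=50_000.0, rate=3624.0)
est, truth = simulate_and_date(cfg)
print(f"rho = {est.rho:.3f}  sigma = {est.sigma:.3f}")
print(f"age = {est.age_years/1000:.1f} ky  95% CI ({est.ci95_years[0]/1000:.1f}-{est.ci95_years[1]/1000:.1f})")

# the published route tables against the Djibouti/Darwin anchor model
model = mt.route_model_from_observations(mt.packaged_route_table("southern"))
res = mt.concordance_test(mt.packaged_route_table("southern"), model)
print(f"southern route: {res.n_concordant} concordant / {res.n_discordant} discordant, "
      f"tau = {res.tau:.2f}, Pearson r = {res.pearson_r:.2f} (p = {res.pearson_p:.3f})")
```

prints

```
rho = 11.833  sigma = 1.641
age = 42.9 ky  95% CI (31.2-54.5)
southern route: 4 concordant / 5 discordant, tau = -0.11, Pearson r = -0.15 (p = 0.709)
```

The simulated clade's true 50-ky age falls inside the recovered CI. On
the southern-route table the observed clade ages sit mostly below the
serial-founder expectation (five of nine CIs miss the band), i.e. the
southernmost N(xR) clades are too young for a simple west-to-east age
gradient — the pattern the route analysis is designed to expose. τ and
r here are this package's own recomputation from the published tables
and differ from the correlation values printed alongside those tables,
whose exact inputs are not stated.

The same stages are available from a shell:

```bash
mtroute simulate --config sim.yaml --out-table haps.tsv --out-truth truth.json
mtroute classify --table haps.tsv --out calls.tsv
mtroute network  --table haps.tsv --outgroup N --out tree.nwk
mtroute date     --tree tree.nwk --clade N7 --calibration linear:3624
mtroute route-test --table route.tsv
mtroute run      --config run.yaml     # full pipeline with a manifest
```

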