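# motifweb

Food-web **motif analysis along plant-diversity gradients**: build plot-level
probabilistic food webs from a trophic metaweb plus local abundances, census
the 13 connected three-species motifs, benchmark their frequencies against
degree-preserving null webs, and model motif counts and representation scores
along a sown plant-richness gradient.

The package is aimed at community ecologists working with grassland
biodiversity experiments (replicated plots sown with 1–60 plant species,
arthropod consumers sampled per plot and season) who want to ask how plant
diversity reshapes the *local interaction structure* of food webs rather
than just their species counts.

## The method

**Web construction.** A metaweb lists all plausible feeding links
(resource *i* → consumer *j*), each tagged with an evidence type 1–5
(specific literature record, generalised record, trophic-guild rule,
trait-based rule, combined trait rules). On a plot, the probability that a
supported link is realised is `A_ij = N(i,j) · T_ij` with `T_ij = 1` on the
metaweb support and encounter probability

    N = 1                       (type 1; and types 2–3 when the resource is a
                                 consumer or a ubiquitous static resource)
    N = min(1, α · n_i · n_j)   (types 2–3, plant resource)
    N = min(1, β · n_i · n_j)   (types 4–5, predator–prey)

where `n` is relative plant cover or within-stratum relative consumer
abundance, and α, β are encounter scalars. Each plot-period matrix is
sampled 50 times into binary webs; degree-0 nodes are dropped.

**Motif census.** Excluding cannibalism, three nodes form 13 connected
directed triad classes: s1 (tri-trophic chain), s2 (omnivory), s3 (loop),
s4 (apparent competition), s5 (exploitative competition) and d1–d8 (classes
with double links). The census is *induced*: each unordered triple counts
toward exactly one class, so an omnivory triple is not also a chain.
Free-floating motifs (no basal node) are counted on the consumer sub-web.

**Null-model benchmarking.** Each sampled web is rewired with the Curveball
algorithm (exchanging exclusive resources between two consumers), which
preserves every node's in- and out-degree exactly. Against an ensemble of
rewired webs the representation of motif *i* is

    z_i = (X_i − X̄_i) / σ_i,        n_i = z_i / √(Σ_j z_j²)

and the unit-norm profile `n` lets webs of different sizes be compared.

**Trend analysis.** Motif counts (log(x+1)) and normalised scores are
modelled against log2(sown richness) with linear mixed models (random
intercepts: time period, block, plot within block; *n* = 320 plot-periods).

A synthetic community generator produces experiment-shaped data (species
pools, rule-based metawebs, 80 plots × 4 blocks × 4 periods, saturating
realised richness, guild-structured colonisation), so the entire pipeline
runs self-contained.

## Worked example

```python
from motifweb import (GeneratorConfig, ScalarConfig, build_probabilistic_web,
                      profile_pipeline, generate_community, MOTIF_CODES)

cfg = GeneratorConfig(global_seed=0, n_consumers=150)
nodes, metaweb, design = generate_community(cfg)
sample = max(design.samples, key=lambda s: s.sown_richness)  # a 60-species plot
pweb = build_probabilistic_web(sample, nodes, metaweb,
                               ScalarConfig(alpha=5000, beta=100))
full, free = profile_pipeline(pweb, iterations=50, R=50, global_seed=0)
for cls in ("s1", "s2", "s4", "s5"):
    i = MOTIF_CODES.index(cls)
    print(f"{cls}: mean count full={full.counts[i]:7.1f} "
          f"free-floating={free.counts[i]:6.1f} "
          f"normalised score={full.n[i]:+.3f}")
```

prints

```
s1: mean count full=  104.3 free-floating=   8.2 normalised score=+0.332
s2: mean count full=   12.7 free-floating=   4.2 normalised score=-0.042
s4: mean count full=  421.0 free-floating=  30.5 normalised score=+0.294
s5: mean count full=  215.8 free-floating=  13.0 normalised score=+0.167
```

i.e. on this species-rich plot the web holds ~750 connected triads per
sampled iteration, apparent competition (s4) is the most frequent motif,
chains and both competition motifs are over-represented relative to the
degree-preserving null (positive normalised scores), and most motifs are
grounded — only a small fraction survives on the consumer sub-web.

The same analysis for a whole experiment, from the command line:

```bash
motifweb simulate --out data/            # synthetic community tables
motifweb run --config cfg.yaml --seed 1  # webs → census → nulls → profiles → trends
```

`motifweb build/census/null/profile/analyze` expose the individual stages on
TSV files; every run writes a `manifest.json` with config, seeds and output
hashes for exact reruns.

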