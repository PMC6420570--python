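# Methods

This note documents the models implemented in `motifweb`, the parameter
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
compute.

## Probabilistic web construction

A plot-period web starts from the metaweb restricted to locally co-occurring
nodes: plants with nonzero cover, consumers with nonzero counts, and all six
static basal resources (detritus, moss, algae, fungi, dung, carrion), which
are treated as ubiquitous. Interaction probabilities combine the trait-based
support (`T_ij = 1` iff the metaweb contains the link) with an
abundance-dependent encounter probability that depends on the link's
evidence type and the resource's role (see README for the formulas).

Assumptions worth making explicit:

* **Clipping.** `α·n_i·n_j` and `β·n_i·n_j` can exceed 1; they are clipped,
  since `A` is a probability. Clipping means sufficiently abundant pairs are
  certain to interact, which is the intended reading of the encounter model.
* **Relative abundances.** Plant `n_i` is cover renormalised over the plants
  present on the plot-period. Consumer `n` is computed separately within the
  ground and herb strata; a species using both strata enters both totals and
  receives the mean of its two shares. In a monoculture the single plant has
  `n = 1`, so plant–consumer encounter probabilities are systematically
  higher per plant at low richness — a structural feature of the model, not
  an artefact.
* **Static resources** carry no abundance; their links are governed entirely
  by the type-2/3 rule (probability 1).
* **Higher-order effects** on interaction probability (environment,
  modification by third species) are fixed at zero; the model is strictly
  pairwise.

Binary webs are sampled independently per potential link; nodes left with
degree 0 are removed (a single pass suffices — removing an isolated node
cannot isolate another). Per-iteration seeds derive deterministically from
(global seed, plot, period, iteration), so any single web can be
regenerated in isolation.

## Encounter scalars α and β

`calibrate_scalars` reproduces a generality-based calibration: over a grid
of (α, β) it picks the pair whose median omnivore generality (resource taxa
per omnivore in sampled webs) is closest to a target of 30, ties broken by
the smaller α then β. On the synthetic pools the median saturates near
16–18 once β is large and is almost insensitive to α (omnivore plant-side
diets are small compared to their animal-side diets), so the procedure
alone cannot pin the pair.

The pipeline defaults are therefore a documented package choice:
**α = 5000, β = 100**. With these values plant–consumer links are near
certain for dominant plants and still likely for subordinate ones, while
predator–prey links remain genuinely probabilistic (typical probabilities
0.05–0.5). Under these defaults the generator's webs fall inside a
plausible size envelope for well-resolved grassland webs (tens of species,
hundreds of links), the total motif count rises with sown richness, and the
grounded share of each common motif is larger on species-rich plots —
the qualitative structure the pipeline is designed to detect. Both scalars
are ordinary config keys; the sensitivity scenario
(`diversity_scaled_scalars`) additionally lets β decline linearly with sown
richness to emulate prey refugia in denser vegetation.

## Motif census

The 13 connected triad classes are derived at import time by enumerating
all 64 labelled 3-node digraphs and canonicalising over the 6 node
permutations; a frozen mapping to the conventional 16-type triad
nomenclature is shipped (`MOTIF_TO_TRIAD`) and cross-checked against
networkx in the tests. The `d1–d8` ordering sorts the double-link classes
by (number of mutual dyads, number of single links):
111D, 111U, 120D, 120U, 120C, 201, 210, 300.

Counting is *induced*: each unordered triple contributes to exactly one
class, the one matching its full induced subgraph, so denser motifs absorb
the sparser ones they contain. The production path classifies only triples
containing at least one linked dyad (linked-dyad enumeration with the
disconnected remainder obtained by subtraction), compiled with numba; the
tests verify exact equality with per-triple brute force and with networkx's
independent census on random graphs.

Free-floating counts are taken on the consumer sub-web (basal nodes and
their incident links removed, then degree-0 consumers dropped) of the *same*
sampled iteration as the full-web counts, so grounded fractions
`(full − free)/full` are internally consistent. Reported counts are means
over the sampling iterations (default 50).

## Null model and representation profiles

Null webs are produced by Curveball trades on the consumers × resources
incidence view: two consumer rows exchange a random subset of their
exclusive resources, preserving all row and column sums — hence species
number, link number, connectance, every degree, and the impossibility of
basal nodes acquiring prey. Columns equal to either traded row index are
held fixed within a trade so no cannibalistic link can appear; margins are
unaffected.

Each ensemble member restarts from the observed web with an independent
seed (no chain autocorrelation). The default trade count is
`max(5 × consumer rows, 50)`; the factor-5 heuristic alone under-mixes very
small matrices (verified by chi-square against the exhaustively enumerable
set of 4×4 matrices with all margins 2), hence the floor. Both knobs are
exposed (`trades_factor`, `n_trades`).

z-scores use the ensemble mean and population SD per class. Degenerate
classes (σ = 0) score 0 when the observed count equals the null mean;
otherwise the difference is scaled by the smallest nonzero σ in the
ensemble (or 1 if none), keeping the direction finite, and the occurrence
is counted in a `flags` field. Profiles are normalised to unit Euclidean
norm *per iteration* and then averaged over iterations (normalise-then-
average, matching per-web normalisation); the Monte-Carlo SE of the mean
normalised score is reported alongside. Each iteration's full web and
consumer sub-web get their own independent ensembles.

## Synthetic community generator

The generator emulates the *shape* and the documented marginal patterns of
a sown-diversity grassland experiment:

* **Plant pool:** 60 species in four functional groups (16 grasses, 12
  small herbs, 20 tall herbs, 12 legumes), nested into families.
* **Consumer pool:** 403 species by default — 20% detritivores, 38%
  herbivores, 12% omnivores, 30% predators — with guild-specific lognormal
  body lengths (mm) and strata (ground/herb/both).
* **Metaweb rules:** monophagous herbivores (15%) get one type-1 plant
  link; oligophages (50%) a type-2 family; the rest a type-3 functional
  group. Detritivores eat 2–4 static resources (types 2–3). Predators eat
  consumers whose body length falls in 0.15–1.2× their own and whose
  stratum is compatible (type 4 when only the size rule binds, type 5 when
  stratum also binds). Omnivores combine a plant/static side with a
  narrower predatory window. `validate_pool` re-checks every link against
  these rules independently.
* **Design:** 80 plots in 4 blocks (per block 4,4,4,4,3,1 plots at sown
  richness 1,2,4,8,16,60), 4 time periods — 320 plot-period records.
* **Realised richness** thins the sown set with survival
  `1/(1 + 0.01386·(sown − 1))`, giving ≈ 33 realised species at sown 60 and
  no thinning in monocultures; covers follow a geometric rank-abundance
  series (decay 0.1) scaled to total cover 0.8.
* **Colonisation** is logistic in the fraction of a consumer's metaweb diet
  present locally, staged up the trophic hierarchy (detritivores/herbivores,
  then omnivores, then predators), with guild intercepts and slopes
  (−0.8/0, −4.8/6, −0.8/1.2, −3.8/4.2) chosen so herbivore richness
  responds to plant richness more steeply than predator richness and the
  omnivore share declines along the gradient. A species with none of its
  diet present cannot colonise. Counts are lognormal (meanlog 2, sdlog 1.2).

What the generator does **not** emulate: real taxa and their phenology,
spatial block structure beyond labels, within-season turnover,
weather/soil covariates, observation error in cover estimates, and any
calibration to actual field abundance distributions. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
documented qualitative gradients emerge under the stated mechanism — not
that the field system's coefficients are reproduced.

## Trend models

Responses are modelled with `statsmodels` MixedLM using variance components
for time period, block, and plot (the one-group trick for crossed random
intercepts). The fixed effect is log2(sown richness), reflecting the
doubling design; a linear option is retained. Counts are log(x+1)
transformed (zeros occur for the rare classes); normalised scores enter
untransformed. Classes whose response is constant (typically all-zero
d-classes) are skipped and listed rather than modelled.

p-values default to a two-tailed Wald normal approximation on the slope —
with n = 320 and ~236 residual degrees of freedom the difference from a
t/Satterthwaite reference is immaterial — and a likelihood-ratio test
(`pvalue_method="lrt"`, ML refits) is available. When the full random
structure cannot be fitted, the structure is downgraded stepwise
(period+block/plot → period+plot → plot → OLS) with a warning, and the
structure actually used is recorded in the result.

## Problem sizes used in the shipped checks

The acceptance-style checks run the full 80 × 4 design with a reduced
consumer pool (150 species), 50 sampling iterations and 50 null webs per
iteration and scope — sizes at which the complete run takes a few minutes
on one CPU while exercising every stage at experiment scale. The
acceptance script uses 20 iterations × 30 null webs for its gradient
summary and a 4×4 margin class for the exhaustive uniformity check. Slope
recovery uses 60–100 replicates and the type-I-error check 120–200
replicates of the 320-record design.

## Known limitations

* The census is exact but the profile machinery is Monte Carlo; with 50
  iterations the SE of mean normalised scores is reported, not removed.
* The σ = 0 z-score convention is a pragmatic finite-direction rule; rigid
  tiny webs (few rewirable links) should be interpreted via the `flags`
  count.
* Curveball mixing is assessed empirically on small matrices; for very
  large, very sparse webs the default trade count is a heuristic, and
  `trades_factor` should be raised for formal convergence studies.
* The mixed models assume Gaussian responses; log(x+1) counts with many
  zeros (rare classes) are excluded rather than modelled with a count
  family.
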