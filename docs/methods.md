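# Methods

## Scope and model

`netpharm` implements a network-pharmacology inference chain for
multi-arm treatment studies: differential-expression screening,
scored-interaction network construction, two-stage topological hub
selection, chemical-similarity target prediction, hypergeometric pathway
enrichment, treatment-reversal classification and herb-pair core-gene
intersection. All stages are deterministic functions of their inputs; the
only randomness in the package lives in the synthetic study generator.

## Differential expression

Inputs are assumed already log2-normalised, so the log2 fold change of a
contrast is the difference of arm means; no background correction,
probe collapsing or quantile normalisation is performed.

The per-gene location test defaults to the **pooled-variance (Student)
two-sample t-test**, with Welch available via `test="welch"`. At the
design's n = 3 replicates per arm the choice matters: the pooled test is
exact under the equal-variance null (empirical type-I ≈ 0.050 at nominal
0.05 in the package's own null simulations), while Welch's Satterthwaite
approximation is markedly conservative at such depths (≈ 0.035), which
distorts any calibration-sensitive downstream count. Equal within-group
variances are plausible here because arms are technical-scale replicate
groups of the same tissue; users with strong variance heterogeneity
should switch to Welch and accept the conservatism.

Screening uses strict inequalities — |log2FC| > 0.5 and p < 0.05 — so
boundary values are never called. The stricter |log2FC| > 1 dialect is a
parameter, not a code path. Raw p-values are used for screening by
design (matching common microarray practice for small designs); a BH
option exists but is off by default. Genes constant in both arms get
p = 1 when their means are equal, otherwise a variance floor of 1e-12
produces a finite, effectively-zero p rather than a division by zero.

QC views: average-linkage hierarchical clustering of samples on Euclidean
distance over a gene subset (samples pre-sorted lexicographically so
distance ties break deterministically toward the first pair), and PCA by
SVD of the gene-centred matrix with component signs fixed so the
largest-magnitude score is positive.

## Networks and hub selection

Networks are simple undirected graphs with a positive `combined_score`
per edge (the STRING dialect; treated as an opaque positive number).
Construction restricts the edge table to a gene set, takes the **median
combined score of the restricted edges** as the threshold, and keeps
edges scoring **≥** the median — the median edge itself survives, which
keeps the rule deterministic. Medians over an even count are the mean of
the two central values; this convention matters because the hub rules
hinge on strict comparisons against medians. Duplicate edges collapse to
their maximum score; self-loops are dropped.

The four topological features:

- degree — incident-edge count;
- betweenness — unnormalised shortest-path betweenness on the unweighted
  graph, endpoints excluded, each unordered pair counted once
  (normalisation is irrelevant because only the order relative to the
  median matters);
- closeness — Wasserman–Faust component-adjusted,
  ((r−1)/Σd)·((r−1)/(n−1)) with r reachable nodes including self, because
  the filtered networks are not guaranteed connected; the classic
  within-component formula is a config dialect; isolated nodes score 0;
- k-coreness — the largest k a node survives under iterative removal of
  degree-< k nodes.

Hub selection is two-stage: *hubs* have degree strictly above 2× the
median degree of all profiled nodes; *major hubs* are strictly above the
median of **all four** features. By default the four features for the
major-hub stage are recomputed on the hub-induced subnetwork (the stage
is meant to rank within the hub set); computing them on the parent
network instead is the `major_hub_scope="full_network"` dialect.

The candidate (disease-gene/drug-gene) network is assembled over the
union of four sets — disease-network hubs, known disease genes,
treatment-regulated genes, putative compound targets — with per-node
provenance tags. Unlike plain construction, union members without a
surviving edge remain as isolated nodes so provenance is never lost.

## Target prediction

The predictor is a similarity-transfer heuristic: for every
(compound, reference drug) pair with Tanimoto similarity ≥ 0.85 on
fixed-length binary fingerprints, the drug's annotated targets become
putative targets of the compound. Fingerprints are consumed as
precomputed bit strings (hex in files); no chemistry toolkit is required
or used. Per-herb profiles are unions over each herb's compounds and the
formula-level set is the union over herbs. No QSAR, docking or ADME
modelling is attempted.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) per pathway (so an overlap
of zero scores exactly 1), BH correction across all tested pathways.
The universe defaults to all genes annotated to any pathway in the
collection; pathway members outside the universe are dropped with a
count, and pathways emptied by restriction are removed. A q < 0.05 call
is the default significance rule and is configurable.

## Reversal and the herb pair

Reversal is classified per gene from two screened tables over the same
universe: genes not dysregulated in the disease model are *unaffected*;
dysregulated genes whose treatment contrast (treatment vs model) moves
strictly in the opposite direction are *reversed*; everything else —
unresponsive or pushed further the same way — is *not reversed*. The
deleted-herb arms are contrasted **against the full formula**: a gene
dysregulated in that contrast responds differently when the herb is
absent, i.e. its reversal depends on the herb. Genes dysregulated in
both deleted-herb contrasts form the herb pair's core regulating genes.
The same (0.5, 0.05) screening thresholds are reused for these contrasts.

The known-disease-gene list ships as two plain-text fixtures (three
FDA-approved goiter drug targets from DrugBank; eight disease genes from
KEGG entry H00251) whose de-duplicated union is ten genes, with thyroid
peroxidase (TPO) tagged by both sources.

## The synthetic study generator

The generator emulates the five-arm goiter study design the package is
modelled on: arms control/model/full/minus_a/minus_b at **3 replicates**
each (the generator exposes `n_per_arm` for power studies; the emulated
study pooled RNA per group but clusters three samples per arm, and the
generator assumes three independent replicates).

Defaults, chosen once as the study conditions:

- 500 genes, per-gene baselines N(8, 1.5²) log2 units, noise sd 0.4;
- 50 disease genes shifted ±2.0 log2 units in the model arm, half up and
  half down so both DEG directions are exercised;
- the full formula returns 90% of disease genes to baseline; each
  deleted-herb arm only 30%, drawn as a subset of the full-formula
  reversals so `minus ⊆ full ⊆ disease` holds for every seed;
- 60 off-module drug-affected genes shifted identically in every treated
  arm — multi-component treatments regulate far more genes than the
  disease module, and without them the candidate network would consist
  almost solely of disease genes and degenerate under median filtering;
- a genome-wide preferential-attachment interaction backbone
  (attachment 3) with integer scores uniform on [150, 999]; the planted
  hub module is a 10-gene clique (hubs drawn from the full-formula
  reversals) with 25 extra spokes per hub and one extra neighbourhood
  edge per non-hub disease gene, and every module edge (hub-incident or
  disease–disease) has its score boosted by 300 (capped at 999) so the
  module survives median filtering with degree well above 2× the median;
- 20 pathways of 15–40 genes, one planted with ~70% of its members drawn
  from the disease genes;
- 30 compounds over the formula's eleven herbs, 1024-bit fingerprints at
  density 0.1; half the compounds carry planted targets and a matched
  reference drug sharing 95% of their set bits with an equal bit count
  and disjoint remainder, giving Tanimoto s/(2−s) ≈ 0.905 — above the
  0.85 transfer threshold; the other reference drugs are random decoys
  (expected decoy Tanimoto p²/(2p−p²) ≈ 0.053).

Each artifact draws from its own RNG stream, seeded as
(master seed, stream offset), so generating an additional artifact never
perturbs an existing one and identical configs are byte-reproducible.

What the generator does **not** emulate: probe-level physics, dye bias,
normalisation artefacts, correlated noise between genes, score
distributions of real interaction databases (real combined scores are
heavily right-skewed; the generator's are uniform), or annotation bias
in pathway membership. Passing recovery tests therefore demonstrates
that the inference chain is correct and well-calibrated under its own
assumptions, not that it would reach the same operating point on real
arrays.

## Numerical and degenerate-input choices

- Strict inequalities throughout the screening and hub rules; ties fall
  on the conservative side (not selected).
- An empty restricted edge set yields an empty network with a warning,
  not an error; empty gene-set unions and empty topology profiles are
  errors.
- Tanimoto is undefined for two all-zero fingerprints and raises.
- Hypergeometric inputs are validated against 0 ≤ k ≤ min(n, K) ≤ N.
- The two-stage hub recovery is a stochastic property of a study draw:
  under the default conditions it reaches Jaccard ≥ 0.5 against the
  planted module in roughly 9 of 10 seeds (both for the disease network
  alone and end-to-end), and single seeds can fail outright when the
  filtered hub subnetwork happens to be metric-degenerate (e.g. uniform
  k-coreness, where a strict above-the-median rule selects nobody).
  Tests and the acceptance script therefore assert rates over many
  seeds, not single draws.

## Problem sizes used by the test and acceptance runs

Unit tests run on a reduced scenario (120 genes, 5 planted hubs);
recovery rates are measured over 100 seeds at the default conditions in
the acceptance suite and over 40 seeds in `scripts/acceptance.py`; the
null type-I rate uses 1000-gene null studies (100 seeds in the suite,
20 in the script). Graph-metric exactness is checked against a
brute-force all-pairs enumeration oracle on 200 random graphs of ≤ 12
nodes, and hypergeometric tails against literal enumeration of all draws
for universes up to 15 genes.
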