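# Methods

## The model

DERA (differentially expressed regulation analysis) asks, for every tumor
sample separately, which edges of a prior signed regulatory network are
*expressed consistently* in that sample, and then which of those
sample-specific findings recur across a phenotype group.

The pipeline has four stages.

**1. Prior network.** A set of regulations — directed signed edges
(source gene, effect ∈ {activation, inhibition}, target gene) — read from a
plain-text edge list. The package treats gene identifiers as opaque,
case-sensitive strings; harmonising symbols across data sources is a
data-cleaning task upstream of the method. Duplicate triples are collapsed;
a gene pair carrying both effects is kept as two distinct regulations and
each is evaluated independently (curated databases do contain both).
Self-loops are permitted: a self-activation fires whenever its gene is
differentially expressed, while a self-inhibition can never be
sign-consistent and is reported once as structurally dead.

**2. Gene-activity indicator.** For gene *i* and tumor *j*, the log2 fold
change is

    fc_ij = x_ij − mean_k(y_ik)

where x is the tumor expression, y the expression in the reference
(control) samples, all on the log2 scale. The ternary indicator is

    +1  if fc_ij ≥ log2(K)     (over-expressed)
    −1  if fc_ij ≤ −log2(K)    (under-expressed)
     0  otherwise              (unchanged)

with K = 2 by default (a two-fold change). Two conventions are deliberate
and documented rather than implied: the subtraction runs tumor-minus-
reference so that over-expression is positive — this is the direction the
indicator semantics require — and the boundary is inclusive ("at least a
K-fold change"). Missing measurements propagate to a missing fold change
and an indicator of 0: a gene that was not measured never supports a
regulation. Mean-centering of gene rows (offered in preprocessing) cannot
change any indicator, because the fold change subtracts the reference mean
and cancels any per-gene constant; the property-test suite asserts this.

**3. Sample-specific regulation networks.** A regulation (A, B, effect) is
kept for a sample iff both genes are differentially expressed and their
signs match the effect: activation requires equal states, inhibition
opposite states. The retained unit is a *regulation instance* — the edge
plus its concrete sign pattern — so the same edge seen as (+1, +1) in one
sample and (−1, −1) in another yields two distinct instances that are never
merged. Network genes absent from the expression matrix have state 0 (a
counted warning, not an error or silent inflation).

**4. Core regulations.** Within a phenotype group, an instance is *core*
when its frequency across the group's sample networks is at least T. The
denominator is the whole group including samples with empty networks
("T% of the total number of samples"), and the comparison is inclusive.
T = 0.5 is the standard discovery setting; T = 0.4 is the usual relaxation
for small or heterogeneous validation cohorts, passed explicitly rather
than hard-coded. Core sets decompose into *subnetworks*: connected
components of the undirected graph on genes whose edges are the core
instances' regulations. Component labels are contiguous integers assigned
by decreasing gene count (ties: lexicographically smallest member gene),
so the count of instances and the count of subnetworks are both
well-defined summaries of one core set.

Group comparison is a set difference at the instance level: an edge
up-regulated in the target group and down-regulated elsewhere *is* a
group-specific finding; collapsing to edges would hide it (an edge-level
mode is available behind a flag). Cross-cohort validation computes the
validation cohort's core set at its own threshold and intersects with the
discovery core; composing several validation cohorts ("validated in one or
both") is explicit caller logic via set union/intersection. A regulation's
expression score in a sample is the sum of its two genes' log2 fold
changes; no significance measure is attached to core regulations — the
method defines none.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| K (`cutoff`) | linear fold-change threshold | 2.0 | must exceed 1; applied as log2(K) on log2 data |
| T (`threshold`) | core prevalence threshold | 0.5 | in (0, 1]; 0.4 conventional for validation |
| `reference_label` | phenotype token marking controls | `REFERENCE` | |
| `collapse` | multi-probe-per-gene summary | mean | median/max available; probe filtering removes multi-gene and unmapped probes first |

## The synthetic-data generator

`dera.synthetic` emulates the data the method consumes: a random simple
directed network (default 30 genes, 50 edges, 30 % inhibitory), log2-scale
expression for reference samples and phenotype groups, and planted
regulation instances. Every entry is baseline (7.0) plus independent
Gaussian noise (SD 0.3 log2 units, the scale of replicate scatter on
log-intensity arrays). A planted instance activates per sample as an
independent Bernoulli(p) event, shifting its source and target genes by
±2.0 log2 units according to the planted sign pattern. With that effect
size and noise, an active gene clears the two-fold cutoff with probability
> 0.999 (the margin is 1.0 log2 unit ≈ 3.2 noise SDs, and averaging over
10 references adds little), so observed instance prevalence tracks the
nominal p; a noise-only gene crosses the cutoff with probability ≈ 7e-4.

For recovery experiments the planting helper draws high-prevalence edges
whose genes touch no other network edge. This matters: two independently
planted instances at prevalence 0.7 are co-active in ~49 % of samples, so
an un-planted edge joining their genes would cross T = 0.5 in a large
fraction of cohorts and the "ground truth" would not be the truth. Decoy
(low-prevalence) edges only need vertex-disjointness, since their joint
activation rates with neighbours are far below any threshold in use.
Topologies that cannot host the requested planting are redrawn
deterministically. All randomness flows from one seed through fixed child
streams (topology, planting, expression), so regeneration is bit-exact;
the network seed is pinned separately so that independent cohorts (new
expression seed) share their network and planted truth.

What the generator does **not** emulate: correlated co-expression beyond
the planted edges, batch or dye effects, count noise of RNA-seq, probe-
level artifacts. Passing recovery tests therefore show the *logic* of the
pipeline is exact under its own assumptions — they say nothing about how
often real cohorts satisfy those assumptions.

## Numerical and design choices

- Discretization is exact integer arithmetic after one floating
  subtraction; no tolerances are involved anywhere in the pipeline, which
  is why the oracle-equivalence tests can demand exact set equality.
- NaN handling: row means and reference means are computed over observed
  entries; NaN fold changes discretize to 0.
- Empty results are states, not errors: a gene-restricted network or a
  core set may be empty and every downstream operation accepts that. The
  only hard input errors are malformed files, unknown identifiers,
  non-positive values under log2, and thresholds outside their domain.
- Deterministic output ordering everywhere (rows sorted by source, target,
  effect, source state); two runs on identical inputs produce
  byte-identical files.
- The estimator layer follows the scikit-learn contract: samples × genes
  orientation, `fit`/`transform`, trailing-underscore fitted attributes,
  `get_params`/`clone` compatibility. The functional layer keeps the
  field's genes × samples orientation used by the file formats; the
  estimators transpose at the boundary.

## Problem sizes used by the test and acceptance runs

Oracle-equivalence checks run on 100 random problems of up to 50 genes,
80 edges and 25 samples. Recovery runs use cohorts of 40 tumors and 10
references over 30-gene/50-edge networks (5 planted shared instances at
p = 0.7, 5 decoys at p = 0.2); the four-group comparison uses 150-gene/
130-edge networks with 30 samples per group (10 shared + 5 private
instances per group at p = 0.8); cross-cohort validation pairs two cohorts
from the same spec with independent expression seeds (discovery T = 0.5,
validation T = 0.4). These sizes give every planted instance a miss
probability below ~2.5e-3 per cohort, so exact recovery is the expected
outcome, while rare binomial tail events remain possible by construction
— they are reported as measured, never patched over.

## Known limitations

- Undirected (protein–protein interaction) edges have no defined
  consistency rule and are not supported.
- No symbol normalization, probe re-annotation, or platform
  normalization (RMA etc.); the package consumes normalized, log2-scale
  matrices.
- The frequency threshold is the method's only inferential device; there
  are no p-values, and survival or enrichment follow-ups are out of scope.
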