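# Methods

This note documents the models, conventions and design choices behind
`coregut`, in the order the pipeline applies them.

## Data model

The central object is an `OtuTable`: a samples × OTUs matrix of
non-negative integer read counts with aligned per-sample metadata
(animal, gut region, replicate) and an optional clustering-identity tag
(0.90/0.95/0.97/0.99). Counts stay integral until an explicit conversion
to relative abundance, because subsampling without replacement and Good's
coverage are defined on integer reads. The eight admissible regions carry
an anatomical grouping used throughout: the terminal ileum stands apart;
caecum, right and left ventral colon form the proximal large intestine;
right dorsal colon, small colon and faeces the distal large intestine;
the left dorsal colon is intermediate. Tables at different clustering
identities are independent objects — no cross-identity OTU mapping is
attempted, since none is defined.

Replicate subsamples are supported by the data model, but every analysis
operates on one sample per animal × region; `pool_replicates` sums
replicate counts into that granularity. Whether a given study sequenced
pooled or individual subsamples does not change the downstream
arithmetic, so the pooling utility covers both readings.

Taxonomy is a four-rank lineage (phylum, class, order, family) with the
sentinel `unclassified` allowed at any rank under a monotonicity
constraint: nothing may be classified below an unclassified rank. OTUs
missing from the taxonomy are treated as fully unclassified (with a
warning when they are core members).

## Low-count exclusion

Nonzero counts below `min_reads = 4` per animal × region sample are
likely artefacts of amplicon sequencing. The rule's natural-language
statement admits two readings, both implemented behind `FilterParams
.mode`:

* `zero_per_sample` (default): any cell with 1–3 reads is zeroed;
  OTU columns left empty are dropped. This preserves OTUs genuinely
  present elsewhere and matches the artefact-removal intent.
* `drop_global`: an OTU is removed outright if *any* sample holds a
  nonzero count below the threshold. This is the stricter reading; it
  discards region-specific taxa and is off by default.

The filter is idempotent in both modes.

## Even-depth normalisation (rarefaction)

Each sample is subsampled **without replacement** to a common depth — a
multivariate hypergeometric draw per row (`numpy`'s generator), seeded
and therefore bit-reproducible. The default depth is the minimum row sum
("the lowest number seen"); the emulated study's value is 3225 reads per
sample, i.e. 32 250 pooled reads per region across ten animals.
Consequences that the tests assert: row sums equal the depth exactly,
rarefied cells never exceed the originals, and across seeds the mean
rarefied count equals the hypergeometric expectation $n\,N_i/N$.
Sampling *with* replacement is rejected by design: it would break the
conservation and subsample properties. A sample shallower than the
target depth is a named error, never silently dropped.

## Diversity and the two-way ANOVA

Shannon–Wiener entropy is reported in **nats**; with ~700 OTUs the
index's ceiling is $\ln 700 \approx 6.55$, which is the scale on which
values near 5.5–5.9 for hindgut communities make sense. Simpson is
reported as the Gini–Simpson complement $1-\sum p_i^2$ by default
(values near 0.99 for even communities); the unbiased small-sample form
$1-\sum N_i(N_i-1)/[N(N-1)]$ is available since published tables rarely
state which was used. Good's coverage uses the singleton count on
integer reads, which is why it is computed after (or without)
normalisation but never on fractions. Rarefaction curves are computed
both analytically (log-gamma evaluation of the hypergeometric
expectation) and by seeded Monte-Carlo; the two agree within Monte-Carlo
error and the analytic form is the default.

Per-sample scalars are compared with the additive two-way model
$y = \mu + \text{region} + \text{animal} + \varepsilon$. With one
observation per cell the interaction is inestimable, so it is not in
the model; a complete layout is required and missing cells are an error
(no imputation). The fit and the type-II ANOVA table come from
`statsmodels`; Fisher's LSD
$t_{1-\alpha/2,\mathrm{df_{res}}}\sqrt{2\,\mathrm{MSE}/n_\text{animals}}$
and the compact letter display are implemented here (the sorted-means
sweep: maximal runs of levels whose extremes differ by less than the
LSD share a letter; exact ties always share). Degenerate inputs (all
values identical) yield a single letter and an undefined F ratio rather
than an error.

## Core community

An OTU is core to a region when

1. it is detected (≥ 1 read after normalisation) in at least
   $\lceil f \cdot A \rceil$ of the $A$ animals ($f = 1$ by default), and
2. its pooled count is at least $\theta = 0.1\%$ of the region's pooled
   normalised total (32 250 in the emulated design). The denominator is
   the *region's* pooled total, not per-animal totals. The abundance
   predicate can be switched off to obtain the prevalence-only core.

"Present" means detection, nothing more: normalisation has already
removed depth bias, so no per-animal abundance floor is applied. Both
predicates are monotone, so raising $\theta$ or $f$ can only shrink the
core — a property the tests exercise alongside an exhaustive-enumeration
oracle on small tables.

Core sizes across identity levels are rendered `"n_core/n_total (p%)"`
with the percentage rounded half-away-from-zero to one decimal; a
trim-trailing-zero option reproduces tables that print `(3%)` for 3.0.
The abundance profile lists each core OTU's share plus a non-core
remainder defined by subtraction on integer reads, so the segments
conserve the region total exactly.

Family-level summaries group core OTUs by their full four-rank lineage;
distinct partially-unclassified lineages stay separate (an unclassified
family within *Bacteroidales* is not the row of an OTU known only to be
*Bacteroidetes*). The abundance column is the pooled share of the
region's sequences (× 100); the dispersion column is the standard
deviation across animals of the per-animal family share — at even depth
the pooled share equals the across-animal mean, so the two columns are
mean ± s.d. in the usual sense. Family trajectories project these
summaries onto the fixed passage order caecum → RVC → LVC → LDC → RDC →
SC → faeces, with zeros where a family is absent from a region's core.

## Community structure

The heatmap analysis selects OTUs at ≥ 0.1% of the grand total and
clusters samples and OTUs agglomeratively. Since no sequences exist
downstream of a count table, the axis trees are abundance-profile
dendrograms, not phylogenies — the nearest computable structure to the
cladogram annotations such figures usually carry. Distances are
Bray–Curtis on relative abundances (default) or Euclidean on
log10(x+1); linkage is average (UPGMA) or complete, via
`scipy.cluster.hierarchy` (deterministic for a fixed input order, and
verified against a brute-force O(n³) agglomeration oracle). Dendrograms
export to Newick with ultrametric branch lengths (parent height minus
child height). Whether to log-scale the displayed abundances is a flag,
defaulting to log, since tabled counts span three orders of magnitude.

## Synthetic studies

The generator is the package's stand-in for raw survey data and defines
the conditions under which the pipeline is validated:

* **Design**: 10 animals × 8 regions, 4818 OTUs, per-sample depths
  uniform on [3225, 3800] — so the observed minimum matches the
  normalisation depth and rarefaction never fails on fixtures.
* **Regional signatures**: two contrasting lognormal signatures (sdlog
  1.5, ~85% occupancy) are mixed 0.9/0.1 for proximal regions, 0.1/0.9
  for distal ones and 0.5/0.5 for the LDC; the ileum has its own
  signature over a smaller OTU subset. This reproduces the
  proximal/distal split that two-way clustering should recover
  (the tests require adjusted Rand > 0.9 against the planted grouping).
* **Phylum composition**: per-region signature mass is tilted so planted
  phylum totals hit fixed targets — large intestine: Firmicutes 46%,
  Bacteroidetes 43%, minor phyla the rest; ileum: Firmicutes 70%,
  Proteobacteria 14%, Bacteroidetes 10%. Core slots carry
  field-realistic lineages (*Lactobacillaceae* dominating the ileal
  core; *Lachnospiraceae* and an unclassified *Bacteroidales* family the
  proximal; *Prevotellaceae* the distal).
* **Planted core**: each region's core OTUs are present in every animal
  with shares following a decreasing geometric profile (strongly skewed
  in the ileum, flat in the large intestine) above a per-OTU floor —
  0.6% in the large intestine, 1% in the ileum, i.e. 6–10× the 0.1%
  core threshold. The floor is a detectability margin: at depth 3225
  with per-animal lognormal jitter (sdlog 0.25) it puts the probability
  of a zero count in any animal near 2 × 10⁻⁷ per cell, so planted-core
  recovery at sensitivity 1 is a fair demand across 20 seeded studies.
  The consequence is that default core sizes per region (7–16) sit below
  the counts of the emulated survey while the core *totals* keep its
  pattern (large concentrated ileal core ≈ 32%; large-intestine cores
  5–15% spread over more OTUs).
* **Non-core OTUs** miss core status through one of two mechanisms, so
  both predicates are exercised: *rare* OTUs sit below θ/2 in the
  planted truth; *patchy* OTUs (any OTU at or above 0.45 θ, plus a
  random 30% of the rest) are structurally absent from 1–5 animals.
* **Counts** are multinomial per sample, conditional on the region truth
  × per-animal lognormal jitter × occupancy mask, renormalised; an
  optional Dirichlet concentration adds overdispersion for stress tests.
  Everything is a pure function of the seed.

Two consequences matter when reading validation results. First, the
per-animal renormalisation after occupancy masking means the *expected
observed* share of an always-present OTU exceeds its planted share (mass
of absent patchy OTUs is redistributed); oracle tests therefore compare
against the masked expectation computed from the emitted truth, and the
worked example's 39.5% observed ileal core versus 32% planted is this
effect, not a bias in the estimator. Second, phyla whose mass is mostly
core (immune to masking) drift a point or two above their planted
targets in observed composition.

What the generator does **not** emulate: sequencing artefacts (so
recovery tests run rarefy → identify-core without the low-count filter,
which models exactly those artefacts and would otherwise zero genuine
low-count core cells), chimeras, read-length or error profiles, true
phylogenetic correlation between OTU abundances, and any cross-identity
OTU lineage structure. Passing tests therefore demonstrate the
pipeline's statistical contracts under a faithful abstraction of the
study design, not performance on raw reads.

## Problem sizes

The test suite and acceptance script run full-study simulations
(80 samples × 4818 OTUs) — 20 seeds for core recovery — plus a
10 000-seed hypergeometric calibration on a 3-OTU row and a
100 000-replicate Monte-Carlo rarefaction check on a toy vector; these
sizes give stable 3-standard-error comparisons while keeping a full run
in well under a minute.

## Known limitations

* Published diversity tables and absolute core counts of the emulated
  survey depend on its raw sequence data (EBI SRA ERP002202) and are not
  reproduced here; the embedded reference tables support desk-checkable
  arithmetic only.
* The compact letter display uses the classic sweep, which can differ
  from graph-colouring CLD algorithms on pathological mean patterns.
* Bray–Curtis on rarefied counts inherits rarefaction noise; no
  variance-stabilising alternative (e.g. Aitchison) is offered because
  the emulated workflow does not use one.
* The BIOM reader covers the JSON (1.0) dialect only, dense or sparse;
  HDF5 BIOM is out of scope.
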