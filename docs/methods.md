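# Methods

`mqtlkit` implements a multi-study quantitative-genetics integration
pipeline for hexaploid bread wheat (and, via arbitrary chromosome labels,
any mapped organism): consensus genetic map construction from partially
overlapping marker maps, projection of published QTLs onto that consensus,
meta-QTL (MQTL) computation by penalised maximum-likelihood clustering, and
synteny-based candidate-gene identification under MQTL confidence
intervals.

## Consensus map construction

A genetic map is a per-chromosome ordering of markers with positions in
centiMorgans.  Maps are merged iteratively: the first (by default the
densest) map is the backbone; each subsequent map is first screened against
the running consensus for order consistency, then its unique markers are
projected into consensus coordinates.

**Order consistency.** For each chromosome, the markers shared by the two
maps are sorted by their position in the first map and the retained set is
a maximum-cardinality subset whose positions in the second map are
non-decreasing — a longest common monotone subsequence, computed by
patience sorting in O(n log n).  Ties (co-segregating markers) are
permitted; markers placed on different chromosomes in the two maps are
flagged separately (`chromosome_assignment`) and never enter the order
check.  Flagged markers are removed from the *incoming* map only: the
consensus keeps its copy, which guarantees the consensus stays internally
monotone across successive merges.

**Homothetic projection.** Retained shared markers define per-chromosome
anchor pairs (source cM, consensus cM).  A position p between consecutive
anchors (a_s, a_d), (b_s, b_d) maps to

    p' = a_d + (p − a_s) · (b_d − a_d) / (b_s − a_s),

i.e. piecewise-linear rescaling.  Anchors sharing a source position are
collapsed to the mean of their destinations, so source positions are
strictly increasing; destination positions are non-decreasing by
construction (they come from the order-consistent set), which makes the
projection monotone — the property that preserves CI containment for QTLs.
Positions outside the anchored range extend the terminal interval's scale
factor; a terminal interval of zero destination length extrapolates at
scale 1 (the least-surprise choice; upstream tools do not document their
behaviour here).  Projection requires at least two anchors; chromosomes
with fewer contribute nothing and the skipped markers are logged.

Shared markers always keep their consensus (backbone) position rather than
an average of sources.  Averaging can break monotonicity after several
merges; keeping backbone coordinates cannot.  Marker identity is exact,
case-sensitive name equality — alias resolution across genotyping
platforms is a pre-processing concern, not this package's.

Interchange files print positions at 2 decimals (0.01 cM), so a file
round-trip quantises coordinates at that resolution; all in-memory
computation is full precision.

## QTL projection

Each QTL carries a peak, a 95% confidence interval, a trait class (GY =
grain yield, GPC = grain protein content, BQ = baking quality) and a
free-text component (TKW, GrN, Visco, ...).  Peak and CI borders are
projected through the anchor frame of the QTL's source map; monotonicity
guarantees `ci_left <= peak <= ci_right` survives.  Flags record
extrapolation beyond the terminal anchors, frames with fewer than four
anchors (`sparse_anchors`), and imputed CIs.  QTLs whose chromosome has no
usable frame are excluded with a logged reason, never force-placed.

Source studies occasionally publish no CI.  Such QTLs receive a default
95% interval of width 20 cM centred on the peak (configurable), floored at
0 cM with the width preserved, and are flagged `imputed_ci`.  20 cM is a
typical support-interval width for a moderate-LOD QTL in a biparental
wheat population of 100–200 lines.

## Meta-QTL model

Within one chromosome × trait-class group, each projected QTL i becomes an
observation x_i (peak, cM) with standard deviation s_i = CI width / 3.92
(the Gaussian 95% convention) and weight w_i = 1/s_i².  The model: K true
MQTL positions mu_1 < ... < mu_K, x_i ~ N(mu_k(i), s_i²), with hard
assignment that is contiguous in x-order.  For fixed K the ML partition
maximises

    logL = Σ_i [ −(x_i − mu_k(i))² / (2 s_i²) − ln(s_i √(2π)) ],

with mu_k the precision-weighted mean of its block; it is found exactly by
O(n²K) dynamic programming over breakpoints (verified against exhaustive
partition enumeration in the test suite).  Candidate models are K ∈
{1, 2, 3, 4} and the degenerate n-model (every QTL its own locus).

**Model selection.** The free parameters of the K-cluster model are
counted as p = 2K − 1: K positions *and* K − 1 ordered breakpoints.
Counting breakpoints matters.  Because the breakpoint search maximises the
likelihood over ~n split points, a plain Akaike penalty of one unit per
cluster position is far too weak: under the package's own recovery
conditions (three well-separated loci, six QTLs each) plain AIC selects a
spurious fourth cluster in ~97% of replicates.  The default criterion is
therefore AWE (approximate weight of evidence, Banfield & Raftery 1993),

    AWE = −2 logL + p (3 + 2 ln n),

which was derived precisely for classification (hard-assignment)
likelihoods of this form and selects the planted K essentially always in
the recovery tests.  Selectable alternatives: `maic` (small-sample
corrected Akaike with p = 2K − 1, the "modified AIC" family upstream
meta-QTL software alludes to; correction denominator floored at 1),
`aic`, `aicc`, `bic` (classical forms with p = K).  Criterion ties break
toward smaller K.

**Segmentation.** When the n-model wins (more than four loci supported) or
a group holds more than 25 observations, the chromosome is split at
QTL-free gaps — connected components of the union of member CIs, where
touching intervals (shared endpoint) stay together and only open gaps of
positive length separate segments — and each segment is analysed
independently (recursion capped at depth 3 with a logged warning).

**MQTL formation.** A cluster becomes an MQTL only when it holds at least
two QTLs from at least two distinct populations; its consensus position is
the precision-weighted mean, its pooled variance is 1/Σw_i, and its 95% CI
is mu ± 1.96/√(Σw_i) — never wider than the best member's own CI.
Singleton and single-population clusters are retained in the audit table,
never silently dropped; every input QTL appears exactly once in
{MQTL member, unresolved, excluded-with-reason}.  Reported cM values are
rounded half-away-from-zero to 2 decimals at serialisation only.

## Syntenome anchoring and candidate genes

The syntenome is an ordered gene list per chromosome (order inferred from
synteny with related grass genomes); it carries rank, not calibrated
positions, so gene cM values are interpolated *linearly in ordinal rank*
between flanking backbone markers (markers that carry both an ordinal slot
in the gene order and a consensus cM).  Genes outside the terminal markers
extend the terminal cM-per-ordinal rate; chromosomes with fewer than two
backbone markers stay unanchored.  Gene extraction under an MQTL CI is a
closed-interval query in anchored cM, returned in ordinal order; nested
intervals yield nested repertoires.

Candidate genes are scored from 12-column BLAST tabular (outfmt 6) HSPs.
For each query–subject pair the HSPs are made non-redundant greedily by
descending bitscore; an HSP whose query span overlaps already-accepted
coverage by more than 5% of its own span is discarded.  Over the retained
HSPs,

    CIP  = 100 · Σ(identity_i/100 · len_i) / Σ len_i
    CALP = 100 · Σ len_i / query_length   (capped at 100),

so CIP is the coverage-weighted identity and CALP the query coverage.
Without the overlap rule, redundant HSP stacking could push CALP past
100%; the 5% tolerance admits the small junction overlaps real local
aligners produce.  Queries are ranked CIP-first, then CALP, then subject
id (deterministic tie-break); default acceptance thresholds are CIP ≥ 60
and CALP ≥ 70, conventional values for this statistic pair.

## Synthetic data

The generators produce inputs with known truth for every stage, each a
pure function of (parameters, seed); per-stage streams are spawned from a
master seed so stages regenerate independently.

- **Maps**: a true map with uniformly placed markers; each derived map
  samples a fraction of them (default 0.8), applies a per-chromosome
  monotone affine transform (the first derived map keeps identity,
  mirroring the backbone convention) plus order-preserving jitter
  (default sd 0.5 cM), and optionally reverses short marker runs to plant
  inversions.
- **QTL studies**: each population detects each true locus with a given
  probability; peaks scatter Normal around the truth with either a fixed
  sd or, in the model-consistent `"ci"` mode, the sd implied by the QTL's
  own CI width; CI widths are Uniform (default 10–25 cM, the typical
  published range); LOD ~ U(3, 15) and R² ~ U(0.03, 0.25) as dressing.
- **Syntenome**: genes interleaved between consecutive markers on a
  shared ordinal axis, so anchored gene positions fall strictly between
  flanking markers.
- **HSPs**: one planted subject per query whose merged CIP equals the
  planted identity exactly and whose CALP matches the planted coverage to
  within 0.5 (integer column rounding), plus strictly lower-identity
  decoys.

What the generators do *not* emulate: real linkage maps' non-uniform
marker density and cluster structure, segregation distortion,
platform-specific marker-name aliasing, genuinely non-Gaussian QTL
position error, correlated detection across traits, and paralogy-confused
alignments.  Passing tests therefore demonstrate algorithmic correctness
and statistical calibration under the stated model, not robustness to
every artefact of real data.

## Verification conditions and problem sizes

The test suite checks the DP against exhaustive partition enumeration for
n ≤ 12 (200 random instances), parameter recovery with three true loci at
20/60/100 cM on a 150 cM chromosome (6 QTLs each from 6 populations,
s ~ U(1, 3), 200 replicates: correct K in ≥90% of replicates, positions
within 2 cM in ≥95% of clusters), exact collapse of the no-noise pipeline
to the planted loci, projection invariants on 1,000 random frames, the
internal arithmetic of the packaged reference tables, and planted CIP/CALP
recovery over 100 queries.  `scripts/acceptance.py` recomputes the same
quantities from scratch at a user-supplied seed.

## Known limitations

- The exact "modified Akaike" formula of the upstream BioMercator-style
  software is unpublished; results can differ from it in borderline
  groups (the criterion is configurable).
- Contiguity of the optimal hard assignment is assumed, which holds for
  this ordered one-dimensional model, and at most four explicit clusters
  are fitted per segment, mirroring the upstream workflow's segmentation
  workaround rather than an unbounded K search.
- Marker identity is exact string match; maps that name the same locus
  differently will under-anchor.
- The published reference tables contain small internal inconsistencies
  (a one-marker disagreement in one subgenome total, and a few CI widths
  0.01 cM off their printed borders); derived sums here are always
  computed from the per-chromosome/per-row entries.
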