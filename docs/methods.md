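# Methods

This note documents the models and estimators implemented in
`phylospread`, the choices made where the published practice is
ambiguous, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Data model

A survey is a pair: an aligned set of distinct haplotype sequences
(equal length L, IUPAC DNA with `-` for alignment gaps) and a table of
sampling locations, each with decimal-degree coordinates, a region
label, and a count of sampled individuals per haplotype. All statistics
are computed from these counts; no distances or frequencies are stored.
Pooling of adjacent locations (count-weighted centroid, summed counts,
region labels must agree) is applied *before* the minimum-sample-size
filter (default ≥ 5 individuals), so that pooling can rescue small
adjacent samples — the conservative order when pooling exists precisely
to fix unequal sample sizes. Frequency statistics use the
pooled-and-filtered table; network construction and the spread
projection use every sampled location.

## Distances

**Mutational steps.** Substitutions are counted at sites where both
sequences carry unambiguous bases (A/C/G/T); sites with N are ignored.
Indel events are maximal runs of sites gapped in exactly one of the two
sequences, with a run broken when the gapped side switches; they are
reported in a companion matrix and never enter network construction,
segregating sites, or π. The alignments this targets (short rRNA
fragments within a species) are usually gap-free; the rule exists for
robustness and for indel-aware nuclear comparisons.

**Geographic distance** is great-circle (haversine, R = 6371 km).
Planar Euclidean distance on degrees is ill-defined over several
hundred km of latitude; at that extent the two differ by well under 1%,
so results are directly comparable with analyses that used "Euclidean"
distance on projected coordinates.

## Frequency statistics

Haplotypes are treated as unordered alleles at a single locus.

- Gene diversity: unbiased h = n(1 − Σp²)/(n − 1); equivalently the
  probability that two individuals drawn without replacement differ.
  Undefined (NaN) for n < 2.
- F<sub>ST</sub>: the haplotype-identity (Hudson-type) estimator
  1 − H_w/H_b, with H_w the mean of the two unbiased within-population
  diversities and H_b = 1 − Σpᵢqᵢ the probability that one haplotype
  from each population differ. H_b = 0 (identical monomorphic
  populations) returns 0 by convention; n < 2 returns NaN; negative
  estimates are reported as computed, but clamped to 0 before
  M = (1/F<sub>ST</sub> − 1)/4, which is undefined at F<sub>ST</sub> ≤ 0.
  This is an approximation to AMOVA-style variance-component
  F<sub>ST</sub>; with haplotypes as unordered alleles and the
  near-fixed populations this package targets, the two agree closely
  (both → 1 under fixation for different haplotypes).
- Nei's D_A = 1 − Σ√(xᵢyᵢ) over haplotype frequencies.
- Tajima's D uses the standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂
  for sample size n; S counts sites with ≥ 2 distinct unambiguous
  bases; π is the mean pairwise substitution difference with
  pairwise-complete site handling. D is NaN when S = 0 or n < 4 (S and
  π still reported).
- Mismatch distributions are exact histograms over all unordered pairs
  of individuals; the mode count is descriptive only (no model fit).

## Mantel tests

r is the Pearson correlation over unordered off-diagonal pairs; the
null distribution comes from simultaneous row/column relabelling of the
second matrix, with p = (count{as or more extreme} + 1)/(nperm + 1).
Two-sided and both one-sided p-values are always reported; the
isolation-by-distance tests default to two-sided, while the
stepwise-colonization pair test defaults to the directional ("less")
alternative because the model predicts a negative correlation. The
adjusted R² = 1 − (1 − r²)(m − 1)/(m − 2) (m = number of pairs) is
reported alongside r² because it is the quantity comparable with
published "negative r²" values, which plain r² cannot produce.

In the colonization pair test, x for a pair is the distance from the
ancestral location of the pair's *older* member (the member closer to
the ancestor, which under stepwise colonization determines when the
pair's histories separated); the pair mean is available behind a flag.
Significance uses full relabelling of populations (pairs share
populations, so pairwise points are not independent).

## Network construction

The minimum spanning network includes edge (u,v,w) iff u and v lie in
different components of the graph restricted to edges of weight < w.
This is exactly the union of all minimum spanning trees (validated
against exhaustive spanning-tree enumeration in the tests), so tied
alternative connections appear as loops.

Loops are resolved by deleting one cycle edge at a time under a total
order of criteria derived from coalescent expectations (older/abundant
haplotypes are more probable ancestors of new mutations):

1. frequency — delete the cycle edge whose endpoint count sum is
   smallest;
2. topology — among ties, delete the edge with the smaller endpoint
   degree sum (keep edges anchored at interior nodes);
3. geography — delete the edge whose endpoint haplotypes are sampled
   farthest apart (co-occurrence in a location counts as zero);
4. lexicographic edge label, so resolution is fully deterministic.

The published criteria are qualitative; this operationalization is one
defensible total order, and determinism is a requirement for a
reproducible pipeline rather than a scientific claim.

Edges of weight k > 1 are then subdivided with k − 1 latent ("missing")
haplotypes, preserving all pairwise step distances exactly. Lineages
are the components left after removing edges of ≥ `lineage_split_steps`
(default 5) steps *before* subdivision; the default sits between
typical within-lineage gaps (a few steps) and deep splits (≥ 7).

**Ancestor inference.** Within a lineage, each observed haplotype h is
scored 0.5·(count_h/max count) + 0.5·(C_min/C_h), where C_h is h's
eccentricity in the unit-step lineage subgraph. Eccentricity was chosen
over closeness as the centrality because it is integer-valued, so ties
are auditable; the equal weighting reflects that abundance and interior
position are two independent coalescent cues with no published relative
weight. Ties go to the larger count, then the smaller ID. Latent nodes
lengthen paths but are never candidates.

**Nested clades** are built on the unit-step tree by repeatedly
grouping tip clades with the interior clade one mutational connection
away and peeling inward; a stranded singleton joins the adjacent nest
with fewest members (ties to the lexicographically later nest). Latent
nodes participate like observed ones. Nesting is used for display and
summary only — no nested-clade distance inference is attached.

## Time-sliced spread projection

Interior haplotypes are older than tips, so a haplotype's relative age
is its depth — graph distance in single mutations, latent intermediates
included — from the lineage ancestor in the resolved unit-step tree.
With G the maximum depth over lineages and D_Λ a lineage's own maximum
depth, the slice index is T(h) = 1 + G − (D_Λ − depth(h)): the deepest
lineage's ancestor appears at T = 1, every lineage's deepest tip at
T = 1 + G. Aligning lineages at their most recent tips (rather than
their ancestors) encodes the assumption that the youngest haplotypes in
each lineage are contemporaneous, which is the natural anchoring when
lineages share the same sampling time but not the same root age. Latent
haplotypes advance the clock but never appear on maps; each slice shows
haplotypes first appearing at that T ("new") and repeats all earlier
ones ("carried") at every location where they were sampled.

The projection assumes a clock-like accumulation of steps within each
lineage and that ancestors survive to be sampled alongside
descendants; it is a visualization of relative order, not a dated
reconstruction.

## Molecular clock

percent divergence = 100·steps/L; the time bracket is percent divided
by the fast and slow rates (defaults 0.88 and 0.65 %/Myr). Presentation
rounding: percent to 2 decimals, Myr to 1 decimal, years to 2
significant figures — matching how such dates are conventionally
printed. No uncertainty beyond the two-rate bracket is attached.

## Synthetic data

**Fixation cascade (mode a).** A root haplotype seeds an origin
population at the center of a 1-D coastline (populations spaced
`coast_step_km` apart, converted to latitude degrees); one or two
fronts extend outward, each new population founded from the front's
newest. Each founding copies the parent's fixed haplotype and, with
probability f, fixes one new substitution at a fresh site (infinite
sites: step distances equal true mutation counts, so network recovery
can be checked exactly). Every population is monomorphic — the extreme
the pipeline targets. With `lineage_split_steps` = s > 0 a second
lineage, s substitutions from the root, colonizes a disjoint segment.
The `study_shape_preset` (70 locations, two lineages split by 7 steps,
f = 0.65, sample sizes drawn with mean 8.5) reproduces the headline
shape of a range-wide survey: ~45–50 haplotypes, most private to one
location, > 60% of populations monomorphic, mean pairwise
F<sub>ST</sub> near 1.

**Good's model (mode b).** Each population holds N haplotype lineages
under neutral Wright–Fisher resampling with infinite-sites mutation at
rate μ per lineage (individual) per generation; every g generations the
newest population founds the next by copying its exact composition
(identical allele frequencies — the model's defining assumption), after
which there is no gene flow. Sequences are materialized at sampling
time, assigning each surviving mutation a unique alignment site.
Defaults: N = 25, μ = 0.02, g = 50, and `total_generations` equal to
the last founding time — i.e. the survey catches the expansion as the
front arrives, which is the situation the stepwise model describes and
the regime in which its predictions are detectable. Sampling long after
the last founding lets drift erase all haplotype sharing (every pair's
D_A saturates at 1) and the divergence-vs-distance correlation becomes
degenerate; raising μ toward ~0.5/individual/generation does the same.
Under exact-frequency founding there is also no within-population
diversity gradient once populations equilibrate (~N generations), so
the diversity-vs-distance prediction is only testable with the
`propagule_size` option, which founds each population from a finite
bottleneck instead.

**What the generator does not emulate:** homoplasy (finite-sites
back-mutation), migration after founding, selection, heterogeneous
sampling effort correlated with geography, coastline curvature, and
real drainage topology. Passing the recovery experiments therefore
shows the pipeline is correct under its own model assumptions, not that
those assumptions hold for any particular organism.

## Numerical and degenerate-input conventions

- Undefined statistics are NaN (JSON `null` in reports), never silent
  zeros: diversity and F<sub>ST</sub> with n < 2, Tajima's D with S = 0
  or n < 4, Mantel r against a constant matrix, M at F<sub>ST</sub> ≤ 0.
- Permutation p-values use the add-one rule and a 10⁻¹² comparison
  tolerance so that exact ties (e.g. the identity permutation) count as
  "as extreme".
- Zero-distance haplotype pairs (duplicate sequences) are allowed in
  step matrices with a warning; the MSN then contains a zero-weight
  edge.
- All randomness (simulators, Mantel, pair-test permutations) flows
  through seeded NumPy generators; identical seed and parameters give
  byte-identical FASTA/TSV outputs and identical reports.

## Known limitations

- The F<sub>ST</sub> estimator is frequency-based, not the AMOVA
  variance-component estimator; values can differ for highly polymorphic
  populations (not the target regime).
- The ancestor score's abundance term assumes sampling effort is
  roughly even across populations. In the full-fixation regime (every
  haplotype confined to one population) abundance carries no ancestry
  signal, and strongly unequal sample sizes can then outvote the
  centrality cue; the recovery experiments use equal per-population
  sample sizes for this reason.
- Loop resolution and nesting tie-breaks are deterministic conventions;
  alternative valid resolutions exist for heavily looped networks.
- Mismatch distributions are descriptive; no sudden-expansion model is
  fitted and no raggedness inference is made.
- The clock bracket propagates only rate uncertainty, not stochastic
  variance in the number of accumulated substitutions.
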