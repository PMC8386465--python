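# Methods

## The problem

Bacterial genomes carry between 1 and 19 copies of the rRNA (*rrn*) operon,
and the 16S rRNA genes of those copies are often not identical.  Exact
sequence variants (ASVs) therefore split one genome into several units,
while distance-based OTUs at a broad threshold can lump several species into
one unit.  This package quantifies both risks on collections of 16S gene
sequences drawn from assembled genomes: for each *rrn* copy-number class,
the distance threshold at which 95% of genomes keep all their variants in a
single OTU; and, per threshold, the fraction of ASVs/OTUs containing
sequences from more than one species.

## Pipeline model

1. **Catalog.**  Genomes are the units of analysis: one assembly accession,
   one species label, 1–19 gene copies.  Species labels are reduced to
   genus + epithet (strain designations removed; `Candidatus` kept as a
   prefix) because per-copy classifications of one genome can disagree.
   Genomes whose epithet is unresolved (`sp.`, single token, `unclassified`)
   are kept for per-genome statistics but excluded from species-controlled
   resampling, which needs a species label.
2. **Regions.**  Sub-regions are defined by 1-based inclusive positions on
   the unaligned E. coli K-12 MG1655 gene (full-length 28–1491, V4 534–786,
   V3–V4 358–786, V4–V5 534–908) and realized on a specific alignment by
   locating the columns holding the reference's boundary bases.  The package
   consumes pre-aligned input; it does not align.  A sequence gapped at a
   boundary column cannot be reached by a primer landing there, so the
   default policy drops it (`keep` trims regardless; both are exposed
   because either convention is defensible).
3. **ASVs.**  Dereplication is exact string equality on degapped, uppercased,
   U→T-normalized region sequences; `N` compares literally.  The headline
   variants-per-copy average is the unweighted per-genome mean of
   n_ASVs/copies; per-species and pooled variants are reported alongside
   since the three definitions differ on unevenly sampled collections.
4. **Distances.**  Uncorrected difference fractions between aligned ASV
   representatives.  Three gap modes are implemented; the default counts a
   gap run as a single difference and includes terminal gaps, matching the
   documented defaults of the standard distance calculators for this data
   type.  Pairs are kept sparsely up to `d_max` = 0.10, the top of the
   threshold sweep.
5. **Clustering.**  OTUs are formed by iterative MCC maximization over ASV
   pairs: a pair is truth-positive when its distance is ≤ the threshold
   (inclusive), call-positive when co-clustered.  From a singleton start,
   items move in seeded random order to the cluster maximizing global MCC.
   Two details matter:
   * *Tie-breaking.*  Under the boundary convention (MCC = 1 when FP=FN=0,
     0 on a zero denominator), all-positive instances are flat at MCC 0 for
     every non-perfect partition, so a strict "keep current on ties" rule
     can never leave the singleton start.  Ties in MCC are therefore broken
     toward more true-positive pairs; the pair (MCC, TP) strictly increases
     with every accepted move, which guarantees termination and keeps the
     MCC trajectory non-decreasing.
   * *Restarts.*  Single-item moves cannot assemble some optimal clusters
     from below.  Restart 1 begins at all singletons, restart 2 at the
     connected components of the threshold graph, later restarts at random
     coarse partitions; the best run wins.  With 10 restarts the clusterer
     matches an exhaustive-enumeration oracle on ~98% of random 6-item
     instances (the remainder are genuine local optima).  The pipeline
     default is 1 restart.
   A furthest-neighbor (complete-linkage) clusterer with a fixed merge
   order (increasing linkage distance, lexicographic ties) provides nested
   partitions across thresholds and serves as an independent oracle; an
   exhaustive search over all set partitions (n ≤ 10) provides ground truth
   on small instances.
6. **Statistics.**  To control for species sampled by many genomes, every
   statistic is computed on subsets holding one uniformly drawn genome per
   species, 100 times by default; medians and linear-interpolation IQRs are
   reported across randomizations.  Clustering runs on the pooled ASV set of
   the subset, so sequences from other genomes can bridge or absorb a
   genome's ASVs.  A genome is *intact* at a threshold when all ASVs
   containing any of its copies share one OTU; the collapse threshold of a
   copy-number class is the smallest grid value at which ≥95% of the class
   is intact, reported as NONE (not extrapolated) when no grid value
   suffices.  A genome's copy class is its count of copies surviving region
   extraction, since extraction is region-specific.  Classes seen in at
   most `min_species_per_copy_class` species (default 100, scaled down in
   the synthetic analyses) are excluded as too noisy.  Replicate *r* draws
   all its randomness from `SeedSequence([master_seed, r])`, so any single
   replicate is reproducible in isolation.

## Synthetic communities

The generator emulates the statistical structure the pipeline consumes:
species templates drawn independently at random (rejection-checked against a
minimum pairwise separation — independent 1500-nt templates sit near 75%
divergence, so the check binds only for small lengths), genome templates
derived by per-species substitutions, and copies derived from genome
templates.  All mutated positions within a species come from one shuffled
position pool, so no position mutates twice: substitution counts map exactly
to Hamming distances and every ground-truth distance is analytic.  Copy
numbers, genomes-per-species, and the per-copy substitution counts are
constants, explicit lists, or small distribution specs (uniform 1–19 copies;
geometric genome counts; a mixture mode in which each non-template copy is
identical to the template with probability *p*, emulating partially diverged
operons).  Deliberate multi-species ASVs are created by overwriting one copy
of a target genome with an exact sequence from a donor species.

What the generator does **not** emulate: phylogenetic structure between
species (templates are equidistant, so OTU-level lumping saturates instead
of growing the way related taxa make it grow), PCR/sequencing error and
chimeras (inputs are ideal assembly-derived sequences), realistic indel
structure (the default alignment is columnar; an optional indel mode punches
gap columns only to exercise gap-policy code paths), and covariation between
copy number and taxonomy.  Passing tests therefore demonstrate correctness
of the machinery and recovery of constructed parameters, not the field
values of the real database.  A genome that received a cross-species shared
variant carries a ~75%-divergent copy and can never collapse within the 10%
sweep; its copy class can stay below the 95% bar when it is sampled, which
is visible in the synthetic splitting tables.

## Numerical choices

* Threshold grid 0.25%–10.00% in 0.25-point steps; pairs at exactly the
  threshold are within it.
* MCC boundary conventions as above; move acceptance needs a gain > 1e-10.
* Convergence: a full pass with no accepted move, hard cap 100 passes.
* Medians/IQRs use linear-interpolation quantiles.
* Gap-free inputs take a vectorized byte-matrix distance path; gapped inputs
  fall back to the scalar per-column scan (both are cross-checked).
* Degenerate inputs: empty sequence sets produce empty tables; a genome with
  zero surviving copies is omitted and logged; `collapse_threshold` is NONE
  when unreached.

## Problem sizes in the shipped analyses

The shipped analysis scripts run a 150-species community (~500 genomes,
~5,000 gene copies, uniform 1–19 copy numbers, 10 randomizations,
min 5 species per class); the acceptance script uses 200 species × 3 copies
for parameter recovery and 5 randomizations.  These sizes make every stage
rerunnable in minutes on one CPU while exercising all code paths; all
figures and tables are regenerated from the config seed.

## Known limitations

* The full-scale numbers of the real curated database depend on its exact
  taxonomic composition and on the (undocumented) gap-handling settings of
  the original distance computations; this package exposes all three gap
  modes so a full-scale run can sweep them.
* The MCC clusterer is a local search; restarts mitigate but do not remove
  local optima.
* Species-pair ground-truth distances are computed by brute force and are
  the slowest part of community generation for large communities.
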