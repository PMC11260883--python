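# Methods

This note documents the models, rules and numerical choices behind
`barcodegap`, including the places where the underlying procedure is
informal in common practice and this package had to fix an explicit rule.

## Units of analysis

All analyses run within a genus. From one aligned input the package builds
two parallel views:

* **unique-haplotype view** — per species, redundant haplotypes are
  collapsed and each unique haplotype enters once (count *N*<sub>H</sub>);
* **all-sequences view** — every sequence enters, so common haplotypes are
  weighted by their sampling frequency (count *N*<sub>S</sub>).

The first is the traditional barcoding unit; the second asks whether
conclusions survive when redundancy is retained. Default inclusion filters
are *N*<sub>H</sub> ≥ 6, *N*<sub>S</sub> ≥ 12, and ≥ 4 qualifying species
per genus; a species may qualify for one view only, and the report tables
use union semantics (a species "has a local gap" overall if it has one in
either view, flagged as discrepant when the views disagree).

Two sequences are the same haplotype when they have **zero countable
differences**: no column where both carry an unambiguous nucleotide and the
nucleotides differ. Missing data make this relation non-transitive, so
groups are closed transitively with union-find; a warning is logged when a
merged group contains a genuinely differing pair, since common haplotype
callers do not document how they resolve such chains. The group
representative is the sequence with the most non-missing characters, ties
broken by smallest id, making output order-independent.

## Distances

K2P distances use strict pairwise deletion: a site is comparable only when
both sequences carry one of A, C, G, T. IUPAC partial ambiguities count as
present for trimming/coverage but never as comparable sites; this is the
simplest defensible reading, though tools that score partial matches may
differ slightly on low-quality data. Saturated pairs (any log argument
≤ 0) and zero-overlap pairs are masked as *inapplicable* rather than given
a fabricated large distance; every downstream statistic skips masked pairs
and logs their count. Distances are kept in substitutions/site internally
and rendered as % sequence divergence (1 decimal) only in report tables.

## Gap rules

* **Local gap** (per species): minimum interspecific distance to any
  congener strictly greater than maximum intraspecific distance. Ties mean
  no gap. Shared haplotypes force min-inter = 0 and hence no gap.
* **Global gap** (per genus): the per-species mean intraspecific distances
  and per-species-pair mean interspecific distances must not overlap
  (strictly). Species with no measured within-species pair contribute no
  intra value — their placeholder 0 is not a measurement — but still enter
  interspecific pairs. When a gap is present, the threshold ratio
  mean-inter / mean-intra is compared against configurable multipliers
  (default 10 and 5). Genus means are unweighted averages of the
  species-level means (`pooling="species_means"`); pooling raw pairwise
  distances instead is available as `pooling="raw_pairs"` because histogram
  conventions in the literature are ambiguous between the two.

## Sample-size pilot

The pilot treats the full-data mean intraspecific distance of a richly
sampled species as the benchmark "truth", then subsamples without
replacement (10 replicates per size, deterministic given a seed) along a
size gradient. Practice chooses the minimum size by visually judging
convergence; this package fixes an explicit dual tolerance: the smallest
size whose mean absolute relative deviation from truth is ≤ 10% and whose
sd-of-means / truth is ≤ 10% (both configurable). If no size qualifies the
largest is returned with a warning; a zero benchmark raises, pointing the
user to absolute tolerances. At the full sample size the subsample is the
whole dataset, so deviation and spread are exactly zero — subsample indices
are sorted before averaging precisely so that this holds bitwise.

## Permutation comparison of the two views

Whether a genus' per-species mean intra (or per-pair mean inter) distances
differ between the views is tested by a two-group randomization ANOVA with
10,000 iterations by default. The statistic is the one-way F; since the
total sum of squares is label-invariant, the loop compares between-group
sums of squares, which is monotonically equivalent. p-values use the
add-one convention (1 + #{permuted ≥ observed}) / (1 + iterations), and the
null is enumerated exhaustively whenever the number of distinct label
assignments is ≤ 50,000. The groups are treated as independent; a paired
design (species present in both views) would be an alternative reading and
is not implemented. Values are per-species/per-pair means by default since
genus-level comparisons in the field are framed on means.

## Species delimitation

Candidate partitions come from single-linkage agglomeration of the K2P
matrix (ids sorted lexicographically first so ties are deterministic), one
partition per distinct merge height plus the all-singletons start. Each
partition with ≥ 2 clusters is scored by:

* **p_panmixia** — add-one permutation probability that random reassignment
  of ids to clusters of the same sizes yields a mean-within / mean-between
  distance ratio at least as small as observed;
* **W** — (min between-cluster distance − max within-cluster distance) /
  overall mean pairwise distance, floored at 0.

Partitions are ranked on each metric (average ranks on ties) and scored by
the mean of the two ranks; selection takes the lowest score, ties resolved
toward fewer species, and partitions with more than 0.9 × n clusters are
excluded as implausible (nearly one sequence per species). These formulas
are this package's own explicit stand-ins at the level the quantities are
usually described; output from dedicated delimitation tools can be imported
(`import_partition`) and fed to the concordance stage unchanged, which is
the recommended route when fidelity to a specific tool matters.

The all-singleton partition is scored (with max-within taken as 0) rather
than rejected, since the ranking stage needs it as a reference point; the
plausibility cap keeps it from ever being selected.

## Concordance categories

Each recognized species is classified against the selected partition:
perfect taxonomy; pure undersplit (split into exclusively own clusters);
impure undersplit (split, ≥ 1 cluster shared); pure oversplit (wholly
pooled with wholly-pooled others); impure oversplit (pooled with a species
that also has members elsewhere). A species that is both split and sharing
is an impure undersplit — the split takes precedence, so the five
categories are exhaustive and mutually exclusive (verified by enumeration
over all set partitions of up to 6 ids in the tests). Percentages are
rounded half-up to integers; the delimited-to-recognized ratio is reported
to 1 decimal.

## Synthetic data

The simulator evolves sequences on a star phylogeny under the two-rate
Markov process the K2P estimator assumes (transition rate κβ, each
transversion rate β, normalized so branch length is expected
substitutions/site; κ defaults to 2.0). A uniform-random root gives rise to
species ancestors at branch length `inter_depth` and haplotypes at
`intra_depth`, so expected mean distances are 2·intra within and
2·inter + 2·intra between species — closed forms used as calibration
oracles with a ±15% Monte-Carlo band. Defaults (5 species, 8 haplotypes
each, multiplicity cycle 3-2-1 giving 17 sequences per species,
intra 0.01, inter 0.05, 600 bp) describe a clean genus at divergence scales
typical of congeneric arthropod COI with a 5× separation, sampled
redundantly enough that both views pass the default inclusion filters.
Options add the pathologies the pipeline must handle: verbatim haplotype
sharing between chosen species pairs, and missing end-blocks (each affected
sequence gets leading and trailing `N` runs of up to 10% of the alignment).

What the simulator does *not* emulate: coalescent genealogy within species,
rate variation among sites or lineages, indel/alignment error, and numt
contamination. Passing tests therefore demonstrate correctness of the
estimators and decision rules under the generating model, not robustness to
every artifact of real NCBI data.

## Problem sizes and determinism

Statistical checks use sizes chosen to make sampling error negligible at
desk scale: 100 seeded genera for gap truth-recovery, 50 for delimitation
recovery and simulator calibration, 500 null datasets (999 permutations
each) for permutation calibration. Every stochastic routine takes an
explicit seed; the pipeline derives per-stage seeds from its run seed, and
reruns with identical configuration write byte-identical outputs.

## Known limitations

* Delimitation scores are not a reimplementation of any specific published
  tool's internals; cross-tool comparisons should use imported partitions.
* Strict {A,C,G,T} comparability can differ from tools that treat partial
  ambiguity matches probabilistically.
* The permutation comparison assumes independent groups (see above).
* Threshold ratios from rounded report tables need not reproduce ratios
  computed on unrounded means; the package always computes ratios before
  rounding.
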