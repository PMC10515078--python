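# Methods

This note documents the models, parameter choices and numerical details
behind `mtmedip`, in the order the pipeline runs.

## Coordinates and conventions

All coordinates are 1-based and inclusive; BED input/output is converted
at the boundary. Mitochondrial genomes are circular by default: interval
fetches, simulated fragments, the toy aligner and coverage counting all
wrap across the origin. CpN sites are enumerated on the plus strand only
and without wrap by default (a terminal C has no successor); wrap
enumeration is available via a flag. A C followed by N is not a site, and
N bases are excluded from composition denominators. The FASTA plus strand
is labelled "heavy" by default; `plus_is_heavy=False` flips the labels
without touching coordinates.

## Synthetic data generator

The generator emulates the targeted study design so every stage can be
exercised without external data:

* **Genome** — i.i.d. bases over a 16,775 bp circle at the avian mtDNA
  composition A 30.3 / T 23.8 / C 32.5 / G 13.5 % (printed percentages sum
  to 100.1, so frequencies are renormalised exactly). Motif consensus
  sequences can be written over stated positions/strands; overlapping
  plants are rejected.
* **NUMT decoys** — a linear nuclear contig embedding a copy of an mtDNA
  segment in which each base mutates independently at the divergence rate
  (always to a different base), between random flanks at the genome
  composition.
* **Reads** — single-end fragments, starts uniform on the circle, lengths
  truncated-normal with mean 350 bp and σ = 50 bp clipped to the 200–400 bp
  size-selection window (σ is a package choice; only the mean and the
  window are design givens). Note the post-selection mean is ~336 bp
  because the truncation is asymmetric. Each read carries its true origin
  label, which downstream tests use as ground truth.
* **Counts** — CpN-site coverage for twelve samples in fixed order
  (MC×3, MS×3, FC×3, FS×3) as gamma–Poisson (negative binomial) draws
  with mean 170 (the study's average depth) and common dispersion
  φ = 0.05, a typical extra-Poisson coefficient of variation (~22%) for
  biological replicates; φ = 0 gives exact Poisson. A planted region's
  log₂FC multiplies the mean of the *second* group of each affected
  contrast (FC, FS, MS, FS for MCvsFC, MSvsFS, MCvsMS, FCvsFS) at member
  sites, so recovery tests are sign-unambiguous. Because effects act on
  cells, a region planted for MC vs MS is also visible to MS vs FS — as a
  real cell-level shift would be.

What the generator does **not** emulate: sequencing errors, flow-space
artefacts, immunoprecipitation efficiency or CpG-density-dependent
enrichment (a density boost exists behind an option but the default is
flat), and library-size imbalance beyond what sampling noise produces.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated NB model, not robustness to platform-specific
artefacts in real data.

## NUMT filtering

The four-step control is implemented as set operations over alignments:
unique whole-genome reads → re-alignment against the nuclear-only index →
keep the unaligned → keep those aligning to mtDNA alone. For synthetic
data the alignments come from a toy exhaustive Hamming-distance aligner
(both strands, every occurrence, circular wrap, default max 2 mismatches,
no indels — adequate because simulated reads are substrings of the same
genomes). For real data, SAM/BAM files produced by an external aligner are
accepted; "unique" is approximated by primary records with MAPQ > 0 and no
secondary/supplementary alignments, an explicit proxy for the original
samtools-based extraction.

## Differential coverage testing

Per contrast: subset the two cells, drop sites whose summed count is below
10, normalise, estimate dispersion, exact-test each site.

* **TMM** follows the weighted-trimmed-mean-of-M-values construction:
  reference sample = upper-quartile fraction closest to the mean; M and A
  computed over doubly-positive sites; symmetric rank trimming of 30% on M
  and 5% on A; weights are inverse asymptotic variances
  (N−y)/(Ny) summed over the pair; factors rescaled to geometric mean 1.
  One test cross-checks the factors against the independent Bioconductor
  implementation to 1e-8.
* **Common dispersion** maximises the conditional likelihood of replicate
  counts given per-site group sums (which is free of the site means) on
  pseudo-counts equalised to the geometric-mean library size, via bounded
  scalar optimisation on log φ with a boundary check that returns exactly
  0 when within-group variability is at or below Poisson. There is no
  per-site shrinkage; with thousands of sites and three replicates the
  common estimate is the stable choice.
* **Exact test**: group sums of n equalised replicates are treated as
  NB(n·μ, φ/n); conditioning on the site total, the two-sided p-value sums
  the probabilities of all integer splits no more probable than the
  observed outcome, normalised over splits. Fractional pseudo-sums are
  handled by evaluating the NB pmf continuously through the gamma
  function; sums within 1e-6 of an integer are snapped so the enumeration
  grid lands on them, and tie comparison uses a 1e-8 log-tolerance so
  symmetric outcomes are included. φ = 0 switches to the Poisson pmf,
  making the test exactly the conditional binomial. log₂FC uses
  normalised group means with a 0.5 prior count per group.
* **Significance** is unadjusted p ≤ 0.05 by default, matching the
  region-calling design this feeds (clustering, not per-site inference);
  Benjamini–Hochberg adjustment is available behind a flag.

Scaling one sample's counts and library size by a common factor leaves
p-values unchanged only up to the discreteness of the conditional split
(the total changes), an O(1/√t) effect verified at the 2% level in tests.

## mtDMR delimitation

Adjacent significant positions join a region when their plain positional
difference is ≤ x; the gap-scan evaluates the region count for every x in
1..1962 (breakpoints sit exactly at the distinct adjacent-gap values) and
returns maximal constant runs as plateaus. CI = x_max − x_min + 1,
the inclusive convention, under which the principal published plateau
(127–179) has CI 53.

Selection rule: raw scans of noisy position sets contain CI = 1 plateaus
throughout the small-x fragmenting regime, so candidates are first
restricted to the most stable plateaus — by default the four largest-CI
plateaus (mirroring the four "important ranges" treatment of the published
scan; a `min_ci` threshold is the configurable alternative, and plateaus
entirely below x = 2 are always excluded). Among candidates the lowest CI
wins, ties go to the smaller x_min, and that plateau's smallest x is
returned as the conservative choice.

A region's end extends 1 bp past its last member C so the final
dinucleotide is covered; a singleton region has length 2. Clustering is
per contrast and linear (no wrap across the origin) by default.

## Characterization

Composition tests are chi-squared goodness-of-fit of pooled region
base (A/T/C/G) and CpN-context counts against genome proportions, per
contrast; zero-expectation categories are dropped (an observation there
forces p = 0). CpN absence is the percent of regions containing no
occurrence of a context. Cross-contrast identity uses ≥ 1 bp overlap with
transitive (single-linkage) merging — the weakest defensible notion of
"the same region", configurable via a minimum-overlap parameter; classes
a–d derive purely from contrast membership (a: both between-sex contrasts
only; b: both within-sex; c: exactly one within-sex; d: all four;
anything else n/a), and the between-sex Venn view labels identities
lost/gained/remained. Both accountings — merged identities and
per-contrast instances — are reported, since published tallies can follow
either.

## Motif scanning

Log-odds scores use log₂(p/b) with a 0.1 pseudocount per count cell. The
null distribution discretizes the score matrix onto 1000 integer bins
(columns shifted to non-negative values) and convolves position-wise under
the 0-order background, exactly as in FIMO-style scanners; window scores
are computed with the same integer matrix, so reported p-values are exact
for the discretized score, and enumeration over all 4^w words reproduces
them to 1e-9 for small w. The background defaults to the scanned
sequence's composition, symmetrised over strands when both strands are
scanned (so a genome and its reverse complement give mirrored hit sets);
the minus strand gets its own null distribution because an asymmetric
background makes the reverse-complement score matrix a different random
variable. Windows containing N never match. Scanning is linear by default
with an option to append w−1 bases for circular genomes. All overlapping
hits are reported.

Conservation windows extract hit ± 20 bp per species in motif orientation
(minus-strand hits reverse-complemented), and the consensus takes the
majority base per column where its fraction meets the 70% threshold,
otherwise '.'.

## Problem sizes and determinism

Tests and examples run the full design (16,775 bp genome, 12 samples,
~170× depth) but restrict to the first 2000 CpN sites for the
calibration/power checks and use few hundred reads and kilobase genomes
for alignment-heavy checks; these sizes give stable statistics while
keeping the suite fast. Every stochastic component draws from
`numpy.random.default_rng` seeded from a single configuration seed
(sub-streams offset per stage), so all outputs — including pipeline TSVs —
are byte-identical across reruns.

## Known limitations

* Coverage is an enrichment proxy; no base-resolution methylation calls.
* Common dispersion only; no tagwise shrinkage or GLM/quasi-likelihood
  testing.
* The toy aligner is substitution-only and exhaustive (quadratic); real
  datasets should be aligned externally and supplied as SAM/BAM.
* Region-level significance is not recomputed after clustering.
* No de-novo motif discovery or q-values; 0-order backgrounds only.
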