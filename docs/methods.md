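# Methods

## Scope and model

`amplifam` re-implements, as a tested pipeline, the standard workflow for
characterizing a large multigene family from pooled CCS amplicon reads:
quality filtering, length demultiplexing, greedy identity clustering,
de novo PCR-chimera removal, majority-rule consensus calling,
open-reading-frame classification, repertoire-size bracketing at dual
identity thresholds, cross-validation against reference locus sets, and
population-genetic summarization. The object of study is a family of
20–40 single-exon paralogous loci per subfamily (e.g. mouse-lemur V1R
subfamilies V1RI, ~725 bp amplicons, and V1RIX, ~800 bp), sampled in two
diploid individuals that share a fraction of their loci.

## Pairwise identity

All identity decisions use *global, end-to-end* alignment identity:
matches divided by alignment columns, each gap column counting as a
non-match. Scoring is affine (match +1, mismatch −2, gap open −4, gap
extend −1, via Biopython's `PairwiseAligner`). This replaces the local
(BLAST-style) identity sometimes used for such comparisons: for
same-length amplicons it is deterministic and parameter-closed, and it
cannot inflate identity by clipping divergent ends. Terminal-gap-free
identity is available (`ignore_terminal_gaps=True`) for comparing
fragments against full-length references.

Inside the clustering loop, candidate pairs are first screened with a
*provably safe* edit-distance bound: for any alignment,
identity ≤ m/(m+d) with m the shorter length and d the unit-cost edit
distance (matches ≤ m; non-match columns ≥ d). edlib computes the bounded
edit distance in ~60 µs per 725 bp pair, versus ~5 ms for the exact affine
aligner, so the screen rejects hopeless comparisons cheaply while the
exact aligner still confirms every accepted membership — the screen can
never change a clustering decision, only skip work.

## Quality filter and demultiplexing

A read is kept iff it has ≥ `min_passes` (default 4) CCS passes and
≥ `min_fraction_at_threshold` (default 0.90) of its bases individually at
Phred ≥ `phred_threshold` (default 20). The published wording of such
filters is ambiguous between this per-base reading and "mean quality of
the best 90% of bases ≥ 20"; the per-base rule is the parameter-free
reading and is the default, the mean rule is available via
`QCParams(rule="best_fraction_mean")`. Each rejection carries exactly one
reason; a read failing both gates is attributed to the pass-count gate
(the first applied in the workflow). Demultiplexing assigns a read to the
unique amplicon class whose length window (default expected ± 30 bp)
contains it; windows must be disjoint (classes ~65 bp apart guarantee
this) and out-of-window reads are reported as unassigned, so the partition
is exhaustive and checkable.

## Clustering and consensus

Greedy centroid clustering processes sequences in decreasing length order,
ties broken by decreasing abundance of byte-identical sequences then by
id — mirroring the default sort of the widely used greedy clustering tools
and making the result independent of input file order. A sequence joins
the first existing centroid at identity ≥ 0.98, else founds a new cluster;
the output is a partition and every member is within threshold of its
centroid by construction.

Consensus calling center-stars the members around the centroid: each
member is aligned to the centroid (unit-cost global alignment paths from
edlib; at ≥ 98% identity the unit-cost and affine paths are effectively
identical and the former is ~100× faster), member insertions are merged
into shared, left-aligned insertion columns, and the consensus takes the
per-column majority character, dropping columns whose majority is a gap.
Ties prefer a base over a gap (keeping the consensus length stable) and
are otherwise broken alphabetically, so consensus calling is
deterministic. Clusters below the coverage floor (default 7×) yield no
consensus and are reported as low-coverage; a flag
(`include_small_clusters`) lets validation studies include them.

## Chimera screen

The de novo screen follows the UCHIME model: for each cluster
representative, candidate parents are representatives of clusters with
abundance ≥ `abskew` (default 2.0) times the query's. Over all ordered
parent pairs and interior breakpoints, the model minimizing query
mismatches (left of the breakpoint scored against parent A, right against
parent B, on the query's coordinate frame, with prefix-sum minimization
over breakpoints) is selected. The query is called chimeric when three
gates all pass:

* ≥ `min_diag` (3) diagnostic sites per side — positions where the query
  matches that side's parent and mismatches the other;
* improvement ≥ `min_improvement` (2) — the two-parent model explains at
  least that many more query sites than the best single parent;
* improvement / best-single-parent-mismatches ≥ `min_improvement_ratio`
  (0.5).

The third gate is the package's addition: a genuine chimera is explained
*almost completely* by its two-parent model (residual mismatches come only
from sequencing error, so the ratio approaches 1), whereas for a
non-chimeric query the optimal breakpoint of a random mismatch walk gains
about √(number of divergent sites) ≈ 8–15 sites by chance — enough to pass
any small absolute gate, but a ratio of only ~0.15–0.3. Without the ratio
gate, divergent true loci are flagged wholesale whenever two more-abundant
clusters exist; with it, measured sensitivity on injected perfect chimeras
(parents ≤ 95% identical, abundance-eligible) is ~100% and the
false-positive rate on true-locus representatives is ~0%. Clusters called
chimeric are removed before consensus and all downstream analyses.

## Repertoire estimation, validation, comparison

A consensus locus is putatively functional iff some reading-frame offset
(0, 1, 2) yields a stop-free translation over all complete codons; the
smallest stop-free offset is recorded and pseudogenes are excluded from
repertoire counts. Loci sharing **greater than** 98% identity (strict
inequality) are considered the same gene; grouping is by single-linkage
connected components — the most conservative construction, giving the
smallest locus count — and the same construction at 99% gives the maximum
count, so `min_loci ≤ max_loci ≤ n` always.

Validation against a reference set reports, per reference locus, whether
any query reaches the match threshold (recovered), matches at every base
over the compared span (identical), and, per query, whether no reference
matches (novel). Full-length references can first be trimmed to the
amplicon span by global alignment against an amplicon profile.
Cross-individual comparison reports the fraction of each repertoire with a
counterpart at ≥ 98% in the other, plus one-to-one best-hit pairs (greedy
by descending identity, preventing one locus matching many) above 99% and
at 100%.

## Population genetics

Statistics use complete deletion: columns containing any gap or N are
excluded from everything. On the L included columns, S counts columns with
more than one state, k is the mean pairwise difference count over all
C(N,2) pairs, π = k/L, and θ_W = S/(a_{N−1}·L) with a_{N−1} the harmonic
number. Synonymous/nonsynonymous *site* counts follow Nei–Gojobori:
each codon position contributes the fraction of its three single-base
changes that are synonymous, averaged over sequences, on codons whose
three columns are all included; changes that would create a stop codon
count as nonsynonymous, so syn + nonsyn equals the number of
codon-complete sites analyzed and the bookkeeping is auditable
(`n_codons` is reported alongside).

Distance matrices use pairwise deletion. The Kimura 2-parameter distance
is d = −½ln(1−2P−Q) − ¼ln(1−2Q) from the transition and transversion
proportions P and Q; log-domain violations (saturated pairs) yield an NaN
"undefined" marker rather than an exception, and tree building lists the
offending pairs if asked to consume them. Amino-acid p-distance skips
gaps, X and stops. The differentiation test collapses the pooled sequence
sets into haplotypes and computes the classical chi-square on the 2×H
count table with df = H−1 (the construction behind "haplotype frequency"
chi-square tests in the standard polymorphism packages; the exact variant
used historically is not specified anywhere, so the simplest is
implemented and named).

Neighbor joining is the Saitou–Nei algorithm; ties in the Q-criterion are
broken by the smallest index pair, and negative branch lengths are clamped
to zero with the deficit shifted to the sister branch. On additive
matrices the input metric is reproduced exactly (this is asserted against
brute-force four-point-condition checks and against scikit-bio's
independent implementation in the test suite).

## Synthetic data generator

The generator defines the study conditions:

* **Repertoire**: per subfamily, one random stop-free ancestor of the
  amplicon length; each of n loci (default 30) diverges from it by
  d ~ U(lo/2, hi/2) with `target_pairwise_divergence` (lo, hi) defaulting
  to (0.03, 0.20), so pairwise paralog divergence lands in the configured
  range. Substitutions are drawn with transitions twice as likely as
  transversions (so K2P estimation is exercised non-trivially) and redrawn
  if they would create an in-frame stop in functional loci. The two
  individuals share exactly round(0.7·n) loci by default; shared copies
  differ by an allelic divergence of 0.002. Exactly round(0.1·n) loci per
  subfamily carry a premature TAA stop at a codon fixed per locus (so a
  shared pseudogene is the same pseudogene in both individuals).
* **Reads** (default 5,000 per individual): parent loci are drawn with
  lognormal weights (σ = 1.0; PCR amplification bias), pass counts from a
  geometric distribution truncated to [2, 10], per-base error
  ε(p) = ε₁/p with ε₁ = 0.02 — the published behavior is a monotone
  quality gain per pass with no stated functional form, and 1/p is the
  simplest non-increasing choice; errors are 90% substitutions and 10%
  single-base indels; base qualities are the Phred equivalent of ε(p)
  with N(0, 2) integer jitter, capped at Q60. With probability
  `chimera_fraction` a read is a two-parent, single-breakpoint splice
  (uniform interior breakpoint, parents from the same subfamily) — the
  standard bimolecular PCR-chimera model.
* **Truth**: every read has exactly one origin record (locus, individual,
  or parent pair + breakpoint), and fixed seeds give byte-identical FASTQ.

What the generator does *not* emulate: polymerase-specific error spectra,
position-dependent quality, heteroduplexes, multi-breakpoint chimeras, or
true allelic variation within an individual (each individual is
homozygous per locus). Passing tests therefore demonstrate correctness of
the pipeline's logic under the stated stochastic model, not robustness to
every artifact of real instruments.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 2 individuals × (30 + 30) loci ×
5,000 reads (the study-scale condition) once, and smaller configurations
(6–15 loci, 300–1,000 reads) elsewhere; the acceptance script repeats the
study-scale run plus the chimera screen at 2 × 15 loci × 1,000 reads with
10% chimeras. Identity thresholds are compared with ≥ in clustering and
strictly > in repertoire collapsing (the "greater than" rule). Consensus
and clustering are exactly deterministic; the only randomness anywhere is
the generator's, driven by a single integer seed.

## Known limitations

* A locus with *exactly* `min_cluster_size` reads can be lost when its
  longest read is an error outlier: longest-first greedy ordering makes
  that read the centroid, the remaining reads can fall just below the 98%
  threshold against it, and the cluster splits (e.g. 1+6), dropping below
  the coverage floor. This is inherent to greedy centroid clustering at
  the coverage boundary; in study-scale runs it costs at most ~1 locus in
  ~110.
* Paralogs at < 2% divergence collapse into one cluster by construction —
  the known conservative bias of identity-threshold repertoire counting;
  the 99% threshold bracket partially compensates.
* The center-star consensus stands in for iterative MSA plus manual
  curation; isolated-column disagreements with hand-curated consensus
  sequences are expected.
* Saturated K2P pairs (1−2P−Q ≤ 0 or 1−2Q ≤ 0) are undefined by
  construction; analyses on highly divergent sets should use the
  amino-acid p-distance mode.
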