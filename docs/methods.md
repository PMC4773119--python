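# Methods

## Duplex model

An intermolecular lncRNA:RNA duplex is modelled as an antiparallel local
alignment: ascending positions on the lncRNA pair with descending positions
on the target, and each column is scored by the strength of the base pair it
would form — G:C = +4, A:U = +2, the G:U wobble = +1, anything else
(including any pair involving N) a mismatch at −6. Gap costs are affine with
a LAST-style convention: a maximal gap run of length *g* on one molecule
costs `gap_open + g·gap_extend` = −20 − 8·g, so the first gapped column of a
run costs −28. The 4/2/1 proportions are the ones conventionally used for
RNA:RNA pairing (e.g. in miRNA target scoring); the approach deliberately
reduces hybridization to similarity scoring — it does not model secondary
structure, accessibility or thermodynamics, which is what makes it fast
enough for all-vs-all transcriptome scans.

Internally the problem is transformed to a plain local alignment of the
query against the reverse complement of the target: G:C pairing becomes a
(G,G) identity, A:U becomes (A,A), and the wobble maps to the off-diagonal
(G,A)/(T,C) cells of the transformed matrix. All sequence is held in the DNA
alphabet (U folded to T on input); N is a legal character because it is how
masked intron interiors are represented.

## Search

Two entry points share one extraction engine (a Gotoh affine-gap
Smith–Waterman, compiled with numba):

* `align_duplex_exact` fills the full DP matrix and extracts all locally
  maximal, mutually non-overlapping alignments at or above the threshold,
  greedily by descending score; each extracted alignment's footprint is
  masked on both molecules before re-running. Ties among co-optimal end
  cells are broken toward the smaller (lnc_start, target_start). This is the
  oracle: quadratic, exact, used directly at small scale.
* `align_duplex_seeded` is the production search. Exact Watson–Crick
  complementary runs of `seed_len` (default 10; wobble excluded from seeds,
  allowed in extension) gate the expensive work: a pair with no seed is
  never aligned; around each cluster of seeds a window (default ±400 nt) of
  the DP matrix is solved exhaustively, and candidates undergo a global
  greedy non-overlap selection.

Whenever |q|·|t| is at most a cutoff (default 640,000 cells ≈ 800×800 nt),
the seeded search simply runs the exhaustive DP. This is a deliberate design
choice rather than an optimization: no WC-seed length can make seeding
provably complete, because an alignment can in principle reach any score
through wobble chains alone (poly-G vs poly-U scores +1 per column with no
WC pair), and mixed wobble/WC columns routinely interrupt fixed-length WC
runs in borderline-scoring alignments. Below the cutoff the seeded search
therefore *is* the oracle; above it, it carries the documented seeding
contract (every alignment containing a perfect WC run of `seed_len` is
recovered) — which planted and biological duplexes at the default thresholds
satisfy comfortably, since a 107-scoring duplex is dominated by long WC
stretches in practice.

Role-swap symmetry holds for the best score always, and for the full
reported set whenever optima are unique; with ties, the asymmetric
tie-break can select different members of a co-optimal family depending on
which molecule is the query.

## Threshold calibration

The cutoffs used by the pipeline (107 mature / 108 pre-mRNA) are
configuration constants calibrated at transcriptome scale. For other search
spaces, `calibrate_threshold` reproduces the calibration empirically:
maximal duplex scores of n (default 200) composition-preserving shuffled
sequence pairs are collected, a Gumbel law is fitted to the maxima by
maximum likelihood (`scipy.stats.gumbel_r`), the location/scale (μ, β) are
converted to Karlin–Altschul form λ = 1/β, K = e^(μ/β)/(m₀·n₀) with m₀·n₀
the per-pair search area, and the threshold is the smallest integer s with
E(s) = K·m·n·e^(−λs) strictly below the target (default: one expected
chance alignment), rounded up (conservative) and floored at the smallest
positive pair score. The null is mononucleotide-preserving; dinucleotide
shuffles are out of scope. Calibration accuracy is limited by the ML fit on
a few hundred discrete maxima — the self-consistency test asks only that
the chance-hit count on an independent equal-size null lands inside the 95%
Poisson interval of the target.

## Pre-mRNA mode and junctions

Pre-mRNA queries are unspliced transcripts in which, for every intron longer
than 2·`flank` (flank default 250 nt), positions farther than `flank` from
both splice sites are replaced by N. Masking substitutes rather than
deletes, so pre-mRNA coordinates map linearly and invertibly to the genome.
A long N run behaves as a wall in practice: crossing k masked columns costs
6k (or 20+8k by gapping), which is unprofitable unless the sequence beyond
contributes more than that — guaranteed for the 100+ nt interiors produced
by realistic intron lengths, but *not* a theorem for arbitrarily short runs
between two strong complementary blocks. An interaction "spans" a splice
junction only if the boundary is strictly interior to its target interval
(at least one paired base on each side); short introns (≤ 2·flank) are
retained whole.

## Genome projection and classification

Transcript-space intervals are projected to exon-split genomic blocks
(strand-aware; minus-strand transcripts map 5'→3' onto descending
coordinates), merged per (chromosome, strand) into minimal disjoint unions.
Region classification on coding targets uses containment: entirely within
5' UTR / CDS / 3' UTR gives that class; overlapping the CDS and at least one
UTR gives CDS_UTR; non-coding biotypes are always `noncoding`. Two pre-mRNA
edge cases are resolved as package policy (the underlying protocol is silent):
a span touching both UTRs but no CDS is assigned the larger UTR overlap, and
an intron-only hit is classified by the mature position of its enclosing
junction. An interaction is *cis* when the two gene spans (union of each
gene's transcripts' exonic extents) overlap by ≥1 bp on the same chromosome
on opposite strands — the natural antisense configuration — otherwise
*trans*.

## Regulatory rule filters

All four filters test features against the union of the interaction's
genomic fragments and require the feature to sit on the target transcript's
strand (the protocol states strand explicitly only for the splice filter;
strand-blind matching would admit spurious antisense hits, so it is applied
uniformly):

* **splice_mask** (junction-spanning pre-mRNA interactions): a
  splicing-factor CLIP site entirely within the region. Each spanned splice
  site is classified *constitutive* iff every isoform of the gene whose
  genomic span covers the position uses it as an exon boundary, else
  *alternative*.
* **mirna_mask** (mRNA interactions): at least half of a merged,
  CLIP-supported miRNA site within the region; odd lengths round up
  (ceil(len/2)). The site set is the per-strand intersection of the merged
  CLIP and merged predicted sets; target prediction itself is consumed as
  BED, not re-implemented.
* **smd**: an Alu element entirely within the region *and* entirely within
  the 3' UTR (mature coordinates (CDS end, transcript end]) of a
  protein-coding target.
* **editing**: a single-base A-to-I site inside the region (half-open
  membership: a site at the exclusive end does not count).

All filters are monotone in both arguments and commute with partitioning the
interaction set, so they parallelize trivially.

## Expression support

Read mapping is upstream; the package consumes per-read mapping summaries.
A read is discarded if it has more than ten mapping positions or touches
more than one gene; transcript-level counting additionally requires exactly
one hit (a read hitting one transcript at two positions is not
transcript-unique — the stricter reading of "uniquely mapped to a
transcript"). Hits exceeding the one-mismatch allowance are dropped with a
warning, since they should not have left the mapper. RPKM =
count/(length/1000)/(total/10⁶) with the library total taken as that
library's unique-surviving read count at the chosen level (a stated choice;
total *mapped* reads would be equally defensible). "Expressed" defaults to
RPKM > 0, i.e. one unique read. Co-expression requires both molecules above
the cutoff in at least one common library; balance in a library holds when
the two RPKMs differ by less than ten-fold or the lncRNA is the more
abundant molecule. The transcript-level expressed set is provably contained
in the gene-level set.

## Synthetic fixture

The generator emulates every input class at desk scale: 11 chromosomes
(~4–8 kb), twenty 3-exon genes (exons 200/200/400 nt, introns 600/500 nt —
one maskable, one not — alternating strands, CDS at mature [80, 450), four
non-coding genes, one skipped-exon isoform providing alternative splice
sites), ten lncRNAs including one natural antisense transcript inside the
first gene's long intron, planted perfect-complement duplexes of controlled
G:C/A:U composition (score = 4·n_GC + 2·n_AU by construction), regulatory
features in deliberately rule-satisfying or rule-violating positions,
and a three-library read-mapping design exercising every uniqueness rule.
Background sequence is i.i.d. uniform; GC content is configurable because
chance-hit rates depend on it.

Two generator details matter for exactness. Each plant is flanked by 8-nt
poly-A guard runs on both molecules: an A:A face has no positive column
under the matrix, so the optimal local alignment provably coincides with the
planted segment (without guards, chance extension past the boundary changes
coordinates for a nontrivial fraction of seeds). The antisense lncRNA's two
pre-mRNA hits are bounded by the masking window on one side and the lncRNA
ends on the other, so their coordinates and scores are closed forms of the
generated genome. Truth counts for the rule filters come from construction
knowledge, never from running the filters — the comparison is a genuine
oracle. The default fixture runs both full pipeline modes in about one
second.

What passing on this fixture does **not** show: behaviour under biased
composition, repeat-dense regions, sequencing-error-driven mapping noise, or
isoform-deconvolution ambiguity — real transcriptomes have all of these and
the fixture has none.

## Numerical and scale choices

DP matrices are int32 with a −10⁷ sentinel for masked positions; the exact
path refuses problems above 6.25M cells (≈2500×2500) to bound memory.
Traceback prefers pairing over gap-in-target over gap-in-query, giving
deterministic alignments. Test-suite and acceptance-script problem sizes
(hundreds of pairs of ≤300–400 nt, 300-pair calibration nulls) were chosen
so the whole suite completes in well under a minute while keeping every
stochastic check's expected behaviour unambiguous; they are scale choices,
not statements about the method's capacity.

## Known limitations

* No thermodynamics, structure or accessibility: a perfect complement inside
  a stable hairpin scores the same as an accessible one.
* The seeded path above the exhaustive cutoff can in principle miss
  wobble-only or heavily fragmented alignments that contain no WC seed run.
* Gumbel calibration assumes the scoring regime is local (negative expected
  column score) and the null composition matches the search composition.
* cis/trans uses ≥1 bp gene-span overlap; "same locus" has no universally
  agreed quantification.
* The accuracy harness ships synthetic positives; a curated biological
  positive set must be supplied by the user as FASTA pairs.
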