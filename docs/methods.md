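# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic benchmarks show.

## Split-pool barcodes and demultiplexing

A scheme is an ordered list of ligation rounds; each round holds >= 2 tag
sequences of one length, categorized Odd/Even/Terminal with the Terminal
round ligated last and therefore sequenced first (the default
`read_order: reverse_ligation`; the on-read layout is not dictated by the
chemistry, so it is explicit configuration). The barcode space is the
product of per-round tag counts — 8 rounds of 12 tags give 12^8 =
429,981,696 distinct strings, i.e. a ~1-in-430-million chance that two
beads collide.

Tag matching is positional: fixed offsets derived from tag and spacer
lengths, not sequence search. This is O(1) per round and matches the
deterministic ligation architecture. Each positional slice is compared
first against the expected round's tags, then against every round's tags
of that length; schemes validate that tags are pairwise farther than
2 x `mismatch_tolerance` (default 1), so correction is unambiguous. A tag
identified from the *wrong* round marks the barcode out-of-order, and
cluster filtering removes such strings along with identical-repeat
strings — these cannot arise from sequential ligation and indicate
chimeras. Unmatched slices leave gaps; gapped reads are kept (routed to a
counted sink at clustering) so losses are auditable.

Read routing is by RPM adaptor content: reads whose insert mate carries
`ATCAGCACTTA` (within the mismatch tolerance, anchored trimming at both
ends) are RNA; reads whose insert starts with a known antibody-tag
sequence followed by a UMI are oligo reads; everything else is
UNASSIGNED. Routing is a partition — no read is silently dropped.

## Clusters, deduplication, assignment

A cluster is the multiset of oligo and RNA records sharing one complete
barcode string. PCR duplicates are collapsed exactly: oligo reads on
(antibody tag, UMI) and RNA reads on (reference, start, end, strand).
Two scoping decisions were open:

* UMI deduplication is scoped within (cluster, antibody tag). Global
  scoping would collapse distinct bead-tag species that coincidentally
  share a UMI (likely at UMI length 8 and a few tags per bead).
* The RNA duplicate key includes strand; antisense duplicates are
  biologically distinct molecules.

Both operators are idempotent and commute; the exact-match collapse does
no UMI error correction (directional networks etc. are out of scope).

Assignment applies three rules to the deduplicated tags: >= 3 oligo tags
(`min_oligos`), modal antibody >= 80% of tags (`frac_unique`, boundary
inclusive), and <= 100 RNA reads (`max_rnas`, a guard against bead
aggregates). Ties for the mode are AMBIGUOUS: no principled tie-break
exists, and a false protein label costs more than a lost cluster. The
`max_rnas` filter is applied in all analyses, not only two-condition runs,
for consistency; it is configurable. Multimapping RNA reads are excluded
at ingestion (secondary/supplementary flag, MAPQ < 30, or NH > 1).

## Permutation background and peak calling

Coverage pile-ups shared across antibodies (abundant transcripts, sticky
regions) must not become peaks. For a protein with N reads, the empirical
null is built by sampling exactly N reads uniformly *without replacement*
from the pooled reads of all other proteins — negative controls included —
and counting them on the same grid, n_perms >= 100 times (default 100). If
the pool is smaller than N the run errors out rather than silently
sampling with replacement. Per window,

    enrichment = observed / mean(perm counts)
    p = (k + 1) / (n_perms + 1),  k = #perms with count >= observed

with the observed sample included in numerator and denominator; the
smallest attainable p is 1/(n_perms+1), making the test conservative at
small n_perms. Peaks are windows with observed >= 10 and p < 0.05
(strict). No multiple-testing correction is applied by default (an
optional Benjamini-Hochberg switch would be a trivial addition, but raw
p < 0.05 with the read floor is the operative criterion).

Counting decisions:

* Windows tile genomic coordinates from 0 in fixed non-overlapping steps
  (10 or 100 nt; default 100). A read increments **every** window it
  overlaps. Observed and permuted reads are counted identically, so the
  enrichment ratio is unbiased under either the overlap or the 5'-end
  convention; overlap counting was chosen because it makes window counts
  interpretable as coverage.
* Counting is strand-aware by default (stranded library); switchable by
  merging strands upstream.
* When the permutation mean is zero, the enrichment denominator is floored
  at 1/n_perms — the smallest nonzero mean the permutations could have
  shown — and the window is flagged `expected_floored`. This preserves
  ordering among floored windows without fabricating significance: the
  p-value is computed from the permutation counts and is unaffected.

### Null calibration: what is (and is not) controlled

On a signal-free experiment the per-window p-values are valid, so the
fraction of grid windows passing the *combined* peak criterion
(>= 10 reads and p < 0.05) stays at or below alpha up to Monte-Carlo
noise; the null-calibration study measures exactly this rate (worst
protein ~= 0.05 at 200k reads over 100 kb). The fraction of small
p-values *among* windows preselected for >= 10 reads is a different
quantity and is **not** expected to be small at moderate coverage:
conditioning on an upper-tail read count selects precisely the windows
where the target fluctuated up, which is what a small p records. At mean
window coverage >> 10 the distinction vanishes.

## Truncation (RT-stop) mapping

UV crosslinks stall reverse transcription, so the 3' end of the cDNA —
the alignment end nearest the RNA 5' terminus: the start coordinate for
plus-strand reads, end-1 for minus-strand — marks the binding site at
single-nucleotide resolution. Each read collapses to that 1-nt
coordinate and the identical permutation machinery runs at window width
1. Motif-centered profiles aggregate truncation counts by signed,
strand-aware offset from the first base of motif hits (supplied by an
external motif scanner and restricted to significant peaks); the package
exports peak-restricted read sequences as FASTA for such scanners but
does not do motif discovery itself. No minimum read length is imposed on
truncation reads (none is established; the simulator's reads are all
>= 20 nt).

## Peak annotation

GTF input (GENCODE-style attributes; 1-based closed coordinates converted
to the 0-based half-open used internally, losslessly) is indexed into
interval trees. Each peak gets exactly one label by priority: miRNA >
CDS > 5'UTR > 3'UTR > proximal intron > distal intron > non-coding exon >
non-coding intron, with "intergenic" when nothing overlaps. Choices:

* "Proximal" means within 500 nt of a splice site, measured from the
  nearer of the two boundaries of the *overlapped* intron (the reference
  point was unspecified; the nearer-boundary rule is symmetric and
  monotone in distance).
* Priority is evaluated over the union of all overlapping features across
  genes and isoforms, not per-gene-then-merged.
* Matching requires same-strand overlap by default.
* Peaks whose winning annotation belongs to a miRNA host gene are
  relabelled `miRNA_proximal` (the miRNA body itself still outranks
  everything).
* UTR sides (5' vs 3') are derived from exon/CDS geometry and strand, so
  GTFs without explicit UTR features annotate correctly.
* The blacklist (e.g. for poorly-aligned rRNA regions) is user-supplied
  BED; no default interval ships because no universally valid one exists,
  and intervals are validated (start < end) before use.

Composition vectors drop intergenic peaks, then drop proteins with <= 100
remaining peaks (strictly more than 100 required), then normalize per
protein to fractions summing to 1.

## Cross-dataset statistics

Peak-set overlap uses a 2x2 table over a window universe. The universe is
a real modeling choice: the package defaults to windows observed (>= 1
read) in the combined pool of both datasets, because counting
never-observable windows as "shared absences" inflates significance; an
all-genomic-windows universe is available. The p-value is the exact
hypergeometric upper tail P(X >= |A∩B|); the odds ratio is
(n11*n00)/(n10*n01) with a Haldane-Anscombe 0.5 added to every cell only
when some cell is zero (flagged).

The composition-similarity test compares two protein x category fraction
matrices by the L2 norm of their flattened difference. The null permutes
whole protein rows of one matrix (keeping each protein's composition
intact) while holding the other fixed, alternating which matrix is
shuffled, 1000 draws by default; the empirical p is the fraction of null
draws with L2 <= observed (small = similar), add-one smoothed.

## Two-condition differential binding

Per protein and condition, the background-corrected bedGraph is reduced to
one value per gene: the maximum *absolute* signal over bedGraph intervals
intersecting each isoform's span (absmax semantics — magnitude, not the
signed extreme), keeping the best-covered isoform. Values are divided by
the number of assigned bead clusters for that protein in that condition,
correcting the detection bias of unequal bead recovery; a zero bead count
is an error (the protein is unusable in that condition), and equal bead
counts leave ratios untouched. Genes with zero signal in either condition
are excluded from log2 ratios (the ratio is undefined). Genes are grouped
by an externally supplied per-gene score — e.g. the 5'TOP-motif strength
of Philippe et al. 2020 — with user-configured bin edges (no canonical
edges exist; unscored genes go to an "unscored" bin), and groups are
compared with a two-sided Mann-Whitney U test. The exact path (combined
n <= 20) enumerates all rank assignments with midranks for ties, since
the common exact implementations do not handle ties; larger samples use
the tie-corrected normal approximation, and the two paths agree to within
10% at the crossover. Per-protein read-count ratios between conditions
are bead-normalized the same way; a zero denominator reports as infinite
and flagged rather than dropped.

## The synthetic experiment generator

The generator emulates the data-generating process the pipeline assumes:

* **Beads**: each carries one antibody; oligo-tag counts per bead are
  zero-truncated Poisson with mean 4.0, giving the observed median of 4
  tags per cluster (only a median is established, not a distribution;
  ZTP is the simplest count model conditioned on detection).
* **Crosstalk** (default 5%): a tag reports a different, uniformly chosen
  antibody — modeled at the tag level, matching the observation that
  real clusters contain minority tags. At the defaults >80% of clusters
  carry a single antibody's tags.
* **Barcodes**: one tag per round drawn uniformly; per-read, per-round
  ligation failures (default 5%) render that tag unreadable (emitted as
  Ns). Tag codes are generated with pairwise Hamming distance >= 3
  globally, so decoding and out-of-order detection are exact.
* **RNA reads per bead**: negative binomial (mean 10, dispersion 2) — the
  real distribution is unreported; NB allows the overdispersion bead
  preparations show. Background reads are uniform over the contig, both
  strands, lengths ~ Normal(60, 10) clipped at 20.
* **Planted sites**: a site (protein, position, footprint, fold,
  truncation_fraction, strand, optional condition) adds
  round((fold-1) x E) reads overlapping the footprint, where E is the
  protein's expected background read count over the footprint — total
  coverage at the site is then ~fold x background. A `truncation_fraction`
  of the planted reads start exactly at the crosslink coordinate.
* **PCR duplicates** (default 10%): byte-identical coordinates/UMIs under
  a fresh read name, recorded in the truth tables as `duplicate_of`.
* **Genome/annotation**: one contig (default 100 kb) of uniform random
  sequence with a deterministic gene layout exercising every annotation
  category: a two-isoform coding gene, a minus-strand coding gene, a
  coding miRNA host with the miRNA in its intron, a single-exon
  histone-like gene, and a two-exon lncRNA.
* **Sample multiplexing**: optional condition labels partition the
  first-ligated round's tags across conditions, as used for two-condition
  designs.

All outputs (FASTQ pairs for both libraries, pre-aligned SAM with the
barcode in the `XB` tag, FASTA, GTF, scheme YAML, truth TSVs) are
byte-identical across reruns with the same seed (gzip timestamps pinned).

What the simulator does **not** emulate: sequencing errors beyond
unreadable tags, alignment artifacts (indels, clipping, multimapping),
non-uniform transcriptome expression, fragment-length biases, or
antibody-specific efficiency differences. Passing benchmarks therefore
demonstrate the correctness and calibration of the *computation* under
the model's assumptions, not performance on real libraries — in real
data, expression structure makes the matched-depth permutation background
essential rather than merely calibrated.

## Benchmark study sizes

Chosen so each study carries enough events to measure its rate while the
whole set runs in a few minutes on one CPU:

* Null calibration: 10 proteins, ~200k reads (18,200 beads), 100 kb
  contig, 100 permutations — worst per-protein null peak-call rate.
* Planted recovery: 50 sites at 10-fold on a 30 kb contig (2,000 beads),
  one site per window, >= 45 reads per site after pipeline losses. The
  smaller contig keeps the per-window background near 2 reads, where a
  chance 10-read window is rare; precision is measured against per-read
  truth provenance because planted reads extend read-length beyond the
  footprint.
* Assignment accuracy: 5,000 beads, 5% crosstalk, median 4 tags —
  accuracy over non-ambiguous calls with collision-free barcodes, plus
  exhaustive agreement with a literal three-rule oracle on all small tag
  multisets.
* Truncation resolution: 20 proteins, one site each at 25-fold with
  truncation_fraction 0.5 (>= 20 truncated reads per site), argmax of
  per-nucleotide enrichment per protein.

## Known limitations

* Alignment is consumed, not performed; the simulator emits pre-aligned
  records and real data must be aligned upstream.
* The permutation matrix for truncation analysis is dense
  (n_perms x contig length per strand); fine for the intended per-RNA and
  small-genome use, but a whole-genome single-nucleotide scan would need
  a sparse implementation.
* UMI collapse is exact-match only.
* The annotation index loads the whole GTF into memory; adequate for
  transcriptome-scale annotation, untested against multi-GB GTFs.
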