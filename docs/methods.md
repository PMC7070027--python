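# Methods

## Data model and coordinates

All genome coordinates are 1-based inclusive (GFF3 convention); BED input
is converted on read from 0-based half-open.  A read is one primary spliced
alignment, taken as a full-length mRNA observation (direct RNA-seq
chemistry sequences whole native molecules, polyA tail first).  Exon
chains come from the CIGAR: alignment-match (`M`/`=`/`X`) and deletion
(`D`) operators extend the current exon — deletions of any size stay
intra-exon — and each reference skip (`N`) closes one exon and opens the
next, mirroring spliced-aligner semantics.  Soft clips are recorded in
transcript orientation (for minus-strand alignments the CIGAR-leading clip
is the transcript 3′ clip).  Secondary, supplementary and unmapped records
are skipped and counted; MAPQ is not filtered by default (`min_mapq = 0`).

Strand conventions: a transcript's TSS is its 5′-most aligned base (first
exon start on `+`, last exon end on `-`); a junction is (donor = last
exonic base of the 5′ exon, acceptor = first exonic base of the 3′ exon),
so minus-strand junctions have donor > acceptor.

## End clustering

TSS and TTS positions are tallied exactly per strand, then clustered
greedily by abundance: seed at the most frequent unassigned position
(count ties break to the smaller coordinate, for determinism), absorb all
unassigned positions within ±`window` nt, repeat.  Both windows default to
15 nt and are independently configurable; they are reported in output
headers since there is no a-priori reason they must be equal.  Clustering
is computed on the pooled multi-sample tally so group keys are stable
across time points, which the polyA trend analysis requires.  Two
consequences follow from the rule and are asserted as invariants: cluster
representatives on the same strand/role always differ by more than the
window, and member counts are conserved.

Splice sites are deliberately not clustered: spliceosomal boundaries are
exact, and a 1 nt shift in a donor or acceptor is a different junction.

## Transcript groups

The group key is (strand, TSS-cluster representative, exact ordered
junction chain, TTS-cluster representative).  Reads on different strands
can never share a group.  The group's consensus exon model — used for all
downstream sequence work — is rebuilt from the representatives and the
junction chain; in rare cases a breakage-derived read's first exon is
shorter than the clustering window and the representative would cross a
junction, making the model inconsistent; such groups are skipped during
annotation with a logged warning and counted.  Because the published
counts of splice "patterns" can be read either per full key or per splice
chain, both granularities are reported (full groups, and a
splice-chain-only rollup).

A `min_count` report filter supports "ten or more supporting reads"-style
slices without discarding data.

## Pseudo transcripts and the 5′ extension

Each group's exon model is spliced out of the genome in transcript sense
(minus-strand groups complemented base-by-base along a strictly decreasing
coordinate map).  Before ORF scanning the sequence is extended by
`extension` genomic bases (default 10) upstream of the TSS representative,
clipped at genome ends.  Rationale: mapped nanopore 5′ ends sit
systematically ~8–15 nt downstream of true promoters, which can hide a
start codon lying a few nt from the cap and silently re-classify the
transcript to the next AUG downstream.  The extension is monotone — it can
only add sequence 5′ of existing AUGs — so it never destroys a call, and
the truncated-simulation analysis measures its effect directly
(feature-match accuracy at extension 10 strictly exceeds extension 0).
With truncation uniform on 8–15 nt a 10 nt extension cannot rescue groups
whose modal under-read exceeds 13 nt; the residual loss visible in noisy
runs is expected behaviour, not a defect.

## ORF scanning and canonical matching

Every AUG opens a candidate; reading proceeds to the first in-frame stop
(UAA/UAG/UGA; `complete`) or the transcript end (`incomplete`, retained
and flagged).  Candidates shorter than `min_aa` (default 10 residues) are
dropped unless their start codon sits at a canonical feature position,
which is always retained — so a very short canonical peptide is
representable when listed as a feature and ignored otherwise.  Non-AUG
initiation is out of scope.

Canonical identity is by start-codon genome position + strand, not protein
sequence: spliced leader fusions sharing an N terminus match the same
feature, while full genomic footprints (each call records its spliced
block list) remain available as the dedupe key for distinct-ORF counting.
Matching never fails on length: a positional match whose ORF is shorter
than the feature's `expected_aa` is reported as `truncated`, leaving
interpretation to the user.  Classification is the 5′-most-ORF rule: if
the rank-1 ORF matches a feature the group is that feature's; otherwise
ranks 2, 3, … are scanned and the first canonical hit is flagged
`second_methionine`; no hit at all is `no_known_orf`.

Per-feature usage percentages are computed against all classified reads of
a sample; second-Methionine matches count in neither their feature's row
nor the no-known-ORF row, so columns do not sum to 100.  The dominant
transcript of a feature is the highest-count group whose *rank-1* ORF is
that feature (ties to the smaller TSS representative).

## PolyA statistics

Only reads whose polyA record is QC `PASS` with estimated tail ≥ 20 nt
enter tail-length summaries (the `min_polya` floor is configurable).
Whether non-usable reads should also be excluded from grouping is genuinely
ambiguous; it is exposed as `require_polya_for_grouping` (default false)
rather than guessed.  Class summaries (mean, n−1 standard deviation, n)
are computed per transcript group or rolled up per encoded feature; the
feature rollup is the "mRNA class" unit on which time-course tests are
defined, and is what the acceptance script reports.

The paired test is the Wilcoxon signed-rank test — each class contributes
one paired data point — with zero differences dropped and reported.  The
null distribution is exact for n ≤ 25 (rank-sum convolution over all 2^n
sign assignments, with doubled midranks so ties stay exact) and a
tie-corrected normal approximation without continuity correction beyond.
The unpaired test is the Mann–Whitney U: exact by complete enumeration of
C(n+m, n) group assignments when n + m ≤ 12, tie-corrected normal
approximation otherwise.  Both are two-sided; no multiplicity correction
is applied.  scipy implementations serve as independent oracles in the
test suite only.  Tests are refused below 5 paired classes (3 per group
for the unpaired test); deltas are still reported.

## Splice concordance

A spliced read is concordant iff all its junctions occur in the short-read
junction set, matched exactly on (donor, acceptor, strand); an optional
±k fuzz exists for exploration, default 0.  Unspliced reads carry no
testable junction: the all-junctions criterion is vacuous for them, so
they are tallied separately and excluded from the primary denominator
(the with-unspliced fraction is also emitted).  With per-junction dropout
d, a k-junction transcript is discordant with probability 1−(1−d)^k; the
test suite checks measured discordance against binomial bounds of this
analytic expectation over replicate junction-set draws.

## The simulator

`make_genome` builds a 20 kb genome with 15 designed isoforms over 8
transcription units on both strands: shared promoters with alternative
splice chains and alternative TTS, an unspliced unit, a 2-intron unit, a
designed second-Methionine transcript (a 12-residue decoy ORF upstream of
its feature's AUG) and two designed no-known-ORF transcripts.  Sequence
content is written constructively: ORF bodies use a stop-free, AUG-free
codon alphabet; every base upstream of each isoform's designed rank-1 AUG
(including 15 nt of genomic context beyond the TSS, covering any 5′
extension up to that length) is scrubbed of AUGs; introns are flanked
GT..AG in transcript sense.  Construction fails loudly ("infeasible
geometry") if a scrub region would touch protected content, and a test
runs the annotator over every truth exon model to confirm the designed
classification.

Noise model defaults (the study conditions): 3 samples × 5000 reads;
5′ under-read uniform on 8–15 nt; 3′ jitter uniform on ±5 nt; 5% of reads
start at an internal (breakage) position; soft-clip lengths drawn with 5′
mode 1 and 3′ mode 2; 60% of reads receive a PASS polyA call; per-read
tails are lognormal with CV ≈ 0.5 (so SD ≈ 50 at a mean of ~100 nt) around
per-isoform base means of 85–127 nt declining 20% per successive sample;
short-read junction dropout 10%.  Reads are emitted as SAM alignments, not
signal or FASTQ — the pipeline's contract begins at mapped reads — with
placeholder clipped bases keeping CIGAR/SEQ lengths consistent.  All
randomness flows from one seed; identical configurations produce
byte-identical outputs.

What the simulator does not emulate: base-calling errors and alignment
ambiguity (exon boundaries are exact up to the modelled end noise),
reference/sample sequence divergence, polyA QC failures correlated with
tail length, and cross-mapping from a host transcriptome.  Passing the
recovery tests therefore demonstrates correctness of the classification
logic under the modelled end-noise, not robustness to alignment error.

## Problem sizes and numerical choices

The bundled analyses use 3 × 5000 reads (acceptance) and 3 × 800 reads
(unit fixtures); both recover all 15 isoforms exactly in the noise-free
setting.  Determinism choices throughout: count ties seed to the smaller
coordinate; equidistant cluster assignment prefers the earlier-seeded
cluster; dominant-transcript ties prefer the smaller TSS representative;
clip-mode ties prefer the smaller clip; groups sort by total count then
key.  Exact-test cutoffs (n ≤ 25 signed-rank, n + m ≤ 12 Mann–Whitney)
keep enumeration under a millisecond while covering the class counts the
trend analysis actually produces.

## Known limitations

- Group consensus models assume the end-cluster representative does not
  cross the first/last junction; violating groups (breakage artefacts) are
  skipped and counted rather than repaired.
- Canonical matching is positional only; a feature whose AUG is created or
  destroyed by sequence variation between sample and reference will not
  match.
- The concordance module consumes junction tables; it does not call
  junctions from short-read BAMs.
- Real-data preprocessing (base-calling, error correction, spliced
  alignment, polyA estimation) is out of scope; reference command lines
  are documented as comments in the config template.
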