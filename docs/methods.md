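# Methods

This note documents the models and procedures `txomeval` implements, the
defaults it ships, the numerical choices that matter, and what the
synthetic-data study does and does not demonstrate.

## Assembly statistics and redundancy reduction

**N50.** The smallest length *L* such that transcripts of length ≥ *L*
jointly contain at least half of all assembled bases (sort descending,
accumulate, compare after adding the current transcript). The tie
convention — the accumulating transcript's own length counts before the
half-total comparison — matches common assembly-stats practice; at exact
half-total boundaries other conventions differ by one rank.

**Redundancy clustering.** Pre-assembled contig pools contain near-duplicate
sequences. Two transcripts are *linked* when a local alignment on either
strand reaches ≥ `min_identity` (default 0.90) over the aligned region and
leaves ≤ `max_overhang` (default 30 nt) unaligned at each end of the
shorter sequence; links close transitively (single linkage), and the
longest member (ties: lexicographically smallest id) represents each
cluster. Design notes:

* Identity is matches / aligned columns, gap columns included; positions
  involving IUPAC ambiguity codes never count as matches.
* The overhang budget applies to each end separately. Whether a summed
  budget was intended is ambiguous in the field's tool descriptions; the
  per-end reading is declared here, not inferred.
* Candidate pairs are prefiltered by a shared canonical 16-mer
  (strand-independent) before alignment; at ≥ 90% identity over any
  usefully long overlap a shared exact 16-mer exists with high probability.
* Both strand alignments are tested independently against the link
  criterion. Selecting a single "best" alignment by identity is a trap: a
  spurious 12 nt perfect local alignment on the wrong strand would outrank
  a genuine 96%-identity full-length alignment.
* The representative is the longest member, not a base-level consensus:
  the merge's observable effect (one sequence per redundancy group) is
  preserved without reimplementing consensus calling.
* Alignments use Bio.Align.PairwiseAligner (local; match 2, mismatch −3,
  gap open −5, extend −2).

## Six-frame translation and ORFs

Translation uses the standard genetic code; frames −1..−3 read the reverse
complement. Any codon containing an ambiguity code renders `X` — stricter
than resolving partially ambiguous codons (GCN → Ala), deliberately: an
ambiguous position must never support a peptide identification, and the
matcher treats `X` as matching nothing.

ORFs are **stop-to-stop**: maximal stop-free codon stretches, sequence ends
counting as boundaries, with no start-codon requirement. The search
database keeps ORFs strictly longer than 25 aa (26 aa in, 25 aa out).
Headers (`id|frame|ntstart-ntend`, 0-based half-open forward-strand
coordinates) round-trip. The longest-ORF tie-break is frame order
+1, +2, +3, −1, −2, −3, then leftmost within the frame.

## Coding-potential null model

For transcripts with no homology evidence, coding potential is assessed
against a random null: a set with the same number and lengths as the input
(replicated `n_replicates` times), base composition matched to the input
pool by default (uniform on request). Per 50 bp length bin the report gives
the null maximum longest-ORF and the count/fraction of real transcripts
strictly exceeding it; binning respects the strong length-dependence of
random ORF lengths. A pooled (global-maximum) variant exists but conflates
lengths and is not the default reading.

Calibration: when the "real" set is itself drawn from the null, each real
transcript exceeds the maximum of the *m* null values in its bin with
probability 1/(m+1) for continuous exchangeable values. Longest-ORF lengths
are integers, so exact ties at the maximum occur (a percent-level effect at
these lengths) and the exact expectation is P(unique maximum)/(m+1). The
test suite verifies the implementation against a 10,000-draw Monte-Carlo
oracle built on an independent translation path, checks the tie-corrected
expectation, and confirms the continuous-case anchor to within the tie
rate.

## Peptide evidence

Matching is exact substring search of identified peptide strings against
the six-frame search database. Leucine and isoleucine are isobaric in
standard MS/MS, so matching collapses I to L (configurable); distinct
peptide counting uses the same collapse. Spectrum-level scoring is out of
scope — the pipeline consumes peptide sequences, not spectra.

**Validation tiers.** A transcript with ≥ 1 distinct matched peptide is
peptide-verified; the ≥ 2-peptide tier is the conservative protein-coding
call, mirroring standard two-peptide practice.

**Frameshift detection.** Per transcript, non-decoy hits sorted by
nucleotide start are collapsed into runs of same-frame hits; each adjacent
pair of segments in different frames, on the same strand, with
non-overlapping spans counts one shift. At least one peptide per segment is
therefore required to see a shift — an implanted indel with an unsampled
flank is invisible, which is why recovery is asserted only under full
segment coverage, and why calls can undercount but never exceed the truth.
Transcripts with peptide evidence on both strands are reported as
anomalies, never counted: a genuine assembly indel continues the coding
sequence on the same strand.

**Target–decoy FDR.** Decoys are per-entry reversed database sequences;
FDR = distinct decoy-matched peptides / distinct target-matched peptides,
passing strictly below 1%. Reversal preserves composition and length while
destroying order; for substring matching this is adequate, and K/R
positions need not be preserved because no enzymatic scoring is applied.
With hundreds of thousands of database residues and thousands of peptides,
a handful of *reversal coincidences* — peptides whose reversed sequence
genuinely occurs somewhere in the target database — is expected; the test
suite enumerates them with a brute-force oracle and requires the decoy
matches to be exactly that set.

## Annotation filtering

Hits arrive as 12-column BLAST tabular plus a description column; database
and taxon are file-level metadata. The working cutoff is e-value ≤ 1e-15
(inclusive — the boundary convention is declared, since "cutoff at e-15"
alone does not fix it). Descriptions containing `mRNA`, `cDNA`, `clone` or
`genomic` (case-insensitive substring; word-boundary matching available)
are flagged low-quality but retained. Per (query, taxon, database) the top
3 hits by ascending e-value (ties: descending bitscore, then subject id)
are kept; the functional assignment per (query, taxon) is the best-rated
GO-bearing hit at the stricter 1e-20 cutoff.

Annotation-rate curves count a transcript annotated when ≥ 1 hit survives
the cutoff, binned at 50 bp; L50 is the smallest bin start whose rate
reaches 0.5, scanning ascending with no requirement that later bins stay
above it (a cumulative variant is available). The ≥ 400 bp length filter
separates mostly-coding from mostly-unknown sequence, and the report gives
the annotation rate above it.

## Orthologue fullness

"Recursive best mapping" is implemented as reciprocal best hit: a
transcript and a reference protein pair iff each is the other's best match
(lowest e-value, bitscore tie-break); a one-directional mode exists for
comparison. Full length means the alignment covers strictly more than 75%
of the orthologue protein. The alignment length column (gap columns
included) is used rather than subject coordinates, because assembled
transcripts running 5–25% longer than their orthologues legitimately
produce fractions above 1, which subject coordinates cannot express.

## Specificity and novelty

Among peptide-verified transcripts, `no_hit` means no surviving hit in any
database at the working cutoff; `urodele_only` means all surviving hits
come from databases designated urodele-only; anything else is `annotated`.
Candidates for novel urodele-specific proteins are the verified
`no_hit` ∪ `urodele_only` set — peptide evidence is what separates a novel
protein from a misassembly.

The PROSITE-dialect parser supports exactly the constructs needed: fixed
residues, bracketed residue classes, and `x`/`x(n)`/`x(m,n)` wildcards
joined by `-`, with optional wrapping parentheses. Anchors (`<`, `>`),
class repetition and negated classes are rejected loudly rather than
half-supported. The scanner reports a match at every start position
(overlaps included), with greedy leftmost-longest extension per start —
earlier flexible elements take their maximal width first, the same
preference order as a greedy regular expression, which the regex-oracle
equivalence test pins down exactly.

Candidate proteins cluster by direct pairwise local alignment (BLOSUM62,
open −11 / extend −1): link at identity ≥ 0.35 over ≥ 0.6 coverage of the
shorter sequence, single linkage; clusters of ≥ 2 are putative families.
Profile-iteration search would add sensitivity on real data but no testable
surface at this scale; the direct-similarity stand-in is a declared
simplification.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the pipeline assumes:

* **Coding transcripts**: 5'UTR + ATG-initiated, stop-terminated ORF +
  3'UTR. ORF length 60–400 aa and UTRs 30–300 nt by default — typical
  mRNA-scale values chosen once as realistic for a normalized cDNA-derived
  assembly; composition uniform by default. An ORF of *n* residues with
  UTRs *u5*, *u3* gives a transcript of exactly *u5* + 3(*n*+1) + *u3* nt.
* **Frameshifted transcripts**: coding transcripts with 1–3 single-
  nucleotide indels implanted inside the ORF, ≥ 90 nt apart and from the
  ORF ends — the minimal event reproducing the multi-frame peptide
  signature, spaced so each inter-indel segment can carry tryptic
  peptides. Positions, directions and corrupted codons are recorded.
* **Peptides**: tryptic digest (cleave after K/R except before P) of each
  source protein, filtered to 7–30 aa (standard MS-detectable range),
  peptides spanning a corrupted indel codon removed (the assembled
  transcript no longer encodes them), each survivor observed with
  probability `peptide_sampling_rate` (default 0.5, reflecting MS
  undersampling).
* **Hit tables**: conserved transcripts (70% by default) always get a
  protein-database hit at e ≤ 1e-20 (log10-uniform), urodele-only
  transcripts (15%) get hits only in the urodele EST table at e ≤ 1e-16,
  no-hit transcripts (15%) get nothing; a configurable fraction of
  descriptions carries a low-quality keyword.
* **Orthologues**: conserved coding transcripts get a planted mutual-best
  hit with alignment fraction uniform on (0.5, 1.05), plus weaker cross
  hits that reciprocal-best filtering must reject.

Determinism: one seeded generator stream per operation (transcriptome,
digestion, hit tables, orthologues), so outputs are byte-identical for a
fixed seed and adding one stage never reshuffles another.

Not emulated: read-level sequencing and assembly errors other than clean
indels, chimeric transcripts, paralogy and shared domains between distinct
genes, homology-score correlation with true divergence, spectrum-level
identification noise, and abundance structure. Passing tests therefore
demonstrate the correctness of the pipeline's logic and bookkeeping — exact
threshold behaviour, coordinate arithmetic, recovery of implanted signals —
not robustness to the full messiness of real assemblies.

## Problem sizes and numerical notes

The standard synthetic study is 200 coding / 100 noncoding / 50
frameshifted transcripts (~350 kb, ~9k search-database ORFs, ~3k peptides
at full sampling) — large enough for every stage to see hundreds of events
while a complete end-to-end run stays under a minute. Monte-Carlo
calibration of the coding-potential null uses 10,000 draws on 450 nt
transcripts. Oracle-equivalence checks run on 1,000 random instances each.

Degenerate inputs: empty transcript sets are rejected where a statistic is
undefined (N50, rate curves); empty peptide tables, empty hit tables and
proteins without cleavage sites flow through as empty results. E-value and
fraction comparisons are exact floating-point comparisons at the documented
boundaries (≤ cutoff, > 0.75, < 0.01); no epsilon fuzzing is applied, so
boundary cases resolve exactly as specified.
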