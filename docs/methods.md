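# Methods

This note documents the models, algorithms and numerical choices behind
mitokit, the assumptions of the synthetic-data generator, and what the
test suite does and does not establish about real data.

## Genome model and coordinates

A multipartite organelle genome is an ordered list of named isoforms
(independent circular- or linear-mapping molecules), stored as the
linearized strings in which such genomes are deposited. Circularity is a
per-isoform flag; operations that must honor it do so explicitly (see
below). All internal coordinates are 0-based half-open on the forward
strand; GFF3 I/O uses 1-based inclusive coordinates and BED output 0-based
half-open, matching each format's convention. Sequences are over
{A,C,G,T,N}; other IUPAC codes are rejected by default because downstream
identity computations need a defined alphabet (a lenient mode maps them to
N). GC content excludes N from the denominator, and an all-N window is
undefined (NaN) rather than 0.

## Homology search

Two aligners are provided, deliberately redundant:

**Exact Smith–Waterman** (`align.local_align_exact`) with affine gaps,
implemented as a quadratic-DP numba kernel. It exists as the optimum
against which the heuristic is validated and is practical to a few kb.
Among co-optimal alignments the end cell with smallest (q_end, s_end) is
chosen and the traceback prefers diagonal moves, making results
deterministic. (Selecting the co-optimum with minimal *start* would require
enumerating all co-optimal tracebacks; the end-minimal rule is an
equivalent-cost deterministic convention.)

**Seed-and-extend** (`align.seed_extend_align`), the workhorse for
genome-scale search: exact k-mer seeds (default k=13) against an indexed
subject, seeds sharing a diagonal chained when closer than 50 bp, each
chain extended ungapped in both directions under an X-drop criterion
(drop 20, trimmed back to the score maximum), overlapping segments on a
diagonal merged, then filtered by aligned length, percent identity and
Karlin–Altschul E-value (E = K·m·n·exp(−λ·score), raw lengths, no edge
correction). Both query strands are searched; coordinates are always
reported on forward strands with a strand flag. Default scoring is
megablast-like (+1/−2, gap open 2, extend 1; λ=1.28, K=0.46).

Two deliberate refinements:

- *Chain gap 50 bp.* An inverted repeat pair with a short spacer places
  both copies on a single anti-diagonal; chaining across the spacer would
  merge them into one diluted hit. Ungapped extension already bridges
  benign gaps inside a homology, so the chain gap only needs to be smaller
  than spacers worth separating.
- *Bounded identity trimming.* The score-optimal extension can overshoot a
  borderline homology into random flanks: with +1/−2 scoring, a mismatch
  followed by three chance matches is score-positive, and for a homology
  sitting just above the identity filter this dilution can push the
  reported identity below threshold. Segments failing the filter are
  therefore trimmed at their outermost mismatches — at most 2×X-drop
  (40 bp) per end, the scale of a chance overshoot — and kept if a
  compliant segment remains. The bound matters: unlimited trimming would
  carve compliant windows out of homologies genuinely below threshold,
  changing the meaning of the identity filter.

Extension is ungapped because the repeat/MTPT identity model is
substitution-only (see below); indel-containing homologies would be split
into separate diagonal hits and merged only on the mitochondrial side
during MTPT segment merging. Long-read alignment does not use this engine
at all (reads get an edit-distance aligner, below). A reader/writer for
BLAST tabular (`-outfmt 6`) allows hits from an external BLASTN run to be
substituted anywhere hits are consumed, for exact replication of
accession-based numbers; BLAST's 1-based, strand-encoded coordinates are
normalized on ingestion.

## Dispersed repeats

The genome is aligned against itself over all isoform pairs (including
self), both strands; trivial full-length self-hits and mirror duplicates
(a,b)/(b,a) are removed, keeping the copy with lexicographically smaller
(isoform, start) first. Defaults follow the standard thresholds for this
analysis: identity ≥ 95%, length > 20 bp, E < 1e−5. Size classes assign
both boundary values of 100–1000 bp to "intermediate" so the partition is
well defined. For circular isoforms the search runs on the doubled
sequence S+S with hits normalized to [0, L); rotations of already-seen
hits and artifacts longer than the isoform are dropped, so repeats
spanning the deposited origin are found. Non-redundant repeat content is
the per-isoform interval union of all repeat copies (origin-wrapping
intervals are wrapped before the union), reported in bp and as a fraction
of genome length.

The reported identity of a repeat pair is the identity of the aligned
segment. For pairs of ~100 bp and more this tracks the planted (Hamming)
identity to within one point; for very short repeats a single chance
flank match entering the score-optimal alignment shifts identity by
several points — an aligner-independent resolution limit, since exact
Smith–Waterman reports the same extended segment.

## SSRs

SSR loci are maximal perfect tandem runs of a 1–6 bp motif with at least
8 copies (mononucleotide) or 5 copies (longer motifs); only whole motif
copies count, and a trailing partial unit is not part of the locus. Runs
are found per period m from the lag-m self-match profile of the sequence.
Motifs are canonicalized to their lexicographically minimal rotation, and
runs whose motif is itself periodic are reported at the primitive period
only. Overlapping candidates (possible across motif lengths) are resolved
by keeping the longer locus, ties broken by smaller start then shorter
motif. Compound/interrupted SSRs are out of scope. An independent
position-by-position scanner exists in the test suite and the finder is
required to match it exactly on random sequences.

## Plastome repeat typology

For a single sequence, all maximal equal-length substring pairs within
Hamming distance 3 at length ≥ 20 bp are enumerated under four
orientation relations: forward (B ≈ A), reverse (B ≈ A reversed),
complement (B ≈ complement(A)) and palindromic (B ≈ revcomp(A)). Each
relation reduces to diagonal comparison of the sequence against a
transform of itself; per diagonal, the maximal windows containing at most
3 mismatches are bounded by the next excluded mismatch on each side, so
they are enumerated directly from the mismatch positions. Pairs are
canonicalized (start_a ≤ start_b) and identical intervals excluded. The
inverted-repeat pair of a quadripartite plastome appears as the longest
palindromic repeat. The oracle here is an independent two-pointer
enumeration plus a direct per-pair maximality check (every reported pair
must become invalid under each one-step outward extension).

## Recombination frequency from long reads

For each repeat pair, four templates are built: original_1/2 (each copy
with its own ±2,000 bp flanks) and alt_1/2 (left flank of one copy, right
flank of the other — the recombinant molecules). Flanks are truncated at
linear isoform ends, wrap across the origin on circular isoforms, and are
shortened (and flagged) where they would enter another detected repeat
interval, so flanks are single-copy by construction. For inverted pairs
the second copy's flanks are reverse-complemented so all four templates
are on one strand.

Read assignment uses edit-distance infix alignment (edlib) of each
configuration's *diagnostic region* — the repeat copy plus a 100 bp anchor
into each flank — against the read in both orientations. The
best-distance class wins only if (i) whole-region identity ≥ 0.8, and
(ii) each of the winning configuration's two anchors independently aligns
within the read at that identity. The anchor check is what enforces
"spans both flanks": a read ending mid-repeat absorbs its missing tail as
scattered gaps in an infix alignment, so global identity alone, or cigar
end-inspection, under-detects partial spans. Distance ties between the
original and alternative class are ambiguous. The frequency is
N_alt/(N_orig+N_alt); with no informative reads it is NaN (never 0), and
a pair whose repeat exceeds the longest read minus both anchors is
flagged "unassessable" rather than given frequency 0. A pair is called
recombinationally active with ≥ 2 alternative-supporting reads and
frequency > 0.01 (both tunable); this guards against single chimeric
reads and is a package convention, not an inferred one.

Anchor length 100 bp and read identity 0.8 are defaults chosen so anchors
exceed typical Nanopore indel noise at ~5–15% error; both are parameters.

## MTPT detection and the binned correlation

Mitochondrial isoforms are aligned against the plastome (k=11, both
strands); hits with identity > 80%, length > 200 bp and E < 1e−5 are
merged on the mitochondrial side with gap tolerance 0 (strict
overlap/adjacency — merging policy changes totals, so the strict,
reproducible default is used and the tolerance is a parameter). A merged
segment keeps its longest component's donor interval and the
length-weighted mean identity. A plastid gene is *intact* in a segment
iff its entire donor interval lies within the segment's plastome
interval; edge-overlapping genes are fragments. Length histograms use
bins (200,500], (500,1000], (1000,1500], (1500,3000], >3000 by default.

For the correlation analysis the isoforms are concatenated in order, the
concatenated sequence is cut into non-overlapping 3,000 bp bins (a
trailing partial bin is dropped — unequal bins bias GC and counts), and
per bin the GC fraction, repeat-interval count and cp-segment count are
computed. A feature increments every bin it overlaps (counting only the
start bin is a config switch). Pearson r with two-sided p-values comes
from scipy; a zero-variance variable yields NaN with a diagnostic, and
fewer than 3 bins is an error. Pooling bins across several genomes is
explicit (pass lists); a single genome is never pooled implicitly. An
independent two-pass Pearson implementation is compared against the
scipy result on every test run.

## Comparative statistics

Shared-sequence fraction: all hits of genome A against genome B below the
E-value threshold are projected onto A and unioned, so overlapping hits
never double-count; the fraction is union/length(A), computed in both
directions because coverage is asymmetric when sizes differ. Gene
clusters are maximal runs of consecutive genes with intergenic gaps
≤ 5 kb (pure adjacency without a gap cap would chain whole isoforms);
clusters match between genomes when their ordered gene lists are
identical or exactly reversed, each cluster matching at most once.
RSCU(c) = count(c)·k / Σ counts over the k synonymous codons of c's amino
acid (standard genetic code; plant mitochondria use it); stop codons are
excluded by default, CDS with internal stops are skipped with a warning,
and unobserved families are NaN. Duplicate gene copies are the caller's
choice of dictionary keys (counted once by default in the analysis
scripts). ORFs are ATG-to-stop spans > 300 bp including the stop, on all
six frames, collapsed to the longest ORF per stop per frame, with
minus-strand ORFs reported in forward coordinates.

## Phylogenomic matrices

Per-isoform alignment blocks (produced externally in a real study) are
concatenated into a supermatrix with a partition map; taxa missing from a
block receive all-gap rows. "Missing data" is gap or N. Both readings of
the 50% rule are applied and logged: blocks whose overall missing
fraction exceeds 0.5 are dropped, and within retained blocks every column
with missing fraction > 0.5 is removed (idempotent). cp-masking excises
the detected cp-derived intervals from each isoform and emits an old→new
coordinate map; the masked genome is shorter by exactly the merged
segment union. Writers produce FASTA, relaxed PHYLIP and NEXUS with
charset partitions, ready for external ML/BI inference (tree search
itself is out of scope); a Robinson–Foulds utility compares two input
newick topologies.

## The synthetic-data generator

The generator emulates the structure of the genomes this pipeline
targets, with defaults matching their published scale: 22 isoforms of
20,401–124,954 bp at GC 0.44 for the mitogenome; a plastome of LSC
84,962 / IR 26,128 / SSC 14,001 bp at GC 0.3752 with IR_B the exact
reverse complement of IR_A. Tests and the bundled analyses pass smaller
sizes explicitly (3–5 isoforms totalling 150–300 kb) so every stage runs
in seconds on one CPU.

Backgrounds are i.i.d. bases at the target GC. Mitogenome, plastome and
read streams are seeded on separate entropy paths, so a mitogenome and a
plastome generated from the same seed are statistically independent
sequences (identically-seeded streams would otherwise correlate and plant
phantom MTPTs). Features are placed by rejection sampling with a 60 bp
clearance and never overlap; a plan exceeding half the genome is rejected
before any output. Repeat pairs are planted by copying a background
segment and applying exactly round((1−id)·L) substitutions — no indels —
so the planted identity is an exact Hamming identity; substitution sites
avoid the outermost ~5% (at least 3 bp) of the copy so that an
end-trimming aligner reports the planted identity rather than a trimmed
variant. MTPTs are copied from disjoint donor plastome windows and mutated
the same way. SSR insertions force a run-breaking base on each side so
the planted copy number is exact. Genes are ATG + random non-stop codons
+ stop, planted in clusters with 100–800 bp intergenic gaps.

The smallest planted repeat class is a 35 bp exact copy: at the E < 1e−5
threshold in a 150–300 kb genome, a 30 bp copy carrying even one
substitution scores at the detection boundary (E ≈ 1e−5), so a short
exact copy is the minimal unit a threshold-faithful detector can be
required to find.

Reads are log-normal in length (median ≈ 9 kb, truncated to
[1 kb, 50 kb]), uniform in start, random in strand, with errors applied
per base at the requested rate split 50/25/25 between substitutions,
insertions and deletions. Each read is drawn from an original template
with probability 1−f and an alternative template otherwise, and its true
class, template, coordinates and strand are recorded.

What the generator does **not** emulate: Nanopore homopolymer bias and
quality structure, structural variants beyond the planted features,
within-genome GC heterogeneity, real gene sequence content, and
origin-spanning planted features (detection handles origin-spanning
repeats, but the generator never plants them). Passing tests therefore
demonstrate correctness of the algorithms under a clean, fully specified
data model — recovery of known truth, agreement with exact oracles,
statistical calibration of the frequency estimator — not performance on
the error structure of any particular sequencing run.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run: 10 synthetic genomes of
150–300 kb for planted-feature recovery; 2,000 reads per point of the
recombinant-fraction grid {0, 0.1, 0.3, 0.5} at 5% error; 100 random
pairs ≤ 2 kb for the aligner-vs-optimum comparison; 100 random 10 kb
strings for the SSR oracle; and 5 kb sequences for the plastome-repeat
oracle. Every random choice descends from a single integer seed, and a
fixed seed reproduces all outputs byte-for-byte.

## Interfaces

The library modules are the interface, driven by the numbered scripts in
`analysis/`; no console entry point is installed because the intended use
is scripted analysis, not shell invocation. File formats: FASTA
(multi-record genomes, alignments, supermatrices), FASTQ (simulated
reads), GFF3/TSV (annotations), BED/TSV (intervals and tables), BLAST
tabular (hit interchange), JSON (truth sets, correlation reports),
relaxed PHYLIP and NEXUS (matrices).

## Known limitations

- The seed-and-extend aligner is substitution-oriented; diverged
  homologies containing indels are reported as split diagonal segments,
  not single gapped hits. The BLAST adapter is the route to exact
  replication of numbers computed with gapped BLASTN on real accessions.
- MTPT detection and similarity run on linearized sequences; only
  dispersed-repeat detection and flank extraction honor circularity.
- E-values use raw sequence lengths without BLAST's length adjustment, so
  they differ from BLAST's near the detection boundary.
- Identity of reported repeats below ~100 bp has a coarse resolution
  (one alignment column ≈ several identity points).
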