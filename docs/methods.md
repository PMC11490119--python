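# Methods

## The annotation model

A SINE insertion is recognized by two independent kinds of evidence.

**Homology evidence** is an alignment of a curated SINE profile HMM to the
genome. sinekit consumes nhmmer-style tabular hits (1-based, reversed
coordinates on the minus strand) and reduces them to genomic loci by
interval union: hits on one target are sorted by `(start, end)` — equal
starts ordered larger-end-first so a contained hit never opens a new
chain — and a single left-to-right sweep chains every hit whose start lies
within `max_gap` (default 0, i.e. strict overlap) of the running chain
end. Each chain becomes one locus spanning the union of its members, with
the maximum-bit-score hit recorded as `best_model`. The sweep visits each
hit exactly once after sorting, so merging is `O(n log n)`; the test suite
checks it against a quadratic repeated-pairwise-merging oracle and checks
the iteration-count slopes of both. Merging crosses models and strands
deliberately: the object of interest is a genomic SINE locus, not a
per-model footprint. Hits above an E-value cutoff (default 1e-5,
configurable) are discarded before merging.

**Structural evidence** is the insertion signature itself: a poly-A tail
at the 3′ end of the element and a target site duplication (TSD) — a
short direct repeat of host sequence created on insertion — flanking it.
The scanner anchors on terminations of A-runs. At each anchor `e` it asks
for the longest window ending at `e`, up to `tail_max_len` (64 bp), with
A-fraction ≥ `tail_purity` (0.9) and, after stripping any leading non-A
bases from that window, length ≥ `tail_min_len` (8 bp). If a tail exists,
the region that could contain the left TSD copy (constrained so the
element body length lands in `[body_min_len, body_max_len]` = [80, 800])
is compared against the `flank_window` (40 bp) to the right of `e` for
the best ungapped equal-length substring pair with length in
`[tsd_min_len, tsd_max_len]` = [5, 20] and at most `t` mismatches. A pair
of length `L` with `m` mismatches scores `L − 2m` (matches minus
mismatches — the simplest scheme consistent with a mismatch tolerance and
a score cutoff; users recalibrating `s_score` should know this is the
scale). The element start is the end of the left TSD copy. Both strands
are scanned (the minus strand as a poly-T head on the forward sequence,
implemented by scanning the reverse complement and mapping back).

Tie-breaks are fixed and documented: higher score, then greater length,
then smaller left-flank offset, then smaller right-flank offset. One
consequence: an exact TSD can tie with a chance-extended longer window
(e.g. 12 exact vs 16 with 2 mismatches, both scoring 12), which the
greater-length rule wins, shifting a reported boundary by up to ~2 bp on
roughly a quarter of clean implants. Recovery tests therefore score
reciprocal overlap rather than exact coordinates, and the bp-level effect
is negligible.

The TSD search is exhaustive within its window (it equals an independent
all-pairs enumeration oracle on every tested instance), implemented as a
cumulative-mismatch recurrence over numpy arrays.

**Partitioned scanning.** For parallel decomposition the sequence is cut
into `n_parts` cores; each part's scan window is extended by
`flank_window + tsd_max_len + body_max_len` on both sides, and a
candidate is owned by the part whose core contains its anchor (the tail
termination). Ownership is exclusive and every owned anchor has full
context, so the partitioned result is provably identical to the
single-pass scan — the invariant the tests assert for
`n_parts ∈ {1, 2, 8}`, including an implant placed across a partition
seam. Parts are processed sequentially; the decomposition, not the thread
pool, is the contract.

## Copy-number support and boundary consensus

A real SINE family has many near-identical genomic copies. The candidate
sequence is aligned genome-wide externally (minimap2; PAF converted to
BLAST outfmt 6 by `sinekit.alignio`), and each alignment's footprint *on
the candidate* (its query span, translated by the candidate's genomic
start) is the frame in which boundary agreement is judged — "boundary
shift" is how far a copy's alignment endpoints stray from the consensus,
not where the copy sits in the genome. Only alignments covering ≥
`min_cov` (0.8) of the candidate count. The consensus is anchored on the
hit with the most neighbours within `s` bp at both boundaries (ties: the
smaller `(start, end)` pair, making the result order-independent); its
neighbourhood members are the copies, and the reported modal boundaries
are the lower medians of member boundaries. Anchoring membership on the
maximizing hit makes `copy_count` provably weakly increasing in `s`;
every member lies within `s` of the anchor and hence within `2s` of the
median. Candidates with `copy_count < minc` are dropped; survivors'
intervals snap to the modal boundaries when the shift is ≤ `s` per end
(otherwise the candidate is flagged and left unchanged). The defaults
`s = 10`, `minc = 2` are exposed; raising `s` trades false positives for
sensitivity, raising `minc` suppresses both — the monotonicities the ROC
sweep reproduces on fixtures.

`min_cov = 0.8` defines what counts as a "copy"; it mirrors the
redundancy-threshold scale used in cleanup. Copies on either strand count
equally (SINE insertion is orientation-agnostic).

## Hybrid mode and provenance

Mode 3 unions the homology and structure candidate sets before any
filtering: records overlapping by ≥ 1 bp collapse into one spanning
record whose provenance lists both sources. Copy filtering and cleanup
run after the union, so the pre-filter mode-3 footprint always contains
both single-mode footprints. Mode 3 without a hit table degrades to mode
2 with a warning — the situation of a taxon with no curated profiles.
The provenance report gives element and bp fractions over
{homology-only, structure-only, both}.

## Cleanup

Nested-redundancy removal processes sequences in decreasing-length order
(ties: lexicographically earlier id first), removing a sequence iff a
single alignment to an already-retained sequence covers ≥ `cov` (0.95) of
its own length at identity ≥ `miniden` (80) with alignment length ≥
`minlen` (50 bp). Coverage is measured on the sequence being tested, and
removal is only ever against retained sequences, so a mutually redundant
pair loses exactly one member and the retained set is independent of
input order.

Purging consumes externally produced mask intervals (bases matched by
LINE/LTR libraries) rather than running a masker, keeping it hermetic.
Terminal masked-or-N runs are trimmed first; the trimmed candidate is
removed when its masked fraction exceeds `nr` (0.8) or its length falls
below `minlen` (50). Trimming before the fraction test makes the
operation idempotent (a survivor has no terminal masked/N run left), at
the cost that the fraction is judged on the trimmed length. Tandem-repeat
filtering and N-screening as removal criteria are deliberately absent;
N-trimming is retained.

## Evaluation

Base-pair confusion counts come from interval arithmetic on the
self-overlap-merged prediction and truth sets (double-covered bases are
never double-counted), cross-checked against explicit per-base boolean
vectors. Strand is ignored, matching practice for repeat-annotation
ground truths. Undefined ratios (e.g. precision of an empty prediction)
are reported as None, never as 0 or an exception. `roc_sweep` re-runs the
pipeline per grid setting on fixed inputs and tabulates (TPR, FPR) with
full parameter provenance.

## Formats and conversion

Internal coordinates are 0-based half-open everywhere; 1-based inclusive
conventions (RepeatMasker `.out`, BLAST tabular) and the strand-by-
reversed-coordinates convention are handled only in readers/writers.
PAF→outfmt-6 conversion: `pident = 100·nmatch/blocklen`, `mismatch =
blocklen − nmatch`, gap opens counted from the `cg` CIGAR tag's indel
runs (0 when absent), minus-strand subject spans reported reversed.
outfmt 6's evalue and bitscore have no PAF equivalent; the sentinel `−1`
and the matching-base count are emitted and documented — downstream logic
consumes coordinates and identity only. Conversion streams the input in
chunks of `chunk_lines` (default 100,000) lines and rolls output shards
at `shard_records` (default 1e8) records, bounding resident memory while
keeping concatenated output byte-identical to a single-pass conversion.
Secondary alignments are kept by default (a flag drops them). The
external-aligner batching mode switches to low-memory (`-K 1M`) when the
candidate FASTA exceeds 10 Mb, by strict greater-than comparison (the
boundary case stays standard).

Sequence chunking for windowed scanning defaults to 10 kb chunks with
2,000 bp overlap — an overlap at least as long as the longest expected
element so nothing is lost at seams; duplicates are removed downstream by
parent-coordinate identity. Soft-masked (lowercase) input is uppercased
and retained: the pipeline does its own masking-based purging. IUPAC
ambiguity codes other than N are demoted to N with a warning.

## Synthetic fixtures

`sinekit.synthgen` overwrites background-genome segments with
left-TSD + body + poly-A-tail + right-TSD implants: TSDs are exact direct
repeats of 10–16 bp whose first base is never A (an A would fuse with the
tail's A-run and blur the element end); bodies are 120–400 bp including a
12 bp pure tail; family copies share a body with per-copy point mutations
(default 2%) confined to the body core. Truth intervals exclude the TSDs
(the duplication is host sequence), which is what "correct boundary"
means in recovery tests. Companion generators fabricate nhmmer-style hit
tables (with dropout, jitter, and split-hit modes) and family-alignment
PAFs, so fixtures double as format-conformance tests. The default
end-to-end scenario is a 100 kb genome with 20 implants in families of 3,
25% hit-table dropout and exact alignments; the acceptance script rebuilds
it from the given seed. All generation is integer-state (numpy
`default_rng`) and fully reproducible.

What passing fixtures shows — and does not. Implants have exact TSDs,
clean tails, uniform background and unambiguous family structure; real
SINEs carry tRNA-derived heads, CpG decay, 5′ truncations, nested
insertions and LINE-shared tails. Fixture results bound the correctness
of the machinery (coordinate handling, merging, filtering, scoring), not
expected accuracy on real genomes.

## Problem sizes and numerical choices

Tests and the acceptance script run on 20–100 kb genomes, 200 random
merge instances of up to 1,000 hits, 500 random TSD flank pairs, 100
random evaluation instances up to 100 kb, and a 250,000-record synthetic
PAF — sizes chosen so the whole suite completes in about a minute on one
CPU while still exercising every code path at meaningful density.

Deterministic tie-breaks appear wherever a choice is otherwise arbitrary:
TSD ties (greater length, then smaller offsets), copy-consensus anchor
ties (smaller coordinates), redundancy-removal ties (earlier id retained),
modal boundaries (lower median). Degenerate inputs have defined
behaviour: empty genomes and empty hit tables yield empty results, empty
predictions yield None precision, candidates without alignments have
copy count 0, and flank windows shorter than `tsd_min_len` simply yield
no TSD.

## Known limitations

- No Pol III A-box/B-box promoter scoring; the structural definition is
  tail + TSD + length only.
- TSD comparison is ungapped; a TSD interrupted by an indel is found only
  as its longest exact-frame fragment.
- Tails must end in A (scan anchors on A-run terminations); a tail whose
  final base mutated is anchored at its last surviving A.
- The profile library itself (and its curation beyond keyword
  bookkeeping) is out of scope; hit tables are consumed, not produced.
- SAM/BAM alignment input is not supported; PAF and outfmt 6 are.
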