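# Methods

This note records the procedures, parameter choices and numerical
conventions behind `ampliclean`, including the places where the design was
genuinely open and a choice had to be made.

## Read model and step order

A raw read is modelled as `barcode | forward primer | target |
rc(reverse primer) | adapter B`, with one integer quality per base taken
from a parallel `.qual` file. The seven cleaning steps run in a fixed
order: adapter trimming, N-filtering, low-frequency removal,
demultiplexing, length filtering, primer removal (with the boundary
filter), mean-quality filtering. Two consequences of this order are worth
stating explicitly:

* **Low-frequency removal is pooled.** Step 3 counts exact full-string
  copies over the still-multiplexed read set (barcodes included), so a
  variant shared by two samples contributes separate counts per sample.
  Running it before demultiplexing lets several datasets be combined to
  protect true low-frequency variants; the cost is that copy thresholds
  act on per-sample strings.
* **The length window applies to the barcode- and adapter-stripped read**,
  i.e. primers still attached, because the length filter precedes primer
  removal.
* Reads re-made singletons by the final quality filter are *not*
  re-filtered; low-frequency removal runs exactly once.

All coordinates are 0-based, half-open. Sequences are uppercased on read;
`N` is the only ambiguity code kept (other IUPAC codes become `N` with a
warning, since only `N`-containing reads are ever filtered on ambiguity).

## Adapter matching

The adapter is located by an ungapped scan: full-length occurrences at
every offset, plus a 3'-truncated occurrence (a prefix of the adapter, at
least half its length) anchored at the read end. An occurrence qualifies
when its mismatch count is ≤ ⌈f·L⌉ for matched length L, with
f = `ADAPTER_MAX_MISMATCH_FRACTION` (default 0.1). Among qualifying
occurrences the lowest mismatch fraction wins; ties go to the *leftmost*
start — trimming more is the safe direction, since any later match would
retain adapter-derived bases. Reads with no qualifying occurrence are
discarded (step 1 is a filter, not a pass-through), as is the degenerate
case of a match at position 0.

## The homopolymer boundary filter

Pyrosequencing's dominant error is a length error in a homopolymer run.
When the run spans the primer/target junction, the error shifts the entire
target by ±1 while leaving the primer intact, so primer-anchored trimming
silently produces a frame-shifted target. The filter exploits that the
true junction k-mer is strongly conserved across reads sharing a primer
pair:

1. Among reads with both primers intact, tally the `BOUNDARY_WINDOW`-mer
   (default 8) immediately after the forward primer; the modal k-mer is
   the consensus (ties broken lexicographically; support recorded).
2. For each read compare the consensus against the windows at offsets +1
   and −1. A clean read mismatches heavily at both; a read with a junction
   indel reproduces the consensus at one offset. Reads with fewer than
   `BOUNDARY_MISMATCH_THRESHOLD` (default 3) mismatches at either offset
   are discarded. Windows that would run past the read end (or before
   position 0) are skipped.

The −1 case is detected because a junction deletion removes the target's
first base, and in the homopolymer configuration that base equals the
primer's last base, so `primer_last + target[1:w]` reconstructs the
consensus exactly.

Open points resolved as package defaults: the filter is applied at the
forward junction only (`BOUNDARY_FILTER_REVERSE_JUNCTION` enables a
mirrored check at the reverse junction); the <3-mismatch rule is applied
literally even to reads whose offset-0 window equals the consensus —
`EXEMPT_EXACT_BOUNDARY` opts out of that for tandem-repeat-like targets,
where a repeat can match the consensus at offset 0 *and* ±1.

## Dereplication

Grouping is exact string identity — indels are informative, so two
sequences differing only by an indel stay separate records. Output is
ordered by copy number descending, ties broken lexicographically by
sequence (determinism). Headers follow
`>{sample}_NR{rank:06d};size={frequency}`; the `;size=` tag is the
machine-readable frequency consumed by all downstream stages.

## Gap-excluded similarity

The analysis stages share one similarity: on an optimal global alignment,
`100 × identical columns / columns where neither sequence has a gap`.
This is reconstructed from two stated properties of the original measure —
gaps are not considered, and a cutoff of 100 groups sequences identical up
to indels. Scoring is linear (match +1, mismatch −1, gap −2). Because
co-optimal alignments under linear scoring can trade one mismatch against
two gap columns (same score, different similarity), the alignment is made
canonical by lexicographic optimisation: maximise score, then matched
columns, then minimise mismatched columns. The DP packs the three additive
objectives into one 64-bit integer with non-interfering weights, so the
canonical optimum is decoded from the final cell without traceback. Pairs
with zero gap-free columns have undefined similarity and are treated as
no-match (distance 1.0 in the rarefaction exporter).

The aligner is validated in the test suite against an independently
written memoized lexicographic DP, full enumeration of all alignments at
tiny sizes, and biopython's `PairwiseAligner` for the score component.

## Taxonomy assignment

The search backend is pluggable: an internal deterministic aligner over an
in-memory reference (offline tests and small references), a parser for
classic 12-column tabular alignment output (+ optional 13th taxid column,
or an accession→taxid map), and a thin BLAST+ wrapper. The internal
provider reports the gap-excluded similarity as percent identity, the raw
alignment score as bitscore, and a monotone e-value surrogate
`total_reference_length × query_length × 2^(−score)` (floored at 1e-180) —
sufficient for ordering and cutoff filtering, not a Karlin–Altschul
statistic.

Best-hit resolution, in order: minimal e-value → maximal bitscore (two
alignments can share a printed e-value; a numeric criterion comes before a
taxonomic one) → deepest lineage path ("most detailed classification"
operationalised as the count of named ranks) → per-rank strict majority
over the tied lineages, walking from the root and truncating at the
deepest rank that still has a strict majority → accession order, flagged
`unresolved`. The majority rule is applied over the tied best-hit set
only. Lineages come from a local table (4-column TSV or NCBI dump
dialect); parent traversal detects cycles, and hits whose taxid cannot be
resolved are excluded with a warning.

The output table has the six classification columns (query, percent
similarity, e-value, accession, species name, semicolon-joined path) plus
a stable seventh `flag` column — empty for single-best rows, otherwise the
resolution mode — so the file is uniformly parseable.

## Overlap counting and rarefaction exports

For each query sequence, `target_copies[t]` sums the frequencies of *all*
target-t sequences within the similarity cutoff (a query's copy number
"in" a sample is naturally a sum); `--best-hit-only` switches to the
single most similar target (ties: longer gap-free span, then id). Raising
the cutoff can only shrink these counts.

The rarefaction exporter writes column-format distances
(`idA idB distance`, lower triangle; phylip square behind a flag) with
distance `1 − similarity/100` under the internal engine (an external
engine's values pass through untransformed), plus a names file expanding
each copy number `f` into `f` replicate ids (`id, id_dup1, …`) so
clustering tools weight abundances correctly. The abundance list groups
sequences by single-linkage at the cutoff — the natural closure of
"within-cutoff" pairs — and writes per-group summed frequencies in
descending order.

## The simulator

The simulator emulates multiplexed pyrosequencing amplicon data: MID-style
equal-length barcodes, adapter-terminated reads, and one injected defect
per read drawn from eight classes (no adapter, ambiguous base, singleton,
bad barcode, off-length, primer mutation, ±1 boundary indel, low
quality). Default per-class rates follow the per-step attrition profile of
a large 18S freshwater survey, leaving ~62% of reads clean. Three design
features make every read's fate exact rather than probable:

* all target seeds share a conserved junction prefix (primer's last base
  followed by a period-4 base cycle), so clean reads sit 7–8 mismatches
  from the consensus at both offsets while every injected indel reproduces
  it exactly at one offset;
* classes that must survive pooled low-frequency removal are emitted in
  groups of ≥ `MIN_COPY_NUMBER` identical strings, with globally unique
  target variants per group (classes allocated fewer reads than a group
  are folded into the singleton class);
* a simulator-local adapter scanner verifies at generation time that
  adapter-bearing reads match exactly at the true junction and that
  `no_adapter` reads match nowhere.

Qualities are uniform on [30, 40] (clean) or [5, 15] (low-quality), so any
mean-quality threshold in (15, 30] classifies unambiguously; the simulator
refuses configurations outside that range rather than emit ambiguous
truth. What the simulator does *not* model: flowgram-level noise, indels
away from the junction, chimeras, quality decay along the read, or
cross-sample sequence sharing (variants are sample-private by
construction). Tests passing on simulated data therefore certify the
pipeline's bookkeeping and filter logic, not its behaviour on the full
error spectrum of real instruments.

## Problem sizes and tolerances

The standard simulated run used by the tests and the acceptance script is
3 samples × 500 reads with all defect classes at the default rates —
large enough that every step discards a two-digit read count, small
enough to process in about a second. Randomised conservation checks run
1,000 small trials (6–14 reads per sample, random defect mixtures).
Similarity checks compare 500 random pairs (lengths 5–25, 30%
indel-biased) against the independent DP oracle; equality is exact, as
both sides compute the same canonical optimum in integer arithmetic. Mean
qualities are compared to the threshold in exact float arithmetic with no
rounding; "mean equal to threshold" keeps the read (the discard rule is
strictly-below).

## Known limitations

* Error-tolerant barcode or primer matching is deliberately absent
  (barcodes match exactly at the 5' end; primers require perfect
  identity): mismatch tolerance there would change step-4/6 semantics.
* The internal e-value is a surrogate; mixing internal-provider hits with
  external BLAST hits in one resolution pass would compare incompatible
  e-value scales and is not supported.
* The overlap and rarefaction stages align all pairs with the internal
  quadratic-time aligner; for very large non-redundant sets an external
  search engine should produce a tabular hit file instead.
* FASTQ and SFF inputs are out of scope; the tool targets FASTA + `.qual`
  read sets.
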