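# ampliclean

Trimming, quality filtering and downstream-analysis exporters for
454-style amplicon biodiversity surveys.

Early pyrosequencing platforms made deep amplicon sequencing (e.g. of the
18S rRNA gene across environmental samples) cheap enough for routine
biodiversity work, but their reads need substantial cleaning before any
ecological analysis: each read carries a sample barcode, PCR primers and a
3' sequencing adapter around the actual target, a tail of low-quality
bases, and — characteristically for pyrosequencing — homopolymer
insertion/deletion errors, which at the primer/target junction shift the
whole target by one base. `ampliclean` is aimed at researchers running such
surveys: it turns raw multiplexed FASTA + `.qual` read sets into
per-sample, frequency-annotated non-redundant sequence sets, assigns
taxonomy against a reference collection, counts sequence sharing between
samples, and exports the input files that external rarefaction tools
(MOTHUR-style clustering, abundance-list tools) consume.

## The processing model

Reads are cleaned by seven sequential, individually-accounted steps:

1. **Adapter-B trimming** — the 3' adapter is located by a mismatch-tolerant
   scan (full occurrences anywhere, or a 3'-truncated adapter prefix of at
   least half its length at the read end, with mismatches ≤
   ⌈f·L⌉ for matched length L); reads without a detectable adapter are
   discarded.
2. **Ambiguity filter** — any read containing one or more `N` is discarded.
3. **Low-frequency removal** — over the *pooled*, still-multiplexed read
   set, reads whose exact sequence occurs fewer than `MIN_COPY_NUMBER`
   times are removed (pyrosequencing errors are dominated by singletons).
4. **Demultiplexing** — exact 5' barcode match assigns each read to a
   sample; the barcode is removed; unmatched reads are discarded.
5. **Length window** — reads outside `[MIN_LEN, MAX_LEN]` are discarded.
6. **Primer removal with a homopolymer boundary filter** — both PCR primers
   must match perfectly. Before removal, the modal 8-mer of the target
   immediately after the forward primer is taken as a consensus motif; any
   read whose +1 or −1 offset window shows fewer than 3 mismatches to this
   consensus carries a junction indel and is discarded. For a clean read
   both offsets are far from the consensus; a one-base slip reproduces it
   almost exactly.
7. **Mean-quality filter** — reads whose mean target quality is strictly
   below `MIN_MEAN_QUALITY` are discarded.

Each sample is then dereplicated: identical sequences (indels count as
differences) collapse into one record whose copy number is carried in the
FASTA header (`>S1_NR000001;size=3`), ranked by descending frequency.

Downstream, the analysis stages share one similarity measure, the
**gap-excluded similarity**: on an optimal global alignment, identical
aligned bases divided by aligned columns where neither sequence has a gap.
Two sequences differing only by indels therefore score 100%, so a cutoff of
100 groups sequences that are identical once gaps are ignored.

A built-in read simulator emits multiplexed datasets with a ground-truth
manifest (which defect each read carries and at which step it must be
discarded), so the whole tool is testable offline.

## Worked example

Simulate a small three-sample run, clean it, and inspect the accounting:

```sh
$ ampliclean simulate --out sim --n 200 --seed 42
wrote 600 reads across 3 samples to sim
$ ampliclean tsfs --config sim/options.txt --fasta sim/reads.fasta \
    --qual sim/reads.qual --out trimmed
adapter_trimming        600     504     96
ambiguity_filtering     504     483     21
low_frequency_removal   483     420     63
demultiplexing          420     414     6
length_filtering        414     408     6
primer_trimming         408     375     33
quality_filtering       375     369     6
kept 369 reads in 3 sample(s); outputs in trimmed
```

Each line is `step  n_in  n_kept  n_discarded`; every row conserves reads
(`n_in = n_kept + n_discarded`), and 369/600 ≈ 62% of raw reads survive —
the attrition profile the simulator's default defect rates emulate. The
non-redundant output carries copy numbers in its headers:

```
$ head -2 trimmed/S1.nr.fasta
>S1_NR000001;size=3
GTACGTACGCGTGAATGAAGCGCTTAAACAGCTCAGGAGCCAGTCCCCTACG...
```

Counting how often each S1 sequence occurs in other samples (here: against
S1 itself, where every query must recover at least its own copies):

```sh
$ ampliclean ba --query trimmed/S1.nr.fasta --targets trimmed/S1.nr.fasta \
    --cutoff 100 --out self.tsv
$ head -3 self.tsv
query_id        self_copies     S1
S1_NR000001     3       3
S1_NR000002     2       2
```

Taxonomy assignment against the packaged toy reference (for real surveys,
point `--reference`/`--lineage` at your own collection or feed BLAST
tabular output via `--hits`):

```sh
$ ampliclean ta --nr query.nr.fasta --out tax.tsv
$ cut -f1,4,5 tax.tsv
query_id  accession  species_name
Q1        CR0001.1   Chlamydomonas reinhardtii
Q2        PT0001.1   Paramecium tetraurelia
```

`ampliclean ra` writes the rarefaction inputs: a column-format distance
file plus a names file (copy numbers expanded into `_dupN` replicate ids)
and a plain descending abundance list.

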