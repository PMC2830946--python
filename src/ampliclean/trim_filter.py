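"""The seven-step read trimming/filtering stage plus dereplication.

Raw 454-style amplicon reads are laid out 5'→3' as

    barcode | forward primer | target | rc(reverse primer) | adapter B

and are cleaned by seven sequential steps, each with per-step accounting:

1. adapter-B trimming (reads without a detectable adapter are discarded);
2. removal of reads containing one or more ``N``;
3. removal of low-frequency variants over the *pooled* (pre-demultiplexing)
   read set by exact full-string identity;
4. demultiplexing on exact 5' barcode matches (barcode bases removed);
5. length-window filtering of the barcode-stripped read;
6. primer removal — perfect identity to both primers required — preceded by
   the homopolymer boundary filter: the modal ``boundary_window``-mer
   immediately after the forward primer is the consensus, and any read whose
   +1 or −1 offset window has fewer than ``boundary_mismatch_threshold``
   mismatches to that consensus is discarded (a junction indel shifts the
   target so an offset window reproduces the consensus);
7. mean-quality filtering over the remaining (target-only) qualities.

Each surviving sample is then dereplicated into a non-redundant set ranked
by copy number; indels are informative, so sequences differing only by an
indel stay distinct.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import hamming, revcomp
from .config_io import (
    PipelineConfig,
    ReadRecord,
    StepReport,
    read_paired_fasta_qual,
    write_fasta,
    write_nr_fasta,
    write_qual,
)

__all__ = [
    "STEP_NAMES",
    "BoundaryConsensus",
    "BoundaryConsensusError",
    "DereplicatedRecord",
    "PipelineResult",
    "strip_adapter_b",
    "filter_ambiguous",
    "remove_low_frequency",
    "demultiplex",
    "filter_length",
    "compute_boundary_consensus",
    "boundary_offset_filter",
    "strip_primers",
    "mean_quality",
    "quality_filter",
    "dereplicate",
    "run_pipeline",
    "run_pipeline_files",
    "write_pipeline_outputs",
]

#: Step names in fixed pipeline order; manifest fates "1".."7" map onto these.
STEP_NAMES = (
    "adapter_trimming",
    "ambiguity_filtering",
    "low_frequency_removal",
    "demultiplexing",
    "length_filtering",
    "primer_trimming",
    "quality_filtering",
)


class BoundaryConsensusError(ValueError):
    """No read supplies a full boundary window; the consensus is undefined."""


@dataclass(frozen=True)
class BoundaryConsensus:
    """Modal target motif immediately adjacent to a PCR primer."""

    primer_pair_key: str
    motif: str
    support: int


@dataclass(frozen=True)
class DereplicatedRecord:
    """A unique sequence with its copy number and rank within a sample."""

    sample: str
    sequence: str
    frequency: int
    rank: int


@dataclass
class PipelineResult:
    """Everything the trimming stage produces, per sample plus accounting."""

    samples: dict[str, list[ReadRecord]]
    nonredundant: dict[str, list[DereplicatedRecord]]
    reports: list[StepReport]
    consensus: BoundaryConsensus | None
    discarded_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def kept_ids(self) -> set[str]:
        return {r.id for reads in self.samples.values() for r in reads}


# ---------------------------------------------------------------------------
# step 1: adapter B

def _adapter_match_start(sequence: str, adapter: str, max_mismatch_fraction: float) -> int | None:
    """Start index of the best adapter-B occurrence, or None.

    Full-length occurrences are sought at every offset; a 3'-truncated
    occurrence (a prefix of the adapter, at least half its length) is sought
    anchored at the read end. An occurrence qualifies when its mismatch count
    is ≤ ceil(fraction × matched length). Among qualifying occurrences the
    lowest mismatch fraction wins; ties go to the leftmost start.
    """
    la, n = len(adapter), len(sequence)
    min_trunc = math.ceil(la / 2)
    best: tuple[float, int] | None = None
    for start in range(0, n - min_trunc + 1):
        matched_len = min(la, n - start)
        allowed = math.ceil(max_mismatch_fraction * matched_len)
        mm = hamming(sequence[start:start + matched_len], adapter[:matched_len], limit=allowed + 1)
        if mm <= allowed:
            frac = mm / matched_len
            if best is None or frac < best[0]:
                best = (frac, start)
    return None if best is None else best[1]


def strip_adapter_b(
    read: ReadRecord, adapter: str, max_mismatch_fraction: float
) -> ReadRecord | None:
    """Trim the 3' adapter B; return the trimmed read or None (rejected).

    Rejection also covers the degenerate case where the adapter starts at
    position 0 (nothing of the read would remain).
    """
    start = _adapter_match_start(read.sequence, adapter, max_mismatch_fraction)
    if start is None or start == 0:
        return None
    return read.sliced(0, start)


# ---------------------------------------------------------------------------
# step 2: ambiguous bases

def filter_ambiguous(read: ReadRecord) -> bool:
    """True (keep) iff the sequence contains no N."""
    return "N" not in read.sequence


# ---------------------------------------------------------------------------
# step 3: low-frequency variants (pooled)

def remove_low_frequency(
    reads: Sequence[ReadRecord], min_copy_number: int
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Split reads into (kept, discarded) by pooled exact-string frequency.

    A read survives iff its full sequence occurs at least ``min_copy_number``
    times in the pool; ``min_copy_number == 1`` is the identity map.
    """
    if min_copy_number <= 1:
        return list(reads), []
    counts = Counter(r.sequence for r in reads)
    kept, discarded = [], []
    for r in reads:
        (kept if counts[r.sequence] >= min_copy_number else discarded).append(r)
    return kept, discarded


# ---------------------------------------------------------------------------
# step 4: demultiplexing

def demultiplex(
    reads: Iterable[ReadRecord], barcodes: Mapping[str, str]
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to samples by exact 5' barcode prefix; strip the barcode.

    Returns (sample → barcode-stripped reads, unassigned reads). Barcodes are
    validated upstream to be unique and equal length, so assignment is
    unambiguous.
    """
    by_barcode = {bc: sample for sample, bc in barcodes.items()}
    bc_len = len(next(iter(by_barcode))) if by_barcode else 0
    out: dict[str, list[ReadRecord]] = {sample: [] for sample in barcodes}
    unassigned: list[ReadRecord] = []
    for read in reads:
        sample = by_barcode.get(read.sequence[:bc_len])
        if sample is None or len(read) <= bc_len:
            unassigned.append(read)
        else:
            out[sample].append(read.sliced(bc_len, len(read)))
    return out, unassigned


# ---------------------------------------------------------------------------
# step 5: length window

def filter_length(read: ReadRecord, min_length: int, max_length: int) -> bool:
    """True (keep) iff min_length ≤ len(read) ≤ max_length (inclusive)."""
    return min_length <= len(read) <= max_length


# ---------------------------------------------------------------------------
# step 6: boundary filter + primer removal

def compute_boundary_consensus(
    reads: Sequence[ReadRecord],
    forward_primer: str,
    window: int = 8,
    primer_pair_key: str = "default",
) -> BoundaryConsensus:
    """Modal ``window``-mer of the target immediately after the forward primer.

    Only reads beginning with an exact forward-primer match and long enough
    to supply a full window contribute. Ties are broken lexicographically.
    """
    p = len(forward_primer)
    tally: Counter[str] = Counter()
    for read in reads:
        if read.sequence.startswith(forward_primer) and len(read) >= p + window:
            tally[read.sequence[p:p + window]] += 1
    if not tally:
        raise BoundaryConsensusError(
            "no read supplies a full boundary window; consensus undefined"
        )
    motif = min(tally, key=lambda m: (-tally[m], m))
    return BoundaryConsensus(primer_pair_key, motif, tally[motif])


def boundary_offset_filter(
    read: ReadRecord,
    consensus: BoundaryConsensus | str,
    primer_length: int,
    threshold: int = 3,
    exempt_exact: bool = False,
) -> bool:
    """True (keep) unless a ±1 offset window nearly reproduces the consensus.

    For a read beginning with an exact forward primer of length ``p``, the
    windows read[p+1 : p+1+w] and read[p−1 : p−1+w] are compared to the
    consensus motif; the read is discarded iff either window has fewer than
    ``threshold`` mismatches. Windows running past the read end (or before
    position 0) are skipped. With ``exempt_exact``, reads whose offset-0
    window equals the consensus exactly are never discarded (tandem-repeat
    false-positive mitigation; off by default).
    """
    motif = consensus.motif if isinstance(consensus, BoundaryConsensus) else consensus
    w = len(motif)
    p = primer_length
    seq = read.sequence
    if exempt_exact and seq[p:p + w] == motif:
        return True
    for offset in (1, -1):
        start = p + offset
        if start < 0 or start + w > len(seq):
            continue
        if hamming(motif, seq[start:start + w], limit=threshold) < threshold:
            return False
    return True


def strip_primers(
    read: ReadRecord,
    forward_primer: str,
    reverse_primer: str,
    reverse_literal: bool = False,
) -> ReadRecord | None:
    """Remove both PCR primers, requiring perfect identity to each.

    The reverse primer is sought as its reverse complement at the 3' end
    (read-strand layout); ``reverse_literal`` switches to literal-orientation
    matching. Returns None (rejected) on any mismatch or if no target would
    remain.
    """
    tail = reverse_primer if reverse_literal else revcomp(reverse_primer)
    p, q = len(forward_primer), len(tail)
    if len(read) <= p + q:
        return None
    if not read.sequence.startswith(forward_primer) or not read.sequence.endswith(tail):
        return None
    return read.sliced(p, len(read) - q)


# ---------------------------------------------------------------------------
# step 7: mean quality

def mean_quality(read: ReadRecord) -> float:
    """Arithmetic mean of the per-base qualities (exact float, no rounding)."""
    if not read.qualities:
        raise ValueError(f"read {read.id}: empty quality vector")
    return sum(read.qualities) / len(read.qualities)


def quality_filter(read: ReadRecord, min_mean_quality: float) -> bool:
    """True (keep) iff mean quality is NOT strictly below the threshold."""
    return not (mean_quality(read) < min_mean_quality)


# ---------------------------------------------------------------------------
# dereplication

def dereplicate(reads: Sequence[ReadRecord], sample: str) -> list[DereplicatedRecord]:
    """Collapse exact duplicate sequences into ranked frequency records.

    Exact string identity groups reads (indels distinguish sequences); output
    is ordered by frequency descending, ties broken lexicographically by
    sequence. Frequencies sum to the redundant read count.
    """
    counts = Counter(r.sequence for r in reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        DereplicatedRecord(sample, seq, freq, rank)
        for rank, (seq, freq) in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# orchestration

def _reverse_junction_keep(
    read: ReadRecord, motif: str, tail_len: int, threshold: int
) -> bool:
    """Optional mirror of the boundary filter at the reverse-primer junction."""
    w = len(motif)
    j = len(read) - tail_len  # first base of the reverse-primer tail
    seq = read.sequence
    for offset in (1, -1):
        start = j - w + offset
        if start < 0 or start + w > len(seq):
            continue
        if hamming(motif, seq[start:start + w], limit=threshold) < threshold:
            return False
    return True


def run_pipeline(config: PipelineConfig, records: Sequence[ReadRecord]) -> PipelineResult:
    """Apply the seven steps in fixed order and dereplicate each sample."""
    reports: list[StepReport] = []
    discarded_ids: dict[str, list[str]] = {}

    def report(step: str, n_in: int, kept: int, dropped_ids: list[str]) -> None:
        reports.append(StepReport(step, n_in, kept, len(dropped_ids)))
        discarded_ids[step] = dropped_ids

    # step 1: adapter B
    current: list[ReadRecord] = []
    dropped: list[str] = []
    for r in records:
        trimmed = strip_adapter_b(r, config.adapter_b, config.adapter_max_mismatch_fraction)
        if trimmed is None:
            dropped.append(r.id)
        else:
            current.append(trimmed)
    report(STEP_NAMES[0], len(records), len(current), dropped)

    # step 2: ambiguous bases
    n_in = len(current)
    kept = [r for r in current if filter_ambiguous(r)]
    report(STEP_NAMES[1], n_in, len(kept), [r.id for r in current if not filter_ambiguous(r)])
    current = kept

    # step 3: low-frequency variants over the pooled set
    n_in = len(current)
    current, low = remove_low_frequency(current, config.min_copy_number)
    report(STEP_NAMES[2], n_in, len(current), [r.id for r in low])

    # step 4: demultiplexing (skipped in single-sample mode)
    n_in = len(current)
    if config.barcodes:
        samples, unassigned = demultiplex(current, config.barcodes)
    else:
        samples, unassigned = {"all": current}, []
    report(STEP_NAMES[3], n_in, n_in - len(unassigned), [r.id for r in unassigned])

    # step 5: length window (on the barcode- and adapter-stripped read)
    n_in = sum(len(v) for v in samples.values())
    dropped = []
    for sample, reads in samples.items():
        kept = [r for r in reads if filter_length(r, config.min_length, config.max_length)]
        dropped.extend(r.id for r in reads if not filter_length(r, config.min_length, config.max_length))
        samples[sample] = kept
    report(STEP_NAMES[4], n_in, n_in - len(dropped), dropped)

    # step 6: boundary filter on primer-bearing reads, then primer removal
    n_in = sum(len(v) for v in samples.values())
    dropped = []
    tail = (
        config.reverse_primer
        if config.reverse_primer_literal
        else revcomp(config.reverse_primer)
    )
    p, q = len(config.forward_primer), len(tail)
    primer_ok: dict[str, list[ReadRecord]] = {}
    for sample, reads in samples.items():
        ok = []
        for r in reads:
            if (
                len(r) > p + q
                and r.sequence.startswith(config.forward_primer)
                and r.sequence.endswith(tail)
            ):
                ok.append(r)
            else:
                dropped.append(r.id)
        primer_ok[sample] = ok

    consensus: BoundaryConsensus | None = None
    rev_consensus: str | None = None
    pooled = [r for reads in primer_ok.values() for r in reads]
    if pooled:
        consensus = compute_boundary_consensus(
            pooled, config.forward_primer, config.boundary_window
        )
        if config.boundary_filter_reverse_junction:
            w = config.boundary_window
            tally: Counter[str] = Counter()
            for r in pooled:
                start = len(r) - q - w
                if start >= p:
                    tally[r.sequence[start:len(r) - q]] += 1
            if tally:
                rev_consensus = min(tally, key=lambda m: (-tally[m], m))

    for sample, reads in primer_ok.items():
        survivors = []
        for r in reads:
            keep = boundary_offset_filter(
                r,
                consensus,  # type: ignore[arg-type]  # pooled non-empty here
                p,
                config.boundary_mismatch_threshold,
                config.exempt_exact_boundary,
            )
            if keep and rev_consensus is not None:
                keep = _reverse_junction_keep(
                    r, rev_consensus, q, config.boundary_mismatch_threshold
                )
            if not keep:
                dropped.append(r.id)
                continue
            stripped = strip_primers(
                r, config.forward_primer, config.reverse_primer, config.reverse_primer_literal
            )
            if stripped is None:  # unreachable given the checks above
                dropped.append(r.id)
            else:
                survivors.append(stripped)
        samples[sample] = survivors
    report(STEP_NAMES[5], n_in, n_in - len(dropped), dropped)

    # step 7: mean quality over the remaining (target-only) qualities
    n_in = sum(len(v) for v in samples.values())
    dropped = []
    for sample, reads in samples.items():
        kept = [r for r in reads if quality_filter(r, config.min_mean_quality)]
        dropped.extend(
            r.id for r in reads if not quality_filter(r, config.min_mean_quality)
        )
        samples[sample] = kept
    report(STEP_NAMES[6], n_in, n_in - len(dropped), dropped)

    nonredundant = {sample: dereplicate(reads, sample) for sample, reads in samples.items()}
    return PipelineResult(samples, nonredundant, reports, consensus, discarded_ids)


def write_pipeline_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write per-sample redundant FASTA/.qual, non-redundant FASTA, steps.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample, reads in result.samples.items():
        write_fasta(reads, out_dir / f"{sample}.trimmed.fasta")
        write_qual(reads, out_dir / f"{sample}.trimmed.qual")
        write_nr_fasta(result.nonredundant[sample], out_dir / f"{sample}.nr.fasta", sample)
    with (out_dir / "steps.tsv").open("w") as fh:
        fh.write("step\tn_in\tn_kept\tn_discarded\n")
        for rep in result.reports:
            fh.write(f"{rep.step_name}\t{rep.n_in}\t{rep.n_kept}\t{rep.n_discarded}\n")
    return out_dir


def run_pipeline_files(
    config: PipelineConfig, fasta: str | Path, qual: str | Path, out_dir: str | Path
) -> PipelineResult:
    """File-level wrapper: read paired input, run the pipeline, write outputs."""
    records = read_paired_fasta_qual(fasta, qual)
    result = run_pipeline(config, records)
    write_pipeline_outputs(result, out_dir)
    return result
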