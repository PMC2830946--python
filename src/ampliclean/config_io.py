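"""Shared input/output: options file, paired FASTA/.qual reads, records.

All stages of the pipeline are driven by one plain-text options file
(``KEY=value`` lines, ``#`` comments, case-insensitive keys). Reads arrive as
a FASTA file plus a parallel ``.qual`` file carrying one integer quality per
base; the two files must list the same record IDs in the same order, and any
disagreement is fatal rather than silently re-paired.

Coordinates are 0-based half-open throughout. Sequences are uppercase
normalised on read; ``N`` is the only ambiguity code recognised — any other
IUPAC code is converted to ``N`` with a warning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from ._util import is_dna

__all__ = [
    "ConfigError",
    "PairedInputError",
    "FormatError",
    "ReadRecord",
    "NrRecord",
    "StepReport",
    "PipelineConfig",
    "parse_options",
    "write_options_file",
    "read_paired_fasta_qual",
    "write_fasta",
    "write_qual",
    "write_nr_fasta",
    "read_nr_fasta",
]


class ConfigError(ValueError):
    """An options-file key is missing or its value is malformed."""


class PairedInputError(ValueError):
    """FASTA and .qual files disagree (IDs, order, or lengths)."""


class FormatError(ValueError):
    """A sequence file does not follow the documented dialect."""


_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class ReadRecord:
    """One sequencing read: identifier, DNA string, per-base qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"read ID must be a non-empty token, got {self.id!r}")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if _NON_ACGTN.search(self.sequence):
            raise ValueError(f"read {self.id}: sequence contains non-ACGTN characters")
        self.qualities = list(self.qualities)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} quality values for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def sliced(self, start: int, stop: int) -> "ReadRecord":
        """Sub-read over [start, stop); sequence and qualities in lockstep."""
        return ReadRecord(self.id, self.sequence[start:stop], self.qualities[start:stop])


@dataclass(frozen=True)
class NrRecord:
    """A dereplicated (non-redundant) sequence read back from a `;size=` FASTA."""

    id: str
    sequence: str
    frequency: int


@dataclass(frozen=True)
class StepReport:
    """Per-step read accounting: input, kept and discarded counts."""

    step_name: str
    n_in: int
    n_kept: int
    n_discarded: int

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_kept, self.n_discarded) < 0:
            raise ValueError("step counts must be non-negative")
        if self.n_in != self.n_kept + self.n_discarded:
            raise ValueError(
                f"step {self.step_name}: {self.n_in} != {self.n_kept} + {self.n_discarded}"
            )


@dataclass
class PipelineConfig:
    """Every user parameter shared by the pipeline stages, validated."""

    adapter_b: str
    forward_primer: str
    reverse_primer: str
    min_length: int
    max_length: int
    barcodes: dict[str, str] = field(default_factory=dict)
    adapter_max_mismatch_fraction: float = 0.1
    min_mean_quality: float = 0.0
    min_copy_number: int = 1
    boundary_window: int = 8
    boundary_mismatch_threshold: int = 3
    similarity_cutoff: float = 100.0
    evalue_cutoff: float = 1e-5
    seed: int = 42
    # option switches (defaults follow the documented procedure)
    reverse_primer_literal: bool = False
    boundary_filter_reverse_junction: bool = False
    exempt_exact_boundary: bool = False

    def __post_init__(self) -> None:
        for key, seq in (
            ("ADAPTER_B", self.adapter_b),
            ("FORWARD_PRIMER", self.forward_primer),
            ("REVERSE_PRIMER", self.reverse_primer),
        ):
            if not is_dna(seq):
                raise ConfigError(f"{key}: must be non-empty DNA over A/C/G/T, got {seq!r}")
        if not 0.0 <= self.adapter_max_mismatch_fraction <= 1.0:
            raise ConfigError("ADAPTER_MAX_MISMATCH_FRACTION: must be in [0, 1]")
        if self.min_length < 1:
            raise ConfigError("MIN_LEN: must be a positive integer")
        if self.min_length > self.max_length:
            raise ConfigError(
                f"MIN_LEN/MAX_LEN: MIN_LEN ({self.min_length}) exceeds MAX_LEN ({self.max_length})"
            )
        if self.min_mean_quality < 0:
            raise ConfigError("MIN_MEAN_QUALITY: must be non-negative")
        if self.min_copy_number < 1:
            raise ConfigError("MIN_COPY_NUMBER: must be >= 1")
        if self.boundary_window < 1:
            raise ConfigError("BOUNDARY_WINDOW: must be >= 1")
        if self.boundary_mismatch_threshold < 0:
            raise ConfigError("BOUNDARY_MISMATCH_THRESHOLD: must be >= 0")
        if not 0.0 < self.similarity_cutoff <= 100.0:
            raise ConfigError("SIMILARITY_CUTOFF: must be in (0, 100]")
        if self.evalue_cutoff < 0:
            raise ConfigError("EVALUE_CUTOFF: must be non-negative")
        seen: dict[str, str] = {}
        lengths = set()
        for sample, bc in self.barcodes.items():
            if not is_dna(bc):
                raise ConfigError(f"BARCODE_{sample}: must be DNA over A/C/G/T, got {bc!r}")
            if bc in seen:
                raise ConfigError(
                    f"BARCODE_{sample}: duplicate barcode {bc} (also sample {seen[bc]})"
                )
            seen[bc] = sample
            lengths.add(len(bc))
        if len(lengths) > 1:
            raise ConfigError("BARCODE_*: all barcodes must have equal length")


# ---------------------------------------------------------------------------
# options file

_REQUIRED_KEYS = ("ADAPTER_B", "FORWARD_PRIMER", "REVERSE_PRIMER", "MIN_LEN", "MAX_LEN")

_BOOL_VALUES = {"1": True, "TRUE": True, "YES": True, "0": False, "FALSE": False, "NO": False}

_SCALAR_KEYS = {
    "ADAPTER_B": ("adapter_b", str),
    "FORWARD_PRIMER": ("forward_primer", str),
    "REVERSE_PRIMER": ("reverse_primer", str),
    "MIN_LEN": ("min_length", int),
    "MAX_LEN": ("max_length", int),
    "ADAPTER_MAX_MISMATCH_FRACTION": ("adapter_max_mismatch_fraction", float),
    "MIN_MEAN_QUALITY": ("min_mean_quality", float),
    "MIN_COPY_NUMBER": ("min_copy_number", int),
    "BOUNDARY_WINDOW": ("boundary_window", int),
    "BOUNDARY_MISMATCH_THRESHOLD": ("boundary_mismatch_threshold", int),
    "SIMILARITY_CUTOFF": ("similarity_cutoff", float),
    "EVALUE_CUTOFF": ("evalue_cutoff", float),
    "SEED": ("seed", int),
    "REVERSE_PRIMER_LITERAL": ("reverse_primer_literal", bool),
    "BOUNDARY_FILTER_REVERSE_JUNCTION": ("boundary_filter_reverse_junction", bool),
    "EXEMPT_EXACT_BOUNDARY": ("exempt_exact_boundary", bool),
}


def parse_options(path: str | Path) -> PipelineConfig:
    """Parse a ``KEY=value`` options file into a validated PipelineConfig.

    Keys are case-insensitive; ``#`` starts a comment; unknown keys produce a
    warning; missing required keys and malformed values raise
    :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    values: dict[str, object] = {}
    barcodes: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path.name}:{lineno}: expected KEY=value, got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip().upper()
        value = value.strip()
        if key.startswith("BARCODE_"):
            sample = key[len("BARCODE_"):]
            if not sample:
                raise ConfigError(f"{path.name}:{lineno}: BARCODE_ key missing a sample name")
            barcodes[sample] = value.upper()
            continue
        if key not in _SCALAR_KEYS:
            warnings.warn(f"{path.name}: unknown option key {key!r} ignored", stacklevel=2)
            continue
        field_name, caster = _SCALAR_KEYS[key]
        try:
            if caster is bool:
                values[field_name] = _BOOL_VALUES[value.upper()]
            elif caster is str:
                values[field_name] = value.upper()
            else:
                values[field_name] = caster(value)
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"{key}: malformed value {value!r}") from exc
    missing = [k for k in _REQUIRED_KEYS if _SCALAR_KEYS[k][0] not in values]
    if missing:
        raise ConfigError(f"missing required option key(s): {', '.join(missing)}")
    return PipelineConfig(barcodes=barcodes, **values)  # type: ignore[arg-type]


def write_options_file(config: PipelineConfig, path: str | Path) -> Path:
    """Serialise a config back to the options-file dialect (round-trips)."""
    path = Path(path)
    lines = ["# ampliclean options file"]
    for key, (field_name, caster) in _SCALAR_KEYS.items():
        value = getattr(config, field_name)
        if caster is bool:
            value = "TRUE" if value else "FALSE"
        lines.append(f"{key}={value}")
    for sample, bc in config.barcodes.items():
        lines.append(f"BARCODE_{sample}={bc}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTA / .qual

def _normalise_sequence(seq: str, read_id: str, source: str) -> str:
    seq = seq.upper()
    if _NON_ACGTN.search(seq):
        warnings.warn(
            f"{source}: read {read_id} contains IUPAC ambiguity codes other than N; "
            "converted to N",
            stacklevel=3,
        )
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def read_paired_fasta_qual(fasta: str | Path, qual: str | Path) -> list[ReadRecord]:
    """Read a FASTA file and its parallel .qual file as paired records.

    Pairing is strict: the files must present identical IDs in identical
    order, and each record's quality count must equal its sequence length.
    """
    fasta, qual = Path(fasta), Path(qual)
    records: list[ReadRecord] = []
    fa_iter = SeqIO.parse(str(fasta), "fasta")
    q_iter = SeqIO.parse(str(qual), "qual")
    for fa, q in zip_longest(fa_iter, q_iter):
        if fa is None:
            raise PairedInputError(
                f"{qual.name}: extra quality record {q.id} with no FASTA counterpart"
            )
        if q is None:
            raise PairedInputError(
                f"{fasta.name}: record {fa.id} has no quality record ({qual.name} truncated)"
            )
        if fa.id != q.id:
            raise PairedInputError(
                f"ID mismatch between {fasta.name} and {qual.name}: {fa.id} vs {q.id}"
            )
        seq = _normalise_sequence(str(fa.seq), fa.id, fasta.name)
        quals = q.letter_annotations["phred_quality"]
        if len(quals) != len(seq):
            raise PairedInputError(
                f"read {fa.id}: sequence length {len(seq)} != {len(quals)} quality values"
            )
        records.append(ReadRecord(fa.id, seq, list(quals)))
    return records


def write_fasta(records: Iterable[ReadRecord], path: str | Path) -> Path:
    """Write records as unwrapped FASTA."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
    return path


def write_qual(records: Iterable[ReadRecord], path: str | Path) -> Path:
    """Write per-base qualities in 454 .qual format (one header per read)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{' '.join(str(q) for q in rec.qualities)}\n")
    return path


_SIZE_RE = re.compile(r";size=(\d+)")


def write_nr_fasta(records: Sequence, path: str | Path, sample: str) -> Path:
    """Write dereplicated records with `>{sample}_NR{rank:06d};size={freq}` headers."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{sample}_NR{rec.rank:06d};size={rec.frequency}\n{rec.sequence}\n")
    return path


def read_nr_fasta(path: str | Path) -> list[NrRecord]:
    """Read a non-redundant FASTA whose headers carry `;size=N` frequencies."""
    path = Path(path)
    out: list[NrRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SIZE_RE.search(rec.description)
        if not m:
            raise FormatError(f"{path.name}: record {rec.id} lacks a ';size=N' frequency tag")
        seq = _normalise_sequence(str(rec.seq), rec.id, path.name)
        out.append(NrRecord(rec.id.split(";", 1)[0], seq, int(m.group(1))))
    return out
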