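"""454-style amplicon read simulator with a ground-truth fate manifest.

Each simulated read follows the standard amplicon anatomy

    barcode | forward primer | target | rc(reverse primer) | adapter B

and carries at most one injected defect, chosen so that the step at which
the trimming pipeline must discard the read is known *by construction*:

==================  =================================================  ====
defect              construction                                       fate
==================  =================================================  ====
no_adapter          adapter B omitted (verified free of look-alikes)    1
ambiguous_base      one N in the target interior                        2
singleton           unique full string, emitted exactly once            3
bad_barcode         5' tag replaced by a non-barcode sequence           4
out_of_length       target shortened below the length window            5
primer_mutation     one substitution inside the forward primer          6
boundary_indel      ±1 homopolymer indel at the primer/target junction  6
low_quality         qualities drawn from [5, 15] instead of [30, 40]    7
==================  =================================================  ====

Design features that make fates exact rather than probable:

* All target seeds share a conserved junction prefix of ``boundary_window+1``
  bases whose first base equals the forward primer's last base (the
  homopolymer-spanning-junction configuration the boundary filter targets)
  and whose remainder cycles through the four bases, so clean reads show 7–8
  mismatches at the ±1 offsets while every injected junction indel
  reproduces the consensus exactly at one offset.
* Reads in classes that must survive pooled low-frequency removal are
  emitted in groups of at least ``min_copy_number`` identical strings;
  target variants are globally unique across groups.
* Every read is checked at generation time against a simulator-local adapter
  scanner: adapter-bearing reads must match exactly at the true junction and
  ``no_adapter`` reads must not match anywhere (variants are resampled
  otherwise).

Quality model: clean bases uniform on [30, 40], low-quality reads uniform on
[5, 15], so any mean-quality threshold in (15, 30] classifies unambiguously.
Default defect rates mirror the per-step attrition profile of a large 18S
rRNA freshwater survey processed with this kind of pipeline (roughly 63% of
raw reads surviving all seven steps).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from ._util import hamming, revcomp
from .config_io import (
    PipelineConfig,
    ReadRecord,
    StepReport,
    write_fasta,
    write_options_file,
    write_qual,
)
from .trim_filter import STEP_NAMES

__all__ = [
    "DEFECT_CLASSES",
    "DEFAULT_RATES",
    "SimTruth",
    "default_demo_config",
    "inject_boundary_indel",
    "simulate_sample_set",
    "write_truth",
    "read_truth",
    "manifest_step_counts",
    "manifest_discard_ids",
]

DEFECT_CLASSES = (
    "no_adapter",
    "ambiguous_base",
    "singleton",
    "bad_barcode",
    "out_of_length",
    "primer_mutation",
    "boundary_indel",
    "low_quality",
)

#: Fractions of total input discarded per step in the reference attrition
#: profile (steps 1..7 of a ~448k-read 18S survey), used as default rates.
DEFAULT_RATES: dict[str, float] = {
    "no_adapter": 0.16,
    "ambiguous_base": 0.034,
    "singleton": 0.104,
    "bad_barcode": 0.012,
    "out_of_length": 0.010,
    "primer_mutation": 0.030,
    "boundary_indel": 0.024,
    "low_quality": 0.010,
}

_FATE_BY_DEFECT = {
    "no_adapter": "1",
    "ambiguous_base": "2",
    "singleton": "3",
    "bad_barcode": "4",
    "out_of_length": "5",
    "primer_mutation": "6",
    "boundary_indel": "6",
    "low_quality": "7",
}

# classes whose reads must survive pooled low-frequency removal to reach
# their designated fate
_NEEDS_MULTIPLICITY = frozenset(
    {"bad_barcode", "out_of_length", "primer_mutation", "boundary_indel", "low_quality", "clean"}
)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated read."""

    id: str
    sample: str
    clean_target: str
    defects: tuple[str, ...]
    expected_fate: str  # "1".."7" (discarding step) or "kept"


def default_demo_config(**overrides) -> PipelineConfig:
    """A ready-to-run multiplexed demo configuration (three MID barcodes)."""
    params: dict = dict(
        adapter_b="CTGAGACTGCCAAGGCACAC",
        forward_primer="GTGCCAGCAGCCGCGG",
        reverse_primer="GAATTACCGCGGCTGC",
        min_length=100,
        max_length=400,
        barcodes={"S1": "ACGAGTGCGT", "S2": "ACGCTCGACA", "S3": "AGACGCACTC"},
        adapter_max_mismatch_fraction=0.1,
        min_mean_quality=25.0,
        min_copy_number=2,
        similarity_cutoff=100.0,
    )
    params.update(overrides)
    return PipelineConfig(**params)


def inject_boundary_indel(read: ReadRecord, junction: int, direction: int) -> ReadRecord:
    """Inject a ±1 homopolymer indel at the primer/target junction.

    ``junction`` is the index of the first target base. Direction +1 inserts
    a duplicate of the base preceding the junction (the primer's last base);
    −1 deletes the first target base. Qualities stay paired with bases.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if len(read) - junction < 9:
        raise ValueError(f"read {read.id}: fewer than 9 target bases after the junction")
    seq, quals = read.sequence, list(read.qualities)
    if direction == 1:
        new_seq = seq[:junction] + seq[junction - 1] + seq[junction:]
        new_quals = quals[:junction] + [quals[junction - 1]] + quals[junction:]
    else:
        new_seq = seq[:junction] + seq[junction + 1:]
        new_quals = quals[:junction] + quals[junction + 1:]
    return ReadRecord(read.id, new_seq, new_quals)


# ---------------------------------------------------------------------------
# generation helpers

_CYCLE = "ACGT"


def _junction_prefix(forward_primer: str, window: int) -> str:
    """Conserved target prefix: primer's last base + a period-4 base cycle."""
    c0 = forward_primer[-1]
    start = _CYCLE.index(c0) + 1
    return c0 + "".join(_CYCLE[(start + i) % 4] for i in range(window))


def _scan_adapter(seq: str, adapter: str, frac: float) -> int | None:
    """Simulator-local adapter scan mirroring the documented matching rule."""
    la, n = len(adapter), len(seq)
    min_trunc = math.ceil(la / 2)
    best: tuple[float, int] | None = None
    for start in range(0, n - min_trunc + 1):
        m = min(la, n - start)
        allowed = math.ceil(frac * m)
        mm = hamming(seq[start:start + m], adapter[:m], limit=allowed + 1)
        if mm <= allowed and (best is None or mm / m < best[0]):
            best = (mm / m, start)
    return None if best is None else best[1]


def _wrong_tag(barcode: str, all_barcodes: set[str]) -> str:
    """An equal-length 5' tag matching no configured barcode."""
    tag = revcomp(barcode)[::-1]  # plain complement
    while tag in all_barcodes:
        tag = tag[1:] + tag[0]
    return tag


class _VariantFactory:
    """Unique target variants derived from a handful of divergent seeds."""

    def __init__(self, rng: random.Random, prefix: str, target_len: int, n_seeds: int = 5):
        self.rng = rng
        self.prefix = prefix
        self.target_len = target_len
        self.seeds = [
            prefix + "".join(rng.choice(_CYCLE) for _ in range(target_len - len(prefix)))
            for _ in range(n_seeds)
        ]
        self.used: set[str] = set(self.seeds)

    def _mutate(self, template: str) -> str:
        bases = list(template)
        for pos in self.rng.sample(range(len(self.prefix), len(bases)), self.rng.randint(1, 3)):
            bases[pos] = self.rng.choice([b for b in _CYCLE if b != bases[pos]])
        return "".join(bases)

    def new_variant(self, length: int | None = None) -> str:
        """A globally unique target of the given length (default full length)."""
        for _ in range(200):
            if length is None or length == self.target_len:
                cand = self._mutate(self.rng.choice(self.seeds))
            else:
                tail_len = length - len(self.prefix)
                if tail_len < 0:
                    raise ValueError("requested variant shorter than the conserved prefix")
                cand = self.prefix + "".join(self.rng.choice(_CYCLE) for _ in range(tail_len))
            if cand not in self.used:
                self.used.add(cand)
                return cand
        raise RuntimeError("could not generate a unique target variant")


def _plan_counts(
    n: int, rates: Mapping[str, float], min_copy: int, have_barcodes: bool
) -> dict[str, int]:
    """Per-class read counts for one sample; remainder is clean.

    Classes that must survive low-frequency removal but received fewer reads
    than ``min_copy_number`` are folded into the singleton class (count too
    small to ever survive) so every fate stays exact.
    """
    counts = {cat: int(round(rates.get(cat, 0.0) * n)) for cat in DEFECT_CLASSES}
    if not have_barcodes:
        counts["bad_barcode"] = 0
    clean = n - sum(counts.values())
    if clean < 0:
        raise ValueError("defect rates allocate more reads than n_per_sample")
    group = max(2, min_copy)
    if min_copy > 1:
        for cat in sorted(_NEEDS_MULTIPLICITY - {"clean"}):
            if 0 < counts[cat] < group:
                counts["singleton"] += counts[cat]
                counts[cat] = 0
        if 0 < clean < group:
            counts["singleton"] += clean
            clean = 0
    counts["clean"] = clean
    return counts


def _group_sizes(count: int, group: int) -> list[int]:
    """Partition ``count`` into groups of ≥ ``group`` identical reads."""
    if count == 0:
        return []
    n_groups = max(1, count // group)
    sizes = [group] * n_groups
    sizes[-1] += count - group * n_groups
    return sizes


def simulate_sample_set(
    config: PipelineConfig,
    n_per_sample: int,
    defect_rates: Mapping[str, float] | None = None,
    seed: int = 42,
    out_dir: str | Path | None = None,
) -> tuple[list[ReadRecord], list[SimTruth]]:
    """Simulate a multiplexed 454-style dataset with known per-read fates.

    Returns (records, truths); with ``out_dir`` also writes ``reads.fasta``,
    ``reads.qual``, ``truth.tsv`` and an ``options.txt`` reflecting the
    configuration. Deterministic for a fixed seed.
    """
    rates = dict(DEFAULT_RATES if defect_rates is None else defect_rates)
    unknown = set(rates) - set(DEFECT_CLASSES)
    if unknown:
        raise ValueError(f"unknown defect class(es): {sorted(unknown)}")
    if any(r < 0 for r in rates.values()) or sum(rates.values()) > 1.0 + 1e-9:
        raise ValueError("defect rates must be non-negative and sum to at most 1")
    if rates.get("low_quality", 0) > 0 and not (15.0 < config.min_mean_quality <= 30.0):
        raise ValueError(
            "low_quality reads need MIN_MEAN_QUALITY in (15, 30] to classify unambiguously"
        )
    if config.min_mean_quality > 30.0:
        raise ValueError("MIN_MEAN_QUALITY above 30 would discard clean simulated reads")

    rng = random.Random(seed)
    fwd, rev, adapter = config.forward_primer, config.reverse_primer, config.adapter_b
    tail = revcomp(rev)
    p, q = len(fwd), len(tail)
    prefix = _junction_prefix(fwd, config.boundary_window)

    lo = config.min_length - p - q
    hi = config.max_length - p - q
    target_len = min(max(150, lo + 2, len(prefix) + 30), hi - 2)
    if target_len < len(prefix) + 9 or target_len > hi - 1 or target_len < lo + 2:
        raise ValueError("length window too tight for the simulated read anatomy")
    short_len = lo - 10
    off_length_len = short_len if short_len >= len(prefix) else hi + 10

    # one fixed forward-primer mutation for the whole run, so reads in the
    # same multiplicity group share an identical string
    mut_pos = p // 2
    mutated_fwd = (
        fwd[:mut_pos]
        + _CYCLE[(_CYCLE.index(fwd[mut_pos]) + 1) % 4]
        + fwd[mut_pos + 1:]
    )

    factory = _VariantFactory(rng, prefix, target_len)
    samples = list(config.barcodes) if config.barcodes else ["all"]
    all_barcodes = set(config.barcodes.values())
    min_copy = config.min_copy_number
    group = max(2, min_copy)

    records: list[ReadRecord] = []
    truths: list[SimTruth] = []
    for sample in samples:
        barcode = config.barcodes.get(sample, "")
        counts = _plan_counts(n_per_sample, rates, min_copy, bool(config.barcodes))
        # (category, target_variant, direction) per read, groups sharing variants
        specs: list[tuple[str, str, int]] = []
        indel_dir = 1
        for cat in list(DEFECT_CLASSES) + ["clean"]:
            count = counts[cat]
            if cat in ("no_adapter", "ambiguous_base", "singleton"):
                sizes = [1] * count
            else:
                sizes = _group_sizes(count, group)
            for size in sizes:
                length = off_length_len if cat == "out_of_length" else None
                variant = factory.new_variant(length)
                direction = 0
                if cat == "boundary_indel":
                    direction = indel_dir
                    indel_dir = -indel_dir
                specs.extend([(cat, variant, direction)] * size)
        rng.shuffle(specs)

        wrong = _wrong_tag(barcode, all_barcodes) if barcode else ""
        for i, (cat, variant, direction) in enumerate(specs):
            read_id = f"{sample}_r{i:05d}"
            target = variant
            bc = barcode
            fwd_used = fwd
            if cat == "ambiguous_base":
                mid = len(target) // 2
                target = target[:mid] + "N" + target[mid + 1:]
            elif cat == "bad_barcode":
                bc = wrong
            elif cat == "primer_mutation":
                fwd_used = mutated_fwd
            core = bc + fwd_used + target + tail
            low = cat == "low_quality"
            qlo, qhi = (5, 15) if low else (30, 40)
            quals = [rng.randint(qlo, qhi) for _ in range(len(core))]
            record = ReadRecord(read_id, core, quals)
            if cat == "boundary_indel":
                record = inject_boundary_indel(record, len(bc) + p, direction)
            if cat != "no_adapter":
                aquals = [rng.randint(qlo, qhi) for _ in range(len(adapter))]
                record = ReadRecord(
                    read_id, record.sequence + adapter, record.qualities + aquals
                )
                expected = len(record) - len(adapter)
            else:
                expected = None
            found = _scan_adapter(
                record.sequence, adapter, config.adapter_max_mismatch_fraction
            )
            if found != expected:
                raise RuntimeError(
                    f"simulated read {read_id} has a spurious adapter match "
                    f"(found {found}, expected {expected}); adjust the configuration"
                )
            records.append(record)
            fate = _FATE_BY_DEFECT.get(cat, "kept")
            if cat == "singleton" and min_copy <= 1:
                fate = "kept"
            defect: tuple[str, ...]
            if cat == "clean":
                defect = ()
            elif cat == "boundary_indel":
                defect = (f"boundary_indel:{'+1' if direction == 1 else '-1'}",)
            else:
                defect = (cat,)
            truths.append(SimTruth(read_id, sample, variant, defect, fate))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "reads.fasta")
        write_qual(records, out_dir / "reads.qual")
        write_truth(truths, out_dir / "truth.tsv")
        write_options_file(config, out_dir / "options.txt")
    return records, truths


# ---------------------------------------------------------------------------
# manifest I/O and accounting

def write_truth(truths: Sequence[SimTruth], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": [t.id for t in truths],
            "sample": [t.sample for t in truths],
            "clean_target": [t.clean_target for t in truths],
            "defects": [",".join(t.defects) for t in truths],
            "expected_fate": [t.expected_fate for t in truths],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_truth(path: str | Path) -> list[SimTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SimTruth(
            row["id"],
            row["sample"],
            row["clean_target"],
            tuple(d for d in row["defects"].split(",") if d),
            row["expected_fate"],
        )
        for _, row in df.iterrows()
    ]


def manifest_step_counts(truths: Sequence[SimTruth]) -> list[StepReport]:
    """The per-step StepReports the pipeline must reproduce on this dataset."""
    n = len(truths)
    discards = {str(i): 0 for i in range(1, 8)}
    for t in truths:
        if t.expected_fate != "kept":
            discards[t.expected_fate] += 1
    reports = []
    for i, name in enumerate(STEP_NAMES, start=1):
        d = discards[str(i)]
        reports.append(StepReport(name, n, n - d, d))
        n -= d
    return reports


def manifest_discard_ids(truths: Sequence[SimTruth]) -> dict[str, set[str]]:
    """Expected discarded read IDs per pipeline step name."""
    out: dict[str, set[str]] = {name: set() for name in STEP_NAMES}
    for t in truths:
        if t.expected_fate != "kept":
            out[STEP_NAMES[int(t.expected_fate) - 1]].add(t.id)
    return out
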