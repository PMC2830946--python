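"""Cross-sample overlap of non-redundant sequences under a similarity cutoff.

For each query sequence the table reports its copy number in its own sample
and, per target sample, the summed copy number of all target sequences whose
gap-excluded similarity to the query reaches the cutoff (a cutoff of 100
groups sequences that are identical once gaps are ignored, so indel-only
variants count together). A ``best_hit_only`` switch instead reports the
copy number of the single most similar target sequence within the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .align import align_stats
from .config_io import NrRecord

__all__ = ["OverlapRow", "similarity", "match_across_samples", "write_overlap_table"]

from .align import similarity  # re-exported: the shared gap-excluded measure


@dataclass(frozen=True)
class OverlapRow:
    """Copy numbers of one query sequence in its own and each target sample."""

    query_sequence_id: str
    self_copies: int
    target_copies: dict[str, int]


def match_across_samples(
    query_nr: Sequence[NrRecord],
    target_nr_sets: Mapping[str, Sequence[NrRecord]],
    similarity_cutoff: float,
    best_hit_only: bool = False,
) -> list[OverlapRow]:
    """Count query copy numbers across target samples at the cutoff.

    ``target_copies[t]`` sums the frequencies of every target-t sequence
    within the cutoff (zero when none); with ``best_hit_only`` it is the
    frequency of the best match only, ties broken by longer gap-free span
    then by sequence id.
    """
    rows: list[OverlapRow] = []
    for query in query_nr:
        copies: dict[str, int] = {}
        for target_name, targets in target_nr_sets.items():
            total = 0
            best: tuple[float, int, str, int] | None = None  # (-sim, -span, id, freq)
            for t in targets:
                stats = align_stats(query.sequence, t.sequence)
                sim = stats.similarity
                if sim is None or sim < similarity_cutoff:
                    continue
                total += t.frequency
                key = (-sim, -stats.gap_free_columns, t.id)
                if best is None or key < best[:3]:
                    best = (*key, t.frequency)
            if best_hit_only:
                copies[target_name] = best[3] if best is not None else 0
            else:
                copies[target_name] = total
        rows.append(OverlapRow(query.id, query.frequency, copies))
    return rows


def write_overlap_table(
    rows: Sequence[OverlapRow], path: str | Path, target_order: Sequence[str] | None = None
) -> Path:
    """Write the tabular output: query id, self copies, one column per target."""
    path = Path(path)
    if target_order is None:
        target_order = list(rows[0].target_copies) if rows else []
    with path.open("w") as fh:
        fh.write("query_id\tself_copies\t" + "\t".join(target_order) + "\n")
        for row in rows:
            counts = "\t".join(str(row.target_copies.get(t, 0)) for t in target_order)
            fh.write(f"{row.query_sequence_id}\t{row.self_copies}\t{counts}\n")
    return path
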