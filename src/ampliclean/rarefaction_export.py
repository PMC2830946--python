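"""Exporters feeding external rarefaction/diversity tools.

Two downstream input flavours are produced from a non-redundant sample:

* a pairwise genetic distance matrix plus a names file (the column-format
  distance + names inputs consumed by MOTHUR-style clustering tools), where
  the internal engine defines distance as ``1 − similarity/100`` under the
  gap-excluded similarity, and the names file expands each sequence's copy
  number into synthetic ``_dupN`` replicate ids so clustering weights
  abundances correctly;
* a plain abundance list (one count per line, descending — the input of
  Analytic-Rarefaction-style tools), obtained by single-linkage grouping of
  the non-redundant sequences at the similarity cutoff and summing the
  grouped frequencies.

An external distance engine can be supplied as a callable; its values are
passed through untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .align import similarity
from .config_io import NrRecord

__all__ = [
    "DistanceMatrix",
    "pairwise_distances",
    "write_mothur_inputs",
    "write_abundance_list",
    "group_at_cutoff",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


Engine = Callable[[Sequence[NrRecord]], np.ndarray]


def _internal_engine(records: Sequence[NrRecord]) -> np.ndarray:
    n = len(records)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = similarity(records[i].sequence, records[j].sequence)
            d = 1.0 if sim is None else 1.0 - sim / 100.0
            values[i, j] = values[j, i] = d
    return values


def pairwise_distances(
    records: Sequence[NrRecord], engine: str | Engine = "internal"
) -> DistanceMatrix:
    """All-against-all genetic distances of a non-redundant sequence set.

    The internal engine uses ``1 − similarity/100``; a callable engine's
    values are passed through untransformed. Requires ≥2 sequences and
    unique ids.
    """
    if len(records) < 2:
        raise ValueError("pairwise distances need at least two sequences")
    ids = tuple(r.id for r in records)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids in input")
    if engine == "internal":
        values = _internal_engine(records)
    elif callable(engine):
        values = np.asarray(engine(records), dtype=float)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return DistanceMatrix(ids, values)


def write_mothur_inputs(
    matrix: DistanceMatrix,
    frequencies: Mapping[str, int],
    out_dir: str | Path,
    square: bool = False,
) -> tuple[Path, Path]:
    """Write a distance file and a names file for MOTHUR-style clustering.

    The distance file is column format (``idA idB distance``, lower
    triangle) by default, or phylip square format with ``square``. The names
    file maps each id to itself plus ``f−1`` synthetic ``_dupN`` replicate
    ids, carrying copy numbers into the clustering.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dist_path = out_dir / ("distances.square.dist" if square else "distances.dist")
    with dist_path.open("w") as fh:
        if square:
            fh.write(f"{len(matrix.ids)}\n")
            for i, name in enumerate(matrix.ids):
                row = "\t".join(f"{matrix.values[i, j]:.6f}" for j in range(len(matrix.ids)))
                fh.write(f"{name}\t{row}\n")
        else:
            for i in range(1, len(matrix.ids)):
                for j in range(i):
                    fh.write(f"{matrix.ids[i]} {matrix.ids[j]} {matrix.values[i, j]:.6f}\n")
    names_path = out_dir / "sequences.names"
    with names_path.open("w") as fh:
        for name in matrix.ids:
            freq = frequencies[name]
            replicates = [name] + [f"{name}_dup{k}" for k in range(1, freq)]
            fh.write(f"{name}\t{','.join(replicates)}\n")
    return dist_path, names_path


def group_at_cutoff(records: Sequence[NrRecord], similarity_cutoff: float) -> list[list[int]]:
    """Single-linkage groups of record indices at the similarity cutoff."""
    n = len(records)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            sim = similarity(records[i].sequence, records[j].sequence)
            if sim is not None and sim >= similarity_cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def write_abundance_list(
    records: Sequence[NrRecord], similarity_cutoff: float, path: str | Path
) -> list[int]:
    """Group sequences at the cutoff, sum frequencies, write one count/line.

    Counts are written in descending order; the summed counts conserve the
    total input frequency mass.
    """
    path = Path(path)
    counts = sorted(
        (sum(records[i].frequency for i in grp) for grp in group_at_cutoff(records, similarity_cutoff)),
        reverse=True,
    )
    with path.open("w") as fh:
        for c in counts:
            fh.write(f"{c}\n")
    return counts
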