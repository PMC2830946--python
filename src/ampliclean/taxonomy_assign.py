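"""Taxonomy assignment: best reference hit, tie-breaking, ranked lineage.

Non-redundant query sequences are searched against a nucleotide reference
collection through a pluggable provider (an internal deterministic aligner
for offline use, a tabular-hit-file parser, or an external BLAST+ run). The
best hit per query is the one with the minimal e-value; among hits with an
identical e-value the numeric tie-break is the higher bitscore, then the hit
with the most detailed taxonomic classification (deepest lineage path) wins.
If equally deep but conflicting lineages remain, a per-rank strict-majority
rule over the tied set resolves the assignment, truncated at the deepest
rank where a strict majority exists; residual ties are flagged unresolved
and broken by accession order so output stays deterministic.

Lineages come from a local table (a simple 4-column TSV, or the NCBI
taxonomy ``nodes.dmp``/``names.dmp`` dump dialect) — never live web queries.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from Bio import SeqIO

from .align import align_stats
from .config_io import FormatError

__all__ = [
    "ReferenceHit",
    "Lineage",
    "TaxonomyAssignment",
    "LineageError",
    "LineageTable",
    "ReferenceSeq",
    "InternalSearchProvider",
    "parse_tabular_hits",
    "blast_search",
    "read_reference_fasta",
    "select_best",
    "assign_taxonomy",
    "write_taxonomy_table",
    "toy_reference",
]


class LineageError(ValueError):
    """A taxid is unknown or the parent chain is cyclic."""


@dataclass(frozen=True)
class ReferenceHit:
    """One alignment of a query against a reference sequence."""

    query_id: str
    subject_accession: str
    percent_identity: float
    evalue: float
    bitscore: float
    subject_taxid: int


@dataclass(frozen=True)
class Lineage:
    """Root→leaf ranked taxonomic path for one taxon."""

    taxid: int
    species_name: str
    path: tuple[tuple[str, str], ...]  # (rank, name), root first
    path_taxids: tuple[int, ...]

    @property
    def depth(self) -> int:
        return len(self.path)

    @property
    def path_string(self) -> str:
        return ";".join(name for _, name in self.path)


@dataclass(frozen=True)
class TaxonomyAssignment:
    """The resolved classification of one query sequence."""

    query_id: str
    chosen: ReferenceHit
    lineage: Lineage
    tie_count: int
    resolved_by: str  # single_best | deepest_path | majority_rule | unresolved


@dataclass(frozen=True)
class ReferenceSeq:
    accession: str
    taxid: int
    sequence: str


# ---------------------------------------------------------------------------
# lineage table

class LineageTable:
    """taxid → (parent, rank, name) mapping with root→leaf traversal."""

    def __init__(self, nodes: Mapping[int, tuple[int, str, str]]):
        self.nodes = dict(nodes)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LineageTable":
        """4-column TSV: taxid, parent_taxid, rank, name (root: parent==taxid)."""
        nodes: dict[int, tuple[int, str, str]] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{Path(path).name}:{lineno}: expected 4 tab-separated columns")
            taxid, parent, rank, name = parts
            nodes[int(taxid)] = (int(parent), rank, name)
        return cls(nodes)

    @classmethod
    def from_ncbi_dumps(cls, nodes_dmp: str | Path, names_dmp: str | Path) -> "LineageTable":
        """NCBI taxonomy dump dialect (fields separated by ``\\t|\\t``)."""
        names: dict[int, str] = {}
        for raw in Path(names_dmp).read_text().splitlines():
            parts = [p.strip() for p in raw.strip().rstrip("|").split("|")]
            if len(parts) >= 4 and parts[3] == "scientific name":
                names[int(parts[0])] = parts[1]
        nodes: dict[int, tuple[int, str, str]] = {}
        for raw in Path(nodes_dmp).read_text().splitlines():
            parts = [p.strip() for p in raw.strip().rstrip("|").split("|")]
            taxid, parent, rank = int(parts[0]), int(parts[1]), parts[2]
            nodes[taxid] = (parent, rank, names.get(taxid, f"taxid:{taxid}"))
        return cls(nodes)

    def lineage(self, taxid: int) -> Lineage:
        """Root→leaf path by parent traversal; unknown taxids and cycles fail."""
        if taxid not in self.nodes:
            raise LineageError(f"unknown taxid {taxid}")
        path: list[tuple[str, str]] = []
        taxids: list[int] = []
        seen: set[int] = set()
        node = taxid
        while True:
            if node in seen:
                raise LineageError(f"cycle in lineage table at taxid {node}")
            seen.add(node)
            parent, rank, name = self.nodes[node]
            path.append((rank, name))
            taxids.append(node)
            if parent == node or parent == 0:
                break
            if parent not in self.nodes:
                raise LineageError(f"taxid {node} has unknown parent {parent}")
            node = parent
        path.reverse()
        taxids.reverse()
        return Lineage(taxid, path[-1][1], tuple(path), tuple(taxids))


# ---------------------------------------------------------------------------
# search providers

class SearchProvider(Protocol):
    """Contract: given (id, sequence) queries, return hits per query id."""

    def search(
        self, queries: Sequence[tuple[str, str]], evalue_cutoff: float
    ) -> dict[str, list[ReferenceHit]]: ...


class InternalSearchProvider:
    """Deterministic offline search against an in-memory reference collection.

    Each query is globally aligned against every reference; the percent
    identity is the gap-excluded similarity and the bitscore is the raw
    alignment score. The e-value is a monotone surrogate,
    ``total_reference_length × query_length × 2^(−score)`` floored at 1e-180
    — adequate for ordering and cutoff filtering, not a Karlin–Altschul
    statistic.
    """

    def __init__(self, references: Iterable[ReferenceSeq]):
        self.references = list(references)
        if not self.references:
            raise ValueError("reference collection is empty")
        self._db_len = sum(len(r.sequence) for r in self.references)

    def search(
        self, queries: Sequence[tuple[str, str]], evalue_cutoff: float
    ) -> dict[str, list[ReferenceHit]]:
        out: dict[str, list[ReferenceHit]] = {}
        for qid, qseq in queries:
            hits: list[ReferenceHit] = []
            for ref in self.references:
                stats = align_stats(qseq, ref.sequence)
                sim = stats.similarity
                if sim is None:
                    continue
                evalue = max(self._db_len * len(qseq) * 2.0 ** (-stats.score), 1e-180)
                if evalue <= evalue_cutoff:
                    hits.append(
                        ReferenceHit(
                            qid, ref.accession, sim, evalue, float(stats.score), ref.taxid
                        )
                    )
            hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_accession))
            out[qid] = hits
        return out


def parse_tabular_hits(
    path: str | Path, taxid_map: Mapping[str, int] | None = None
) -> dict[str, list[ReferenceHit]]:
    """Parse classic 12-column tabular alignment output (+ optional taxid col).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [staxid]. Without the 13th column, ``taxid_map``
    must supply an accession → taxid mapping.
    """
    path = Path(path)
    out: dict[str, list[ReferenceHit]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 12:
            raise FormatError(f"{path.name}:{lineno}: expected >=12 tab-separated columns")
        qid, acc = parts[0], parts[1]
        if len(parts) >= 13 and parts[12] not in ("", "N/A"):
            taxid = int(parts[12].split(";")[0])
        elif taxid_map is not None and acc in taxid_map:
            taxid = taxid_map[acc]
        else:
            raise FormatError(
                f"{path.name}:{lineno}: no subject taxid (13th column) and no mapping for {acc}"
            )
        out.setdefault(qid, []).append(
            ReferenceHit(qid, acc, float(parts[2]), float(parts[10]), float(parts[11]), taxid)
        )
    for hits in out.values():
        hits.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_accession))
    return out


def blast_search(
    queries: Sequence[tuple[str, str]],
    reference_fasta: str | Path,
    taxid_map: Mapping[str, int],
    evalue_cutoff: float = 1e-5,
) -> dict[str, list[ReferenceHit]]:
    """Shell out to BLAST+ (makeblastdb + blastn) and parse tabular output."""
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        qfile = tmp_path / "queries.fasta"
        with qfile.open("w") as fh:
            for qid, qseq in queries:
                fh.write(f">{qid}\n{qseq}\n")
        db = tmp_path / "refdb"
        subprocess.run(
            ["makeblastdb", "-in", str(reference_fasta), "-dbtype", "nucl",
             "-out", str(db)],
            check=True, capture_output=True, text=True,
        )
        hits_file = tmp_path / "hits.tsv"
        subprocess.run(
            ["blastn", "-query", str(qfile), "-db", str(db), "-outfmt", "6 std",
             "-evalue", str(evalue_cutoff), "-out", str(hits_file)],
            check=True, capture_output=True, text=True,
        )
        result = parse_tabular_hits(hits_file, taxid_map)
    for qid, _ in queries:
        result.setdefault(qid, [])
    return result


def read_reference_fasta(path: str | Path) -> list[ReferenceSeq]:
    """Load references from FASTA whose headers carry ``taxid=N`` tokens."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxid = None
        for token in rec.description.split():
            if token.startswith("taxid="):
                taxid = int(token[len("taxid="):])
        if taxid is None:
            raise FormatError(f"{Path(path).name}: record {rec.id} lacks a 'taxid=N' token")
        refs.append(ReferenceSeq(rec.id, taxid, str(rec.seq).upper()))
    return refs


# ---------------------------------------------------------------------------
# best-hit selection

def select_best(
    hits: Sequence[ReferenceHit], lineage_table: LineageTable
) -> TaxonomyAssignment | None:
    """Resolve a query's hit list to one assignment (None = no usable hit).

    Resolution order: minimal e-value → maximal bitscore → deepest lineage →
    per-rank strict majority over the tied lineages → accession order
    (flagged unresolved). Hits whose taxid cannot be resolved are excluded
    with a warning.
    """
    resolved: list[tuple[ReferenceHit, Lineage]] = []
    for hit in hits:
        try:
            resolved.append((hit, lineage_table.lineage(hit.subject_taxid)))
        except LineageError as exc:
            warnings.warn(
                f"hit {hit.subject_accession} excluded: {exc}", stacklevel=2
            )
    if not resolved:
        return None
    qid = resolved[0][0].query_id

    min_e = min(h.evalue for h, _ in resolved)
    tied = [(h, l) for h, l in resolved if h.evalue == min_e]
    tie_count = len(tied)
    if len(tied) > 1:
        max_bits = max(h.bitscore for h, _ in tied)
        tied = [(h, l) for h, l in tied if h.bitscore == max_bits]
    if len(tied) == 1:
        hit, lin = tied[0]
        return TaxonomyAssignment(qid, hit, lin, tie_count, "single_best")

    max_depth = max(l.depth for _, l in tied)
    deep = [(h, l) for h, l in tied if l.depth == max_depth]
    if len(deep) == 1:
        hit, lin = deep[0]
        return TaxonomyAssignment(qid, hit, lin, tie_count, "deepest_path")
    if len({l.path for _, l in deep}) == 1:
        hit, lin = min(deep, key=lambda hl: hl[0].subject_accession)
        return TaxonomyAssignment(qid, hit, lin, tie_count, "deepest_path")

    # strict per-rank majority over the k tied lineages, root downwards
    k = len(deep)
    prefix_len = 0
    for i in range(max_depth):
        counts = Counter(l.path[i] for _, l in deep)
        (_, top_count), = counts.most_common(1)
        if 2 * top_count > k:
            prefix_len = i + 1
        else:
            break
    if prefix_len:
        majority_prefix: list[tuple[str, str]] = []
        pool = deep
        for i in range(prefix_len):
            counts = Counter(l.path[i] for _, l in pool)
            majority_prefix.append(counts.most_common(1)[0][0])
        matching = [
            (h, l) for h, l in deep if l.path[:prefix_len] == tuple(majority_prefix)
        ]
        hit, full = min(matching, key=lambda hl: hl[0].subject_accession)
        lineage = Lineage(
            full.path_taxids[prefix_len - 1],
            majority_prefix[-1][1],
            tuple(majority_prefix),
            full.path_taxids[:prefix_len],
        )
        return TaxonomyAssignment(qid, hit, lineage, tie_count, "majority_rule")

    hit, lin = min(deep, key=lambda hl: hl[0].subject_accession)
    return TaxonomyAssignment(qid, hit, lin, tie_count, "unresolved")


def assign_taxonomy(
    queries: Sequence[tuple[str, str]],
    provider: SearchProvider,
    lineage_table: LineageTable,
    evalue_cutoff: float = 1e-5,
) -> dict[str, TaxonomyAssignment | None]:
    """Search all queries and resolve each hit list; None marks 'no hit'."""
    hits_by_query = provider.search(queries, evalue_cutoff)
    return {
        qid: select_best(hits_by_query.get(qid, []), lineage_table)
        for qid, _ in queries
    }


def write_taxonomy_table(
    assignments: Mapping[str, TaxonomyAssignment | None],
    path: str | Path,
    group: str | None = None,
) -> Path:
    """Write the 6-column classification table (+ stable ``flag`` column).

    Columns: query id, percent similarity, e-value, closest accession,
    species name, semicolon-joined taxonomic path. The ``flag`` column
    carries ``resolved_by`` for rows not resolved as single best (and
    ``no_hit`` for queries without a usable hit). With ``group``, only rows
    whose path contains the substring are written.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "query_id\tpercent_similarity\tevalue\taccession\tspecies_name\t"
            "taxonomic_path\tflag\n"
        )
        for qid, a in assignments.items():
            if a is None:
                if group is None:
                    fh.write(f"{qid}\t\t\t\t\t\tno_hit\n")
                continue
            path_str = a.lineage.path_string
            if group is not None and group not in path_str:
                continue
            flag = "" if a.resolved_by == "single_best" else a.resolved_by
            fh.write(
                f"{qid}\t{a.chosen.percent_identity:.2f}\t{a.chosen.evalue:.3g}\t"
                f"{a.chosen.subject_accession}\t{a.lineage.species_name}\t"
                f"{path_str}\t{flag}\n"
            )
    return path


# ---------------------------------------------------------------------------
# packaged toy reference (offline demo / fixtures)

_TOY_LINEAGE_ROWS: tuple[tuple[int, int, str, str], ...] = (
    (1, 1, "no rank", "root"),
    (2, 1, "superkingdom", "Eukaryota"),
    (10, 2, "phylum", "Chlorophyta"),
    (11, 10, "class", "Chlorophyceae"),
    (12, 11, "order", "Chlamydomonadales"),
    (13, 12, "family", "Chlamydomonadaceae"),
    (14, 13, "genus", "Chlamydomonas"),
    (15, 14, "species", "Chlamydomonas reinhardtii"),
    (16, 13, "genus", "Volvox"),
    (17, 16, "species", "Volvox carteri"),
    (20, 2, "phylum", "Ciliophora"),
    (21, 20, "class", "Oligohymenophorea"),
    (22, 21, "order", "Peniculida"),
    (23, 22, "family", "Parameciidae"),
    (24, 23, "genus", "Paramecium"),
    (25, 24, "species", "Paramecium tetraurelia"),
    (30, 2, "phylum", "Bacillariophyta"),
    (31, 30, "class", "Bacillariophyceae"),
    (32, 31, "genus", "Navicula"),
)

_TOY_REFERENCES: tuple[tuple[str, int, str], ...] = (
    ("CR0001.1", 15, "GTTAGACCGATGGCTCATTAAATCAGTTATAGTTTATTTGATGGTACCTACTACTCGGAT"),
    ("VC0001.1", 17, "GTTAGACCGATGGCTCATTAAATCAGTTATAGTTTATTTGGTGGTACCTACAACTCGGAT"),
    ("PT0001.1", 25, "ACCTGGTTGATCCTGCCAGTAGTCATATGCTTGTCTCAAAGATTAAGCCATGCATGTCTA"),
    ("NV0001.1", 32, "CGAATTGTAGTCTCGAGGTCACGACTTCGGTCGACTAAGCTTCGGATCTGGTTACGACTT"),
)


def toy_reference() -> tuple[list[ReferenceSeq], LineageTable]:
    """A tiny packaged 18S-style reference + lineage table for offline use."""
    refs = [ReferenceSeq(acc, taxid, seq) for acc, taxid, seq in _TOY_REFERENCES]
    table = LineageTable({t: (p, r, n) for t, p, r, n in _TOY_LINEAGE_ROWS})
    return refs, table
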