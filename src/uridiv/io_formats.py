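"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain text: FASTA for reads and templates, a
4-column BLAST-tabular subset for hit tables, tab-separated ranked
lineage strings for the reference taxonomy, a phylip-style lower-triangle
distance matrix, and tab-separated OTU membership lists.  Extra columns
in hit tables are ignored; everything else is strict and failures name
the offending line (1-based).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .distances import DistanceMatrix
from .errors import FormatError, InvariantError

__all__ = [
    "SequenceRecord",
    "PrimerSpec",
    "HitRecord",
    "TaxNode",
    "TaxonomyTree",
    "IUPAC",
    "RANKS",
    "DEFAULT_PRIMERS",
    "FORWARD_PRIMERS",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_taxonomy",
    "read_primers",
    "write_primers",
    "read_truth_table",
    "write_truth_table",
    "write_otu_lists",
]

#: IUPAC nucleotide ambiguity codes and the base sets they denote.
IUPAC: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SEQ_RE = re.compile(r"^[ACGTRYSWKMBDHVN]+$")

REGIONS = ("V1V2", "V6", "unknown")


@dataclass
class SequenceRecord:
    """One read: id, uppercase IUPAC nucleotide string, sample and region."""

    id: str
    seq: str
    sample: str = ""
    region: str = "unknown"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise InvariantError(f"record {self.id!r}: empty sequence")
        if not _SEQ_RE.match(self.seq):
            bad = sorted(set(self.seq) - set(IUPAC))
            raise InvariantError(f"record {self.id!r}: non-IUPAC characters {bad}")
        if self.region not in REGIONS:
            raise InvariantError(f"record {self.id!r}: unknown region {self.region!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PrimerSpec:
    """A composite amplicon primer: sequencing adapter + target-specific part.

    ``adapter`` is the 19-base sequencing-adapter segment at the 5' end,
    ``target`` the 17-20 base 16S-specific segment (IUPAC codes allowed).
    ``composite`` is what a read must begin with to be assigned to
    ``region``.
    """

    name: str
    region: str
    adapter: str
    target: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "adapter", self.adapter.upper())
        object.__setattr__(self, "target", self.target.upper())
        if len(self.adapter) != 19:
            raise InvariantError(f"primer {self.name!r}: adapter must be 19 bases")
        if not 17 <= len(self.target) <= 20:
            raise InvariantError(f"primer {self.name!r}: target must be 17-20 bases")
        for part in (self.adapter, self.target):
            if not _SEQ_RE.match(part):
                raise InvariantError(f"primer {self.name!r}: non-IUPAC characters")
        if self.orientation not in ("forward", "reverse"):
            raise InvariantError(f"primer {self.name!r}: bad orientation")
        if self.region not in REGIONS:
            raise InvariantError(f"primer {self.name!r}: unknown region")

    @property
    def composite(self) -> str:
        return self.adapter + self.target


#: GS FLX amplicon adapters A and B.
_ADAPTER_A = "GCCTCCCTCGCGCCATCAG"
_ADAPTER_B = "GCCTTGCCAGCCCGCTCAG"

#: The study's composite PCR primers; reads start with the A-side primer.
DEFAULT_PRIMERS: tuple[PrimerSpec, ...] = (
    PrimerSpec("A2+V1F", "V1V2", _ADAPTER_A, "AGAGTTTGATCMTGGCTCAG", "forward"),
    PrimerSpec("B2+V2R", "V1V2", _ADAPTER_B, "CYNACTGCTGCCTCCCGTAG", "reverse"),
    PrimerSpec("A2+1061R", "V6", _ADAPTER_A, "CRRCACGAGCTGACGAC", "forward"),
    PrimerSpec("B2+784F", "V6", _ADAPTER_B, "AGGATTAGATACCCTGGTA", "reverse"),
)

#: The read-orientation (A-adapter) primers used for region splitting.
FORWARD_PRIMERS: tuple[PrimerSpec, ...] = tuple(
    p for p in DEFAULT_PRIMERS if p.orientation == "forward"
)


@dataclass(frozen=True)
class HitRecord:
    """One similarity-search hit of a query read against a reference taxon."""

    query_id: str
    subject_taxon: str
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.bit_score < 0:
            raise InvariantError(f"hit {self.query_id!r}: negative bit score")
        if self.evalue < 0:
            raise InvariantError(f"hit {self.query_id!r}: negative E-value")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, sample: str = "", region: str = "unknown") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, in file order.

    Sequences are uppercased and whitespace-stripped.  Malformed headers,
    empty sequences and duplicate ids raise :class:`FormatError` naming the
    1-based line number.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"line {header_line}: entry {header!r} has an empty sequence")
        records.append(SequenceRecord(id=header, seq=seq, sample=sample, region=region))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"line {lineno}: FASTA header without an id")
                if header in seen:
                    raise FormatError(f"line {lineno}: duplicate sequence id {header!r}")
                seen.add(header)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {lineno}: sequence data before any FASTA header")
                chunks.append(line.replace(" ", "").replace("\t", ""))
        _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST-tabular hit tables

def read_hit_table(
    path: str | Path,
    max_evalue: float = 1e-5,
    top_k: int = 25,
) -> dict[str, list[HitRecord]]:
    """Load a 4+-column BLAST-tabular file into per-query hit lists.

    Columns: query id, subject taxon, bit score, E-value; extra columns
    are ignored.  Hits with ``evalue > max_evalue`` are dropped and at most
    ``top_k`` hits per query are kept, sorted by descending bit score
    (ties by input order).
    """
    by_query: dict[str, list[HitRecord]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"line {lineno}: expected >= 4 tab-separated columns")
            try:
                score = float(cols[2])
                evalue = float(cols[3])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric score or E-value") from exc
            if evalue > max_evalue:
                continue
            by_query.setdefault(cols[0], []).append(
                HitRecord(query_id=cols[0], subject_taxon=cols[1], bit_score=score, evalue=evalue)
            )
    for qid, hits in by_query.items():
        hits.sort(key=lambda h: -h.bit_score)
        del hits[top_k:]
    return by_query


def write_hit_table(hits: Mapping[str, list[HitRecord]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for qid in hits:
            for h in hits[qid]:
                fh.write(f"{h.query_id}\t{h.subject_taxon}\t{h.bit_score:g}\t{h.evalue:g}\n")


# ---------------------------------------------------------------------------
# phylip lower-triangle distance matrix

def write_distance_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a phylip-style lower-triangle matrix (6 decimal places)."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, sid in enumerate(matrix.ids):
            row = "\t".join(f"{matrix.data[i, j]:.6f}" for j in range(i))
            fh.write(sid + ("\t" + row if row else "") + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        first = fh.readline()
        try:
            n = int(first.strip())
        except ValueError as exc:
            raise FormatError("line 1: expected the sequence count") from exc
        ids: list[str] = []
        data = np.zeros((n, n))
        for i in range(n):
            lineno = i + 2
            line = fh.readline()
            if not line:
                raise FormatError(f"line {lineno}: expected {n} rows, file ended early")
            cols = line.rstrip("\n").split("\t")
            if len(cols) != i + 1:
                raise FormatError(f"line {lineno}: expected {i + 1} fields, got {len(cols)}")
            ids.append(cols[0])
            for j, val in enumerate(cols[1:]):
                try:
                    data[i, j] = data[j, i] = float(val)
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: non-numeric distance {val!r}") from exc
    return DistanceMatrix(ids=ids, data=data)


# ---------------------------------------------------------------------------
# taxonomy

RANKS = ("root", "phylum", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxNode:
    id: str
    name: str
    rank: str
    parent: str | None  # None only for the root


class TaxonomyTree:
    """Ranked taxonomy with ranks root > phylum > order > family > genus > species.

    Internal node ids are the semicolon-joined lineage prefix, so shared
    lineage prefixes share nodes; leaf ids are caller-supplied (reference
    accessions).
    """

    ROOT = "root"

    def __init__(self) -> None:
        self.nodes: dict[str, TaxNode] = {
            self.ROOT: TaxNode(self.ROOT, "root", "root", None)
        }

    def add_lineage(self, leaf_id: str, names: list[str]) -> str:
        """Add a ranked lineage ending in leaf ``leaf_id``; returns the leaf id."""
        if not names:
            raise FormatError(f"taxon {leaf_id!r}: empty lineage")
        if len(names) > len(RANKS) - 1:
            raise FormatError(f"taxon {leaf_id!r}: lineage deeper than {len(RANKS) - 1} ranks")
        parent = self.ROOT
        for depth, name in enumerate(names, start=1):
            rank = RANKS[depth]
            node_id = leaf_id if depth == len(names) else ";".join(names[:depth])
            existing = self.nodes.get(node_id)
            if existing is not None:
                if existing.parent != parent or existing.name != name:
                    raise FormatError(
                        f"node {node_id!r}: conflicting parents or names in lineage input"
                    )
            else:
                self.nodes[node_id] = TaxNode(node_id, name, rank, parent)
            parent = node_id
        return parent

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to and including the root."""
        path = []
        cur: str | None = node_id
        seen: set[str] = set()
        while cur is not None:
            if cur in seen:
                raise InvariantError(f"cycle in taxonomy at node {cur!r}")
            seen.add(cur)
            node = self.nodes.get(cur)
            if node is None:
                raise InvariantError(f"unknown taxonomy node {cur!r}")
            path.append(cur)
            cur = node.parent
        if path[-1] != self.ROOT:
            raise InvariantError(f"parent chain of {node_id!r} does not reach the root")
        return path

    def validate(self) -> None:
        rank_level = {r: i for i, r in enumerate(RANKS)}
        for node_id, node in self.nodes.items():
            path = self.path_to_root(node_id)
            levels = [rank_level[self.nodes[p].rank] for p in path]
            if any(levels[i] <= levels[i + 1] for i in range(len(levels) - 1)):
                raise InvariantError(f"ranks not strictly increasing toward {node_id!r}")

    def lca(self, node_ids: Iterable[str]) -> str:
        """Lowest common ancestor of the given nodes (root if disjoint)."""
        paths = [list(reversed(self.path_to_root(n))) for n in set(node_ids)]
        if not paths:
            raise ValueError("lca of an empty set")
        lca = self.ROOT
        for depth in range(min(len(p) for p in paths)):
            step = {p[depth] for p in paths}
            if len(step) != 1:
                break
            lca = step.pop()
        return lca

    def ancestor_at_rank(self, node_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``node_id`` at ``rank``; None if the node
        sits above that rank."""
        for nid in self.path_to_root(node_id):
            if self.nodes[nid].rank == rank:
                return nid
        return None

    def name(self, node_id: str) -> str:
        return self.nodes[node_id].name


def read_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read tab-separated rows of (leaf id, semicolon-delimited lineage)."""
    tree = TaxonomyTree()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"line {lineno}: expected 'id<TAB>lineage'")
            leaf_id = cols[0].strip()
            names = [n.strip() for n in cols[1].split(";") if n.strip()]
            try:
                tree.add_lineage(leaf_id, names)
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# primers, truth tables, OTU lists

def read_primers(path: str | Path) -> list[PrimerSpec]:
    """Read a tab-separated primer table: name, region, adapter, target,
    orientation."""
    primers = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise FormatError(f"line {lineno}: expected 5 tab-separated columns")
            try:
                primers.append(PrimerSpec(cols[0], cols[1], cols[2], cols[3], cols[4]))
            except InvariantError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return primers


def write_primers(primers: Iterable[PrimerSpec], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in primers:
            fh.write(f"{p.name}\t{p.region}\t{p.adapter}\t{p.target}\t{p.orientation}\n")


def write_truth_table(truth: Mapping[str, tuple], path: str | Path) -> None:
    """Write the simulator's truth table: read id, template id,
    contaminant flag, error count."""
    with open(path, "w") as fh:
        fh.write("read_id\ttemplate_id\tis_contaminant\terrors\n")
        for rid, entry in truth.items():
            tid, contam, errors = entry
            fh.write(f"{rid}\t{tid}\t{int(contam)}\t{errors}\n")


def read_truth_table(path: str | Path) -> dict[str, tuple[str, bool, int]]:
    truth: dict[str, tuple[str, bool, int]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise FormatError("line 1: expected the truth-table header")
        for lineno, raw in enumerate(fh, start=2):
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 4:
                raise FormatError(f"line {lineno}: expected 4 columns")
            truth[cols[0]] = (cols[1], bool(int(cols[2])), int(cols[3]))
    return truth


def write_otu_lists(partitions, path: str | Path) -> None:
    """Write OTU membership lists: cutoff, cluster id, comma-joined members."""
    with open(path, "w") as fh:
        fh.write("cutoff\totu\treads\tmembers\n")
        for part in partitions:
            for cl in part.clusters:
                fh.write(
                    f"{part.cutoff:g}\t{cl.id}\t{cl.count}\t{','.join(cl.members)}\n"
                )
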