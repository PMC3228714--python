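"""Pairwise sequence distances from global alignment with free end gaps.

Distances follow the convention used for pyrosequencing amplicon OTU
analysis: a Needleman-Wunsch global alignment is computed with terminal
(end) gaps free, end-gap columns are discounted entirely, and each
*internal* gap column counts as one difference, so

    d(a, b) = (mismatches + internal gap columns) / compared columns

where ``compared columns = alignment length - end-gap columns``.  The
distance is 0 when every aligned column is an end gap (e.g. a proper
prefix against the full sequence).

The dynamic-programming alignment itself is delegated to Biopython's
:class:`Bio.Align.PairwiseAligner`; the column bookkeeping that defines
the distance is done here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from Bio import Align

from .errors import InvariantError

__all__ = [
    "AlignmentResult",
    "DistanceMatrix",
    "align_pair",
    "distance",
    "count_diffs",
    "pairwise_distance_matrix",
]

#: default scoring: match +1, mismatch -1, gap -2 per column, end gaps free
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one semi-global alignment.

    ``compared_cols`` excludes terminal gap runs; ``mismatches`` and
    ``internal_gap_cols`` are counted inside the compared region only.
    """

    aligned_a: str
    aligned_b: str
    score: float
    mismatches: int
    internal_gap_cols: int
    endgap_cols: int
    compared_cols: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise InvariantError("aligned strings differ in length")
        if self.compared_cols != len(self.aligned_a) - self.endgap_cols:
            raise InvariantError("compared_cols inconsistent with endgap_cols")
        if self.mismatches + self.internal_gap_cols > self.compared_cols:
            raise InvariantError("differences exceed compared columns")


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # terminal gaps are free (semi-global alignment)
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _terminal_runs(ra: str, rb: str) -> tuple[int, int]:
    """Lengths of the leading and trailing runs of gap columns."""
    n = len(ra)
    lead = 0
    while lead < n and (ra[lead] == "-" or rb[lead] == "-"):
        lead += 1
    if lead == n:  # degenerate: every column is a gap column
        return n, 0
    trail = 0
    while ra[n - 1 - trail] == "-" or rb[n - 1 - trail] == "-":
        trail += 1
    return lead, trail


def _summarize(ra: str, rb: str, score: float) -> AlignmentResult:
    lead, trail = _terminal_runs(ra, rb)
    n = len(ra)
    mism = 0
    internal = 0
    for i in range(lead, n - trail):
        if ra[i] == "-" or rb[i] == "-":
            internal += 1
        elif ra[i] != rb[i]:
            mism += 1
    return AlignmentResult(
        aligned_a=ra,
        aligned_b=rb,
        score=score,
        mismatches=mism,
        internal_gap_cols=internal,
        endgap_cols=lead + trail,
        compared_cols=n - (lead + trail),
    )


def align_pair(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> AlignmentResult:
    """Optimal global alignment of ``a`` and ``b`` with free end gaps.

    Among co-optimal alignments the aligner's first reported traceback is
    used; it is deterministic for a given pair of inputs.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(match, mismatch, gap).align(a.upper(), b.upper())[0]
    return _summarize(str(aln[0]), str(aln[1]), float(aln.score))


def _hp_adjacent(row: str, col: int) -> bool:
    """True if the base opposite a gap at ``col`` extends a homopolymer.

    ``row`` is the aligned string carrying a base at ``col``; the gap sits
    in the other row.  The indel is homopolymer-associated when the nearest
    non-gap neighbour on either side of ``col`` in ``row`` equals that base,
    i.e. the inserted/deleted base belongs to a run of length >= 2.
    """
    base = row[col]
    i = col - 1
    while i >= 0 and row[i] == "-":
        i -= 1
    if i >= 0 and row[i] == base:
        return True
    j = col + 1
    while j < len(row) and row[j] == "-":
        j += 1
    return j < len(row) and row[j] == base


def count_diffs(
    a: str,
    b: str,
    hp_discount: bool = False,
    gap_mode: str = "columns",
    **scores: float,
) -> float:
    """Number of differences between ``a`` and ``b`` (not normalized).

    Differences are mismatches plus internal gap columns of the optimal
    free-end-gap alignment.  With ``hp_discount`` an internal gap column
    whose base lies in a homopolymer run of length >= 2 counts 0.5, the
    platform's characteristic error mode being indels at such runs.  With
    ``gap_mode='runs'`` each maximal run of internal gap columns counts
    once instead of once per column.
    """
    if gap_mode not in ("columns", "runs"):
        raise ValueError(f"unknown gap_mode: {gap_mode!r}")
    if a == b:
        return 0.0
    res = align_pair(a, b, **scores)
    ra, rb = res.aligned_a, res.aligned_b
    lead, trail = _terminal_runs(ra, rb)
    diffs = float(res.mismatches)
    in_run = False
    for i in range(lead, len(ra) - trail):
        gap_in_a = ra[i] == "-"
        if gap_in_a or rb[i] == "-":
            if gap_mode == "runs":
                if not in_run:
                    diffs += 1.0
                    in_run = True
                continue
            w = 1.0
            if hp_discount and _hp_adjacent(rb if gap_in_a else ra, i):
                w = 0.5
            diffs += w
        else:
            in_run = False
    return diffs


def distance(a: str, b: str, gap_mode: str = "columns", **scores: float) -> float:
    """End-gap-discounted alignment distance in [0, 1].

    The pair is aligned in a canonical order so that
    ``distance(a, b) == distance(b, a)`` exactly even when co-optimal
    alignments with different difference counts exist.
    """
    if a == b:
        return 0.0
    x, y = sorted((a.upper(), b.upper()))
    res = align_pair(x, y, **scores)
    if res.compared_cols == 0:
        return 0.0
    if gap_mode == "columns":
        ndiff = res.mismatches + res.internal_gap_cols
    elif gap_mode == "runs":
        ndiff = count_diffs(x, y, gap_mode="runs", **scores)
    else:
        raise ValueError(f"unknown gap_mode: {gap_mode!r}")
    return ndiff / res.compared_cols


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by sequence id."""

    ids: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise InvariantError(f"matrix shape {self.data.shape} != ({n}, {n})")
        if len(set(self.ids)) != n:
            raise InvariantError("duplicate sequence ids in distance matrix")
        if not np.array_equal(self.data, self.data.T):
            raise InvariantError("distance matrix is not symmetric")
        if np.any(np.diag(self.data) != 0.0):
            raise InvariantError("distance matrix diagonal is not zero")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise InvariantError("distances outside [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.data[self.ids.index(id_a), self.ids.index(id_b)])


def _id_seq_pairs(seqs) -> list[tuple[str, str]]:
    entries = getattr(seqs, "entries", None)
    if entries is not None:
        return [(e.id, e.seq) for e in entries]
    items = list(seqs)
    if items and isinstance(items[0], str):
        return [(str(i), s) for i, s in enumerate(items)]
    return [(str(i), s) for i, s in items]


def pairwise_distance_matrix(
    seqs: Iterable[tuple[str, str]] | Sequence[str],
    gap_mode: str = "columns",
    **scores: float,
) -> DistanceMatrix:
    """All-pairs distance matrix; accepts a DereplicatedSet, (id, seq)
    pairs, or bare sequences (then ids are 0-based indices)."""
    pairs = _id_seq_pairs(seqs)
    if not pairs:
        raise ValueError("need at least one sequence")
    ids = [str(i) for i, _ in pairs]
    if len(set(ids)) != len(ids):
        raise InvariantError("duplicate sequence ids")
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = distance(pairs[i][1], pairs[j][1], gap_mode=gap_mode, **scores)
    return DistanceMatrix(ids=ids, data=d)
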