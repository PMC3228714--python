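"""Preclustering and agglomerative OTU formation.

Preclustering absorbs likely sequencing noise before OTU formation:
less-abundant unique sequences within two differences of a more abundant
one are merged into it (single pass against surviving representatives).

OTUs are then formed by hierarchical agglomerative clustering of the
remaining unique sequences under a pairwise distance matrix.  Average
linkage weights every unique sequence by its read count (equivalent to
clustering the replicated reads), matching how amplicon OTU tools operate
on dereplicated data; complete linkage is used by the contamination
filter at 1% difference.  Merging is deterministic: ties are broken by
the smallest pair of member indices.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import DistanceMatrix
from .errors import InvariantError
from .preprocess import DereplicatedSet, greedy_abundance_merge

__all__ = [
    "Cluster",
    "OTUPartition",
    "precluster",
    "hier_cluster",
    "unique_otus",
    "LINKAGES",
]

LINKAGES = ("single", "complete", "average")


@dataclass
class Cluster:
    id: str
    members: list[str]
    count: int


@dataclass
class OTUPartition:
    """Sequences partitioned into OTUs at a stated distance cutoff."""

    cutoff: float
    clusters: list[Cluster]
    linkage: str

    def __post_init__(self) -> None:
        members = [m for c in self.clusters for m in c.members]
        if len(members) != len(set(members)):
            raise InvariantError("clusters do not partition the sequence ids")

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clusters)

    def abundance_counts(self) -> list[int]:
        """Per-OTU read counts, descending."""
        return sorted((c.count for c in self.clusters), reverse=True)

    def assignment(self) -> dict[str, str]:
        """Sequence id -> OTU id."""
        return {m: c.id for c in self.clusters for m in c.members}


def precluster(dereps: DereplicatedSet, max_diffs: float = 2) -> DereplicatedSet:
    """Huse-style single-linkage preclustering.

    Shorter, less abundant sequences are merged into longer, more
    abundant ones when at most ``max_diffs`` nucleotides differ
    (default 2), comparing each candidate against the surviving seed
    representatives in abundance order.
    """
    return greedy_abundance_merge(dereps, max_diffs=max_diffs, hp_discount=False)


def unique_otus(dereps: DereplicatedSet) -> int:
    """Number of distinct sequences — the cutoff-0 OTU count."""
    return len(dereps)


def _tie_key(mins: np.ndarray, i: int, j: int) -> tuple[int, int]:
    a, b = int(mins[i]), int(mins[j])
    return (a, b) if a <= b else (b, a)


def hier_cluster(
    matrix: DistanceMatrix,
    weights: Sequence[int] | None = None,
    linkage: str = "average",
    cutoffs: Sequence[float] = (0.03,),
    weighted: bool = True,
) -> list[OTUPartition]:
    """Agglomerative clustering emitting a partition per requested cutoff.

    Merge criteria: single = minimum, complete = maximum, average =
    read-count-weighted mean of the inter-cluster pairwise distances
    (``weighted=False`` averages over unique sequences instead).  A
    partition labelled ``c`` contains every merge whose criterion is
    <= ``c``.  Ties in merge order are broken by the lowest pair of
    smallest member indices, making runs deterministic.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    for c in cutoffs:
        if not 0.0 < c < 1.0:
            raise ValueError(f"cutoff {c} outside (0, 1)")
    n = len(matrix.ids)
    if weights is None:
        weights = [1] * n
    if len(weights) != n:
        raise ValueError("weights length does not match the matrix")

    # working state: slot i holds a live cluster or is dead (alive[i]=False)
    d = matrix.data.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    alive = np.ones(n, dtype=bool)
    # linkage weight per slot: read counts for weighted average,
    # unique-sequence counts otherwise
    w = np.array(weights if weighted else [1] * n, dtype=float)
    mins = np.arange(n)  # smallest original member index per slot
    merges: list[tuple[float, int, int]] = []  # (height, slot_i, slot_j)

    dead_mask = np.zeros_like(d, dtype=bool)
    for _ in range(n - 1):
        # criteria are quantized so that semantically tied pairs (equal up
        # to float summation noise) fall to the member-id tie-break
        dd = np.where(dead_mask, np.inf, np.round(d, 10))
        height = dd.min()
        # candidate pairs at the minimum; break ties on smallest member ids
        cand = np.argwhere(dd == height)
        cand = [(int(i), int(j)) for i, j in cand if i < j]
        i, j = min(cand, key=lambda p: _tie_key(mins, *p))
        merges.append((float(height), i, j))
        # Lance-Williams update into slot i
        others = np.flatnonzero(alive)
        others = others[(others != i) & (others != j)]
        if linkage == "single":
            d[i, others] = np.minimum(d[i, others], d[j, others])
        elif linkage == "complete":
            d[i, others] = np.maximum(d[i, others], d[j, others])
        else:  # average
            d[i, others] = (w[i] * d[i, others] + w[j] * d[j, others]) / (w[i] + w[j])
        d[others, i] = d[i, others]
        w[i] += w[j]
        mins[i] = min(mins[i], mins[j])
        alive[j] = False
        dead_mask[j, :] = True
        dead_mask[:, j] = True

    # replay merges up to each cutoff with a union-find over original indices
    read_w = np.asarray(weights)
    partitions = []
    for cutoff in cutoffs:
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for height, i, j in merges:
            if height <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
        groups: dict[int, list[int]] = {}
        for idx in range(n):
            groups.setdefault(find(idx), []).append(idx)
        clusters = sorted(
            groups.values(), key=lambda g: (-int(read_w[g].sum()), min(g))
        )
        width = len(str(len(clusters)))
        partitions.append(
            OTUPartition(
                cutoff=cutoff,
                linkage=linkage,
                clusters=[
                    Cluster(
                        id=f"OTU_{k + 1:0{width}d}",
                        members=[matrix.ids[idx] for idx in g],
                        count=int(read_w[g].sum()),
                    )
                    for k, g in enumerate(clusters)
                ],
            )
        )
    return partitions
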