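"""Lowest-common-ancestor taxonomic assignment from similarity-search hits.

Each dereplicated query's hit list is replicated to every member read (so
abundance is reflected), hits below a bit-score floor are dropped, the
hits within a top-percent window of the best score are retained, and the
read is placed on the lowest taxonomy node that is an ancestor of every
retained hit.  Taxa supported by fewer reads than a minimum-support
threshold are suppressed (their reads become "Not assigned"), and
per-sample tallies are normalized to a common read total for cross-sample
comparison.

A toy alignment-free hit scorer against known template sequences is
bundled so the module is fully testable on synthetic data; real
BLAST-tabular hit files are accepted unchanged through
:func:`uridiv.io_formats.read_hit_table`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .distances import align_pair
from .errors import ConsistencyError
from .io_formats import HitRecord, TaxonomyTree
from .preprocess import DereplicatedSet

logger = logging.getLogger(__name__)

__all__ = [
    "NOT_ASSIGNED",
    "NO_HITS",
    "AssignmentResult",
    "replicate_hits",
    "lca_assign",
    "apply_min_support",
    "normalize_and_summarize",
    "summarize_at_rank",
    "toy_hit_table",
]

NOT_ASSIGNED = "Not assigned"
NO_HITS = "No hits"
_BUCKETS = (NOT_ASSIGNED, NO_HITS)


@dataclass
class AssignmentResult:
    """Read-to-taxonomy-node mapping, including the two special buckets."""

    assignments: dict[str, str]  # read id -> node id, NOT_ASSIGNED or NO_HITS
    tree: TaxonomyTree = field(repr=False)

    @property
    def total_reads(self) -> int:
        return len(self.assignments)

    def bucket_count(self, bucket: str) -> int:
        return sum(1 for v in self.assignments.values() if v == bucket)

    def node_tallies(self) -> dict[str, int]:
        """Reads per assigned node (exact node, no roll-up), buckets included."""
        tally: dict[str, int] = {}
        for node in self.assignments.values():
            tally[node] = tally.get(node, 0) + 1
        return tally

    def rank_tallies(self, rank: str) -> dict[str, int]:
        """Reads per node at ``rank``, rolling species-level (etc.)
        assignments up; reads assigned above ``rank`` are excluded."""
        tally: dict[str, int] = {}
        for node in self.assignments.values():
            if node in _BUCKETS:
                continue
            anc = self.tree.ancestor_at_rank(node, rank)
            if anc is not None:
                tally[anc] = tally.get(anc, 0) + 1
        return tally


def replicate_hits(
    hits: Mapping[str, list[HitRecord]],
    dereps: DereplicatedSet,
) -> dict[str, list[HitRecord]]:
    """Copy each representative's hit list to every member read.

    Every query id in ``hits`` must be a representative id in ``dereps``;
    representatives without hits yield member reads with empty hit lists
    (they land in the "No hits" bucket downstream).
    """
    rep_ids = {e.id for e in dereps.entries}
    unknown = set(hits) - rep_ids
    if unknown:
        raise ConsistencyError(
            f"hit queries without a dereplicated entry: {sorted(unknown)[:5]}"
        )
    per_read: dict[str, list[HitRecord]] = {}
    for entry in dereps.entries:
        entry_hits = hits.get(entry.id, [])
        for rid in entry.members:
            per_read[rid] = list(entry_hits)
    return per_read


def lca_assign(
    read_hits: Mapping[str, list[HitRecord]],
    tree: TaxonomyTree,
    min_score: float = 100.0,
    top_percent: float = 0.10,
) -> AssignmentResult:
    """Assign each read to the LCA of its accepted hits.

    Hits with bit score below ``min_score`` are dropped; of the remainder,
    hits within ``top_percent`` of the best score (score >= (1 -
    top_percent) x best) are retained and the read is placed on their
    lowest common ancestor.  Reads with no surviving hits go to the
    "No hits" bucket.
    """
    if not 0.0 <= top_percent <= 1.0:
        raise ValueError("top_percent must be a fraction in [0, 1]")
    assignments: dict[str, str] = {}
    for rid, hits in read_hits.items():
        strong = [h for h in hits if h.bit_score >= min_score]
        if not strong:
            assignments[rid] = NO_HITS
            continue
        best = max(h.bit_score for h in strong)
        window = [h for h in strong if h.bit_score >= (1.0 - top_percent) * best]
        taxa = {h.subject_taxon for h in window}
        missing = [t for t in taxa if t not in tree.nodes]
        if missing:
            raise ConsistencyError(f"hits name unknown taxa: {sorted(missing)[:5]}")
        assignments[rid] = tree.lca(taxa)
    return AssignmentResult(assignments=assignments, tree=tree)


def apply_min_support(result: AssignmentResult, min_support: int = 5) -> AssignmentResult:
    """Suppress weakly supported taxa.

    Nodes whose assigned-read tally is below ``min_support`` (default 5;
    a node with exactly ``min_support`` reads is reported) have those
    reads moved to the "Not assigned" bucket.  Applied once over the
    final node tallies.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    tallies = result.node_tallies()
    weak = {
        node for node, n in tallies.items()
        if node not in _BUCKETS and n < min_support
    }
    new = {
        rid: (NOT_ASSIGNED if node in weak else node)
        for rid, node in result.assignments.items()
    }
    return AssignmentResult(assignments=new, tree=result.tree)


def summarize_at_rank(
    results: Mapping[str, AssignmentResult],
    rank: str,
    target: int = 100_000,
) -> pd.DataFrame:
    """Rank-by-sample table of normalized read tallies.

    Each sample's tallies at ``rank`` are scaled by ``target`` / (total
    reads in the sample), so samples of unequal depth are comparable.
    Rows are taxon names at the rank, columns are samples.
    """
    if target <= 0:
        raise ValueError("normalization target must be positive")
    data = {}
    for sample, result in results.items():
        scale = target / result.total_reads if result.total_reads else 0.0
        tallies = result.rank_tallies(rank)
        data[sample] = {
            result.tree.name(node): n * scale for node, n in tallies.items()
        }
    table = pd.DataFrame(data).fillna(0.0)
    return table.sort_index()


def normalize_and_summarize(
    results: Mapping[str, AssignmentResult],
    target: int = 100_000,
    ranks: Sequence[str] = ("phylum", "order", "genus"),
) -> dict[str, pd.DataFrame]:
    """Normalized rank summaries plus per-sample distinct-taxon counts.

    Returns one taxon-by-sample DataFrame per requested rank and a
    ``counts`` DataFrame with the number of distinct phyla and genera
    observed per sample (on the un-normalized tallies).
    """
    out = {rank: summarize_at_rank(results, rank, target) for rank in ranks}
    counts = pd.DataFrame(
        {
            sample: {
                f"{rank}_count": len(result.rank_tallies(rank))
                for rank in ("phylum", "genus")
            }
            for sample, result in results.items()
        }
    )
    out["counts"] = counts
    return out


def toy_hit_table(
    dereps: DereplicatedSet,
    templates: Sequence[tuple[str, str, str]],
    max_hits: int = 25,
) -> dict[str, list[HitRecord]]:
    """Score representatives against known templates with a toy scorer.

    ``templates`` are (template id, sequence, taxonomy node id) triples.
    The score is alignment-based: matches - 4 x differences over the
    free-end-gap alignment, so a read from its own template scores near
    its length while templates a few percent divergent fall outside a 10%
    top-score window.  Not a BLAST substitute for real data; a harness
    for exercising the LCA machinery on synthetic communities.
    """
    hits: dict[str, list[HitRecord]] = {}
    for entry in dereps.entries:
        rows = []
        for _tid, tseq, node_id in templates:
            res = align_pair(entry.seq, tseq)
            ndiff = res.mismatches + res.internal_gap_cols
            score = float(res.compared_cols - ndiff) - 4.0 * ndiff
            if score <= 0:
                continue
            rows.append(
                HitRecord(
                    query_id=entry.id,
                    subject_taxon=node_id,
                    bit_score=score,
                    evalue=1e-30,
                )
            )
        rows.sort(key=lambda h: -h.bit_score)
        hits[entry.id] = rows[:max_hits]
    return hits
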