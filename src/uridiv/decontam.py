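"""Negative-control contamination filtering.

Low-biomass specimens (urine approaches reagent-only biomass) pick up
reagent and environment DNA, so a negative extraction control is
sequenced alongside each sample.  The filter clusters sample and control
sequences *jointly* with complete linkage at 1% genetic difference, after
weighting the control reads so both sides contribute the same total read
mass; any sample sequence in a cluster where 50% or more of that mass is
control-derived is removed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .clustering import hier_cluster
from .distances import pairwise_distance_matrix
from .errors import InvariantError
from .preprocess import DerepEntry, DereplicatedSet

logger = logging.getLogger(__name__)

__all__ = [
    "PoolEntry",
    "LabeledPool",
    "RemovalRecord",
    "weight_controls",
    "filter_contaminants",
]


@dataclass
class PoolEntry:
    id: str
    seq: str
    count: int
    source: str  # "sample" | "control"
    weight: float
    members: list[str] | None = None  # read ids, carried through for sample entries

    def __post_init__(self) -> None:
        if self.source not in ("sample", "control"):
            raise InvariantError(f"entry {self.id!r}: bad source {self.source!r}")
        if self.weight <= 0:
            raise InvariantError(f"entry {self.id!r}: weight must be positive")


@dataclass
class LabeledPool:
    """Sample and control sequences pooled for joint clustering, with
    control weights scaled to equal total representation."""

    entries: list[PoolEntry]

    def __post_init__(self) -> None:
        sample_w = sum(e.weight for e in self.entries if e.source == "sample")
        control_w = sum(e.weight for e in self.entries if e.source == "control")
        if control_w and abs(sample_w - control_w) > 1e-6 * max(sample_w, 1.0):
            raise InvariantError(
                f"equal-representation violated: sample {sample_w} vs control {control_w}"
            )

    def uid(self, entry: PoolEntry) -> str:
        return f"{entry.source}:{entry.id}"


@dataclass
class RemovalRecord:
    id: str
    cluster_id: str
    control_fraction: float


def weight_controls(sample: DereplicatedSet, control: DereplicatedSet) -> LabeledPool:
    """Pool sample and control entries, weighting controls so the same
    number of (weighted) reads stems from each side.

    Sample entries keep weight = read count; control entries get read
    count x (total sample reads / total control reads).
    """
    if control.total_reads < 1:
        raise ValueError("empty control: nothing to weight (filter should be skipped)")
    if sample.total_reads < 1:
        raise ValueError("empty sample")
    multiplier = sample.total_reads / control.total_reads
    entries = [
        PoolEntry(e.id, e.seq, e.count, "sample", float(e.count), list(e.members))
        for e in sample.entries
    ] + [
        PoolEntry(e.id, e.seq, e.count, "control", e.count * multiplier)
        for e in control.entries
    ]
    logger.info(
        "weight_controls: %d sample reads, %d control reads, multiplier %.4f",
        sample.total_reads, control.total_reads, multiplier,
    )
    return LabeledPool(entries=entries)


def filter_contaminants(
    pool: LabeledPool,
    cutoff: float = 0.01,
    threshold: float = 0.50,
    count_mode: str = "weights",
) -> tuple[DereplicatedSet, list[RemovalRecord]]:
    """Remove sample sequences co-clustering with the negative control.

    All pool sequences are clustered with complete linkage at ``cutoff``
    (default 1% difference).  Per cluster the control fraction is the
    control share of the summed weights (or of entry counts with
    ``count_mode='entries'``); sample entries in clusters with fraction
    >= ``threshold`` (default 50%, boundary inclusive) are removed.
    """
    if count_mode not in ("weights", "entries"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    by_uid = {pool.uid(e): e for e in pool.entries}
    # joint complete-linkage clustering; identical sequences may occur on
    # both sides, so entries are keyed by a source-qualified uid
    matrix = pairwise_distance_matrix([(uid, e.seq) for uid, e in by_uid.items()])
    (partition,) = hier_cluster(matrix, linkage="complete", cutoffs=(cutoff,))

    removed: list[RemovalRecord] = []
    kept_ids: set[str] = set()
    for cl in partition.clusters:
        entries = [by_uid[m] for m in cl.members]
        if count_mode == "weights":
            total = sum(e.weight for e in entries)
            control = sum(e.weight for e in entries if e.source == "control")
        else:
            total = len(entries)
            control = sum(1 for e in entries if e.source == "control")
        frac = control / total if total else 0.0
        for e in entries:
            if e.source != "sample":
                continue
            if frac >= threshold:
                removed.append(RemovalRecord(e.id, cl.id, frac))
            else:
                kept_ids.add(e.id)

    kept_entries = [
        DerepEntry(e.id, e.seq, e.count, list(e.members) if e.members else [])
        for e in _sample_entries_in_order(pool)
        if e.id in kept_ids
    ]
    logger.info(
        "filter_contaminants: %d sample entries in, %d kept, %d removed",
        sum(1 for e in pool.entries if e.source == "sample"),
        len(kept_entries), len(removed),
    )
    region = getattr(pool, "region", "unknown")
    return DereplicatedSet(entries=kept_entries, region=region), removed


def _sample_entries_in_order(pool: LabeledPool):
    for e in pool.entries:
        if e.source == "sample":
            yield e
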