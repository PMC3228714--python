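"""End-to-end orchestration: per-sample stage composition and
cross-sample comparison.

Stages run in the study's order: primer split -> trim/length filter ->
dereplicate -> denoise -> negative-control decontamination -> precluster
-> pairwise distances -> hierarchical OTUs -> diversity estimates ->
LCA taxonomy.  Every stage's input/output read counts are logged and the
per-sample/region summary mirrors the study's sampling-depth and
diversity table.
"""
from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from . import clustering, decontam, diversity, preprocess, taxonomy
from .distances import pairwise_distance_matrix
from .errors import UridivError
from .io_formats import PrimerSpec, SequenceRecord, TaxonomyTree
from .preprocess import DEFAULT_MIN_LEN, DereplicatedSet, PipelineCounters

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "SampleSummary",
    "RegionResult",
    "StageError",
    "run_sample",
    "compare_samples",
    "write_sample_summaries",
]


class StageError(UridivError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    try:
        yield
    except UridivError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise StageError(name, exc) from exc


@dataclass
class PipelineParams:
    """Tunable thresholds; the defaults are the study's stated values."""

    min_len: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MIN_LEN))
    denoise_max_diffs: float = 3.0
    hp_discount: bool = True
    precluster_max_diffs: float = 2.0
    otu_cutoffs: tuple[float, ...] = (0.03, 0.06)
    diversity_cutoff: float = 0.03
    linkage: str = "average"
    weighted_average: bool = True
    decontam_cutoff: float = 0.01
    decontam_threshold: float = 0.50
    min_score: float = 100.0
    top_percent: float = 0.10
    min_support: int = 5
    normalize_target: int = 100_000
    shannon_reps: int = 100
    shannon_size: int | None = None  # None: subsample at full depth

    def __post_init__(self) -> None:
        if self.diversity_cutoff not in self.otu_cutoffs:
            self.otu_cutoffs = tuple(sorted({*self.otu_cutoffs, self.diversity_cutoff}))


@dataclass
class SampleSummary:
    """One sample x region row of the sampling-depth/diversity report."""

    sample: str
    region: str
    total_reads: int
    after_length_cutoff: int
    denoised: int
    cleaned: int
    unique_otus: int
    otus: dict[float, int]
    phyla: int | None
    genera: int | None
    chao1: float
    chao1_lci95: float
    chao1_hci95: float
    shannon: float
    normalized_shannon: float

    def __post_init__(self) -> None:
        counts = [self.total_reads, self.after_length_cutoff, self.denoised, self.cleaned]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise UridivError(f"summary counters increase along the pipeline: {counts}")
        cutoffs = sorted(self.otus)
        otu_counts = [self.otus[c] for c in cutoffs]
        if any(a < b for a, b in zip(otu_counts, otu_counts[1:])):
            raise UridivError("OTU counts must be non-increasing in the cutoff")
        if not self.chao1_lci95 <= self.chao1 <= self.chao1_hci95:
            raise UridivError("Chao1 CI does not bracket the estimate")


@dataclass
class RegionResult:
    summary: SampleSummary
    counters: PipelineCounters
    cleaned: DereplicatedSet
    partitions: list[clustering.OTUPartition]
    read_labels: dict[str, str]
    assignment: taxonomy.AssignmentResult | None
    removal_report: list[decontam.RemovalRecord]


def _log_counts(stage: str, n_in: int, n_out: int) -> None:
    logger.info("stage=%s reads_in=%d reads_out=%d", stage, n_in, n_out)


def run_sample(
    sample_id: str,
    reads: list[SequenceRecord],
    control_reads: list[SequenceRecord],
    primers: Sequence[PrimerSpec],
    params: PipelineParams | None = None,
    seed: int = 0,
    tree: TaxonomyTree | None = None,
    hits_for: Callable[[DereplicatedSet], Mapping] | None = None,
) -> dict[str, RegionResult]:
    """Run the full pipeline for one sample (and its control), per region.

    ``hits_for`` maps a dereplicated set to per-representative hit lists
    (e.g. a loaded BLAST table or :func:`uridiv.taxonomy.toy_hit_table`);
    taxonomy is skipped when ``tree`` or ``hits_for`` is missing.
    """
    params = params or PipelineParams()
    forward = [p for p in primers if p.orientation == "forward"]
    with _stage("split"):
        by_region = preprocess.split_by_primer(reads, forward)
        control_by_region = preprocess.split_by_primer(control_reads, forward) \
            if control_reads else {p.region: [] for p in forward}

    results: dict[str, RegionResult] = {}
    for primer in forward:
        region = primer.region
        region_reads = by_region.get(region, [])
        if not region_reads:
            logger.warning("sample %s: no reads for region %s", sample_id, region)
            continue
        results[region] = _run_region(
            sample_id, region_reads, control_by_region.get(region, []),
            primer, params, seed, tree, hits_for,
        )
    return results


def _run_region(
    sample_id: str,
    region_reads: list[SequenceRecord],
    region_control: list[SequenceRecord],
    primer: PrimerSpec,
    params: PipelineParams,
    seed: int,
    tree: TaxonomyTree | None,
    hits_for: Callable | None,
) -> RegionResult:
    region = primer.region
    min_len = params.min_len.get(region)

    with _stage("trim_and_filter"):
        trimmed = preprocess.trim_and_filter(region_reads, primer, min_len)
        control_trimmed = preprocess.trim_and_filter(region_control, primer, min_len)
    _log_counts("trim_and_filter", len(region_reads), len(trimmed))

    with _stage("dereplicate"):
        dereps = preprocess.dereplicate(trimmed, region=region)
        control_dereps = preprocess.dereplicate(control_trimmed, region=region)

    with _stage("denoise"):
        denoised = preprocess.denoise(
            dereps, max_diffs=params.denoise_max_diffs, hp_discount=params.hp_discount
        )
        control_denoised = preprocess.denoise(
            control_dereps,
            max_diffs=params.denoise_max_diffs,
            hp_discount=params.hp_discount,
        ) if len(control_dereps) else control_dereps
    _log_counts("denoise", dereps.total_reads, denoised.total_reads)

    removal_report: list[decontam.RemovalRecord] = []
    if control_denoised.total_reads:
        with _stage("decontam"):
            pool = decontam.weight_controls(denoised, control_denoised)
            cleaned, removal_report = decontam.filter_contaminants(
                pool,
                cutoff=params.decontam_cutoff,
                threshold=params.decontam_threshold,
            )
            cleaned.region = region
    else:
        logger.warning(
            "sample %s region %s: empty control, decontamination skipped",
            sample_id, region,
        )
        cleaned = denoised
    _log_counts("decontam", denoised.total_reads, cleaned.total_reads)

    counters = PipelineCounters(
        total_reads=len(region_reads),
        after_split=len(region_reads),
        after_length_cutoff=len(trimmed),
        after_denoise=denoised.total_reads,
        after_decontam=cleaned.total_reads,
    )

    with _stage("precluster"):
        preclustered = clustering.precluster(cleaned, max_diffs=params.precluster_max_diffs)

    with _stage("distances"):
        matrix = pairwise_distance_matrix(preclustered)

    with _stage("cluster"):
        partitions = clustering.hier_cluster(
            matrix,
            weights=[e.count for e in preclustered.entries],
            linkage=params.linkage,
            cutoffs=params.otu_cutoffs,
            weighted=params.weighted_average,
        )

    with _stage("diversity"):
        div_partition = next(
            p for p in partitions if p.cutoff == params.diversity_cutoff
        )
        vector = diversity.AbundanceVector(div_partition.abundance_counts())
        chao = diversity.chao1(vector)
        h = diversity.shannon(vector)
        entry_otu = div_partition.assignment()
        read_labels = {
            rid: entry_otu[e.id]
            for e in preclustered.entries
            for rid in e.members
        }
        labels = list(read_labels.values())
        size = params.shannon_size or len(labels)
        h_norm = diversity.normalized_shannon(
            labels, size=min(size, len(labels)), reps=params.shannon_reps, seed=seed
        )

    assignment = None
    phyla = genera = None
    if tree is not None and hits_for is not None:
        with _stage("taxonomy"):
            hits = hits_for(cleaned)
            per_read = taxonomy.replicate_hits(hits, cleaned)
            assignment = taxonomy.lca_assign(
                per_read, tree,
                min_score=params.min_score,
                top_percent=params.top_percent,
            )
            assignment = taxonomy.apply_min_support(assignment, params.min_support)
            phyla = len(assignment.rank_tallies("phylum"))
            genera = len(assignment.rank_tallies("genus"))

    summary = SampleSummary(
        sample=sample_id,
        region=region,
        total_reads=counters.after_split,
        after_length_cutoff=counters.after_length_cutoff,
        denoised=counters.after_denoise,
        cleaned=counters.after_decontam,
        unique_otus=clustering.unique_otus(cleaned),
        otus={p.cutoff: p.n_otus for p in partitions},
        phyla=phyla,
        genera=genera,
        chao1=chao.estimate,
        chao1_lci95=chao.lci95,
        chao1_hci95=chao.hci95,
        shannon=h,
        normalized_shannon=h_norm,
    )
    return RegionResult(
        summary=summary,
        counters=counters,
        cleaned=cleaned,
        partitions=partitions,
        read_labels=read_labels,
        assignment=assignment,
        removal_report=removal_report,
    )


def compare_samples(
    assignments: Mapping[str, taxonomy.AssignmentResult],
    target: int = 100_000,
    dominance: float = 0.75,
) -> dict:
    """Cross-sample genus comparison on normalized tallies.

    Returns the genus-by-sample normalized matrix, per-genus prevalence
    (in how many samples each genus occurs) and a per-sample flag marking
    a dominant genus (>= ``dominance`` share of genus-level reads).
    """
    if len(assignments) < 2:
        raise ValueError("need at least two samples to compare")
    table = taxonomy.summarize_at_rank(assignments, "genus", target)
    prevalence = (table > 0).sum(axis=1).to_dict()
    dominant = {}
    for sample in table.columns:
        col = table[sample]
        total = col.sum()
        dominant[sample] = bool(total > 0 and col.max() / total >= dominance)
    return {"genus_table": table, "prevalence": prevalence, "dominant": dominant}


_ROW_LABELS = {
    "total_reads": "Total reads",
    "after_length_cutoff": "Lengthcutoff",
    "denoised": "Denoised",
    "cleaned": "Cleaned",
    "unique_otus": "Unique OTUs",
    "phyla": "Phyla",
    "genera": "Genera",
    "chao1": "Chao1 (3%)",
    "chao1_lci95": "Chao1 LCI95",
    "chao1_hci95": "Chao1 HCI95",
    "shannon": "Shannon index (3%)",
    "normalized_shannon": "Normalized Shannon index (3%)",
}


def summaries_frame(summaries: Sequence[SampleSummary]) -> pd.DataFrame:
    """Summaries as a row-labelled table, one column per sample x region."""
    cols = {}
    for s in summaries:
        col = {label: getattr(s, attr) for attr, label in _ROW_LABELS.items()}
        for cutoff, count in sorted(s.otus.items()):
            col[f"OTUs {round(cutoff * 100):d}%"] = count
        cols[f"{s.sample}_{s.region}"] = col
    frame = pd.DataFrame(cols)
    order = [l for l in _ROW_LABELS.values()]
    otu_rows = sorted(set(frame.index) - set(order))
    idx = order[:5] + otu_rows + order[5:]
    return frame.loc[[r for r in idx if r in frame.index]]


def write_sample_summaries(summaries: Sequence[SampleSummary], path: str | Path) -> None:
    summaries_frame(summaries).to_csv(path, sep="\t", float_format="%.4f")
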