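"""Read preprocessing: primer splitting, trimming, length filtering,
dereplication and abundance-aware denoising.

The denoiser is a sequence-space stand-in for flowgram denoising: unique
sequences are ranked by abundance and each is greedily absorbed into the
first more-abundant entry within a small number of differences, with
homopolymer-associated indels — the platform's characteristic error —
discounted by half.  It reproduces the *effect* of flowgram denoising
(near-lossless read counts, error reads folded into their source
template) without modelling flowgram likelihoods.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .distances import count_diffs
from .errors import ConfigurationError, InvariantError
from .io_formats import IUPAC, PrimerSpec, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DerepEntry",
    "DereplicatedSet",
    "PipelineCounters",
    "DEFAULT_MIN_LEN",
    "split_by_primer",
    "trim_and_filter",
    "dereplicate",
    "denoise",
    "greedy_abundance_merge",
]

#: minimum post-trim read length retained, per amplicon region
DEFAULT_MIN_LEN = {"V1V2": 218, "V6": 235}


@dataclass
class DerepEntry:
    """One unique sequence with its read count and member read ids."""

    id: str
    seq: str
    count: int
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise InvariantError(f"entry {self.id!r}: count must be >= 1")
        if not self.members:
            # synthesize member ids when the caller only has counts
            self.members = (
                [self.id] if self.count == 1
                else [f"{self.id}.{k}" for k in range(self.count)]
            )
        if len(self.members) != self.count:
            raise InvariantError(f"entry {self.id!r}: member list does not match count")


@dataclass
class DereplicatedSet:
    """Unique sequences with read counts; the working unit of all
    abundance-aware downstream stages."""

    entries: list[DerepEntry]
    region: str = "unknown"

    def __post_init__(self) -> None:
        seqs = [e.seq for e in self.entries]
        if len(set(seqs)) != len(seqs):
            raise InvariantError("dereplicated sequences are not pairwise distinct")
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise InvariantError("duplicate representative ids")

    @property
    def total_reads(self) -> int:
        return sum(e.count for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PipelineCounters:
    """Per-stage read counts; must be non-increasing stage to stage."""

    total_reads: int
    after_split: int
    after_length_cutoff: int
    after_denoise: int
    after_decontam: int

    def __post_init__(self) -> None:
        seq = (
            self.total_reads,
            self.after_split,
            self.after_length_cutoff,
            self.after_denoise,
            self.after_decontam,
        )
        if any(c < 0 for c in seq):
            raise InvariantError("negative stage counter")
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise InvariantError(f"stage counters must be non-increasing: {seq}")


# ---------------------------------------------------------------------------
# primer splitting and trimming

def _iupac_prefix_match(primer_seq: str, read_seq: str) -> bool:
    """True when the read begins with the primer, ambiguity codes in the
    *primer* matching their base sets (one-directional)."""
    if len(read_seq) < len(primer_seq):
        return False
    return all(read_seq[i] in IUPAC[p] for i, p in enumerate(primer_seq))


def _primers_prefix_disjoint(a: PrimerSpec, b: PrimerSpec) -> bool:
    """True if no read could begin with both composite primers."""
    n = min(len(a.composite), len(b.composite))
    return any(
        not (IUPAC[a.composite[i]] & IUPAC[b.composite[i]]) for i in range(n)
    )


def split_by_primer(
    reads: list[SequenceRecord], primers: list[PrimerSpec]
) -> dict[str, list[SequenceRecord]]:
    """Assign reads to amplicon regions by exact 5' primer match.

    A read belongs to a region iff it begins with that region's composite
    primer (adapter + target), IUPAC codes in the primer matching their
    base sets.  Non-matching reads are discarded (and counted in the log).
    Primers must be prefix-disjoint so no read can match two regions.
    """
    if not primers:
        raise ConfigurationError("need at least one primer")
    for i, p in enumerate(primers):
        for q in primers[i + 1 :]:
            if not _primers_prefix_disjoint(p, q):
                raise ConfigurationError(
                    f"primers {p.name!r} and {q.name!r} are not prefix-disjoint"
                )
    by_region: dict[str, list[SequenceRecord]] = {p.region: [] for p in primers}
    discarded = 0
    for read in reads:
        for p in primers:
            if _iupac_prefix_match(p.composite, read.seq):
                by_region[p.region].append(replace(read, region=p.region))
                break
        else:
            discarded += 1
    logger.info(
        "split_by_primer: %d reads in, %s assigned, %d discarded (no exact primer match)",
        len(reads),
        {r: len(v) for r, v in by_region.items()},
        discarded,
    )
    return by_region


def trim_and_filter(
    reads: list[SequenceRecord],
    primer: PrimerSpec,
    min_len: int | None = None,
) -> list[SequenceRecord]:
    """Strip the composite primer prefix and drop short reads.

    The length cutoff is inclusive (trimmed length >= ``min_len`` kept) and
    defaults to 218 nt for V1V2 and 235 nt for V6, applied *after* primer
    trimming.
    """
    if min_len is None:
        min_len = DEFAULT_MIN_LEN.get(primer.region)
        if min_len is None:
            raise ConfigurationError(
                f"no default length cutoff for region {primer.region!r}"
            )
    k = len(primer.composite)
    kept = []
    dropped = 0
    for read in reads:
        trimmed = read.seq[k:]
        if len(trimmed) >= min_len:
            kept.append(replace(read, seq=trimmed))
        else:
            dropped += 1
    logger.info(
        "trim_and_filter[%s]: %d in, %d kept, %d below %d nt",
        primer.region, len(reads), len(kept), dropped, min_len,
    )
    return kept


# ---------------------------------------------------------------------------
# dereplication and denoising

def dereplicate(reads: list[SequenceRecord], region: str = "unknown") -> DereplicatedSet:
    """Collapse identical sequences; the representative id is the first
    occurrence's id and read counts are conserved."""
    by_seq: dict[str, DerepEntry] = {}
    for read in reads:
        entry = by_seq.get(read.seq)
        if entry is None:
            by_seq[read.seq] = DerepEntry(id=read.id, seq=read.seq, count=1, members=[read.id])
        else:
            entry.count += 1
            entry.members.append(read.id)
    if reads and region == "unknown":
        region = reads[0].region
    return DereplicatedSet(entries=list(by_seq.values()), region=region)


def _abundance_order(e: DerepEntry) -> tuple:
    # count desc, length desc, sequence lexicographic: the deterministic
    # ranking used by every greedy merge stage
    return (-e.count, -len(e.seq), e.seq)


def greedy_abundance_merge(
    dereps: DereplicatedSet,
    max_diffs: float,
    hp_discount: bool = False,
) -> DereplicatedSet:
    """Single-pass abundance-ranked merging of near-identical sequences.

    Entries are sorted by (count desc, length desc, sequence); each entry
    is absorbed into the first earlier *surviving* entry within
    ``max_diffs`` differences, counted on the representative sequences
    (mismatches + internal gap columns; homopolymer-adjacent indels count
    half when ``hp_discount`` is set).  Counts and members accumulate to
    the absorbing entry.
    """
    if max_diffs < 0:
        raise ValueError("max_diffs must be >= 0")
    ranked = sorted(dereps.entries, key=_abundance_order)
    survivors: list[DerepEntry] = []
    for entry in ranked:
        target = None
        for seed in survivors:
            if count_diffs(seed.seq, entry.seq, hp_discount=hp_discount) <= max_diffs:
                target = seed
                break
        if target is None:
            survivors.append(
                DerepEntry(entry.id, entry.seq, entry.count, list(entry.members))
            )
        else:
            target.count += entry.count
            target.members.extend(entry.members)
    # canonical output order reflects the post-merge abundances
    survivors.sort(key=_abundance_order)
    return DereplicatedSet(entries=survivors, region=dereps.region)


def denoise(
    dereps: DereplicatedSet,
    max_diffs: float = 3,
    hp_discount: bool = True,
) -> DereplicatedSet:
    """Abundance-aware denoising of unique sequences.

    Greedy merge with a wider radius than preclustering (default 3
    differences) and the homopolymer discount on, so that single
    homopolymer indel errors (0.5 each) and occasional substitutions fold
    back into the template they came from.  Idempotent: surviving entries
    are pairwise more than ``max_diffs`` apart.
    """
    out = greedy_abundance_merge(dereps, max_diffs=max_diffs, hp_discount=hp_discount)
    logger.info(
        "denoise: %d unique in, %d out (%d reads conserved)",
        len(dereps), len(out), out.total_reads,
    )
    return out
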