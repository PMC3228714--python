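"""Synthetic pyrosequencing-style amplicon reads with known ground truth.

The generator emulates the features of the study system that the pipeline
must handle: multi-template communities with geometrically skewed
abundances (one dominant member, as in most urine specimens), two
amplicon regions with distinct composite primers and length ranges,
per-base substitution errors plus the platform's characteristic
insertion/deletion errors at homopolymer runs, and reagent contamination
shared between a sample and its negative extraction control.

Every operation draws from a named, seed-derived random stream, so a
single integer seed fixes every emitted byte and streams for different
samples do not perturb each other.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .distances import distance
from .errors import GenerationError, InvariantError
from .io_formats import IUPAC, PrimerSpec, SequenceRecord, TaxonomyTree

__all__ = [
    "CommunityModel",
    "ErrorModel",
    "TruthEntry",
    "SimulationTruth",
    "stream",
    "generate_templates",
    "sample_abundances",
    "generate_reads",
    "spike_contamination",
    "toy_taxonomy",
]

_BASES = ("A", "C", "G", "T")


def stream(seed: int, *names: str | int) -> np.random.Generator:
    """A named random stream derived from one integer seed.

    Streams for distinct name tuples are statistically independent, so
    e.g. adding reads to one sample never perturbs another sample's reads.
    """
    keys = [
        zlib.crc32(str(n).encode()) & 0x7FFFFFFF if isinstance(n, str) else int(n)
        for n in names
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


@dataclass(frozen=True)
class ErrorModel:
    """Sequencing error rates: per-base substitutions and per-run
    homopolymer indels of up to ``max_indel`` bases."""

    sub_rate: float = 0.0
    hp_indel_rate: float = 0.0
    max_indel: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.sub_rate <= 1.0 and 0.0 <= self.hp_indel_rate <= 1.0):
            raise InvariantError("error rates must lie in [0, 1]")
        if self.max_indel < 1:
            raise InvariantError("max_indel must be >= 1")


@dataclass(frozen=True)
class CommunityModel:
    """A template community: (template id, sequence, taxonomy node id)
    triples with a probability vector of relative abundances."""

    templates: tuple[tuple[str, str, str], ...]
    abundances: tuple[float, ...]
    region: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.templates) != len(self.abundances):
            raise InvariantError("one abundance per template required")
        if abs(sum(self.abundances) - 1.0) > 1e-9:
            raise InvariantError("abundances must sum to 1")
        seqs = [t[1] for t in self.templates]
        if len(set(seqs)) != len(seqs):
            raise InvariantError("template sequences must be pairwise distinct")


@dataclass(frozen=True)
class TruthEntry:
    template_id: str
    is_contaminant: bool
    errors: int


@dataclass
class SimulationTruth:
    """Read id -> origin template, contaminant flag and error count."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def add(self, read_id: str, entry: TruthEntry) -> None:
        if read_id in self.entries:
            raise InvariantError(f"duplicate truth entry for read {read_id!r}")
        self.entries[read_id] = entry

    def update(self, other: "SimulationTruth") -> None:
        for rid, e in other.entries.items():
            self.add(rid, e)

    def as_rows(self) -> dict[str, tuple[str, bool, int]]:
        return {
            rid: (e.template_id, e.is_contaminant, e.errors)
            for rid, e in self.entries.items()
        }


def generate_templates(
    n: int,
    length: int,
    min_divergence: float,
    seed: int,
    max_attempts_per_template: int = 60,
) -> list[str]:
    """Homologous template sequences with all pairwise distances >=
    ``min_divergence``.

    Templates model amplicons of one 16S region across community members:
    variants of a single random ancestor, each carrying substitutions at a
    random ``min_divergence`` fraction of sites (two such variants differ
    at close to twice that fraction).  Every accepted template is verified
    against all previous ones with the pipeline's own alignment distance;
    unrelated (non-homologous) sequences would not work here because the
    free-end-gap convention assigns them degenerate all-end-gap
    alignments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < min_divergence < 1.0:
        raise ValueError("min_divergence must lie in (0, 1)")
    rng = stream(seed, "generate_templates", n, length)
    ancestor = "".join(rng.choice(_BASES, size=length))
    mut_frac = min(float(min_divergence), 0.45)
    n_mut = max(1, int(round(mut_frac * length)))
    templates: list[str] = []
    attempts = 0
    budget = max_attempts_per_template * n
    while len(templates) < n:
        if attempts >= budget:
            raise GenerationError(
                f"could not place {n} templates of length {length} at "
                f"divergence >= {min_divergence} within {budget} attempts"
            )
        attempts += 1
        bases = list(ancestor)
        for pos in rng.choice(length, size=n_mut, replace=False):
            bases[pos] = rng.choice([b for b in _BASES if b != bases[pos]])
        cand = "".join(bases)
        if all(distance(cand, t) >= min_divergence for t in templates):
            templates.append(cand)
    return templates


def sample_abundances(n: int, shape: float, seed: int = 0) -> np.ndarray:
    """Geometric-series relative abundances p_i proportional to shape**i.

    ``shape`` near 0.25 gives a rank-1 share >= 75%, the dominance regime
    seen in most of the urine specimens; ``shape = 1`` is uniform.  The
    series is deterministic; ``seed`` is accepted for interface symmetry
    with the other generators but unused.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if shape <= 0:
        raise ValueError("shape must be positive")
    p = np.power(float(shape), np.arange(n))
    return p / p.sum()


def _resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Concrete primer sequence: each ambiguity code replaced by one of
    its bases, as a synthesized PCR primer would carry."""
    return "".join(
        c if len(IUPAC[c]) == 1 else rng.choice(sorted(IUPAC[c])) for c in pattern
    )


def _homopolymer_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of length >= 2."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= 2:
            runs.append((i, j - i))
        i = j
    return runs


def _mutate(seq: str, error: ErrorModel, rng: np.random.Generator) -> tuple[str, int]:
    """Apply substitutions then homopolymer-run indels; returns the read
    body and the number of error events (bases changed/inserted/deleted)."""
    n_errors = 0
    bases = list(seq)
    if error.sub_rate > 0:
        for pos in np.flatnonzero(rng.random(len(bases)) < error.sub_rate):
            old = bases[pos]
            bases[pos] = rng.choice([b for b in _BASES if b != old])
            n_errors += 1
    mutated = "".join(bases)
    if error.hp_indel_rate > 0:
        pieces = []
        prev = 0
        for start, length in _homopolymer_runs(mutated):
            pieces.append(mutated[prev:start])
            new_len = length
            if rng.random() < error.hp_indel_rate:
                sign = -1 if rng.random() < 0.5 else 1
                mag = int(rng.integers(1, error.max_indel + 1))
                new_len = max(1, length + sign * mag)
                n_errors += abs(new_len - length)
            pieces.append(mutated[start] * new_len)
            prev = start + length
        pieces.append(mutated[prev:])
        mutated = "".join(pieces)
    return mutated, n_errors


def generate_reads(
    community: CommunityModel,
    n_reads: int,
    error: ErrorModel,
    primer: PrimerSpec,
    seed: int,
    sample: str = "S",
    read_prefix: str | None = None,
    is_contaminant: bool = False,
) -> tuple[list[SequenceRecord], SimulationTruth]:
    """Draw reads from a community through one composite primer.

    Each read is the composite primer (ambiguity codes resolved per read)
    followed by a mutated copy of a template chosen by the community's
    abundances.  The truth table records every read's origin template and
    error count.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    prefix = read_prefix or f"{sample}_{primer.region}"
    rng = stream(seed, "generate_reads", sample, primer.region, prefix)
    p = np.asarray(community.abundances)
    truth = SimulationTruth()
    reads: list[SequenceRecord] = []
    for i in range(n_reads):
        tid, tseq, _node = community.templates[int(rng.choice(len(p), p=p))]
        body, n_err = _mutate(tseq, error, rng)
        rid = f"{prefix}_r{i:06d}"
        reads.append(
            SequenceRecord(
                id=rid,
                seq=_resolve_iupac(primer.composite, rng) + body,
                sample=sample,
                region=primer.region,
            )
        )
        truth.add(rid, TruthEntry(tid, is_contaminant, n_err))
    return reads, truth


def spike_contamination(
    sample_reads: list[SequenceRecord],
    control_community: CommunityModel,
    fraction: float,
    error: ErrorModel,
    primer: PrimerSpec,
    seed: int,
    n_control_reads: int = 500,
) -> tuple[list[SequenceRecord], list[SequenceRecord], SimulationTruth]:
    """Add reagent-contamination reads to a sample and emit its control.

    Contaminant reads drawn from ``control_community`` are appended so
    they make up ``fraction`` of the augmented sample (nearest integer);
    an independent control read set from the same community is generated
    alongside, mimicking a negative extraction control that shares the
    sample's reagent flora.  The truth flags the spiked reads.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    sample_label = sample_reads[0].sample if sample_reads else "S"
    n_contam = int(round(fraction * len(sample_reads) / (1.0 - fraction)))
    contam, truth = generate_reads(
        control_community,
        n_contam,
        error,
        primer,
        seed,
        sample=sample_label,
        read_prefix=f"{sample_label}_{primer.region}_contam",
        is_contaminant=True,
    )
    control, control_truth = generate_reads(
        control_community,
        n_control_reads,
        error,
        primer,
        seed,
        sample="control",
        read_prefix=f"control_{primer.region}",
        is_contaminant=False,
    )
    truth.update(control_truth)
    return sample_reads + contam, control, truth


def toy_taxonomy(
    template_ids: Sequence[str],
    species_per_genus: int = 2,
    genera_per_family: int = 2,
    families_per_order: int = 2,
    orders_per_phylum: int = 2,
) -> TaxonomyTree:
    """A balanced ranked taxonomy over template ids.

    Template ``i`` becomes a species leaf whose id is the template id, so
    synthetic hit tables can name taxa by template directly; consecutive
    templates share genera, then families, orders and phyla.
    """
    tree = TaxonomyTree()
    for i, tid in enumerate(template_ids):
        g = i // species_per_genus
        f = g // genera_per_family
        o = f // families_per_order
        p = o // orders_per_phylum
        tree.add_lineage(
            tid,
            [f"Phylum{p}", f"Order{o}", f"Family{f}", f"Genus{g}", f"Species_{tid}"],
        )
    tree.validate()
    return tree
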