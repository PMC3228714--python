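"""Synthetic community/read generator: determinism, abundances, errors,
contamination bookkeeping."""
from __future__ import annotations

import numpy as np
import pytest

from uridiv import distances as D
from uridiv import synthetic as S
from uridiv.errors import GenerationError
from uridiv.io_formats import FORWARD_PRIMERS
from uridiv.preprocess import split_by_primer, trim_and_filter

PRIMER = FORWARD_PRIMERS[0]


class TestGenerateTemplates:
    def test_single_template(self):
        (t,) = S.generate_templates(1, 120, 0.05, seed=1)
        assert len(t) == 120

    def test_pair_divergence_postcondition(self):
        a, b = S.generate_templates(2, 300, 0.10, seed=2)
        assert D.distance(a, b) >= 0.10

    def test_fifty_templates_full_matrix_check(self):
        ts = S.generate_templates(50, 300, 0.05, seed=7)
        m = D.pairwise_distance_matrix(ts)
        off = m.data[np.triu_indices(50, 1)]
        assert off.min() >= 0.05

    def test_deterministic_given_seed(self):
        assert S.generate_templates(5, 200, 0.05, seed=3) == \
               S.generate_templates(5, 200, 0.05, seed=3)

    def test_infeasible_raises(self):
        with pytest.raises(GenerationError):
            S.generate_templates(300, 10, 0.9, seed=1, max_attempts_per_template=2)


class TestSampleAbundances:
    def test_single_member(self):
        assert S.sample_abundances(1, 0.3).tolist() == [1.0]

    def test_uniform_limit(self):
        assert S.sample_abundances(4, 1.0).tolist() == [0.25] * 4

    def test_dominance_regime(self):
        p = S.sample_abundances(10, 0.25)
        assert p[0] >= 0.75
        assert p.sum() == pytest.approx(1.0)


class TestGenerateReads:
    def test_noiseless_identity(self):
        (t,) = S.generate_templates(1, 150, 0.05, seed=4)
        comm = S.CommunityModel((("t0", t, "t0"),), (1.0,), "V1V2")
        reads, truth = S.generate_reads(comm, 10, S.ErrorModel(), PRIMER, seed=5)
        assert len(reads) == 10
        bodies = {r.seq[len(PRIMER.composite):] for r in reads}
        assert bodies == {t}
        assert all(t.errors == 0 for t in truth.entries.values())
        # reads carry a concrete primer match: splitting must accept them
        split = split_by_primer(reads, [PRIMER])
        assert len(split["V1V2"]) == 10

    def test_forced_homopolymer_indel(self):
        template = "GACCTGATCGAAATGCTGATCGTACGTCCTGATAGGAC"
        comm = S.CommunityModel((("t0", template, "t0"),), (1.0,), "V1V2")
        error = S.ErrorModel(hp_indel_rate=1.0, max_indel=1)
        reads, truth = S.generate_reads(comm, 20, error, PRIMER, seed=6)
        locus = template.index("AAA")
        for r in reads:
            body = r.seq[len(PRIMER.composite):]
            # run length at the AAA locus is never 3 after a forced indel
            prefix_ok = body[:locus].count("A")  # sanity: not used as assert
            run = 0
            k = body.index("AA")  # first AA-run in the mutated body
            while k + run < len(body) and body[k + run] == "A":
                run += 1
            assert run != 3
        assert all(t.errors >= 1 for t in truth.entries.values())

    def test_template_frequencies_match_abundances(self):
        ts = S.generate_templates(10, 200, 0.05, seed=8)
        p = S.sample_abundances(10, 0.5)
        comm = S.CommunityModel(
            tuple((f"t{i}", s, f"t{i}") for i, s in enumerate(ts)), tuple(p), "V1V2"
        )
        n = 5000
        reads, truth = S.generate_reads(comm, n, S.ErrorModel(), PRIMER, seed=9)
        counts = {f"t{i}": 0 for i in range(10)}
        for t in truth.entries.values():
            counts[t.template_id] += 1
        for i, pi in enumerate(p):
            se = np.sqrt(n * pi * (1 - pi))
            assert abs(counts[f"t{i}"] - n * pi) <= 3 * se + 1

    def test_byte_identical_given_seed(self):
        ts = S.generate_templates(3, 150, 0.05, seed=10)
        comm = S.CommunityModel(
            tuple((f"t{i}", s, f"t{i}") for i, s in enumerate(ts)),
            tuple(S.sample_abundances(3, 0.5)), "V1V2",
        )
        err = S.ErrorModel(sub_rate=0.01, hp_indel_rate=0.05)
        a, _ = S.generate_reads(comm, 50, err, PRIMER, seed=11)
        b, _ = S.generate_reads(comm, 50, err, PRIMER, seed=11)
        assert [(r.id, r.seq) for r in a] == [(r.id, r.seq) for r in b]


class TestSpikeContamination:
    def test_zero_fraction_leaves_sample_unchanged(self, kit):
        reads, _ = S.generate_reads(kit.community, 50, S.ErrorModel(), kit.primer, seed=12)
        augmented, control, truth = S.spike_contamination(
            reads, kit.control, 0.0, S.ErrorModel(), kit.primer, seed=12,
            n_control_reads=40,
        )
        assert augmented == reads
        assert len(control) == 40

    def test_one_percent_of_9900_adds_100(self, kit):
        reads, _ = S.generate_reads(kit.community, 9900, S.ErrorModel(), kit.primer, seed=13)
        augmented, _, truth = S.spike_contamination(
            reads, kit.control, 0.01, S.ErrorModel(), kit.primer, seed=13,
            n_control_reads=10,
        )
        added = len(augmented) - 9900
        assert added == 100
        flagged = sum(
            1 for rid, t in truth.entries.items()
            if t.is_contaminant
        )
        assert flagged == added

    def test_error_free_uniques_equal_sampled_templates(self, kit):
        reads, truth = S.generate_reads(
            kit.community, 300, S.ErrorModel(), kit.primer, seed=14
        )
        from uridiv.preprocess import dereplicate

        ds = dereplicate(trim_and_filter(reads, kit.primer), region="V1V2")
        sampled = {t.template_id for t in truth.entries.values()}
        assert len(ds) == len(sampled)
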