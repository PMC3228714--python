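"""Primer splitting, trimming, dereplication and denoising."""
from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uridiv import preprocess as P
from uridiv import synthetic
from uridiv.errors import ConfigurationError, InvariantError
from uridiv.io_formats import FORWARD_PRIMERS, PrimerSpec, SequenceRecord

V1V2, V6 = FORWARD_PRIMERS


def _read(i, seq):
    return SequenceRecord(id=f"r{i}", seq=seq)


class TestSplitByPrimer:
    def test_ambiguity_code_matches_base(self):
        # the V1V2 composite has M at target position 12: A must match it
        read = _read(0, V1V2.composite.replace("M", "A") + "ACGT" * 60)
        out = P.split_by_primer([read], list(FORWARD_PRIMERS))
        assert [r.id for r in out["V1V2"]] == ["r0"]
        assert out["V1V2"][0].region == "V1V2"

    def test_single_target_mismatch_discards(self):
        good = V1V2.composite.replace("M", "A")
        bad = good[:25] + ("A" if good[25] != "A" else "C") + good[26:]
        out = P.split_by_primer([_read(0, bad + "ACGT" * 60)], list(FORWARD_PRIMERS))
        assert not out["V1V2"] and not out["V6"]

    def test_mixed_pool_counts(self):
        reads = []
        for i in range(60):
            reads.append(_read(f"a{i}", V1V2.composite.replace("M", "C") + "ACGT" * 60))
        for i in range(30):
            reads.append(_read(f"b{i}", V6.composite.replace("R", "A") + "TTGGCCAA" * 32))
        for i in range(10):
            reads.append(_read(f"g{i}", "TTTT" + "ACGT" * 60))
        out = P.split_by_primer(reads, list(FORWARD_PRIMERS))
        assert (len(out["V1V2"]), len(out["V6"])) == (60, 30)

    def test_prefix_overlapping_primers_rejected(self):
        p1 = PrimerSpec("p1", "V1V2", "GCCTCCCTCGCGCCATCAG", "AGAGTTTGATCATGGCTCAG")
        p2 = PrimerSpec("p2", "V6", "GCCTCCCTCGCGCCATCAG", "AGAGTTTGATCNTGGCTCA")
        with pytest.raises(ConfigurationError):
            P.split_by_primer([], [p1, p2])


class TestTrimAndFilter:
    @pytest.mark.parametrize(
        "primer,body_len,kept",
        [
            (V1V2, 240, True),
            (V1V2, 218, True),   # boundary inclusive
            (V1V2, 217, False),
            (V6, 235, True),
            (V6, 234, False),
        ],
    )
    def test_length_cutoff_boundaries(self, primer, body_len, kept):
        seq = primer.composite.replace("M", "A").replace("R", "G") + "A" * body_len
        out = P.trim_and_filter([_read(0, seq)], primer)
        assert bool(out) is kept
        if kept:
            assert out[0].seq == "A" * body_len  # primer removed

    def test_custom_cutoff(self):
        seq = V1V2.composite.replace("M", "A") + "A" * 100
        assert P.trim_and_filter([_read(0, seq)], V1V2, min_len=100)


class TestDereplicate:
    def test_counts_and_representative(self):
        reads = [_read(0, "ACGT"), _read(1, "ACGT"), _read(2, "ACGA")]
        ds = P.dereplicate(reads)
        assert [(e.id, e.seq, e.count) for e in ds.entries] == [
            ("r0", "ACGT", 2), ("r2", "ACGA", 1),
        ]
        assert ds.entries[0].members == ["r0", "r1"]
        assert ds.total_reads == 3

    def test_all_distinct_order_preserved(self):
        reads = [_read(i, "ACGT"[: i + 1] * 4) for i in range(3)]
        ds = P.dereplicate(reads)
        assert [e.count for e in ds.entries] == [1, 1, 1]
        assert [e.id for e in ds.entries] == ["r0", "r1", "r2"]

    def test_empty_input(self):
        assert len(P.dereplicate([])) == 0


class TestDenoise:
    def test_low_abundance_absorbed_within_radius(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + ("A" if a[10] != "A" else "C") + a[11:]  # 1 difference
        ds = P.DereplicatedSet([
            P.DerepEntry("A", a, 50), P.DerepEntry("B", b, 2),
        ])
        out = P.denoise(ds, max_diffs=2)
        assert len(out) == 1
        assert out.entries[0].id == "A"
        assert out.entries[0].count == 52

    def test_beyond_radius_unchanged(self):
        # 5 scattered substitutions in a non-periodic sequence (periodic
        # sequences would realign under a shift with zero internal diffs)
        a = "GATTACACTGGTCAGGACTCTTAGCTTGAC"
        b = "GTTTACAGTGGTCAGCACTCTTTGCTTGAC"
        ds = P.DereplicatedSet([
            P.DerepEntry("A", a, 50), P.DerepEntry("B", b, 2),
        ])
        out = P.denoise(ds, max_diffs=2)
        assert len(out) == 2

    def test_read_count_conservation_and_idempotence(self, kit):
        error = synthetic.ErrorModel(sub_rate=0.004, hp_indel_rate=0.03)
        reads, _ = synthetic.generate_reads(kit.community, 300, error, kit.primer, seed=5)
        trimmed = P.trim_and_filter(reads, kit.primer)
        ds = P.dereplicate(trimmed, region="V1V2")
        once = P.denoise(ds)
        assert once.total_reads == ds.total_reads
        twice = P.denoise(once)
        assert [(e.id, e.seq, e.count) for e in twice.entries] == \
               [(e.id, e.seq, e.count) for e in once.entries]

    def test_never_merges_across_divergent_templates(self, kit):
        # error-free reads from templates >= 5% divergent (>= 15 diffs at
        # 300 nt) can never be merged at max_diffs=3
        reads, truth = synthetic.generate_reads(
            kit.community, 400, synthetic.ErrorModel(), kit.primer, seed=9
        )
        trimmed = P.trim_and_filter(reads, kit.primer)
        out = P.denoise(P.dereplicate(trimmed, region="V1V2"))
        origin = {rid: t.template_id for rid, t in truth.entries.items()}
        for e in out.entries:
            assert len({origin[m] for m in e.members}) == 1

    def test_noiseless_sample_recovers_template_count(self, kit):
        reads, truth = synthetic.generate_reads(
            kit.community, 500, synthetic.ErrorModel(), kit.primer, seed=4
        )
        sampled = {t.template_id for t in truth.entries.values()}
        trimmed = P.trim_and_filter(reads, kit.primer)
        out = P.denoise(P.dereplicate(trimmed, region="V1V2"))
        assert len(out) == len(sampled)


class TestPipelineCounters:
    def test_monotonic_ok(self):
        P.PipelineCounters(100, 90, 80, 80, 79)

    def test_increase_rejected(self):
        with pytest.raises(InvariantError):
            P.PipelineCounters(100, 90, 95, 80, 79)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=5, max_size=5))
    def test_any_sorted_sequence_accepted(self, values):
        ordered = sorted(values, reverse=True)
        P.PipelineCounters(*ordered)
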