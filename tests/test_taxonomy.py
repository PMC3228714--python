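"""Hit replication, LCA assignment, min-support, normalization."""
from __future__ import annotations

import pytest

from uridiv import preprocess as P
from uridiv import synthetic
from uridiv import taxonomy as T
from uridiv.errors import ConsistencyError
from uridiv.io_formats import HitRecord, TaxonomyTree
from uridiv.preprocess import DerepEntry, DereplicatedSet


@pytest.fixture(scope="module")
def tree() -> TaxonomyTree:
    t = TaxonomyTree()
    t.add_lineage("spA1", ["PhyX", "OrdX", "FamX", "GenA", "Species A1"])
    t.add_lineage("spA2", ["PhyX", "OrdX", "FamX", "GenA", "Species A2"])
    t.add_lineage("spB", ["PhyX", "OrdX", "FamY", "GenB", "Species B"])
    t.add_lineage("spC", ["PhyZ", "OrdZ", "FamZ", "GenC", "Species C"])
    return t


def _hit(q, taxon, score):
    return HitRecord(query_id=q, subject_taxon=taxon, bit_score=score, evalue=1e-20)


class TestReplicateHits:
    def test_copies_hits_to_every_member(self):
        ds = DereplicatedSet([DerepEntry("u1", "ACGT", 3, ["r1", "r2", "r3"])])
        hits = {"u1": [_hit("u1", "spA1", 150), _hit("u1", "spA2", 140)]}
        per_read = T.replicate_hits(hits, ds)
        assert set(per_read) == {"r1", "r2", "r3"}
        assert all(len(v) == 2 for v in per_read.values())

    def test_total_rows_bookkeeping(self):
        ds = DereplicatedSet([
            DerepEntry("u1", "ACGT", 3), DerepEntry("u2", "ACGA", 2),
        ])
        hits = {"u1": [_hit("u1", "spA1", 150)] * 4, "u2": [_hit("u2", "spB", 120)]}
        per_read = T.replicate_hits(hits, ds)
        assert sum(len(v) for v in per_read.values()) == 3 * 4 + 2 * 1

    def test_unknown_query_rejected(self):
        ds = DereplicatedSet([DerepEntry("u1", "ACGT", 1)])
        with pytest.raises(ConsistencyError):
            T.replicate_hits({"ghost": [_hit("ghost", "spA1", 150)]}, ds)


class TestLcaAssign:
    def test_single_strong_hit_assigns_species(self, tree):
        res = T.lca_assign({"r1": [_hit("r1", "spA1", 150)]}, tree)
        assert res.assignments["r1"] == "spA1"

    def test_two_species_one_genus_gives_genus(self, tree):
        res = T.lca_assign(
            {"r1": [_hit("r1", "spA1", 150), _hit("r1", "spA2", 150)]}, tree
        )
        assert tree.nodes[res.assignments["r1"]].rank == "genus"
        assert tree.name(res.assignments["r1"]) == "GenA"

    def test_two_phyla_gives_root(self, tree):
        res = T.lca_assign(
            {"r1": [_hit("r1", "spA1", 150), _hit("r1", "spC", 150)]}, tree
        )
        assert res.assignments["r1"] == TaxonomyTree.ROOT

    def test_min_score_floor_yields_no_hits_bucket(self, tree):
        res = T.lca_assign({"r1": [_hit("r1", "spA1", 99.9)]}, tree, min_score=100)
        assert res.assignments["r1"] == T.NO_HITS

    def test_top_percent_window_excludes_weak_hits(self, tree):
        res = T.lca_assign(
            {"r1": [_hit("r1", "spA1", 200), _hit("r1", "spC", 150)]},
            tree, top_percent=0.10,
        )
        assert res.assignments["r1"] == "spA1"  # 150 < 0.9 * 200
        wide = T.lca_assign(
            {"r1": [_hit("r1", "spA1", 200), _hit("r1", "spC", 150)]},
            tree, top_percent=1.0,
        )
        assert wide.assignments["r1"] == TaxonomyTree.ROOT

    def test_unknown_taxon_rejected(self, tree):
        with pytest.raises(ConsistencyError):
            T.lca_assign({"r1": [_hit("r1", "mystery", 150)]}, tree)


class TestMinSupport:
    def _result(self, tree, n_a, n_b):
        assignments = {f"a{i}": "spA1" for i in range(n_a)}
        assignments.update({f"b{i}": "spB" for i in range(n_b)})
        return T.AssignmentResult(assignments=assignments, tree=tree)

    def test_below_threshold_moves_to_not_assigned(self, tree):
        res = T.apply_min_support(self._result(tree, 4, 5), min_support=5)
        assert res.bucket_count(T.NOT_ASSIGNED) == 4
        assert res.node_tallies().get("spB") == 5  # boundary inclusive

    def test_min_support_one_is_identity(self, tree):
        before = self._result(tree, 2, 1)
        after = T.apply_min_support(before, min_support=1)
        assert after.assignments == before.assignments

    def test_read_conservation(self, tree):
        res = T.apply_min_support(self._result(tree, 3, 7), min_support=5)
        tallies = res.node_tallies()
        assert sum(tallies.values()) == 10


class TestNormalization:
    def test_proportional_scaling(self, tree):
        assignments = {f"a{i}": "spA1" for i in range(20)}
        assignments.update({f"b{i}": "spB" for i in range(30)})
        res = T.AssignmentResult(assignments=assignments, tree=tree)
        table = T.summarize_at_rank({"s1": res}, "genus", target=100_000)
        assert table.loc["GenA", "s1"] == pytest.approx(40_000)
        assert table.loc["GenB", "s1"] == pytest.approx(60_000)

    def test_scale_invariance_across_samples(self, tree):
        small = {f"a{i}": "spA1" for i in range(2)}
        small.update({f"b{i}": "spB" for i in range(3)})
        big = {f"a{i}": "spA1" for i in range(20)}
        big.update({f"b{i}": "spB" for i in range(30)})
        table = T.summarize_at_rank(
            {
                "small": T.AssignmentResult(assignments=small, tree=tree),
                "big": T.AssignmentResult(assignments=big, tree=tree),
            },
            "genus",
        )
        assert (table["small"] == table["big"]).all()

    def test_rank_tallies_sum_rule(self, tree):
        # reads assigned at genus or below contribute to the genus rank;
        # a root-assigned read does not
        assignments = {"r1": "spA1", "r2": "spA2", "r3": TaxonomyTree.ROOT}
        res = T.AssignmentResult(assignments=assignments, tree=tree)
        assert sum(res.rank_tallies("genus").values()) == 2


class TestToyHits:
    def test_genus_composition_recovered_exactly_at_zero_error(self, kit):
        reads, truth = synthetic.generate_reads(
            kit.community, 400, synthetic.ErrorModel(), kit.primer, seed=33
        )
        dereps = P.dereplicate(P.trim_and_filter(reads, kit.primer), region="V1V2")
        hits = T.toy_hit_table(dereps, kit.templates)
        per_read = T.replicate_hits(hits, dereps)
        res = T.lca_assign(per_read, kit.tree)
        # every read must land on its own template's species leaf
        want = {rid: t.template_id for rid, t in truth.entries.items()}
        trimmed_ids = set(per_read)
        for rid in trimmed_ids:
            assert res.assignments[rid] == want[rid]
        genus = res.rank_tallies("genus")
        truth_genus: dict[str, int] = {}
        for rid in trimmed_ids:
            g = kit.tree.ancestor_at_rank(want[rid], "genus")
            truth_genus[g] = truth_genus.get(g, 0) + 1
        assert genus == truth_genus
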