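import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import gene
from tfcensus import context as ctx


def layout(plan, gap_default=10):
    """Build genes from (strand, gap_before) tuples, 900 bp each."""
    genes, cursor = [], 0
    for i, item in enumerate(plan):
        strand, gap = item if isinstance(item, tuple) else (item, gap_default)
        start = cursor + gap + 1
        genes.append(gene(f"g{i}", start, start + 899, strand))
        cursor = start + 899
    return genes


class TestIntergenicDistance:
    def test_bases_strictly_between(self):
        a, b = gene("a", 100, 900, "+"), gene("b", 1001, 1900, "+")
        assert ctx.intergenic_distance(a, b) == ctx.IntergenicGap(100)

    def test_abutting_genes(self):
        a, b = gene("a", 100, 900, "+"), gene("b", 901, 1800, "+")
        assert ctx.intergenic_distance(a, b) == ctx.IntergenicGap(0)

    def test_overlap_clamps_to_zero_with_flag(self):
        a, b = gene("a", 100, 900, "+"), gene("b", 850, 1700, "+")
        assert ctx.intergenic_distance(a, b) == ctx.IntergenicGap(0, overlap=True)

    def test_cross_replicon_is_an_error(self):
        a = gene("a", 100, 900, "+", replicon="chr1")
        b = gene("b", 1001, 1900, "+", replicon="chr2")
        with pytest.raises(ValueError):
            ctx.intergenic_distance(a, b)


class TestPredictTus:
    def test_gaps_under_threshold_join_one_tu(self):
        genes = layout([("+", 100), ("+", 20), ("+", 30)])
        (tu,) = ctx.predict_tus(genes, gap_max=50)
        assert tu.gene_ids == ("g0", "g1", "g2")

    def test_large_gap_splits(self):
        genes = layout([("+", 100), ("+", 500)])
        tus = ctx.predict_tus(genes, gap_max=50)
        assert [t.gene_ids for t in tus] == [("g0",), ("g1",)]

    def test_strand_switch_splits_even_at_zero_gap(self):
        genes = layout([("+", 100), ("-", 0), ("+", 0)])
        assert all(len(t.gene_ids) == 1 for t in ctx.predict_tus(genes, gap_max=50))

    @given(
        st.lists(
            st.tuples(st.sampled_from("+-"), st.integers(0, 200)),
            min_size=1,
            max_size=30,
        )
    )
    def test_tus_partition_the_replicon(self, plan):
        genes = layout(plan)
        tus = ctx.predict_tus(genes, gap_max=50)
        covered = [gid for t in tus for gid in t.gene_ids]
        assert sorted(covered) == sorted(g.gene_id for g in genes)
        assert len(covered) == len(set(covered))
        for t in tus:
            assert len({g.strand for g in genes if g.gene_id in t.gene_ids}) == 1


class TestClassifyTfContext:
    def test_divergent_with_distance(self):
        left = gene("n", 100, 900, "-")
        tf = gene("tf", 1000, 1800, "+")
        call = ctx.classify_tf_context(tf, [left, tf], ctx.predict_tus([left, tf]))
        assert call.relation == "divergent"
        assert call.partner_gene_id == "n" and call.intergenic_bp == 99

    def test_minus_strand_tf_divergent_with_right_neighbor(self):
        tf = gene("tf", 100, 900, "-")
        right = gene("n", 1000, 1800, "+")
        call = ctx.classify_tf_context(tf, [tf, right], ctx.predict_tus([tf, right]))
        assert call.relation == "divergent" and call.intergenic_bp == 99

    def test_convergent_neighbor_is_not_divergent(self):
        # TF on '-' whose *left* neighbor is '+': promoters face away pairwise
        left = gene("n", 100, 900, "+")
        tf = gene("tf", 1500, 2300, "-")
        call = ctx.classify_tf_context(tf, [left, tf], ctx.predict_tus([left, tf], gap_max=50))
        assert call.relation == "isolated"

    def test_cotranscribed_interior_gene(self):
        genes = layout([("+", 100), ("+", 10), ("+", 10)])
        tus = ctx.predict_tus(genes, gap_max=50)
        call = ctx.classify_tf_context(genes[1], genes, tus)
        assert call.relation == "in_tu" and call.partner_gene_id == "g0"

    def test_lone_gene_isolated(self):
        g = gene("solo", 1000, 1900, "+")
        call = ctx.classify_tf_context(g, [g], ctx.predict_tus([g]))
        assert call == ctx.ContextCall("solo", "isolated")

    def test_edge_tf_without_upstream_neighbor(self):
        # plus-strand TF first on a linear replicon: divergence impossible
        tf = gene("tf", 100, 900, "+")
        right = gene("n", 950, 1850, "+")
        genes = [tf, right]
        call = ctx.classify_tf_context(tf, genes, ctx.predict_tus(genes, gap_max=50))
        assert call.relation == "in_tu"  # classified from the remaining side

    def test_circular_flag_wraps_neighbors(self):
        tf = gene("tf", 200, 1100, "+")
        last = gene("n", 5000, 5900, "-")
        genes = [tf, last]
        call = ctx.classify_tf_context(tf, genes, ctx.predict_tus(genes), circular=True)
        assert call.relation == "divergent" and call.partner_gene_id == "n"

    def test_overlapping_divergent_promoters_distance_zero_flagged(self):
        left = gene("n", 100, 1050, "-")
        tf = gene("tf", 1000, 1800, "+")
        call = ctx.classify_tf_context(tf, [left, tf], ctx.predict_tus([left, tf]))
        assert call.relation == "divergent"
        assert call.intergenic_bp == 0 and call.overlap

    @given(
        st.lists(
            st.tuples(st.sampled_from("+-"), st.integers(0, 200)),
            min_size=1,
            max_size=15,
        )
    )
    def test_relations_exhaustive_exclusive_and_tu_consistent(self, plan):
        genes = layout(plan)
        tus = ctx.predict_tus(genes, gap_max=50)
        tu_of = {gid: t for t in tus for gid in t.gene_ids}
        for g in genes:
            call = ctx.classify_tf_context(g, genes, tus)
            assert call.relation in ctx.RELATIONS
            if call.relation == "divergent":
                # a divergent partner is never a co-TU member
                assert call.partner_gene_id not in tu_of[g.gene_id].gene_ids
            if call.relation == "in_tu":
                assert call.partner_gene_id in tu_of[g.gene_id].gene_ids

    def test_planted_contexts_recovered(self, small_collection):
        """Generator-planted divergent/in-TU/isolated labels are recovered
        exactly when gap distributions are separated from the threshold."""
        _, bundles, truth = small_collection
        for b in bundles:
            tus = ctx.predict_tus(b.genes)
            by_id = {g.gene_id: g for g in b.genes}
            for pid, rec in truth.genomes[b.genome_id].tfs.items():
                call = ctx.classify_tf_context(by_id[pid], b.genes, tus)
                assert call.relation == rec.relation
                if rec.relation == "divergent":
                    assert call.intergenic_bp == rec.divergent_gap


class TestDivergentDistanceHistogram:
    def calls(self, distances):
        return [
            ctx.ContextCall(f"t{i}", "divergent", partner_gene_id=f"p{i}", intergenic_bp=d)
            for i, d in enumerate(distances)
        ]

    def test_binning(self):
        hist = ctx.divergent_distance_histogram(self.calls([10, 60, 110]), bin_width=50)
        assert hist.bins == {0: 1, 1: 1, 2: 1}
        assert hist.frac_le_100 == pytest.approx(2 / 3)

    def test_empty_input(self):
        hist = ctx.divergent_distance_histogram([])
        assert hist.bins == {} and hist.frac_le_100 is None

    def test_non_divergent_calls_ignored(self):
        mixed = self.calls([10]) + [ctx.ContextCall("x", "isolated")]
        assert ctx.divergent_distance_histogram(mixed).n == 1

    def test_geometric_gaps_match_analytic_cdf(self):
        # gaps ~ Geometric(p=1/60) - 1; P(gap <= 100) = 1 - (1-p)^101
        rng = np.random.default_rng(12)
        p = 1 / 60
        gaps = rng.geometric(p, size=2000) - 1
        hist = ctx.divergent_distance_histogram(self.calls(gaps.tolist()))
        analytic = 1 - (1 - p) ** 101
        assert hist.frac_le_100 == pytest.approx(analytic, abs=0.03)
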