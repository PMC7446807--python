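import numpy as np
import pytest

from conftest import gene
from tfcensus import predict
from tfcensus.formats_io import DomainHit, SimilarityHit

TF_PFAMS = frozenset({"PF00126", "PF00440", "PF00486"})


def dhit(pid, acc, e, bit=50.0):
    return DomainHit(pid, acc, "", e, bit, 1, 90)


def shit(q, s, e=1e-20, bit=300.0, qcov=0.9, scov=0.9):
    return SimilarityHit(q, s, e, bit, qcov, scov)


class TestAssignTfByDomain:
    def test_qualifying_hit_assigns_family(self):
        assert predict.assign_tf_by_domain([dhit("p1", "PF00440", 1e-10)], TF_PFAMS) == {
            "p1": "PF00440"
        }

    def test_threshold_boundary(self):
        hits = [dhit("p2", "PF00440", 1e-2), dhit("p4", "PF00440", 1e-3)]
        assert predict.assign_tf_by_domain(hits, TF_PFAMS) == {"p4": "PF00440"}

    def test_min_evalue_wins_then_bitscore_then_accession(self):
        hits = [dhit("p3", "PF00126", 1e-8), dhit("p3", "PF00440", 1e-4)]
        assert predict.assign_tf_by_domain(hits, TF_PFAMS)["p3"] == "PF00126"
        tie = [dhit("p5", "PF00440", 1e-8, bit=90), dhit("p5", "PF00126", 1e-8, bit=50)]
        assert predict.assign_tf_by_domain(tie, TF_PFAMS)["p5"] == "PF00440"
        lex = [dhit("p6", "PF00440", 1e-8, bit=50), dhit("p6", "PF00126", 1e-8, bit=50)]
        assert predict.assign_tf_by_domain(lex, TF_PFAMS)["p6"] == "PF00126"

    def test_non_tf_pfams_ignored_and_empty_inputs(self):
        assert predict.assign_tf_by_domain([dhit("p1", "PF99999", 1e-30)], TF_PFAMS) == {}
        assert predict.assign_tf_by_domain([], TF_PFAMS) == {}
        with pytest.raises(ValueError):
            predict.assign_tf_by_domain([], frozenset())


def brute_force_rbh(hits_ab, hits_ba, e_max=1e-5, cov_min=0.70):
    """Independent oracle: exhaustive mutual-best enumeration over all pairs."""

    def best(hits, query):
        qualifying = [
            h
            for h in hits
            if h.query_id == query and h.e_value <= e_max and min(h.query_cov, h.subject_cov) >= cov_min
        ]
        if not qualifying:
            return None
        return min(qualifying, key=lambda h: (-h.bit_score, h.e_value, h.subject_id)).subject_id

    queries = {h.query_id for h in hits_ab}
    subjects = {h.query_id for h in hits_ba}
    return {
        (a, b)
        for a in queries
        for b in subjects
        if best(hits_ab, a) == b and best(hits_ba, b) == a
    }


def random_tables(rng, n=20, m=20, density=0.3):
    ab, ba = [], []
    for i in range(n):
        for j in range(m):
            if rng.random() < density:
                ab.append(
                    shit(
                        f"a{i}",
                        f"b{j}",
                        e=10.0 ** rng.uniform(-30, 0),
                        bit=float(rng.integers(20, 500)),
                        qcov=float(rng.uniform(0.4, 1.0)),
                        scov=float(rng.uniform(0.4, 1.0)),
                    )
                )
            if rng.random() < density:
                ba.append(
                    shit(
                        f"b{j}",
                        f"a{i}",
                        e=10.0 ** rng.uniform(-30, 0),
                        bit=float(rng.integers(20, 500)),
                        qcov=float(rng.uniform(0.4, 1.0)),
                        scov=float(rng.uniform(0.4, 1.0)),
                    )
                )
    return ab, ba


class TestFindOrthologsRbh:
    def test_canonical_mutual_best(self):
        ab, ba = [shit("a1", "b1")], [shit("b1", "a1")]
        assert predict.find_orthologs_rbh(ab, ba) == {("a1", "b1")}

    def test_coverage_below_70_percent_fails(self):
        ab = [shit("a2", "b2", qcov=0.65)]
        ba = [shit("b2", "a2", qcov=0.65)]
        assert predict.find_orthologs_rbh(ab, ba) == set()
        # exactly 70% qualifies
        ab = [shit("a2", "b2", qcov=0.70, scov=0.70)]
        ba = [shit("b2", "a2", qcov=0.70, scov=0.70)]
        assert predict.find_orthologs_rbh(ab, ba) == {("a2", "b2")}

    def test_one_sided_coverage_mode(self):
        ab = [shit("a1", "b1", qcov=0.9, scov=0.5)]
        ba = [shit("b1", "a1", qcov=0.9, scov=0.5)]
        assert predict.find_orthologs_rbh(ab, ba) == set()
        assert predict.find_orthologs_rbh(ab, ba, both_sides_coverage=False) == {("a1", "b1")}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ab, ba = random_tables(rng, n=5, m=5, density=0.6)
        assert predict.find_orthologs_rbh(ab, ba) == brute_force_rbh(ab, ba)

    def test_symmetry_and_uniqueness(self):
        rng = np.random.default_rng(99)
        ab, ba = random_tables(rng)
        pairs = predict.find_orthologs_rbh(ab, ba)
        swapped = predict.find_orthologs_rbh(ba, ab)
        assert {(b, a) for a, b in pairs} == swapped
        for side in (0, 1):
            ids = [p[side] for p in pairs]
            assert len(ids) == len(set(ids))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        ab, ba = random_tables(rng)
        strict = {
            a for a, _ in predict.find_orthologs_rbh(ab, ba, e_max=1e-10, cov_min=0.8)
        }
        loose = {a for a, _ in predict.find_orthologs_rbh(ab, ba, e_max=1e-3, cov_min=0.5)}
        # relaxing thresholds never removes a predicted protein
        assert strict <= loose


class TestMergePredictions:
    def test_set_algebra_partition(self):
        preds = predict.merge_predictions("G", {"A": "PF00126", "B": "PF00440"}, {"B", "C"})
        by_prov = {p.provenance: p.protein_id for p in preds}
        assert by_prov == {"domain_only": "A", "both": "B", "orthology_only": "C"}
        assert preds[2].family_pfam == ""  # orthology-only carries no family

    def test_empty_orthology_all_domain_only(self):
        preds = predict.merge_predictions("G", {"A": "PF00126"}, set())
        assert predict.partition_counts(preds) == {
            "domain_only": 1,
            "both": 0,
            "orthology_only": 0,
        }

    def test_partition_sizes_always_sum_to_union(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ids = [f"p{i}" for i in range(rng.integers(0, 30))]
            dom = {i: "PF00126" for i in ids if rng.random() < 0.5}
            orth = {i for i in ids if rng.random() < 0.5}
            preds = predict.merge_predictions("G", dom, orth)
            counts = predict.partition_counts(preds)
            assert sum(counts.values()) == len(set(dom) | orth)

    def test_planted_detectability_recovered(self, small_collection, bundle_dir):
        """Route-detectability flags in the generator truth map exactly onto
        the merged provenance partition."""
        from tfcensus.cli import PipelineConfig, load_inputs, stage_predict, _read_predictions

        cfg = PipelineConfig(input_dir=str(bundle_dir), out_dir=str(bundle_dir / "out_pred"))
        stage_predict(cfg, load_inputs(bundle_dir))
        from pathlib import Path

        preds = {
            (p.genome_id, p.protein_id): p for p in _read_predictions(Path(cfg.out_dir))
        }
        _, _, truth = small_collection
        for gid, gtruth in truth.genomes.items():
            for pid, rec in gtruth.tfs.items():
                expected = {
                    (True, True): "both",
                    (True, False): "domain_only",
                    (False, True): "orthology_only",
                    (False, False): None,
                }[(rec.domain_detectable, rec.orthology_detectable)]
                got = preds.get((gid, pid))
                assert (got.provenance if got else None) == expected
                if expected in ("domain_only", "both"):
                    assert got.family_pfam == rec.family


class TestCensus:
    def test_printed_density_example(self):
        genes = [gene(f"g{i}", 1 + i * 1000, 900 + i * 1000, "+", genome="Sc")
                 for i in range(10_514)]
        preds = [
            predict.TFPrediction("Sc", f"g{i}", "PF00126", "domain_only", 1e-9)
            for i in range(402)
        ]
        (c,) = predict.census(preds, genes)
        assert c.n_orfs == 10_514 and c.n_tfs == 402
        assert round(100 * c.tf_density, 1) == 3.8

    def test_density_bounds(self):
        genes = [gene(f"g{i}", 1 + i * 1000, 900 + i * 1000, "+") for i in range(5)]
        assert predict.census([], genes)[0].tf_density == 0.0
        all_tf = [predict.TFPrediction("G", g.protein_id, "PF00126", "domain_only", 1e-9)
                  for g in genes]
        assert predict.census(all_tf, genes)[0].tf_density == 1.0

    def test_unknown_protein_is_an_error(self):
        genes = [gene("g0", 1, 900, "+")]
        bad = [predict.TFPrediction("G", "ghost", "PF00126", "domain_only", 1e-9)]
        with pytest.raises(ValueError, match="ghost"):
            predict.census(bad, genes)


class TestFamilyGenomePrevalence:
    def test_fraction_of_genomes_with_a_member(self):
        preds = [
            predict.TFPrediction(f"G{i}", f"p{i}", "PF04397", "domain_only", 1e-9)
            for i in range(3)
        ]
        prevalence = predict.family_genome_prevalence(preds, n_genomes=4)
        assert prevalence["PF04397"] == pytest.approx(0.75)

    def test_empty_family_and_bad_n(self):
        with pytest.raises(ValueError):
            predict.family_genome_prevalence([], 0)
        assert predict.family_genome_prevalence([], 5) == {}
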