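"""Isoform categorization: decision cascade, gene assignment, end distances,
minority filtering, intergenic locus clustering, and oracle equivalence."""

import numpy as np
import pytest

import isokit
from isokit import Category, GenomicInterval, IsoformRecord
from isokit.classify import (
    assign_gene,
    classify_isoform,
    cluster_intergenic_loci,
    count_distant_ends,
    end_distances,
    filter_minority_isoforms,
)
from isokit.simulate import SimulationConfig, generate_observed_isoforms, random_annotation

from conftest import make_transcript
from _oracles import oracle_classify, oracle_overlap_components


class TestDecisionCascade:
    def test_identical_chain_is_fsm(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(110, 200), (300, 400), (500, 590)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.category is Category.FSM
        assert cls.matched_transcript == "A.t1"
        assert cls.assigned_gene == "geneA"

    def test_consecutive_proper_subchain_is_ism(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(320, 400), (500, 580)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.category is Category.ISM
        assert cls.matched_transcript == "A.t1"

    def test_known_sites_novel_chain_is_nic(self, toy_annotation):
        # junction (200,500): donor 200 and acceptor 500 are annotated in
        # A.t1, but no transcript has this chain (exon skip)
        q = make_transcript("q", "chr1", "+", [(110, 200), (500, 590)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.category is Category.NIC
        assert cls.assigned_gene == "geneA"

    def test_unannotated_site_is_nnc_with_novel_sites(self, toy_annotation):
        # acceptor at 480 is not annotated (annotated acceptors: 300, 450, 500)
        q = make_transcript("q", "chr1", "+", [(110, 200), (480, 590)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.category is Category.NNC
        assert [(s.position, s.side) for s in cls.novel_sites] == [(480, "acceptor")]

    def test_no_locus_overlap_is_intergenic(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(50_000, 50_100), (50_200, 50_300)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.category is Category.INTERGENIC
        assert cls.assigned_gene is None

    def test_opposite_strand_only_overlap_is_genic_other(self, toy_annotation):
        q = make_transcript("q", "chr1", "-", [(120, 180), (350, 380)])
        assert classify_isoform(q, toy_annotation).category is Category.GENIC_OTHER

    def test_mono_exon_categories(self, toy_annotation):
        inside = make_transcript("q1", "chr1", "+", [(120, 180)])
        assert classify_isoform(inside, toy_annotation).category is Category.MONO_EXON_KNOWN
        intronic = make_transcript("q2", "chr1", "+", [(230, 280)])
        assert classify_isoform(intronic, toy_annotation).category is Category.MONO_EXON_GENIC
        distant = make_transcript("q3", "chr1", "+", [(90_000, 90_100)])
        assert classify_isoform(distant, toy_annotation).category is Category.INTERGENIC

    def test_invariant_to_reference_order_and_exon_permutation(self, toy_annotation):
        from isokit import Gene, GenomeAnnotation

        genes = list(toy_annotation.genes.values())
        reordered = GenomeAnnotation(
            [Gene(g.gene_id, g.chrom, g.strand, g.transcripts[::-1], g.name, g.biotype)
             for g in genes[::-1]]
        )
        q = make_transcript("q", "chr1", "+", [(500, 590), (110, 200), (300, 400)])
        assert classify_isoform(q, toy_annotation).category is Category.FSM
        assert classify_isoform(q, reordered).category is Category.FSM


class TestAssignGene:
    def test_site_sharing_dominates_span_overlap(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(110, 200), (300, 400), (500, 590)])
        assert assign_gene(q, toy_annotation) == "geneA"

    def test_exonic_overlap_fallback_without_shared_sites(self, toy_annotation):
        q = make_transcript("q", "chr2", "+", [(150, 450)])
        assert assign_gene(q, toy_annotation) == "geneC"

    def test_intergenic_returns_none(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(70_000, 70_100)])
        assert assign_gene(q, toy_annotation) is None


class TestEndDistances:
    def test_identity_gives_zero_everywhere(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
        cls = classify_isoform(q, toy_annotation)
        assert end_distances(cls, q, toy_annotation) == (0, 0, 0, 0)

    def test_absolute_offset_on_plus_strand(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(150, 200), (300, 400), (500, 600)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.d5 == 50 and cls.d3 == 0

    def test_strand_aware_five_prime_on_minus(self, toy_annotation):
        # geneB is minus strand: 5' end is the genomic right end (2300)
        q = make_transcript("q", "chr1", "-", [(2000, 2100), (2200, 2260)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.category is Category.FSM
        assert cls.d5 == 40 and cls.d3 == 0

    def test_gene_min_uses_all_transcripts(self, toy_annotation):
        # 3' end at 600 matches both A.t1 and A.t2 polyA; 5' end at 100 too:
        # a model ending at 650 is closer to no transcript; use A.t2 TSS=100
        q = make_transcript("q", "chr1", "+", [(100, 200), (300, 400), (500, 640)])
        cls = classify_isoform(q, toy_annotation)
        assert cls.d3 == 40 and cls.d3_gene_min == 40
        assert cls.d5 == 0 and cls.d5_gene_min == 0

    def test_non_fsm_is_contract_violation(self, toy_annotation):
        q = make_transcript("q", "chr1", "+", [(320, 400), (500, 580)])
        cls = classify_isoform(q, toy_annotation)
        with pytest.raises(ValueError):
            end_distances(cls, q, toy_annotation)

    def test_matched_transcript_minimizes_end_distance_sum(self):
        from isokit import Gene, GenomeAnnotation

        # two annotated transcripts share the chain but differ at the ends
        t1 = make_transcript("t1", "chr1", "+", [(100, 200), (300, 400)], "g")
        t2 = make_transcript("t2", "chr1", "+", [(150, 200), (300, 350)], "g")
        ann = GenomeAnnotation([Gene("g", "chr1", "+", [t1, t2])])
        q = make_transcript("q", "chr1", "+", [(149, 200), (300, 352)])
        cls = classify_isoform(q, ann)
        assert cls.matched_transcript == "t2"


class TestCountDistantEnds:
    def _cls(self, d5, d3):
        c = isokit.IsoformClassification(
            "x", Category.FSM, assigned_gene="g", matched_transcript="t"
        )
        c.d5_gene_min, c.d3_gene_min = d5, d3
        return c

    def test_strictly_greater_than_threshold(self):
        classes = [self._cls(501, 500), self._cls(500, 2000), self._cls(0, 0)]
        assert count_distant_ends(classes, threshold=500) == (1, 1)

    def test_infinite_threshold_counts_nothing(self):
        classes = [self._cls(10_000, 10_000)]
        assert count_distant_ends(classes, threshold=10**12) == (0, 0)


class TestMinorityFilter:
    def _records(self, totals):
        recs = []
        for i, tot in enumerate(totals):
            m = make_transcript(f"i{i}", "chr1", "+", [(100, 200)])
            recs.append(IsoformRecord(model=m, counts={"s1": tot}))
        return recs

    def test_exact_one_percent_is_retained(self):
        recs = self._records([99, 1])
        gene_of = {"i0": "g", "i1": "g"}
        kept = filter_minority_isoforms(recs, gene_of, 0.01)
        assert {r.id for r in kept} == {"i0", "i1"}

    def test_below_threshold_is_discarded(self):
        recs = self._records([995, 5])
        kept = filter_minority_isoforms(recs, {"i0": "g", "i1": "g"}, 0.01)
        assert {r.id for r in kept} == {"i0"}

    def test_zero_fraction_is_identity_and_zero_gene_total_kept(self):
        recs = self._records([3, 0])
        assert len(filter_minority_isoforms(recs, {"i0": "g", "i1": "g"}, 0.0)) == 2
        recs0 = self._records([0, 0])
        assert len(filter_minority_isoforms(recs0, {"i0": "g", "i1": "g"}, 0.01)) == 2


class TestIntergenicLoci:
    def _spans(self, pairs, n_exons=2):
        models = []
        for i, (s, e) in enumerate(pairs):
            mid = (s + e) // 2
            exons = [(s, mid - 1), (mid + 1, e)] if n_exons == 2 else [(s, e)]
            models.append(make_transcript(f"m{i}", "chr1", "+", exons))
        return models

    def test_transitive_overlap_merges(self):
        loci = cluster_intergenic_loci(self._spans([(0, 100), (50, 150), (200, 300)]))
        assert len(loci) == 2
        assert sorted(loci[0].members) == ["m0", "m1"]

    def test_disjoint_spans_stay_separate(self):
        loci = cluster_intergenic_loci(self._spans([(0, 10), (20, 30), (40, 50)]))
        assert len(loci) == 3

    def test_multiexon_only_excludes_mono_exon(self):
        models = self._spans([(0, 100)]) + self._spans([(0, 100)], n_exons=1)
        assert len(cluster_intergenic_loci(models, multiexon_only=True)[0].members) == 1

    def test_matches_graph_components_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 15))
            starts = rng.integers(0, 2000, n)
            spans = [(int(s), int(s) + int(rng.integers(20, 400))) for s in starts]
            models = self._spans(spans)
            loci = cluster_intergenic_loci(models)
            got = sorted(sorted(int(m[1:]) for m in l.members) for l in loci)
            expected = sorted(oracle_overlap_components([m.span for m in models]))
            assert got == expected


class TestOracleEquivalence:
    def test_classifier_agrees_with_bruteforce_on_random_annotations(self):
        """Indexed classifier vs exhaustive enumeration of the category
        definitions, over random annotations and generated isoforms."""
        rng = np.random.default_rng(11)
        cfg = SimulationConfig(
            n_genes=6, chromosome_length=80_000, n_observed_isoforms=30
        )
        for rep in range(25):
            ann = random_annotation(cfg, rng)
            models, truth = generate_observed_isoforms(ann, cfg, rng)
            for m in models:
                assert classify_isoform(m, ann).category.value == oracle_classify(m, ann)
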