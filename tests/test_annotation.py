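"""Gene assignment, coding-effect calls, and hypergeometric enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from bsrmap.annotation import (EffectCall, GeneModel, classify_snp_effect,
                               genes_in_regions, hypergeometric_enrichment,
                               intersect_gene_sets, read_gff3)
from bsrmap.regions import CandidateRegion
from bsrmap.synthetic import (generate_gene_fixtures, write_cds_fasta,
                              write_gff3)


def gene(gid="g1", lg="LG1", start=100, end=200, strand="+", segs=None):
    return GeneModel(gene_id=gid, linkage_group=lg, start=start, end=end,
                     strand=strand, cds_segments=segs or [(start, end)])


def creg(lg, start, end):
    return CandidateRegion(linkage_group=lg, start=start, end=end,
                           methods=frozenset({"ED5"}))


class TestGenesInRegions:
    def test_overlap_included_adjacency_excluded(self):
        g = gene(start=100, end=201, segs=[(100, 201)])  # 102 bp CDS
        (inside,) = genes_in_regions([g], [creg("LG1", 150, 300)])
        assert [x.gene_id for x in inside] == ["g1"]
        (outside,) = genes_in_regions([g], [creg("LG1", 202, 300)])
        assert outside == []

    def test_matches_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(11)
        genes = []
        for i in range(60):
            s = int(rng.integers(1, 5000))
            length = int(rng.integers(1, 100)) * 3
            genes.append(gene(gid=f"g{i}", lg=f"LG{rng.integers(1, 4)}",
                              start=s, end=s + length - 1,
                              segs=[(s, s + length - 1)]))
        regions = [creg(f"LG{rng.integers(1, 4)}",
                        int(s := rng.integers(1, 5000)),
                        int(s + rng.integers(0, 800)))
                   for _ in range(10)]
        result = genes_in_regions(genes, regions)
        for r, hits in zip(regions, result):
            expected = {g.gene_id for g in genes
                        if g.linkage_group == r.linkage_group
                        and max(g.start, r.start) <= min(g.end, r.end)}
            assert {g.gene_id for g in hits} == expected


class TestIntersectGeneSets:
    def test_basic_intersection(self):
        assert intersect_gene_sets({"A", "B", "C"}, {"B", "C", "D"}) == \
            ["B", "C"]

    def test_disjoint_empty(self):
        assert intersect_gene_sets({"A"}, {"B"}) == []

    def test_duplicates_collapse(self):
        assert intersect_gene_sets(["A", "A", "B"], ["A", "A"]) == ["A"]


class TestClassifySnpEffect:
    def test_first_position_gac_to_aac_is_nonsynonymous(self):
        """GAC->AAC: aspartate to asparagine, as for a G/A coding SNP."""
        g = gene(start=100, end=105, segs=[(100, 105)])
        call = classify_snp_effect(g, "GACGAC", 100, "G", "A")
        assert (call.ref_codon, call.alt_codon) == ("GAC", "AAC")
        assert (call.ref_aa, call.alt_aa) == ("D", "N")
        assert call.synonymous is False and call.codon_index == 1

    def test_second_position_gcc_to_gtc_ala_to_val(self):
        g = gene(start=10, end=15, segs=[(10, 15)])
        call = classify_snp_effect(g, "GCCAAA", 11, "C", "T")
        assert (call.ref_aa, call.alt_aa) == ("A", "V")
        assert not call.synonymous

    def test_wobble_position_synonymous(self):
        g = gene(start=10, end=15, segs=[(10, 15)])
        call = classify_snp_effect(g, "GCGAAA", 12, "G", "A")
        assert call.alt_codon == "GCA"
        assert call.synonymous is True

    def test_minus_strand_uses_reverse_complement(self):
        # genome forward 10..15 = GTCGTC; coding strand (minus) = GACGAC
        g = gene(start=10, end=15, strand="-", segs=[(10, 15)])
        call = classify_snp_effect(g, "GACGAC", 15, "C", "T")
        # position 15 is the first coding base; C complements to G, T->A
        assert call.codon_index == 1
        assert (call.ref_codon, call.alt_codon) == ("GAC", "AAC")
        assert (call.ref_aa, call.alt_aa) == ("D", "N")

    def test_strand_mirror_consistency(self):
        """A minus-strand gene and its plus-strand mirror give the same
        call for the equivalent substitution."""
        from Bio.Seq import Seq

        cds = "ATGGCTTTA"
        plus = gene(gid="p", start=100, end=108, strand="+",
                    segs=[(100, 108)])
        minus = gene(gid="m", start=100, end=108, strand="-",
                     segs=[(100, 108)])
        # substitute coding base at offset 4 (C->T)
        call_p = classify_snp_effect(plus, cds, 104, "C", "T")
        # on the minus gene, coding offset 4 sits at genome 104 counted
        # from the right end; forward-strand alleles are complemented
        call_m = classify_snp_effect(minus, cds, 100 + (8 - 4), "G", "A")
        assert (call_p.ref_codon, call_p.alt_codon) == \
            (call_m.ref_codon, call_m.alt_codon)
        assert call_p.synonymous == call_m.synonymous

    def test_mutate_then_revert_round_trip(self):
        g = gene(start=10, end=15, segs=[(10, 15)])
        fwd = classify_snp_effect(g, "GACGAC", 10, "G", "A")
        mutated = "AACGAC"
        back = classify_snp_effect(g, mutated, 10, "A", "G")
        assert back.alt_codon == fwd.ref_codon
        same = classify_snp_effect(g, "GACGAC", 10, "G", "G")
        assert same.synonymous is True

    def test_position_outside_cds_noncoding(self):
        g = gene(start=100, end=220, segs=[(100, 105), (200, 205)])
        call = classify_snp_effect(g, "GACGACGACGAC", 150, "A", "T")
        assert call.coding is False and call.codon_index is None

    def test_spliced_offset_spans_segments(self):
        g = gene(start=100, end=220, segs=[(100, 105), (200, 205)])
        call = classify_snp_effect(g, "GACGACGACGAC", 200, "G", "A")
        assert call.codon_index == 3  # seventh coding base

    def test_reference_mismatch_raises(self):
        g = gene(start=10, end=15, segs=[(10, 15)])
        with pytest.raises(ValueError, match="15"):
            classify_snp_effect(g, "GACGAC", 15, "A", "T")

    def test_gff_fixture_round_trip(self, tmp_path):
        genes, seqs = generate_gene_fixtures(3, [("LG1", 1000, 20_000)],
                                             seed=4)
        gff = write_gff3(genes, tmp_path / "genes.gff3")
        loaded = read_gff3(gff)
        assert [(g.gene_id, g.start, g.end, g.strand, g.cds_segments)
                for g in loaded] == \
            [(g.gene_id, g.start, g.end, g.strand, g.cds_segments)
             for g in genes]


class TestHypergeometricEnrichment:
    def test_closed_form_by_hand(self):
        """N=10, K=5, n=2, k=2: p = C(5,2)/C(10,2) = 10/45."""
        background = [f"g{i}" for i in range(10)]
        term_map = {g: {"T"} for g in background[:5]}
        results = hypergeometric_enrichment(background[:2], background,
                                            term_map)
        (r,) = results
        assert (r.k, r.K, r.n, r.N) == (2, 5, 2, 10)
        assert r.p_value == pytest.approx(10 / 45)

    def test_term_covering_background_p_one(self):
        background = [f"g{i}" for i in range(8)]
        term_map = {g: {"ALL"} for g in background}
        (r,) = hypergeometric_enrichment(background[:3], background, term_map)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_overlap_p_one(self):
        background = [f"g{i}" for i in range(8)]
        term_map = {g: {"T"} for g in background[4:]}
        (r,) = hypergeometric_enrichment(background[:3], background,
                                         term_map)
        assert r.k == 0 and r.p_value == pytest.approx(1.0)

    def test_set_not_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment(["x"], ["a", "b"], {})

    def test_matches_exhaustive_enumeration_oracle(self):
        """Tail probabilities agree with enumeration of all n-subsets of
        small backgrounds to 1e-12."""
        rng = np.random.default_rng(13)
        for N, K, n in [(8, 3, 4), (10, 5, 2), (12, 6, 5), (15, 4, 6)]:
            background = [f"g{i}" for i in range(N)]
            carriers = set(rng.choice(background, size=K, replace=False))
            gene_set = list(rng.choice(background, size=n, replace=False))
            k = len(carriers & set(gene_set))
            term_map = {g: {"T"} for g in carriers}
            (r,) = hypergeometric_enrichment(gene_set, background, term_map)
            total = hits = 0
            for subset in itertools.combinations(background, n):
                total += 1
                if len(carriers & set(subset)) >= k:
                    hits += 1
            assert r.p_value == pytest.approx(hits / total, abs=1e-12)
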