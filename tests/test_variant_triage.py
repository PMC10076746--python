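import itertools

import pytest
from hypothesis import given, settings, strategies as st

from triodx import demo
from triodx import variant_triage as vt
from triodx.variant_triage import (
    CnvCall,
    CnvType,
    Consequence,
    Genotype,
    KnownRegion,
    Origin,
    TrioGenotypes,
)


def tg(p, f, m):
    return TrioGenotypes("v", Genotype(p), Genotype(f), Genotype(m))


class TestClassifyOrigin:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            (("het", "hom_ref", "hom_ref"), Origin.DE_NOVO),
            (("het", "het", "hom_ref"), Origin.PATERNAL),
            (("het", "hom_ref", "het"), Origin.MATERNAL),
            (("het", "het", "het"), Origin.INHERITED_BOTH),
            (("het", "missing", "hom_ref"), Origin.AMBIGUOUS),
            (("hom_ref", "hom_ref", "hom_ref"), Origin.AMBIGUOUS),
        ],
    )
    def test_examples(self, triple, expected):
        assert vt.classify_origin(tg(*triple)) == expected

    def test_agrees_with_brute_force_over_all_triples(self):
        # independent rule table evaluated by enumeration over all 4^3 triples
        def oracle(p, f, m):
            carries = {"het": True, "hom_alt": True, "hom_ref": False, "missing": None}
            cp, cf, cm = carries[p], carries[f], carries[m]
            if cp is not True or cf is None or cm is None:
                return Origin.AMBIGUOUS
            if cf and cm:
                return Origin.INHERITED_BOTH
            if cf:
                return Origin.PATERNAL
            if cm:
                return Origin.MATERNAL
            return Origin.DE_NOVO

        states = ["hom_ref", "het", "hom_alt", "missing"]
        for p, f, m in itertools.product(states, repeat=3):
            assert vt.classify_origin(tg(p, f, m)) == oracle(p, f, m)


class TestClassifyPtv:
    @pytest.mark.parametrize(
        "consequence,hgvs,expected",
        [
            (Consequence.NONSENSE, "c.4242T>G", True),
            (Consequence.FRAMESHIFT, "c.8595delT", True),
            (Consequence.SPLICE_ACCEPTOR, "c.7395-2A>T", True),
            (Consequence.SPLICE_DONOR, "c.605 + 1G>A", True),  # spacing tolerated
            (Consequence.SPLICE_DONOR, "c.605+5G>A", False),  # beyond canonical site
            (Consequence.MISSENSE, "c.1570C>T", False),
            (Consequence.SYNONYMOUS, "c.99A>G", False),
        ],
    )
    def test_examples(self, consequence, hgvs, expected):
        assert vt.classify_ptv(consequence, hgvs) is expected

    def test_unparseable_splice_offset_errors(self):
        with pytest.raises(vt.ClassificationError):
            vt.classify_ptv(Consequence.SPLICE_DONOR, "c.bogus")


class TestCnvFilters:
    def test_resolution(self):
        big = CnvCall("s", "chr2", 51_046_035, 51_696_622, CnvType.DELETION)
        assert big.size == 650_588
        assert vt.filter_cnv_resolution(big)
        assert not vt.filter_cnv_resolution(
            CnvCall("s", "chr1", 1, 99_999, CnvType.DELETION))
        assert vt.filter_cnv_resolution(  # boundary inclusive
            CnvCall("s", "chr1", 1, 100_000, CnvType.DELETION))

    def test_match_known_region_published_span(self):
        catalog = demo.load_known_regions()
        cnv = CnvCall("s", "chr15", 23_596_697, 28_012_138, CnvType.DUPLICATION)
        hit = vt.match_known_region(cnv, catalog)
        assert hit is not None and "15q11q13" in hit.name

    def test_no_match_across_chromosomes(self):
        catalog = [KnownRegion("r", "chr15", 100, 1_000_000)]
        cnv = CnvCall("s", "chr1", 100, 1_000_000, CnvType.DUPLICATION)
        assert vt.match_known_region(cnv, catalog) is None

    def test_forty_percent_overlap_rejected(self):
        # CNV [1, 1000] vs region [601, 1600]: overlap 400 = 40% of each
        cnv = CnvCall("s", "chr1", 1, 1000, CnvType.DELETION)
        region = KnownRegion("r", "chr1", 601, 1600)
        assert vt.reciprocal_overlap(1, 1000, 601, 1600) == pytest.approx(0.4)
        assert vt.match_known_region(cnv, [region]) is None

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.tuples(st.integers(1, 500), st.integers(1, 500)),
        b=st.tuples(st.integers(1, 500), st.integers(1, 500)),
    )
    def test_reciprocal_overlap_matches_exhaustive_intersection(self, a, b):
        (a1, a2), (b1, b2) = sorted(a), sorted(b)
        ovl = len(set(range(a1, a2 + 1)) & set(range(b1, b2 + 1)))
        expected = 0.0 if ovl == 0 else min(
            ovl / (a2 - a1 + 1), ovl / (b2 - b1 + 1))
        assert vt.reciprocal_overlap(a1, a2, b1, b2) == pytest.approx(expected)

    def test_cnv_origin(self):
        proband = CnvCall("kid", "chr1", 1000, 300_000, CnvType.DUPLICATION)
        same = CnvCall("mo", "chr1", 1000, 300_000, CnvType.DUPLICATION)
        other_type = CnvCall("fa", "chr1", 1000, 300_000, CnvType.DELETION)
        assert vt.cnv_origin(proband, [], []) == Origin.DE_NOVO
        assert vt.cnv_origin(proband, [], [same]) == Origin.MATERNAL
        assert vt.cnv_origin(proband, [other_type], [same]) == Origin.MATERNAL
        assert vt.cnv_origin(proband, [same], [same]) == Origin.INHERITED_BOTH
        shifted = CnvCall("fa", "chr1", 200_000, 500_000, CnvType.DUPLICATION)
        assert vt.cnv_origin(proband, [shifted], []) == Origin.DE_NOVO


class TestTriage:
    def test_demo_cohort_reproduces_published_tallies(self):
        findings = demo.run_demo_triage()
        snv = [f for f in findings if f.kind == "snv"]
        cnv = [f for f in findings if f.kind == "cnv"]
        assert len(snv) == 10 and len(cnv) == 9
        assert all(f.origin is Origin.DE_NOVO for f in snv)
        assert sum(f.origin is Origin.DE_NOVO for f in cnv) == 5
        assert sum(f.cnv_type is CnvType.DUPLICATION for f in cnv) == 6
        assert sum(1 for f in snv if f.gene == "SCN2A") == 3

    def test_output_order_invariant_and_duplicate_free(self):
        snvs = demo.load_diagnosed_snvs()
        cnvs = demo.load_diagnosed_cnvs()
        args = (demo.load_pedigree(), demo.load_gene_list(), demo.load_known_regions())
        base = vt.triage(snvs, cnvs, *args)
        shuffled = vt.triage(list(reversed(snvs)) + snvs,  # duplicates too
                             {k: v * 2 for k, v in cnvs.items()}, *args)
        assert shuffled == base
        assert len({f.key() for f in base}) == len(base)

    def test_non_ptv_and_inherited_snvs_excluded(self):
        ped = demo.load_pedigree()
        gl = demo.load_gene_list()
        missense = vt.SnvCall("ASD0046", "ASH1L", "c.1A>G",
                              Consequence.MISSENSE,
                              genotypes=tg("het", "hom_ref", "hom_ref"))
        inherited = vt.SnvCall("ASD0046", "ASH1L", "c.8595delT",
                               Consequence.FRAMESHIFT,
                               genotypes=tg("het", "het", "hom_ref"))
        assert vt.triage([missense, inherited], {}, ped, gl, []) == []

    def test_haploinsufficient_deletion_without_catalog_match(self):
        from triodx.io_formats import GeneModel
        ped = demo.load_pedigree()
        gl = demo.load_gene_list()
        genes = [GeneModel("NRXN1", "chr2", 51_000_000, 51_200_000)]
        cnv = CnvCall("ASD0060", "chr2", 50_900_000, 51_300_000, CnvType.DELETION)
        hits = vt.triage([], {"ASD0060": [cnv]}, ped, gl, [], gene_models=genes)
        assert len(hits) == 1 and hits[0].kind == "cnv"
        # a duplication of the same gene does not use the haploinsufficiency rule
        dup = CnvCall("ASD0060", "chr2", 50_900_000, 51_300_000, CnvType.DUPLICATION)
        assert vt.triage([], {"ASD0060": [dup]}, ped, gl, [], gene_models=genes) == []

    def test_unknown_proband_errors(self):
        snv = vt.SnvCall("NOBODY", "PTEN", "c.546dupA", Consequence.FRAMESHIFT,
                         genotypes=tg("het", "hom_ref", "hom_ref"))
        with pytest.raises(KeyError, match="NOBODY"):
            vt.triage([snv], {}, demo.load_pedigree(), demo.load_gene_list(), [])
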