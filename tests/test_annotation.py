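"""Region/effect classification, impact tiers, Ka/Ks, Ts/Tv, gene sets."""

import numpy as np
import pandas as pd
import pytest

from popscan import annotation
from popscan.io import ReferenceGenome, reverse_complement
from popscan.model import GeneModel, make_sites_frame
from popscan.annotation import (
    ReferenceMismatchError,
    annotate_variants,
    classify_coding_effect,
    classify_region,
    gene_set_comparisons,
    impact_of,
    ka_ks,
    ts_tv,
    variant_effects,
)

from conftest import TOY_CHROM, TOY_LEN, build_table


class TestImpactMap:
    @pytest.mark.parametrize(
        "effect,impact",
        [
            ("stop_gained", "HIGH"),
            ("frameshift_variant", "HIGH"),
            ("splice_donor_variant", "HIGH"),
            ("missense_variant", "MODERATE"),
            ("inframe_deletion", "MODERATE"),
            ("synonymous_variant", "LOW"),
            ("splice_region_variant", "LOW"),
            ("utr_premature_start_gain", "LOW"),
            ("intron_variant", "MODIFIER"),
            ("intergenic_variant", "MODIFIER"),
        ],
    )
    def test_fixed_mapping(self, effect, impact):
        assert impact_of(effect) == impact


class TestGoldenToyGenome:
    def test_hand_derived_annotation_table(self, toy_cohort):
        ref, genes, variants, table = toy_cohort
        effects, summary = annotate_variants(table, genes, ref)
        eff = {
            (r.pos, r.gene_id): (r.effect, r.impact) for r in effects.itertuples()
        }
        for pos, _, _, gene_id, effect, impact in variants:
            assert eff[(pos, gene_id)] == (effect, impact), (pos, gene_id)
        # every variant gets >= 1 record, at most (overlapping genes + 1)
        per_site = effects.groupby("site_index").size()
        assert per_site.min() >= 1 and per_site.max() <= len(genes) + 1
        assert sum(summary["region_pct"].values()) == pytest.approx(100.0)

    def test_byte_identical_across_runs(self, toy_cohort):
        ref, genes, variants, table = toy_cohort
        e1, s1 = annotate_variants(table, genes, ref)
        e2, s2 = annotate_variants(table, genes, ref)
        assert e1.to_csv() == e2.to_csv()
        assert s1 == s2

    def test_reverse_complement_mirror_invariance(self, toy_cohort):
        ref, genes, variants, _ = toy_cohort
        L = TOY_LEN
        seq = ref.fetch(TOY_CHROM, 0, L)
        mirror_ref = ReferenceGenome({TOY_CHROM: reverse_complement(seq)})
        mirror_genes = [
            GeneModel(
                gene_id=g.gene_id, chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                start=L - g.end, end=L - g.start,
                exons=[(L - e, L - s) for s, e in g.exons],
                cds=[(L - e, L - s) for s, e in g.cds],
            )
            for g in genes
        ]
        comp = dict(zip("ACGT", "TGCA"))
        for pos, ref_allele, alt_allele, gene_id, effect, impact in variants:
            if len(ref_allele) == 1 and len(alt_allele) == 1:
                m_pos = L - 1 - pos
                m_ref, m_alt = comp[ref_allele], comp[alt_allele]
            else:  # 1-bp deletion: re-anchor on the mirrored strand
                m_pos = L - 1 - (pos + 1) - 1
                m_seq = mirror_ref.fetch(TOY_CHROM, m_pos, m_pos + 2)
                m_ref, m_alt = m_seq, m_seq[0]
            recs = variant_effects(
                TOY_CHROM, m_pos, m_ref, m_alt, mirror_genes, mirror_ref
            )
            by_gene = {r["gene_id"]: (r["effect"], r["impact"]) for r in recs}
            assert by_gene.get(gene_id) == (effect, impact), (pos, gene_id, effect)


class TestClassifyRegion:
    def _gene(self, strand="+"):
        return GeneModel(
            gene_id="g", chrom="c", strand=strand, start=10_000, end=11_400,
            exons=[(10_000, 10_300), (10_500, 10_800), (11_000, 11_400)],
            cds=[(10_200, 10_300), (10_500, 10_800), (11_000, 11_200)],
        )

    @pytest.mark.parametrize(
        "pos,region",
        [
            (7_000, "upstream"),        # 3 kb 5' of a plus-strand gene
            (16_000, "downstream"),     # 4.6 kb past the gene end
            (3_000, "intergenic"),      # beyond the 5 kb flank
            (10_300, "splice_site_region"),  # first intronic base (donor side)
            (10_250, "exon"),
            (10_100, "utr5"),
            (11_300, "utr3"),
            (10_400, "intron"),
        ],
    )
    def test_location_precedence(self, pos, region):
        recs = classify_region(pos, "c", [self._gene()])
        assert recs[0][0] == region

    def test_minus_strand_flank_orientation(self):
        recs = classify_region(7_000, "c", [self._gene(strand="-")])
        assert recs[0][0] == "downstream"

    def test_two_genes_two_records(self):
        g1 = self._gene()
        g2 = GeneModel(gene_id="g2", chrom="c", strand="-", start=13_000, end=14_000,
                       exons=[(13_000, 14_000)], cds=[])
        recs = classify_region(12_000, "c", [g1, g2])
        assert len(recs) == 2


class TestCodingEffect:
    def test_reference_mismatch_detected(self, toy_cohort):
        ref, genes, variants, _ = toy_cohort
        gene_a = genes[0]
        pos = gene_a.cds[0][0] + 10
        actual = ref.fetch(TOY_CHROM, pos, pos + 1)
        wrong = "A" if actual != "A" else "C"
        with pytest.raises(ReferenceMismatchError):
            classify_coding_effect(pos, wrong, "G", gene_a, ref)

    def test_inframe_deletion(self, toy_cohort):
        ref, genes, _, _ = toy_cohort
        gene_a = genes[0]
        s = gene_a.cds[1][0] + 30
        refseq = ref.fetch(TOY_CHROM, s, s + 4)
        assert (
            classify_coding_effect(s, refseq, refseq[0], gene_a, ref)
            == "inframe_deletion"
        )


class TestRatios:
    def _sites(self, pairs):
        return make_sites_frame(
            [("c", 10 * k, r, (a,)) for k, (r, a) in enumerate(pairs)]
        )

    def test_ts_tv_mixture(self):
        assert ts_tv(self._sites([("A", "G"), ("C", "T"), ("A", "C")])) == pytest.approx(2.0)

    def test_all_transversions(self):
        assert ts_tv(self._sites([("A", "C"), ("G", "T")])) == 0.0

    def test_no_transversions_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(ts_tv(self._sites([("A", "G")])))

    def test_ka_ks_counts(self):
        eff = pd.DataFrame({"effect": ["missense_variant"] * 3 + ["synonymous_variant"] * 4})
        assert ka_ks(eff) == pytest.approx(0.75)

    def test_ka_ks_no_synonymous(self):
        eff = pd.DataFrame({"effect": ["missense_variant"]})
        with pytest.warns(UserWarning):
            assert np.isnan(ka_ks(eff))


class TestGeneSets:
    def test_private_sets(self, toy_cohort):
        ref, genes, variants, table = toy_cohort
        effects, _ = annotate_variants(table, genes, ref)
        rep = gene_set_comparisons(table, effects, group_by="subspecies")
        # acc1 (pepo) carries every alt allele; acc2 (ovifera) none
        assert set(rep["private_genes"]["pepo"]) == {"geneA", "geneB"}
        assert rep["private_genes"]["ovifera"] == []

    def test_variant_in_all_groups_not_private(self, toy_cohort):
        ref, genes, variants, table = toy_cohort
        shared = table.copy()
        shared.gt[1, :, 1] = 1  # second accession now carries every alt too
        effects, _ = annotate_variants(shared, genes, ref)
        rep = gene_set_comparisons(shared, effects, group_by="subspecies")
        assert rep["private_genes"]["pepo"] == [] and rep["private_genes"]["ovifera"] == []

    def test_empty_gene_table_all_intergenic(self, toy_cohort):
        ref, _, _, table = toy_cohort
        effects, summary = annotate_variants(table, [], ref)
        assert (effects.region == "intergenic").all()
        assert summary["region_pct"]["intergenic"] == pytest.approx(100.0)
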