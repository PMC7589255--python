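"""Annotator correctness: codon-level classes, splice/intron/intergenic
geography, indel handling, oracle equivalence and strand symmetry."""

from __future__ import annotations

import numpy as np
import pytest

from tnsvkit.synthetic_data import PanelSimConfig, child_rng, simulate_panel
from tnsvkit.variant_effects import (
    DataIntegrityError,
    EffectAnnotation,
    GeneModel,
    VariantRecord,
    annotate_table,
    annotate_variant,
    extract_cds,
    normalize_indel,
    reverse_complement,
)

from conftest import oracle_classify_snp, oracle_extract_cds

PAD = "TTTTTTTTTT"

# single-exon gene: CDS ATG GGA CAA TAA at 11..22
TOY_REF = {"toy": PAD + "ATGGGACAATAA" + PAD}
TOY_GENE = GeneModel("g1", "toy", "+", ((11, 22),), family="F1")

# two-exon gene: ATGGGA | GT..20bp..AG | CAATAA ; exons 11..16 and 41..46
_INTRON = "GT" + "ACGTACGTACGTACGTACGT" + "AG"
SPLIT_REF = {"toy2": PAD + "ATGGGA" + _INTRON + "CAATAA" + PAD}
SPLIT_GENE = GeneModel("g2", "toy2", "+", ((11, 16), (41, 46)), family="F1")


def snp(chrom, pos, ref, alt):
    return VariantRecord(chrom, pos, ref, alt, np.zeros(1, dtype=np.int8))


class TestExtractCds:
    def test_plus_strand_single_exon(self):
        assert extract_cds(TOY_GENE, TOY_REF) == "ATGGGACAATAA"

    def test_minus_strand_equals_reverse_complement_of_slices(self):
        ref = {"c": PAD + reverse_complement("ATGGGACAATAA") + PAD}
        gene = GeneModel("gm", "c", "-", ((11, 22),))
        assert extract_cds(gene, ref) == "ATGGGACAATAA"
        assert extract_cds(gene, ref) == oracle_extract_cds(gene, ref)

    def test_spliced_extraction_skips_intron(self):
        assert extract_cds(SPLIT_GENE, SPLIT_REF) == "ATGGGACAATAA"

    def test_out_of_bounds_segment_raises(self):
        gene = GeneModel("g", "toy", "+", ((11, 2000),))
        with pytest.raises(IndexError):
            extract_cds(gene, TOY_REF)


class TestSnpClasses:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected,aa",
        [
            (16, "A", "G", "synonymous", "G2G"),   # GGA -> GGG
            (17, "C", "T", "nonsense", "Q3*"),      # CAA -> TAA
            (18, "A", "T", "missense", "Q3L"),      # CAA -> CTA
            (12, "T", "C", "start_lost", "M1T"),    # ATG -> ACG
            (21, "A", "C", "stop_loss", "*4S"),     # TAA -> TCA
            (21, "A", "G", "synonymous", "*4*"),    # TAA -> TGA
        ],
    )
    def test_codon_level_classification(self, pos, ref, alt, expected, aa):
        ann = annotate_variant(snp("toy", pos, ref, alt), TOY_GENE, TOY_REF)
        assert ann.effect_class == expected
        assert ann.aa_change == aa

    def test_nonsense_records_truncation(self):
        ann = annotate_variant(snp("toy", 17, "C", "T"), TOY_GENE, TOY_REF)
        assert ann.premature_stop is True
        assert ann.truncated_length == 2  # M and G remain

    def test_intergenic_outside_gene_span(self):
        ann = annotate_variant(snp("toy", 5, "T", "A"), TOY_GENE, TOY_REF)
        assert ann.effect_class == "intergenic"

    def test_ref_mismatch_raises_data_integrity_error(self):
        with pytest.raises(DataIntegrityError, match="toy:11"):
            annotate_variant(snp("toy", 11, "C", "G"), TOY_GENE, TOY_REF)

    def test_wrong_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            annotate_variant(snp("elsewhere", 11, "A", "G"), TOY_GENE, TOY_REF)


class TestSpliceAndIntron:
    @pytest.mark.parametrize("pos", [17, 18, 39, 40])
    def test_two_bp_junction_window_is_splice_site(self, pos):
        ref = SPLIT_REF["toy2"][pos - 1]
        alt = "A" if ref != "A" else "C"
        ann = annotate_variant(snp("toy2", pos, ref, alt), SPLIT_GENE, SPLIT_REF)
        assert ann.effect_class == "splice_site"

    def test_deep_intron_is_intronic(self):
        ref = SPLIT_REF["toy2"][25 - 1]
        alt = "A" if ref != "A" else "C"
        ann = annotate_variant(snp("toy2", 25, ref, alt), SPLIT_GENE, SPLIT_REF)
        assert ann.effect_class == "intronic"


class TestIndels:
    @pytest.fixture()
    def plus_gene(self, reference_and_genes):
        reference, genes = reference_and_genes
        gene = next(g for g in genes if g.strand == "+")
        return reference, gene

    def test_single_base_insertion_is_frameshift_with_premature_stop(
        self, plus_gene
    ):
        reference, gene = plus_gene
        a, b = gene.cds_segments[0]
        pos = a + 5
        chrom = reference[gene.chromosome]
        ref = chrom[pos - 1]
        ann = annotate_variant(
            snp(gene.chromosome, pos, ref, ref + "T"), gene, reference
        )
        assert ann.effect_class == "frameshift"
        assert ann.premature_stop is True
        assert ann.truncated_length is not None

    def test_three_base_deletion_is_inframe(self, plus_gene):
        reference, gene = plus_gene
        a, b = gene.cds_segments[0]
        pos = a + 6
        chrom = reference[gene.chromosome]
        ann = annotate_variant(
            snp(gene.chromosome, pos, chrom[pos - 1 : pos + 3], chrom[pos - 1]),
            gene,
            reference,
        )
        assert ann.effect_class == "inframe_indel"

    def test_minus_strand_frameshift_translated_on_coding_strand(
        self, reference_and_genes
    ):
        reference, genes = reference_and_genes
        gene = next(g for g in genes if g.strand == "-")
        a, b = gene.cds_segments[-1]  # 5' end of a minus-strand gene
        pos = b - 10
        chrom = reference[gene.chromosome]
        ref = chrom[pos - 1]
        ann = annotate_variant(
            snp(gene.chromosome, pos, ref, ref + "G"), gene, reference
        )
        assert ann.effect_class == "frameshift"
        assert ann.premature_stop is True

    def test_left_alignment_shifts_deletion_through_repeat(self):
        chrom_seq = "AACCCCGT"
        pos, ref, alt = normalize_indel(5, "CC", "C", chrom_seq)
        assert (pos, ref, alt) == (3, "CC", "C")


class TestAnnotateTable:
    def test_empty_input_empty_output(self, reference_and_genes):
        reference, genes = reference_and_genes
        assert annotate_table([], genes, reference) == []

    def test_variant_overlapping_two_genes_annotated_twice(self):
        gene_b = GeneModel("g1b", "toy", "+", ((14, 22),))
        anns = annotate_table(
            [snp("toy", 16, "A", "G")], [TOY_GENE, gene_b], TOY_REF
        )
        assert [a.gene_id for a in anns] == ["g1", "g1b"]

    def test_variant_in_no_gene_reported_intergenic(self):
        anns = annotate_table([snp("toy", 3, "T", "A")], [TOY_GENE], TOY_REF)
        assert len(anns) == 1
        assert anns[0].effect_class == "intergenic"
        assert anns[0].gene_id is None

    def test_planted_nonsynonymous_sites_recovered_exactly(
        self, reference_and_genes
    ):
        reference, genes = reference_and_genes
        cfg = PanelSimConfig(n_accessions=20, seed=13)
        sim = simulate_panel(cfg, genes, reference)
        anns = annotate_table(sim.variants, genes, reference)
        protein_changing = {"missense", "nonsense", "start_lost", "stop_loss"}
        n_nonsyn = (sim.site_truth["planted_class"] == "non_synonymous").sum()
        n_syn = (sim.site_truth["planted_class"] == "synonymous").sum()
        assert sum(a.effect_class in protein_changing for a in anns) == n_nonsyn
        assert sum(a.effect_class == "synonymous" for a in anns) == n_syn

    def test_output_sorted_and_deterministic(self, reference_and_genes):
        reference, genes = reference_and_genes
        sim = simulate_panel(PanelSimConfig(n_accessions=5, seed=14), genes, reference)
        anns = annotate_table(sim.variants, genes, reference)
        keys = [(a.chromosome, a.pos, a.gene_id or "") for a in anns]
        assert keys == sorted(keys)


class TestOracleEquivalence:
    def _random_cds_snps(self, reference, genes, n, seed):
        rng = child_rng(seed, "oracle-test")
        chrom = reference[genes[0].chromosome]
        picks = []
        positions = []
        for g in genes:
            for a, b in g.cds_segments:
                positions.extend((g, p) for p in range(a, b + 1))
        idx = rng.integers(0, len(positions), size=n)
        for i in idx:
            g, p = positions[i]
            ref = chrom[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            picks.append((g, p, ref, alt))
        return picks

    def test_snp_classes_match_full_protein_oracle(self, reference_and_genes):
        reference, genes = reference_and_genes
        for g, pos, ref, alt in self._random_cds_snps(reference, genes, 300, 15):
            ann = annotate_variant(snp(g.chromosome, pos, ref, alt), g, reference)
            assert ann.effect_class == oracle_classify_snp(g, reference, pos, alt), (
                g.gene_id,
                pos,
                ref,
                alt,
            )

    def test_strand_symmetry_under_mirrored_reference(self, reference_and_genes):
        reference, genes = reference_and_genes
        chrom_name = genes[0].chromosome
        chrom = reference[chrom_name]
        L = len(chrom)
        mirror_ref = {chrom_name: reverse_complement(chrom)}
        for g, pos, ref, alt in self._random_cds_snps(reference, genes, 100, 16):
            mirror_gene = GeneModel(
                g.gene_id,
                chrom_name,
                "-" if g.strand == "+" else "+",
                tuple(sorted((L - b + 1, L - a + 1) for a, b in g.cds_segments)),
                family=g.family,
            )
            mirror_pos = L - pos + 1
            ann = annotate_variant(snp(chrom_name, pos, ref, alt), g, reference)
            mirror_ann = annotate_variant(
                snp(
                    chrom_name,
                    mirror_pos,
                    reverse_complement(ref),
                    reverse_complement(alt),
                ),
                mirror_gene,
                mirror_ref,
            )
            assert ann.effect_class == mirror_ann.effect_class
            assert ann.aa_change == mirror_ann.aa_change

    def test_cds_snp_classes_are_exclusive_and_exhaustive(self, reference_and_genes):
        reference, genes = reference_and_genes
        allowed = {
            "synonymous", "missense", "nonsense", "start_lost", "stop_loss",
        }
        for g, pos, ref, alt in self._random_cds_snps(reference, genes, 200, 17):
            ann = annotate_variant(snp(g.chromosome, pos, ref, alt), g, reference)
            assert ann.effect_class in allowed
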