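"""Gene model, region partition and substitution-effect annotation."""

import pytest
from hypothesis import given, strategies as st
from Bio.Data import CodonTable

from mitovar.genetic_code import COMPLEMENT
from mitovar.reference import (
    CODING_REGIONS,
    REGIONS,
    ReferenceMismatchError,
    annotate_effect,
    classify_substitution,
    load_gene_model,
)
from mitovar import refdata

_BIO_MITO = CodonTable.unambiguous_dna_by_id[2]  # independent code oracle


def _bio_translate_codon(codon: str) -> str:
    if codon in _BIO_MITO.stop_codons:
        return "*"
    return _BIO_MITO.forward_table[codon]


class TestPartition:
    def test_every_position_maps_to_exactly_one_region(self, model):
        counts = {r: 0 for r in REGIONS}
        for pos in range(1, model.length + 1):
            _, region = model.locate(pos)
            counts[region] += 1
        assert sum(counts.values()) == 16569
        assert all(v > 0 for v in counts.values())

    def test_canonical_gene_content(self, model):
        trnas = [f for f in model.features if f.product_class == "tRNA"]
        assert len(trnas) == 22
        assert {f.product_class for f in model.features} == set(REGIONS)
        assert len([f for f in model.features if f.is_coding]) == 13

    @pytest.mark.parametrize(
        ("position", "locus", "region"),
        [
            (9055, "MT-ATP6", "ATPsynthase"),
            (14167, "MT-ND6", "complexI"),
            (11778, "MT-ND4", "complexI"),
            (3480, "MT-ND1", "complexI"),
            (73, "MT-CR", "noncoding"),
            (16569, "MT-CR", "noncoding"),
            (1, "MT-CR", "noncoding"),
            (577, "MT-TF", "tRNA"),
            (648, "MT-RNR1", "rRNA"),
            (14831, "MT-CYB", "complexIII"),
            (5904, "MT-CO1", "complexIV"),
        ],
    )
    def test_locate_known_positions(self, model, position, locus, region):
        assert model.locate(position) == (locus, region)

    @pytest.mark.parametrize("position", [0, -3, 16570])
    def test_locate_rejects_out_of_range(self, model, position):
        with pytest.raises(ValueError, match="outside"):
            model.locate(position)

    def test_known_overlaps_are_the_only_coding_overlaps(self, model):
        coding = sorted((f for f in model.features if f.is_coding),
                        key=lambda f: f.start)
        overlaps = [
            (a.name, b.name)
            for a, b in zip(coding, coding[1:])
            if b.start <= a.end
        ]
        assert overlaps == [("MT-ATP8", "MT-ATP6"), ("MT-ND4L", "MT-ND4")]


class TestTsTv:
    @pytest.mark.parametrize(
        ("ref", "alt", "expected"),
        [("G", "A", "transition"), ("A", "G", "transition"),
         ("C", "T", "transition"), ("T", "C", "transition"),
         ("C", "A", "transversion"), ("A", "C", "transversion"),
         ("A", "T", "transversion"), ("T", "A", "transversion"),
         ("G", "C", "transversion"), ("C", "G", "transversion"),
         ("G", "T", "transversion"), ("T", "G", "transversion")],
    )
    def test_all_ordered_pairs(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected
        # symmetry
        assert classify_substitution(alt, ref) == expected

    @pytest.mark.parametrize(("ref", "alt"), [("A", "A"), ("A", "N"),
                                              ("x", "G"), ("AG", "T")])
    def test_invalid_allele_pairs(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


class TestEffects:
    @pytest.mark.parametrize(
        ("position", "ref", "alt", "category", "protein_change"),
        [
            (9055, "G", "A", "non-synonymous", "p.Ala177Thr"),
            (3480, "A", "G", "synonymous", "p.Lys58="),
            (11299, "T", "C", "synonymous", "p.Thr180="),
            (14167, "C", "T", "synonymous", "p.Glu169="),  # light strand
            (3497, "C", "T", "non-synonymous", "p.Ala64Val"),
            (8836, "A", "G", "non-synonymous", "p.Met104Val"),
            (14831, "G", "A", "non-synonymous", "p.Ala29Thr"),
            (11778, "G", "A", "non-synonymous", "p.Arg340His"),
            (14484, "T", "C", "non-synonymous", "p.Met64Val"),
        ],
    )
    def test_documented_protein_changes(self, model, position, ref, alt,
                                        category, protein_change):
        call = annotate_effect(position, ref, alt, model)
        assert call.category == category
        assert call.protein_change == protein_change

    @pytest.mark.parametrize(
        ("position", "ref", "alt", "category"),
        [(73, "A", "G", "non-coding-change"),
         (709, "G", "A", "rna-change"),      # 12S rRNA
         (12308, "A", "G", "rna-change")],   # tRNA-Leu(CUN)
    )
    def test_noncoding_and_rna_calls(self, model, position, ref, alt, category):
        call = annotate_effect(position, ref, alt, model)
        assert call.category == category
        assert call.protein_change == ""

    def test_reference_mismatch_names_position_and_base(self, model):
        with pytest.raises(ReferenceMismatchError, match="9055"):
            annotate_effect(9055, "T", "C", model)

    def test_overlap_reports_both_reading_frames(self, model):
        calls = annotate_effect(8530, model.base(8530), "A"
                                if model.base(8530) != "A" else "G",
                                model, all_frames=True)
        assert {c.locus for c in calls} == {"MT-ATP8", "MT-ATP6"}

    @given(st.data())
    def test_codon_translation_matches_independent_code_table(self, model,
                                                              data):
        """Brute-force oracle: re-derive the affected codon from the gene
        coordinates and translate both alleles with Biopython's
        vertebrate-mitochondrial table."""
        genes = [g for g in refdata.GENES
                 if g[4] in CODING_REGIONS]
        name, start, end, strand, _ = data.draw(st.sampled_from(genes))
        n_codons = (end - start + 1) // 3
        codon_idx = data.draw(st.integers(1, n_codons))
        within = data.draw(st.integers(0, 2))
        if strand == "heavy":
            position = start + 3 * (codon_idx - 1) + within
            codon = model.sequence[start + 3 * (codon_idx - 1) - 1:
                                   start + 3 * (codon_idx - 1) + 2]
            ref = model.base(position)
            alt = data.draw(st.sampled_from(sorted(set("ACGT") - {ref})))
            alt_codon = codon[:within] + alt + codon[within + 1:]
        else:
            position = end - 3 * (codon_idx - 1) - within
            base0 = end - 3 * (codon_idx - 1)
            codon = "".join(COMPLEMENT[model.base(base0 - k)] for k in range(3))
            ref = model.base(position)
            alt = data.draw(st.sampled_from(sorted(set("ACGT") - {ref})))
            alt_codon = (codon[:within] + COMPLEMENT[alt] + codon[within + 1:])
        expected = ("synonymous"
                    if _bio_translate_codon(codon) == _bio_translate_codon(alt_codon)
                    else "non-synonymous")
        calls = annotate_effect(position, ref, alt, model, all_frames=True)
        call = next(c for c in calls if c.locus == name)
        assert call.category == expected
        assert call.codon_index == codon_idx

    def test_coding_genes_translate_without_internal_stops(self, model):
        for gene in ("MT-ND1", "MT-ND6", "MT-ATP6", "MT-CYB", "MT-CO1"):
            sense = model.gene_sense_sequence(gene)
            aa = "".join(
                _bio_translate_codon(sense[i:i + 3])
                for i in range(0, len(sense) - 2, 3)
            )
            assert "*" not in aa, gene


class TestModelLoading:
    def _write(self, tmp_path, annotation, sequence):
        ann = tmp_path / "genes.tsv"
        ann.write_text(annotation)
        fa = tmp_path / "ref.fasta"
        fa.write_text(">toy\n" + sequence + "\n")
        return ann, fa

    def test_toy_reference_roundtrip(self, tmp_path):
        ann, fa = self._write(
            tmp_path,
            "G1\t1\t9\theavy\tcomplexI\nCR\t10\t12\theavy\tnoncoding\n",
            "ATGCTACTAGGG",
        )
        model = load_gene_model(ann, fa)
        assert model.locate(5) == ("G1", "complexI")
        assert model.locate(11) == ("CR", "noncoding")

    def test_sequence_length_mismatch_is_fatal(self, tmp_path):
        ann, fa = self._write(
            tmp_path, "G1\t1\t9\theavy\tcomplexI\n", "ATGCTA")
        with pytest.raises(ValueError, match="length"):
            load_gene_model(ann, fa)

    def test_unexpected_coding_overlap_is_fatal(self, tmp_path):
        ann, fa = self._write(
            tmp_path,
            "G1\t1\t9\theavy\tcomplexI\nG2\t6\t11\theavy\tcomplexIII\n"
            "CR\t12\t12\theavy\tnoncoding\n",
            "ATGCTACTAGGG",
        )
        with pytest.raises(ValueError, match="overlap"):
            load_gene_model(ann, fa)

    def test_missing_strand_is_fatal(self, tmp_path):
        ann, fa = self._write(
            tmp_path, "G1\t1\t6\t.\tcomplexI\n", "ATGCTA")
        with pytest.raises(ValueError, match="strand"):
            load_gene_model(ann, fa)

    def test_packaged_files_match_programmatic_build(self, model):
        assert model.sequence == refdata.build_sequence()
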