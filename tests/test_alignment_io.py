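"""Alignment I/O, translation, haplotype collapsing and the
lineage-diagnostic substitution screen."""

import numpy as np
import pytest

from clonedelim.alignment_io import (
    Alignment, AlignmentError, LineagePartition, collapse_haplotypes,
    haplotype_alignment, lineage_specific_substitutions, mask_codon_position,
    read_alignment, translate, write_alignment,
)
from conftest import make_alignment, random_alignment


class TestReadWrite:
    def test_roundtrip_preserves_sequences(self, tmp_path):
        aln = make_alignment(["ACGTACGT" * 12, "TGCATGCA" * 12])
        path = tmp_path / "x.fasta"
        write_alignment(aln, path, wrap=80)
        back = read_alignment(path)
        assert back.sample_ids == aln.sample_ids
        assert back.sequences == aln.sequences

    def test_lowercase_normalised(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">s1\nacgt\n>s2\nACGT\n")
        aln = read_alignment(path)
        assert aln.sequences == ["ACGT", "ACGT"]

    def test_ragged_lengths_error_names_record(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text(">s1\nACGT\n>s2\nACGTA\n")
        with pytest.raises(AlignmentError, match="s2"):
            read_alignment(path)

    def test_empty_file_error(self, tmp_path):
        path = tmp_path / "x.fasta"
        path.write_text("")
        with pytest.raises(AlignmentError):
            read_alignment(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            make_alignment(["ACGT", "ACGT"], ids=["s1", "s1"])


class TestTranslate:
    @pytest.mark.parametrize("codon,code,aa", [
        ("ATG", "standard", "M"),
        ("ATA", "standard", "I"),
        ("ATA", "invertebrate_mito", "M"),   # AGA/ATA differ between tables
        ("AT-", "standard", "X"),
        ("ANG", "standard", "X"),
        ("TAA", "standard", "*"),
    ])
    def test_codon_translation(self, codon, code, aa):
        aln = make_alignment([codon], coding=True, genetic_code_id=code)
        assert translate(aln).sequences[0] == aa

    def test_trailing_partial_codon_dropped(self):
        aln = make_alignment(["ATGGC"], coding=True, genetic_code_id="standard")
        assert translate(aln).sequences[0] == "M"

    def test_frame_offset(self):
        aln = make_alignment(["CATGGC"], coding=True,
                             genetic_code_id="standard", frame_offset=1)
        assert translate(aln).sequences[0] == "M"

    def test_noncoding_error(self):
        aln = make_alignment(["ATG"])
        with pytest.raises(AlignmentError):
            translate(aln)


class TestHaplotypes:
    def test_identical_sequences_collapse(self):
        aln = make_alignment(["AAAA", "AAAA", "AAAA", "CCCC"])
        ht = collapse_haplotypes(aln)
        assert ht.n_haplotypes == 2
        assert sorted(len(m) for m in ht.members.values()) == [1, 3]

    def test_all_distinct(self):
        aln = make_alignment(["AAAA", "CCCC", "GGGG"])
        assert collapse_haplotypes(aln).n_haplotypes == 3

    def test_ambiguity_compared_literally(self):
        # N vs A at one position -> distinct haplotypes (strict identity)
        aln = make_alignment(["ANAA", "AAAA"])
        assert collapse_haplotypes(aln).n_haplotypes == 2

    def test_ids_ordered_by_first_occurrence(self):
        aln = make_alignment(["CCCC", "AAAA", "CCCC"])
        ht = collapse_haplotypes(aln)
        assert ht.haplotype_ids == ["H1", "H2"]
        assert ht.representative["H1"] == "CCCC"

    def test_collapse_idempotent_and_bounded(self, rng):
        aln = random_alignment(rng, n=10, L=50)
        ht = collapse_haplotypes(aln)
        assert ht.n_haplotypes <= aln.n
        again = collapse_haplotypes(haplotype_alignment(aln, ht))
        assert again.n_haplotypes == ht.n_haplotypes

    def test_protein_haplotypes_not_more_numerous(self, rng):
        # translation is many-to-one, so aa haplotypes <= nt haplotypes
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, size=30)) for _ in range(12)]
        aln = make_alignment(seqs, coding=True, genetic_code_id="standard")
        nt = collapse_haplotypes(aln).n_haplotypes
        aa = collapse_haplotypes(translate(aln)).n_haplotypes
        assert aa <= nt


class TestLineageSubstitutions:
    def test_fixed_difference_reported_both_directions(self, toy_coding,
                                                       toy_partition):
        rep = lineage_specific_substitutions(toy_coding, toy_partition)
        col6 = rep[rep.alignment_column == 6]
        assert set(col6.lineage) == {"A", "B"}
        a_row = col6[col6.lineage == "A"].iloc[0]
        assert a_row.diagnostic_state == "A"
        assert a_row.background_states == "G"

    def test_synonymous_third_position(self, toy_coding, toy_partition):
        rep = lineage_specific_substitutions(toy_coding, toy_partition)
        assert (rep[rep.alignment_column == 6].synonymy
                == "synonymous").all()

    def test_nonsynonymous_change(self):
        # ATG vs TTG: Met vs Leu at codon 1, first position
        aln = make_alignment(["ATGAAA", "ATGAAA", "TTGAAA", "TTGAAA"],
                             ids=["a1", "a2", "b1", "b2"],
                             coding=True, genetic_code_id="standard")
        part = LineagePartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = lineage_specific_substitutions(aln, part)
        assert (rep[rep.alignment_column == 1].synonymy
                == "non_synonymous").all()

    def test_polymorphic_column_not_reported(self):
        aln = make_alignment(["AAAA", "CAAA", "GAAA", "GAAA"],
                             ids=["a1", "a2", "b1", "b2"])
        part = LineagePartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rep = lineage_specific_substitutions(aln, part)
        # column 1 polymorphic within A -> only B's fixed G is diagnostic
        assert list(rep[rep.alignment_column == 1].lineage) == ["B"]

    def test_single_lineage_error(self):
        aln = make_alignment(["AAAA", "AAAA"])
        with pytest.raises(ValueError):
            lineage_specific_substitutions(
                aln, LineagePartition({"s1": "A", "s2": "A"}))

    def test_brute_force_diagnosticity_oracle(self, rng):
        aln = random_alignment(rng, n=9, L=120, p_gap=0.0)
        groups = {f"s{i+1}": ["A", "B", "C"][i % 3] for i in range(9)}
        part = LineagePartition(groups)
        rep = lineage_specific_substitutions(aln, part)
        # oracle: re-check every reported column directly on the raw strings
        for _, row in rep.iterrows():
            c = row.alignment_column - 1
            members = [s for s, g in groups.items() if g == row.lineage]
            others = [s for s in groups if groups[s] != row.lineage]
            mem_states = {aln.sequence_of(s)[c] for s in members}
            oth_states = {aln.sequence_of(s)[c] for s in others}
            assert mem_states == {row.diagnostic_state}
            assert row.diagnostic_state not in oth_states
        # and completeness: every diagnostic column is reported
        found = set(zip(rep.alignment_column, rep.lineage))
        for c in range(aln.length):
            for lin in "ABC":
                members = [s for s, g in groups.items() if g == lin]
                others = [s for s in groups if groups[s] != lin]
                mem = {aln.sequence_of(s)[c] for s in members}
                oth = {aln.sequence_of(s)[c] for s in others}
                if len(mem) == 1 and not (mem & oth):
                    assert (c + 1, lin) in found


class TestCodonMasking:
    def test_mask_third_positions(self, toy_coding):
        masked = mask_codon_position(toy_coding, 3)
        assert masked.length == 6
        assert masked.sequences[0] == "ATGGAA"[:6]  # cols 1,2,4,5,7,8

    def test_positions_partition_all_sites(self, toy_coding):
        lengths = [mask_codon_position(toy_coding, p).length for p in (1, 2, 3)]
        # each mask removes a disjoint third; union of removals is all sites
        assert sum(toy_coding.length - L for L in lengths) == toy_coding.length

    def test_709_column_count(self, rng):
        bases = np.array(list("ACGT"))
        aln = make_alignment(["".join(rng.choice(bases, size=709))],
                             coding=True, genetic_code_id="invertebrate_mito")
        masked = mask_codon_position(aln, 3)
        assert masked.length == 709 - 709 // 3  # 473 columns retained

    def test_noncoding_error(self):
        with pytest.raises(AlignmentError):
            mask_codon_position(make_alignment(["ACGTAC"]), 3)
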