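"""One-hot encoding of residues, peptides and MHC pseudo-sequences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoimm.alphabet import (
    AMINO_ALPHABET,
    Alphabet,
    AlleleFormatError,
    InvalidResidueError,
    MissingAlleleError,
    PeptideLengthError,
    PSEUDO_POSITIONS,
    decode_peptide,
    encode_allele,
    encode_peptide,
    encode_residue,
    normalize_allele_name,
)

STANDARD = "ACDEFGHIKLMNPQRSTVWY"

peptides = st.text(alphabet=STANDARD, min_size=8, max_size=11)


class TestAlphabet:
    def test_has_21_symbols_with_x_padding(self):
        a = Alphabet()
        assert a.size == 21
        assert a.symbols == AMINO_ALPHABET
        assert a.pad_symbol == "X"
        assert a.symbols[0] == "A"

    def test_rejects_malformed_alphabets(self):
        with pytest.raises(ValueError):
            Alphabet(symbols="ACDEFG")
        with pytest.raises(ValueError):
            Alphabet(symbols="A" * 21)
        with pytest.raises(ValueError):
            Alphabet(pad_symbol="Z")

    def test_pseudo_position_list_has_33_entries(self):
        assert len(PSEUDO_POSITIONS) == 33
        assert PSEUDO_POSITIONS[:4] == (79, 24, 45, 59)


class TestEncodeResidue:
    def test_alanine_is_first_basis_vector(self):
        expected = np.zeros(21)
        expected[0] = 1
        np.testing.assert_array_equal(encode_residue("A"), expected)

    def test_x_is_last_basis_vector(self):
        vec = encode_residue("X")
        assert vec[20] == 1 and vec.sum() == 1

    def test_unknown_residue_maps_to_pad(self):
        np.testing.assert_array_equal(encode_residue("B"), encode_residue("X"))
        np.testing.assert_array_equal(encode_residue("Z"), encode_residue("X"))

    @pytest.mark.parametrize("bad", ["", "AB"])
    def test_non_single_characters_rejected(self, bad):
        with pytest.raises(InvalidResidueError):
            encode_residue(bad)

    @given(st.sampled_from(AMINO_ALPHABET))
    def test_every_symbol_one_hot(self, residue):
        vec = encode_residue(residue)
        assert vec.sum() == 1
        assert vec[AMINO_ALPHABET.index(residue)] == 1


class TestEncodePeptide:
    def test_short_peptide_right_padding_option(self):
        mat = encode_peptide("AAAAAAAA", pad_side="right")
        assert mat.shape == (11, 21)
        a_vec, x_vec = encode_residue("A"), encode_residue("X")
        for row in range(8):
            np.testing.assert_array_equal(mat[row], a_vec)
        for row in range(8, 11):
            np.testing.assert_array_equal(mat[row], x_vec)

    def test_default_center_padding_fixes_both_anchors(self):
        """Peptide position 2 sits at row 1 and the C-terminal residue at
        row 10 for every supported length."""
        for length in range(8, 12):
            pep = "A" + "C" + "D" * (length - 3) + "W"
            mat = encode_peptide(pep)
            assert mat[1].argmax() == AMINO_ALPHABET.index("C")
            assert mat[10].argmax() == AMINO_ALPHABET.index("W")

    def test_full_length_peptide_has_no_padding(self):
        mat = encode_peptide("SIINFEKLQRW")
        assert not np.any(mat[:, 20])

    @pytest.mark.parametrize("bad", ["AAAA", "A" * 12, ""])
    def test_length_errors_name_the_peptide(self, bad):
        with pytest.raises(PeptideLengthError):
            encode_peptide(bad)

    @given(peptides)
    @settings(max_examples=200, deadline=None)
    def test_rows_are_one_hot_and_shape_constant(self, pep):
        mat = encode_peptide(pep)
        assert mat.shape == (11, 21)
        np.testing.assert_array_equal(mat.sum(axis=1), np.ones(11))

    @given(peptides)
    @settings(max_examples=200, deadline=None)
    def test_argmax_decoding_round_trips(self, pep):
        assert decode_peptide(encode_peptide(pep)) == pep

    @given(st.tuples(peptides, peptides))
    @settings(max_examples=200, deadline=None)
    def test_injective_on_standard_residue_peptides(self, pair):
        p, q = pair
        if p != q:
            assert not np.array_equal(encode_peptide(p), encode_peptide(q))

    def test_center_padding_splits_pads(self):
        mat = encode_peptide("CCCCDDDD", pad_side="center")
        x_rows = np.where(mat[:, 20])[0]
        np.testing.assert_array_equal(x_rows, [4, 5, 6])


class TestNormalizeAlleleName:
    @pytest.mark.parametrize("raw,expected", [
        ("HLA-A*02:01:01", "HLA-A*02:01"),
        ("HLA-A*02:01", "HLA-A*02:01"),
        ("HLA-A02:01", "HLA-A*02:01"),
        ("A0201", "HLA-A*02:01"),
        ("a*02:01", "HLA-A*02:01"),
        ("HLA-B*44:02:01:03", "HLA-B*44:02"),
        ("B4402", "HLA-B*44:02"),
    ])
    def test_normalizes_to_four_digit_form(self, raw, expected):
        assert normalize_allele_name(raw) == expected

    def test_idempotent(self):
        once = normalize_allele_name("A0201")
        assert normalize_allele_name(once) == once

    @pytest.mark.parametrize("bad", ["", "HLA-A2", "notanallele", "02:01"])
    def test_unparseable_names_rejected(self, bad):
        with pytest.raises(AlleleFormatError):
            normalize_allele_name(bad)


class TestEncodeAllele:
    def test_uniform_pseudo_sequence(self, pseudo_table):
        mat = encode_allele("HLA-A*02:01", pseudo_table)
        assert mat.shape == (33, 21)
        np.testing.assert_array_equal(mat, np.tile(encode_residue("A"), (33, 1)))

    def test_name_normalization_equivalence(self, pseudo_table):
        np.testing.assert_array_equal(
            encode_allele("HLA-B07:02", pseudo_table),
            encode_allele("HLA-B*07:02", pseudo_table),
        )

    def test_missing_allele_reports_normalized_query(self, pseudo_table):
        with pytest.raises(MissingAlleleError, match=r"HLA-Z\*99:99"):
            encode_allele("HLA-Z*99:99", pseudo_table)


class TestPseudoSequenceTableIO:
    def test_file_round_trip(self, pseudo_table, tmp_path):
        path = tmp_path / "pseudo.dat"
        pseudo_table.to_file(path)
        loaded = type(pseudo_table).from_file(path)
        assert loaded.entries == pseudo_table.entries

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "pseudo.dat"
        path.write_text("# comment\n\nHLA-A*02:01\t" + "C" * 33 + "\n")
        table = type(self).load(path)
        assert table.lookup("A0201") == "C" * 33

    @staticmethod
    def load(path):
        from neoimm.alphabet import PseudoSequenceTable
        return PseudoSequenceTable.from_file(path)
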