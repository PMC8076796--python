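"""Variant application, window enumeration and long-peptide geometry.

Window counts are checked against a brute-force oracle that enumerates
every substring of every configured length and keeps those overlapping
the mutated span.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscreen import (
    MhcClass,
    PipelineConfig,
    ProteinRecord,
    SomaticVariant,
    ValidationError,
    VariantKind,
    apply_variant,
    enumerate_windows,
    make_long_peptide,
)
from neoscreen.io import AMINO_ACIDS
from neoscreen.simulate import load_vaccine_panel, panel_wildtype_27mer


def brute_force_windows(sequence: str, span: tuple[int, int], lengths) -> set[str]:
    """Independent enumeration: all full-length substrings overlapping span."""
    a, b = span
    out = set()
    for length in lengths:
        for start in range(1, len(sequence) - length + 2):
            end = start + length - 1
            if start <= b and end >= a:
                out.add(sequence[start - 1 : end])
    return out


def snv_at(protein: ProteinRecord, pos: int, vaf=0.5) -> SomaticVariant:
    wt = protein.residue(pos)
    alt = next(a for a in AMINO_ACIDS if a != wt)
    return SomaticVariant(gene=protein.gene, protein_id=protein.id,
                          kind=VariantKind.SNV, position=pos, wt=wt, alt=alt, vaf=vaf)


class TestApplyVariant:
    def test_published_substitution_reproduces_printed_mutant(self, toy_protein, toy_snv):
        mutant = apply_variant(toy_protein, toy_snv)
        assert mutant.sequence == "QTDVGGSGLSRLDISVIFEALATGCTS"
        assert mutant.mutated_span == (14, 14)

    def test_frameshift_truncates_and_appends_tail(self):
        protein = ProteinRecord("p", "G", "MKLVAAAA")
        fs = SomaticVariant(gene="G", protein_id="p", kind=VariantKind.FRAMESHIFT,
                            position=5, wt="", alt="RW", vaf=0.5)
        mutant = apply_variant(protein, fs)
        assert mutant.sequence == "MKLVRW"
        assert mutant.mutated_span == (5, 6)

    def test_inframe_insertion_after_position(self):
        protein = ProteinRecord("p", "G", "MKLVAAAA")
        ins = SomaticVariant(gene="G", protein_id="p", kind=VariantKind.INFRAME_INS,
                             position=3, wt="", alt="QQ", vaf=0.5)
        mutant = apply_variant(protein, ins)
        assert mutant.sequence == "MKLQQVAAAA"
        assert mutant.mutated_span == (4, 5)

    def test_inframe_deletion_removes_segment(self):
        protein = ProteinRecord("p", "G", "MKLVAAAA")
        dele = SomaticVariant(gene="G", protein_id="p", kind=VariantKind.INFRAME_DEL,
                              position=3, wt="LV", alt="", vaf=0.5)
        mutant = apply_variant(protein, dele)
        assert mutant.sequence == "MKAAAA"
        assert mutant.mutated_span == (2, 3)  # junction residue pair

    def test_wt_mismatch_rejected(self, toy_protein):
        bad = SomaticVariant(gene="ACAD8", protein_id="ACAD8_toy",
                             kind=VariantKind.SNV, position=15, wt="T", alt="I", vaf=0.5)
        with pytest.raises(ValidationError, match="expected"):
            apply_variant(toy_protein, bad)


class TestEnumerateWindows:
    @pytest.mark.parametrize("mhc_class,expected", [
        (MhcClass.I, 38),   # 8+9+10+11 windows around an interior site
        (MhcClass.II, 54),  # 12+13+14+15
    ])
    def test_interior_snv_window_counts(self, mhc_class, expected):
        rng = np.random.default_rng(0)
        protein = ProteinRecord("p", "G", "".join(rng.choice(list(AMINO_ACIDS), size=200)))
        windows = enumerate_windows(apply_variant(protein, snv_at(protein, 50)), mhc_class)
        assert len(windows) == expected

    def test_terminal_snv_emits_one_start_per_length(self):
        rng = np.random.default_rng(1)
        protein = ProteinRecord("p", "G", "".join(rng.choice(list(AMINO_ACIDS), size=200)))
        windows = enumerate_windows(apply_variant(protein, snv_at(protein, 1)), MhcClass.I)
        assert len(windows) == 4

    def test_every_window_contains_a_mutated_position(self):
        rng = np.random.default_rng(2)
        protein = ProteinRecord("p", "G", "".join(rng.choice(list(AMINO_ACIDS), size=80)))
        mutant = apply_variant(protein, snv_at(protein, 40))
        for w in enumerate_windows(mutant, MhcClass.I):
            assert w.mutation_offset
            assert w.wt_sequence != w.sequence
            assert len(w.wt_sequence) == len(w.sequence)
            # the recorded offsets point at the changed residues
            diffs = {i + 1 for i, (a, b) in enumerate(zip(w.sequence, w.wt_sequence)) if a != b}
            assert diffs == set(w.mutation_offset)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        pos=st.integers(min_value=1, max_value=60),
        length_seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_counts_match_brute_force_oracle(self, pos, length_seed):
        rng = np.random.default_rng(length_seed)
        protein = ProteinRecord("p", "G", "".join(rng.choice(list(AMINO_ACIDS), size=60)))
        mutant = apply_variant(protein, snv_at(protein, pos))
        for mhc_class, lengths in [(MhcClass.I, (8, 9, 10, 11)),
                                   (MhcClass.II, (12, 13, 14, 15))]:
            expected = brute_force_windows(mutant.sequence, mutant.mutated_span, lengths)
            got = {w.sequence for w in enumerate_windows(mutant, mhc_class)}
            assert got == expected

    def test_frameshift_windows_have_no_wildtype_pairing(self):
        protein = ProteinRecord("p", "G", "MKLVAAAAKLMNPQRSTVWY")
        fs = SomaticVariant(gene="G", protein_id="p", kind=VariantKind.FRAMESHIFT,
                            position=10, wt="", alt="GVRWGVRWGVRW", vaf=0.5)
        mutant = apply_variant(protein, fs)
        windows = enumerate_windows(mutant, MhcClass.I)
        assert windows
        assert all(w.wt_sequence is None for w in windows)
        expected = brute_force_windows(mutant.sequence, mutant.mutated_span, (8, 9, 10, 11))
        assert {w.sequence for w in windows} == expected

    def test_ultra_short_protein_yields_empty_result(self):
        protein = ProteinRecord("p", "G", "MKLVA")
        assert enumerate_windows(apply_variant(protein, snv_at(protein, 3)), MhcClass.I) == []


class TestLongPeptide:
    def test_interior_snv_gives_centered_27mer(self):
        rng = np.random.default_rng(3)
        protein = ProteinRecord("p", "G", "".join(rng.choice(list(AMINO_ACIDS), size=150)))
        lp = make_long_peptide(protein, snv_at(protein, 105))
        assert len(lp.sequence) == 27
        assert lp.mutation_offset == 14

    @pytest.mark.parametrize("pos", list(range(1, 61)))
    def test_length_formula_near_termini(self, pos):
        rng = np.random.default_rng(4)
        protein = ProteinRecord("p", "G", "".join(rng.choice(list(AMINO_ACIDS), size=60)))
        lp = make_long_peptide(protein, snv_at(protein, pos))
        expected_len = min(pos - 1, 13) + 1 + min(60 - pos, 13)
        assert len(lp.sequence) == expected_len
        assert len(lp.sequence) <= 27
        assert lp.mutation_offset == min(pos - 1, 13) + 1
        # the mutated residue sits at the stated offset
        assert lp.sequence[lp.mutation_offset - 1] == lp.source_variant.alt

    def test_protein_of_exactly_27_with_central_snv_is_whole_protein(self, toy_protein, toy_snv):
        lp = make_long_peptide(toy_protein, toy_snv)
        assert lp.sequence == "QTDVGGSGLSRLDISVIFEALATGCTS"
        assert lp.mutation_offset == 14


class TestPublishedPanel:
    """The 30 published 27-aa vaccine peptides as worked examples."""

    def test_all_rows_reconstruct_exactly(self):
        panel = load_vaccine_panel()
        assert len(panel) == 30
        for row in panel.itertuples(index=False):
            assert len(row.mutated_sequence) == 27
            wt27 = panel_wildtype_27mer(row)
            protein = ProteinRecord(id=row.gene, gene=row.gene, sequence=wt27)
            variant = SomaticVariant(
                gene=row.gene, protein_id=row.gene, kind=VariantKind.SNV,
                position=14, wt=row.wt_residue, alt=row.mut_residue, vaf=0.5,
            )
            mutant = apply_variant(protein, variant)
            assert mutant.sequence == row.mutated_sequence
            mismatches = sum(a != b for a, b in zip(wt27, row.mutated_sequence))
            assert mismatches == 1
            lp = make_long_peptide(protein, variant)
            assert lp.sequence == row.mutated_sequence
            assert lp.mutation_offset == 14
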