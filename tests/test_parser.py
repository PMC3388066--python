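import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from znfarray.parser import (
    ContactOffsetError,
    InvalidRepeatError,
    MalformedArrayError,
    ScaffoldNotFoundError,
    ZnfRepeat,
    extract_contact_residues,
    locate_scaffold,
    parse_allele,
    split_into_repeats,
    translate_repeats,
    validate_array,
)
from znfarray.simulate import TEMPLATE_AA, TEMPLATE_NT

# Independent standard-genetic-code oracle, hand-transcribed.
_ORACLE_CODE = {}
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"
_i = 0
for b1 in _BASES:
    for b2 in _BASES:
        for b3 in _BASES:
            _ORACLE_CODE[b1 + b2 + b3] = _AA[_i]
            _i += 1


def oracle_translate(nt):
    return "".join(_ORACLE_CODE[nt[i : i + 3]] for i in range(0, len(nt), 3))


class TestSplitIntoRepeats:
    def test_seven_units(self):
        reps = split_into_repeats(TEMPLATE_NT * 7)
        assert len(reps) == 7
        assert all(len(r.nt_seq) == 84 for r in reps)

    def test_single_unit_round_trip(self):
        (rep,) = split_into_repeats(TEMPLATE_NT)
        assert rep.nt_seq == TEMPLATE_NT
        assert rep.index_in_array == 0 and not rep.is_truncated

    def test_order_preserved(self, rng):
        # five distinct units concatenated in a known order
        units = []
        for k in range(5):
            bases = rng.choice(list("ACGT"), size=84)
            units.append("".join(bases))
        reps = split_into_repeats("".join(units))
        assert [r.nt_seq for r in reps] == units
        assert [r.index_in_array for r in reps] == list(range(5))

    def test_truncated_leading_segment(self):
        lead = TEMPLATE_NT[-57:]
        reps = split_into_repeats(lead + TEMPLATE_NT * 3, leading_truncated=True)
        assert reps[0].is_truncated and reps[0].nt_seq == lead
        assert len([r for r in reps if not r.is_truncated]) == 3

    def test_bad_length_carries_remainder(self):
        with pytest.raises(MalformedArrayError) as exc:
            split_into_repeats(TEMPLATE_NT + "ACGT")
        assert exc.value.remainder == 4

    def test_truncated_flag_with_exact_multiple_is_error(self):
        with pytest.raises(MalformedArrayError):
            split_into_repeats(TEMPLATE_NT * 2, leading_truncated=True)

    @given(st.integers(1, 6), st.integers(0, 83), st.data())
    @settings(max_examples=30, deadline=None)
    def test_round_trip_property(self, k, lead_len, data):
        body = data.draw(
            st.text(alphabet="ACGT", min_size=84 * k, max_size=84 * k)
        )
        if lead_len:
            lead = data.draw(st.text(alphabet="ACGT", min_size=lead_len, max_size=lead_len))
            reps = split_into_repeats(lead + body, leading_truncated=True)
            assert "".join(r.nt_seq for r in reps) == lead + body
        else:
            reps = split_into_repeats(body)
            assert "".join(r.nt_seq for r in reps) == body
        assert len([r for r in reps if not r.is_truncated]) == k


class TestTranslateRepeats:
    def test_all_alanine(self):
        (rep,) = translate_repeats([ZnfRepeat(0, "GCT" * 28)])
        assert rep.aa_seq == "A" * 28

    def test_stop_codon_names_repeat(self):
        bad = TEMPLATE_NT[:42] + "TAA" + TEMPLATE_NT[45:]
        with pytest.raises(InvalidRepeatError) as exc:
            translate_repeats([ZnfRepeat(0, TEMPLATE_NT), ZnfRepeat(1, bad)])
        assert exc.value.repeat_index == 1

    def test_out_of_frame(self):
        with pytest.raises(InvalidRepeatError):
            translate_repeats([ZnfRepeat(0, "ACGTA")])

    @given(st.text(alphabet="ACGT", min_size=84, max_size=84))
    @settings(max_examples=50, deadline=None)
    def test_matches_lookup_table_oracle(self, nt):
        expected = oracle_translate(nt)
        if "*" in expected:
            with pytest.raises(InvalidRepeatError):
                translate_repeats([ZnfRepeat(0, nt)])
        else:
            (rep,) = translate_repeats([ZnfRepeat(0, nt)])
            assert rep.aa_seq == expected
            assert len(rep.aa_seq) == 28


class TestScaffold:
    def test_template_positions(self):
        sc = locate_scaffold(TEMPLATE_AA)
        assert (sc.cys1, sc.cys2, sc.his1, sc.his2) == (7, 10, 23, 27)

    def test_constructed_offsets(self):
        # C at 4 and 7, H at 20 and 24, spacing within the default pattern
        aa = "AAAA" + "C" + "AA" + "C" + "A" * 12 + "H" + "AAA" + "H" + "AAA"
        sc = locate_scaffold(aa)
        assert (sc.cys1, sc.cys2, sc.his1, sc.his2) == (4, 7, 20, 24)

    def test_truncated_reports_cys1_absent(self):
        truncated = TEMPLATE_AA[9:]  # drops the first cysteine
        sc = locate_scaffold(truncated, truncated=True)
        assert sc.cys1 is None
        assert truncated[sc.cys2] == "C"

    def test_no_histidine_fails(self):
        with pytest.raises(ScaffoldNotFoundError):
            locate_scaffold("ACDEFGACDEFGACDEFGACDEFGACDE")


class TestContactResidues:
    def test_template_contacts(self):
        sc = locate_scaffold(TEMPLATE_AA)
        cr = extract_contact_residues(TEMPLATE_AA, sc)
        assert cr.pos2 == "S"
        assert cr.triplet == (TEMPLATE_AA[16], TEMPLATE_AA[19], TEMPLATE_AA[22])

    def test_planted_residues_returned(self):
        aa = list(TEMPLATE_AA)
        aa[16], aa[19], aa[22] = "R", "D", "N"
        aa = "".join(aa)
        cr = extract_contact_residues(aa, locate_scaffold(aa))
        assert cr.triplet == ("R", "D", "N")

    def test_invariant_outside_contacts(self):
        aa = list(TEMPLATE_AA)
        aa[0], aa[13] = "M", "V"  # non-contact columns
        aa = "".join(aa)
        base = extract_contact_residues(TEMPLATE_AA, locate_scaffold(TEMPLATE_AA))
        changed = extract_contact_residues(aa, locate_scaffold(aa))
        assert base == changed

    def test_out_of_range_offset(self):
        sc = locate_scaffold(TEMPLATE_AA)
        with pytest.raises(ContactOffsetError):
            extract_contact_residues(TEMPLATE_AA, sc, {"pos_minus1": -40})

    def test_fixed_serine_across_library(self, small_library):
        for aa in small_library.repeats_aa:
            cr = extract_contact_residues(aa, locate_scaffold(aa))
            assert cr.pos2 == "S"


class TestValidateArray:
    def test_clean_allele(self):
        allele = parse_allele("ok", TEMPLATE_NT * 7)
        assert validate_array(allele).ok

    def test_ambiguity_flagged(self):
        seq = "R" + TEMPLATE_NT[1:] + TEMPLATE_NT * 6
        allele = parse_allele("amb", seq, translate=False)
        report = validate_array(allele)
        assert not report.usable_for_catalog
        assert any(i.kind == "ambiguity" for i in report.issues)

    def test_one_broken_repeat_one_issue(self):
        broken = TEMPLATE_NT[:69] + "GCT" + TEMPLATE_NT[72:]  # his1 -> Ala
        assert oracle_translate(broken)[23] != "H"
        seq = TEMPLATE_NT * 3 + broken + TEMPLATE_NT * 3
        allele = parse_allele("broke", seq, translate=False)
        report = validate_array(allele)
        assert len(report.issues) == 1
        assert report.issues[0].kind == "scaffold"
        assert report.issues[0].repeat_index == 3


def test_full_repeats_always_28_residues(small_library):
    for nt in small_library.repeats_nt:
        (rep,) = translate_repeats([ZnfRepeat(0, nt)])
        assert len(rep.aa_seq) == 28


def test_parse_allele_sequence_round_trip():
    seq = TEMPLATE_NT[-30:] + TEMPLATE_NT * 4
    allele = parse_allele("a", seq, leading_truncated=True)
    assert allele.sequence == seq
    assert allele.n_full_repeats == 4
    assert allele.leading_truncated_present
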