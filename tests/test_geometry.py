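"""Pair offset, nick sites, overhang polarity and efficacy windows."""

import numpy as np
import pytest

from nickpair.geometry import (
    GuidePair,
    Orientation,
    OverhangKind,
    SameStrandError,
    classify_efficacy,
    nick_site,
    overhang,
    pair_offset,
)
from nickpair.locus import Guide, MINUS, NickaseVariant, PLUS

from conftest import pair_at_offset, reflect_guide

D10A = NickaseVariant.D10A
H840A = NickaseVariant.H840A
WT = NickaseVariant.WT


def _guide(strand, start, name="g"):
    """A bare located guide; geometry uses only strand and footprint."""
    return Guide(name, "A" * 20, strand, start, "AGG")


class TestPairOffset:
    @pytest.mark.parametrize(
        "other, expected",
        [("white-R", -15), ("white-H", -5), ("white-I", 6), ("white-C", 7)],
    )
    def test_printed_offsets_on_minilocus(self, minilocus, other, expected):
        d = minilocus.guides["white-D"]
        assert pair_offset(d, minilocus.guides[other]) == expected

    def test_abutting_footprints_zero_offset(self):
        assert pair_offset(_guide(PLUS, 20), _guide(MINUS, 0)) == 0

    def test_symmetry_over_random_placements(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            a = _guide(PLUS, int(rng.integers(0, 500)))
            b = _guide(MINUS, int(rng.integers(0, 500)))
            assert pair_offset(a, b) == pair_offset(b, a)

    def test_same_strand_undefined(self):
        with pytest.raises(SameStrandError):
            pair_offset(_guide(PLUS, 0), _guide(PLUS, 40))

    def test_same_strand_pair_flagged(self):
        pair = GuidePair(_guide(PLUS, 0, "a"), _guide(PLUS, 40, "b"))
        assert pair.orientation is Orientation.SAME_STRAND and pair.offset is None


class TestNickSite:
    def test_plus_guide_d10a_nicks_opposite_strand(self):
        ns = nick_site(_guide(PLUS, 100), D10A)
        assert (ns.strand, ns.boundary) == (MINUS, 117)

    def test_plus_guide_h840a_nicks_protospacer_strand(self):
        ns = nick_site(_guide(PLUS, 100), H840A)
        assert (ns.strand, ns.boundary) == (PLUS, 117)

    def test_minus_guide_boundaries(self):
        assert nick_site(_guide(MINUS, 100), D10A).boundary == 103
        assert nick_site(_guide(MINUS, 100), D10A).strand == PLUS

    def test_wt_blunt_pair(self):
        plus_nick, minus_nick = nick_site(_guide(PLUS, 100), WT)
        assert plus_nick.boundary == minus_nick.boundary == 117
        assert {plus_nick.strand, minus_nick.strand} == {PLUS, MINUS}


class TestOverhang:
    def test_white_d_r_five_prime_19(self, minilocus):
        oh = overhang(minilocus.guides["white-D"], minilocus.guides["white-R"], D10A)
        assert (oh.kind, oh.length) == (OverhangKind.FIVE_PRIME, 19)

    def test_offset_minus35_h840a_five_prime_1(self):
        # the geometry of the offset -35 pair from the H840A screen
        res = pair_at_offset(-35, np.random.default_rng(3))
        assert res is not None
        _, plus, minus = res
        oh = overhang(plus, minus, H840A)
        assert (oh.kind, oh.length) == (OverhangKind.FIVE_PRIME, 1)

    def test_offset_minus34_blunt(self):
        res = pair_at_offset(-34, np.random.default_rng(4))
        _, plus, minus = res
        oh = overhang(plus, minus, D10A)
        assert (oh.kind, oh.length) == (OverhangKind.BLUNT, 0)

    def test_same_strand_none(self):
        oh = overhang(_guide(PLUS, 0, "a"), _guide(PLUS, 50, "b"), D10A)
        assert (oh.kind, oh.length) == (OverhangKind.NONE, 0)

    def test_wt_rejected(self):
        with pytest.raises(ValueError, match="blunt"):
            overhang(_guide(PLUS, 0, "a"), _guide(MINUS, 40, "b"), WT)

    def test_closed_form_duality_and_rc_invariance_sweep(self):
        """Exhaustive sweep over offsets -100..100 on synthetic loci.

        Checks three properties at once: the |offset+34| closed form for
        D10A (5' overhang iff offset+34 > 0), D10A/H840A duality (equal
        length, swapped polarity, blunt fixed), and invariance of offset,
        overhang and efficacy under reverse-complementing the locus.
        """
        rng = np.random.default_rng(5)
        tested = 0
        for off in range(-100, 101):
            res = pair_at_offset(off, rng)
            if res is None:
                assert off in (-45, -44, -43)  # PAM constraints collide
                continue
            locus, plus, minus = res
            assert pair_offset(plus, minus) == off
            oh_d = overhang(plus, minus, D10A)
            oh_h = overhang(plus, minus, H840A)
            # closed form
            if off + 34 > 0:
                assert (oh_d.kind, oh_d.length) == (OverhangKind.FIVE_PRIME, off + 34)
            elif off + 34 < 0:
                assert (oh_d.kind, oh_d.length) == (OverhangKind.THREE_PRIME, -(off + 34))
            else:
                assert oh_d.kind is OverhangKind.BLUNT
            # duality
            assert oh_d.length == oh_h.length
            expected_dual = {
                OverhangKind.FIVE_PRIME: OverhangKind.THREE_PRIME,
                OverhangKind.THREE_PRIME: OverhangKind.FIVE_PRIME,
                OverhangKind.BLUNT: OverhangKind.BLUNT,
            }[oh_d.kind]
            assert oh_h.kind is expected_dual
            # reverse-complement frame
            rplus, rminus = reflect_guide(plus, locus), reflect_guide(minus, locus)
            assert pair_offset(rplus, rminus) == off
            for v in (D10A, H840A):
                assert overhang(rplus, rminus, v) == overhang(plus, minus, v)
                assert (
                    classify_efficacy(rplus, rminus, v).effective
                    == classify_efficacy(plus, minus, v).effective
                )
            tested += 1
        assert tested == 198


class TestEfficacy:
    def test_offset7_d10a_effective(self, minilocus):
        call = classify_efficacy(minilocus.guides["white-D"], minilocus.guides["white-C"], D10A)
        assert call.effective

    def test_offset_minus15_d10a_not_effective(self, minilocus):
        call = classify_efficacy(minilocus.guides["white-D"], minilocus.guides["white-R"], D10A)
        assert not call.effective and "window" in call.reason

    def test_offset_minus35_h840a_effective(self):
        _, plus, minus = pair_at_offset(-35, np.random.default_rng(6))
        assert classify_efficacy(plus, minus, H840A).effective

    def test_same_strand_not_effective(self):
        call = classify_efficacy(_guide(PLUS, 0, "a"), _guide(PLUS, 60, "b"), D10A)
        assert not call.effective and "same-strand" in call.reason

    def test_windows_configurable(self):
        _, plus, minus = pair_at_offset(7, np.random.default_rng(7))
        assert not classify_efficacy(plus, minus, D10A, d10a_window=(10, 26)).effective

    def test_orientation_of_outward_overlapping_pair(self, minilocus):
        # overlapping footprints with outward PAMs still classify pam_out
        pair = GuidePair(minilocus.guides["white-D"], minilocus.guides["white-R"])
        assert pair.orientation is Orientation.PAM_OUT and pair.offset == -15
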