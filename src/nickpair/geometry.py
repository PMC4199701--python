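"""Paired-guide geometry: offset, nick sites, overhang, efficacy.

The offset between two guides on opposite strands is measured between
their PAM-distal (5') protospacer ends.  In the plus-strand half-open
frame this collapses to a single formula::

    offset = start(plus-strand guide) - end(minus-strand guide)

A positive offset means the PAM-distal ends are separated with
outward-facing PAMs; a negative offset means the footprints overlap or
the PAMs face inward.  Same-strand pairs have no offset.

Cas9 cuts 3 bp PAM-proximal inside the protospacer (between protospacer
positions 17 and 18 counted from the PAM-distal end).  The cut register
is the canonical SpCas9 value and is exposed as a module constant.  With
a nickase, which strand is cut depends on the variant: D10A (RuvC dead)
nicks the strand the sgRNA base-pairs with — the opposite of the
protospacer strand; H840A (HNH dead) nicks the protospacer strand; WT
cuts both at the same boundary, a blunt DSB.

Two nicks on opposite strands leave an overhang whose polarity follows
the nick order: a 5' overhang when the plus-strand nick lies left of the
minus-strand nick.  For an opposite-strand pair under D10A the closed
form is length ``|offset + 34|`` with a 5' overhang iff ``offset + 34 > 0``;
H840A swaps the polarity at the same length.  Heritable mutagenesis in
the fly germline requires a 5' overhang and an offset inside an
empirically effective window (defaults below).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .locus import MINUS, PLUS, Guide, NickaseVariant

#: Cut boundary distance from the PAM-proximal protospacer edge (bp).
CUT_REGISTER = 3

#: Empirically effective offset windows (inclusive), per nickase variant.
D10A_WINDOW = (-1, 26)
H840A_WINDOW = (-88, -35)


class Orientation(str, Enum):
    PAM_OUT = "pam_out"
    PAM_IN = "pam_in"
    SAME_STRAND = "same_strand"


class OverhangKind(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"
    BLUNT = "blunt"
    NONE = "none"  # both nicks on one strand: no DSB


class SameStrandError(ValueError):
    """Offset is undefined for a same-strand guide pair."""


@dataclass(frozen=True)
class NickSite:
    """A single-strand cut between plus-strand positions boundary-1 and boundary."""

    strand: str
    boundary: int


@dataclass(frozen=True)
class Overhang:
    kind: OverhangKind
    length: int


@dataclass(frozen=True)
class EfficacyCall:
    effective: bool
    reason: str


def _split_strands(a: Guide, b: Guide) -> tuple[Guide, Guide]:
    """Return (plus-strand guide, minus-strand guide) or raise SameStrandError."""
    if a.strand == b.strand:
        raise SameStrandError("offset undefined for same-strand pair")
    return (a, b) if a.strand == PLUS else (b, a)


def pair_offset(a: Guide, b: Guide) -> int:
    """Signed PAM-distal offset of an opposite-strand guide pair (bp).

    Symmetric in argument order.  Raises :class:`SameStrandError` for
    same-strand pairs.
    """
    plus, minus = _split_strands(a, b)
    return plus.start - minus.end


def orientation(a: Guide, b: Guide) -> Orientation:
    if a.strand == b.strand:
        return Orientation.SAME_STRAND
    plus, minus = _split_strands(a, b)
    # plus guide's PAM sits right of its footprint, minus guide's PAM left
    # of its footprint; PAMs face outward when the plus PAM lies right of
    # the minus PAM.
    if plus.start + 21 > minus.start - 2:
        return Orientation.PAM_OUT
    return Orientation.PAM_IN


def nick_site(g: Guide, v: NickaseVariant) -> NickSite | tuple[NickSite, NickSite]:
    """Cut site(s) of a located guide under a Cas9 variant.

    Returns one :class:`NickSite` for a nickase, or a pair (both strands,
    same boundary — a blunt DSB) for WT.
    """
    if g.strand == PLUS:
        boundary = g.end - CUT_REGISTER
        proto_strand, other_strand = PLUS, MINUS
    else:
        boundary = g.start + CUT_REGISTER
        proto_strand, other_strand = MINUS, PLUS
    if v is NickaseVariant.WT:
        return (NickSite(PLUS, boundary), NickSite(MINUS, boundary))
    if v is NickaseVariant.D10A:
        return NickSite(other_strand, boundary)
    return NickSite(proto_strand, boundary)


def overhang(a: Guide, b: Guide, v: NickaseVariant) -> Overhang:
    """Overhang left by the two nicks of a guide pair under a nickase.

    Polarity follows nick order on the two strands; both nicks on one
    strand yield kind ``none`` (no DSB).  WT is rejected — its DSB is
    blunt by construction, see :func:`nick_site`.
    """
    if v is NickaseVariant.WT:
        raise ValueError("overhang is for nickases; WT gives a blunt DSB (use nick_site)")
    na = nick_site(a, v)
    nb = nick_site(b, v)
    assert isinstance(na, NickSite) and isinstance(nb, NickSite)
    if na.strand == nb.strand:
        return Overhang(OverhangKind.NONE, 0)
    plus_nick = na if na.strand == PLUS else nb
    minus_nick = nb if na.strand == PLUS else na
    delta = minus_nick.boundary - plus_nick.boundary
    if delta > 0:
        return Overhang(OverhangKind.FIVE_PRIME, delta)
    if delta < 0:
        return Overhang(OverhangKind.THREE_PRIME, -delta)
    return Overhang(OverhangKind.BLUNT, 0)


def classify_efficacy(
    a: Guide,
    b: Guide,
    v: NickaseVariant,
    d10a_window: tuple[int, int] = D10A_WINDOW,
    h840a_window: tuple[int, int] = H840A_WINDOW,
) -> EfficacyCall:
    """Is this pair expected to generate heritable mutants with this nickase?

    Effective iff the pair leaves a 5' overhang and its offset falls in
    the variant's empirical window.  Window bounds are configurable.
    """
    if v is NickaseVariant.WT:
        return EfficacyCall(True, "WT Cas9 generates a blunt DSB at any single target")
    if a.strand == b.strand:
        return EfficacyCall(False, "same-strand pair: single nicked strand, no DSB")
    off = pair_offset(a, b)
    oh = overhang(a, b, v)
    if oh.kind is not OverhangKind.FIVE_PRIME:
        return EfficacyCall(False, f"overhang is {oh.kind.value}, not five_prime")
    lo, hi = d10a_window if v is NickaseVariant.D10A else h840a_window
    if not lo <= off <= hi:
        return EfficacyCall(False, f"offset {off} outside effective window [{lo}, {hi}]")
    return EfficacyCall(True, f"five_prime overhang, offset {off} in [{lo}, {hi}]")


@dataclass(frozen=True)
class GuidePair:
    """Two guides on one locus with derived geometry.

    ``offset`` is None for same-strand pairs (reported as NA).
    """

    guide_a: Guide
    guide_b: Guide
    orientation: Orientation = field(init=False)
    offset: int | None = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "orientation", orientation(self.guide_a, self.guide_b))
        off = None
        if self.orientation is not Orientation.SAME_STRAND:
            off = pair_offset(self.guide_a, self.guide_b)
        object.__setattr__(self, "offset", off)

    def nick_sites(self, v: NickaseVariant):
        return (nick_site(self.guide_a, v), nick_site(self.guide_b, v))

    def overhang(self, v: NickaseVariant) -> Overhang:
        return overhang(self.guide_a, self.guide_b, v)

    def efficacy(self, v: NickaseVariant, **windows) -> EfficacyCall:
        return classify_efficacy(self.guide_a, self.guide_b, v, **windows)
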