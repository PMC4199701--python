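"""Allele-replacement HDR design: donor arms, edited allele, junction PCR.

Models a marker knock-in that replaces the segment between two homology
arms: the predicted edited allele is locus[0:left_arm.end) + insert +
locus[right_arm.start:end).  Junction PCR is modeled as exact-match
priming (a primer amplifies where it occurs exactly once on the proper
strand); a diagnostic junction pair yields a product only on the edited
allele, typically one primer inside the insert and its mate outside the
homology arm.  No melting-temperature or mispriming thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .locus import Guide, Locus, NickaseVariant, revcomp
from .geometry import nick_site
from .screen import RateEstimate, ScreenRecord, heritable_rate

MIN_PRIMER_LEN = 18


class HDRDesignError(ValueError):
    pass


class PrimerAmbiguityError(ValueError):
    """A primer matches a template at more than one site."""


@dataclass(frozen=True)
class HDRDesign:
    """Donor design: two homology arms flanking a replaced segment.

    Arm intervals are 0-based half-open on the wild-type locus; the
    replaced segment is [left_arm.end, right_arm.start).  Guides whose
    blunt (WT) cut boundary falls outside the replaced segment are
    reported as warnings, not rejected.
    """

    locus: Locus
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    insert_seq: str
    guides: tuple[Guide, ...] = ()
    primers: tuple[tuple[str, str], ...] = ()  # (name, sequence 5'->3')

    def __post_init__(self) -> None:
        ls, le = self.left_arm
        rs, re_ = self.right_arm
        if not (0 <= ls < le and rs < re_ <= len(self.locus)):
            raise HDRDesignError("arm intervals out of bounds or empty")
        if le > rs:
            raise HDRDesignError("arms overlap or are out of order (left must precede right)")

    def validate_cut_sites(self) -> list[str]:
        """Warnings for guide cut boundaries outside the replaced segment."""
        warnings = []
        le, rs = self.left_arm[1], self.right_arm[0]
        for g in self.guides:
            plus_nick, _ = nick_site(g, NickaseVariant.WT)
            if not le <= plus_nick.boundary <= rs:
                warnings.append(
                    f"guide {g.name!r}: cut boundary {plus_nick.boundary} outside "
                    f"replaced segment [{le}, {rs}]"
                )
        return warnings


@dataclass(frozen=True)
class EditedAllele:
    """Predicted post-HDR allele with insert junction coordinates."""

    seq: str
    left_junction: int   # edited-allele coordinate where the insert begins
    right_junction: int  # edited-allele coordinate where the insert ends
    warnings: tuple[str, ...] = field(default_factory=tuple)


def predict_hdr_allele(design: HDRDesign) -> EditedAllele:
    """Splice the insert between the homology arms of the wild-type locus.

    Length change = len(insert) - len(replaced segment).
    """
    le, rs = design.left_arm[1], design.right_arm[0]
    seq = design.locus.seq[:le] + design.insert_seq + design.locus.seq[rs:]
    return EditedAllele(
        seq=seq,
        left_junction=le,
        right_junction=le + len(design.insert_seq),
        warnings=tuple(design.validate_cut_sites()),
    )


def _unique_match(template: str, query: str, what: str) -> int | None:
    """Start of the unique occurrence of query in template, None if absent."""
    first = template.find(query)
    if first == -1:
        return None
    if template.find(query, first + 1) != -1:
        raise PrimerAmbiguityError(f"{what} matches template at multiple sites")
    return first


def _product_length(template: str, fwd: str, rev: str, label: str) -> int | None:
    """Length of the exact-priming PCR product of (fwd, rev) on a template.

    The forward primer must match the plus strand, the reverse primer's
    reverse complement must match downstream of it; None if either fails.
    """
    f = _unique_match(template, fwd, f"{label}: forward primer")
    r = _unique_match(template, revcomp(rev), f"{label}: reverse primer")
    if f is None or r is None:
        return None
    end = r + len(rev)
    if end <= f:
        return None  # primers face away from each other
    return end - f


@dataclass(frozen=True)
class AmpliconPrediction:
    pair_name: str
    length_edited: int | None
    length_wildtype: int | None
    template: str  # edited | wildtype | both | none

    @property
    def diagnostic(self) -> bool:
        """True when the pair amplifies the edited allele only."""
        return self.template == "edited"


def junction_amplicons(
    allele: EditedAllele,
    wildtype: Locus,
    primer_pairs: list[tuple[str, str, str]],
) -> list[AmpliconPrediction]:
    """Predict PCR products of primer pairs on edited vs wild-type templates.

    ``primer_pairs`` rows are (pair name, forward seq, reverse seq); both
    primers must be at least 18 nt.  A pair whose product appears only on
    the edited allele is a diagnostic junction check.
    """
    out = []
    for name, fwd, rev in primer_pairs:
        fwd, rev = fwd.upper(), rev.upper()
        if len(fwd) < MIN_PRIMER_LEN or len(rev) < MIN_PRIMER_LEN:
            raise HDRDesignError(f"{name}: primers must be >= {MIN_PRIMER_LEN} nt")
        le = _product_length(allele.seq, fwd, rev, name)
        lw = _product_length(wildtype.seq, fwd, rev, name)
        template = {
            (True, True): "both",
            (True, False): "edited",
            (False, True): "wildtype",
            (False, False): "none",
        }[(le is not None, lw is not None)]
        out.append(AmpliconPrediction(name, le, lw, template))
    return out


def screen_marker_carriers(
    f1_records: list[ScreenRecord],
) -> dict[str, RateEstimate]:
    """HDR rate per screened unit from marker-positive G1 counts."""
    out: dict[str, RateEstimate] = {}
    for rec in f1_records:
        if rec.n_g1_total is None or rec.n_g1_positive is None:
            raise ValueError(f"{rec.unit}: HDR block (G1 counts) missing")
        out[rec.unit] = heritable_rate(rec.n_g1_positive, rec.n_g1_total)
    return out
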