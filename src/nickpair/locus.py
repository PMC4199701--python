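"""Sequence and guide data model.

A :class:`Locus` is a named plus-strand DNA sequence; every coordinate in
this package is 0-based, half-open, and anchored to the locus plus strand.
A :class:`Guide` is a 20-nt protospacer located on a locus together with
its strand and its NGG PAM.  Minus-strand guides are anchored by their
plus-strand footprint (``start`` is the leftmost plus-strand base of the
20-mer), so all geometry downstream lives in a single coordinate frame.

SpCas9 requires the protospacer to be followed immediately 3' by an NGG
PAM on the protospacer strand; on the locus plus strand a minus-strand
guide therefore shows up as a CCN trinucleotide immediately left of the
footprint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq

PROTOSPACER_LEN = 20
PAM_LEN = 3

_PAM_RE = re.compile(r"^[ACGT]GG$")  # N never satisfies any PAM position
_SEQ_RE = re.compile(r"^[ACGTN]+$")

PLUS = "+"
MINUS = "-"


class LocusParseError(ValueError):
    """Raised when a FASTA record cannot be turned into a Locus."""


class GuideError(ValueError):
    """Base class for guide placement/validation failures."""


class GuideNotFoundError(GuideError):
    """Protospacer does not occur on either strand of the locus."""


class AmbiguousGuideError(GuideError):
    """Protospacer occurs at more than one PAM-adjacent site."""


class MissingPamError(GuideError):
    """Protospacer occurs but is never followed by an NGG PAM."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Locus:
    """A named plus-strand DNA sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise LocusParseError(f"locus {self.name!r}: empty sequence")
        m = _SEQ_RE.match(self.seq)
        if m is None:
            bad = next(i for i, c in enumerate(self.seq) if c not in "ACGTN")
            raise LocusParseError(
                f"locus {self.name!r}: illegal character {self.seq[bad]!r} "
                f"at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self, name: str | None = None) -> "Locus":
        return Locus(name or f"{self.name}_rc", revcomp(self.seq))


@dataclass(frozen=True)
class Guide:
    """A 20-nt protospacer located on a locus.

    ``protospacer`` reads 5'->3' on the guide's own strand; ``start`` is the
    leftmost plus-strand base of the footprint regardless of strand; ``pam``
    is the NGG trinucleotide immediately 3' of the protospacer, read on the
    protospacer strand.
    """

    name: str
    protospacer: str
    strand: str
    start: int
    pam: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise GuideError(
                f"guide {self.name!r}: protospacer must be "
                f"{PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if self.strand not in (PLUS, MINUS):
            raise GuideError(f"guide {self.name!r}: bad strand {self.strand!r}")
        if _PAM_RE.match(self.pam) is None:
            raise GuideError(
                f"guide {self.name!r}: PAM {self.pam!r} does not match NGG"
            )

    @property
    def end(self) -> int:
        """Half-open right edge of the plus-strand footprint."""
        return self.start + PROTOSPACER_LEN

    @property
    def pam_distal_end(self) -> int:
        """Plus-strand coordinate of the PAM-distal (5') protospacer end.

        For a plus-strand guide this is ``start``; for a minus-strand guide
        the 5' end sits at the right edge of the footprint, ``end``.
        """
        return self.start if self.strand == PLUS else self.end

    def validate(self, locus: Locus) -> None:
        """Check the guide against its locus; raise GuideError on mismatch."""
        if self.start < 0 or self.end > len(locus):
            raise GuideError(f"guide {self.name!r}: footprint outside locus")
        window = locus.seq[self.start : self.end]
        if self.strand == PLUS:
            if window != self.protospacer:
                raise GuideError(f"guide {self.name!r}: sequence mismatch on plus strand")
            pam = locus.seq[self.end : self.end + PAM_LEN]
        else:
            if revcomp(window) != self.protospacer:
                raise GuideError(f"guide {self.name!r}: sequence mismatch on minus strand")
            pam = revcomp(locus.seq[self.start - PAM_LEN : self.start]) if self.start >= PAM_LEN else ""
        if pam != self.pam or _PAM_RE.match(pam) is None:
            raise GuideError(f"guide {self.name!r}: PAM {pam!r} is not NGG")


class NickaseVariant(str, Enum):
    """Cas9 nuclease-domain status.

    WT cuts both strands (blunt DSB).  D10A inactivates RuvC, leaving HNH
    to nick the strand the sgRNA base-pairs with (the non-protospacer
    strand).  H840A inactivates HNH, leaving RuvC to nick the displaced
    protospacer strand.
    """

    WT = "WT"
    D10A = "D10A"
    H840A = "H840A"


def read_locus(fasta_path: str | Path, name: str | None = None) -> Locus:
    """Read one record from a FASTA file as a :class:`Locus`.

    Selects the record whose id equals ``name``; by default the first
    record.  The sequence is uppercased and U is mapped to T; characters
    outside {A,C,G,T,N} raise :class:`LocusParseError` naming the position.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(str(fasta_path))
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise LocusParseError(f"{fasta_path}: no FASTA records")
    if name is None:
        rec = records[0]
    else:
        try:
            rec = next(r for r in records if r.id == name)
        except StopIteration:
            raise LocusParseError(f"{fasta_path}: no record named {name!r}") from None
    seq = str(rec.seq).upper().replace("U", "T")
    return Locus(rec.id, seq)


def write_locus(locus: Locus, fasta_path: str | Path) -> None:
    with open(fasta_path, "w") as fh:
        fh.write(f">{locus.name}\n")
        for i in range(0, len(locus.seq), 70):
            fh.write(locus.seq[i : i + 70] + "\n")


def _pam_at(locus: Locus, start: int, strand: str) -> str | None:
    """NGG PAM adjacent to footprint [start, start+20) on ``strand``, or None."""
    if strand == PLUS:
        pam = locus.seq[start + PROTOSPACER_LEN : start + PROTOSPACER_LEN + PAM_LEN]
    else:
        if start < PAM_LEN:
            return None
        pam = revcomp(locus.seq[start - PAM_LEN : start])
    return pam if _PAM_RE.match(pam) else None


def place_guide(locus: Locus, name: str, protospacer: str) -> Guide:
    """Locate a protospacer on a locus and return the fully placed Guide.

    The protospacer must occur exactly once across both strands with a
    valid NGG PAM; zero occurrences, multiple occurrences and
    PAM-less occurrences raise distinct errors.
    """
    protospacer = protospacer.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise GuideError(f"protospacer must be {PROTOSPACER_LEN} nt")
    hits: list[tuple[str, int]] = []  # (strand, start), PAM-valid
    seen = 0
    rc = revcomp(protospacer)
    for strand, query in ((PLUS, protospacer), (MINUS, rc)):
        pos = locus.seq.find(query)
        while pos != -1:
            seen += 1
            if _pam_at(locus, pos, strand) is not None:
                hits.append((strand, pos))
            pos = locus.seq.find(query, pos + 1)
    if not hits:
        if seen:
            raise MissingPamError(
                f"guide {name!r}: protospacer found but never adjacent to an NGG PAM"
            )
        raise GuideNotFoundError(f"guide {name!r}: protospacer not found in {locus.name!r}")
    if len(hits) > 1:
        raise AmbiguousGuideError(
            f"guide {name!r}: protospacer occurs at {len(hits)} PAM-adjacent sites"
        )
    strand, start = hits[0]
    pam = _pam_at(locus, start, strand)
    assert pam is not None
    return Guide(name, protospacer, strand, start, pam)


def enumerate_guides(locus: Locus) -> list[Guide]:
    """All PAM-adjacent 20-mers on both strands of a locus.

    Every 20-mer followed by NGG on the plus strand, and every 20-mer whose
    plus-strand left-adjacent context reads CCN (an NGG PAM on the minus
    strand), is returned once.  Windows containing N are skipped.  Output
    is sorted by start, plus strand first.
    """
    guides: list[Guide] = []
    n = len(locus)
    for start in range(0, n - PROTOSPACER_LEN + 1):
        window = locus.seq[start : start + PROTOSPACER_LEN]
        if "N" in window:
            continue
        pam = _pam_at(locus, start, PLUS)
        if pam is not None:
            guides.append(Guide(f"{locus.name}_{start}_+", window, PLUS, start, pam))
        pam = _pam_at(locus, start, MINUS)
        if pam is not None:
            guides.append(Guide(f"{locus.name}_{start}_-", revcomp(window), MINUS, start, pam))
    guides.sort(key=lambda g: (g.start, g.strand))
    return guides


def read_guides_tsv(path: str | Path, locus: Locus) -> list[Guide]:
    """Read a guide table (columns: name, protospacer[, strand, start]).

    Rows carrying strand and start are validated in place; rows without
    are located with :func:`place_guide`.
    """
    guides = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for col in ("name", "protospacer"):
            if col not in idx:
                raise ValueError(f"{path}: missing required column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[idx["name"]]
            proto = fields[idx["protospacer"]].upper()
            if "strand" in idx and "start" in idx and fields[idx["strand"]]:
                strand = fields[idx["strand"]]
                start = int(fields[idx["start"]])
                pam = _pam_at(locus, start, strand)
                if pam is None:
                    raise MissingPamError(f"guide {name!r}: no NGG PAM at stated position")
                g = Guide(name, proto, strand, start, pam)
                g.validate(locus)
                guides.append(g)
            else:
                guides.append(place_guide(locus, name, proto))
    return guides


def write_guides_tsv(guides: Iterable[Guide], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tprotospacer\tstrand\tstart\tpam\n")
        for g in guides:
            fh.write(f"{g.name}\t{g.protospacer}\t{g.strand}\t{g.start}\t{g.pam}\n")


def write_guides_bed(guides: Iterable[Guide], locus: Locus, path: str | Path) -> None:
    """BED6 of guide footprints (0-based half-open, score 0)."""
    with open(path, "w") as fh:
        for g in guides:
            fh.write(f"{locus.name}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
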