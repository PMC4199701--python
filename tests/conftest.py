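"""Shared fixtures: the assembled mini-locus and synthetic pair placements."""

from __future__ import annotations

import numpy as np
import pytest

from nickpair.locus import Guide, Locus, MINUS, PLUS, revcomp
from nickpair.synthetic import reconstruct_white_minilocus

BASES = np.array(list("ACGT"))


@pytest.fixture(scope="session")
def minilocus():
    return reconstruct_white_minilocus()


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def pair_at_offset(offset: int, rng: np.random.Generator,
                   p: int = 130, length: int = 260) -> tuple[Locus, Guide, Guide] | None:
    """Random locus with a plus guide at ``p`` and a minus guide at PAM-distal
    offset ``offset``, both with valid NGG PAMs.

    Returns None where no placement exists (the two PAM constraints collide
    on a shared base, which happens for offsets -45..-43).
    """
    m = p - 20 - offset
    seq = list(random_seq(length, rng))
    constraints = {p + 21: "G", p + 22: "G"}
    for pos, base in ((m - 3, "C"), (m - 2, "C")):
        if pos in constraints and constraints[pos] != base:
            return None
        constraints[pos] = base
    for pos, base in constraints.items():
        seq[pos] = base
    locus = Locus(f"pair_off{offset}", "".join(seq))
    plus = Guide("P", locus.seq[p : p + 20], PLUS, p, locus.seq[p + 20 : p + 23])
    minus = Guide("M", revcomp(locus.seq[m : m + 20]), MINUS, m,
                  revcomp(locus.seq[m - 3 : m]))
    plus.validate(locus)
    minus.validate(locus)
    return locus, plus, minus


def reflect_guide(g: Guide, locus: Locus) -> Guide:
    """The same physical guide in the reverse-complemented coordinate frame."""
    L = len(locus)
    return Guide(g.name, g.protospacer,
                 MINUS if g.strand == PLUS else PLUS, L - g.end, g.pam)
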