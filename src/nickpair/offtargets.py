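"""Mismatch-bounded off-target search with strict NGG PAM requirement.

A candidate off-target is any 20-mer window, on either genome strand,
within a Hamming-distance budget of the protospacer (default 4
mismatches, uniformly weighted over all 20 positions — no seed-region
weighting) and followed on the same strand by an NGG PAM.  Genomic N
counts as a mismatch and never satisfies a PAM G position.

Mismatch positions are reported 1-based counted from the PAM-distal
(5') end of the protospacer.

For paired nickases, a lone off-target nick is not expected to mutate;
:func:`paired_dsb_offtargets` finds configurations where two off-target
hits could cooperate into a DSB-competent (effective) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .locus import MINUS, PLUS, PROTOSPACER_LEN, Guide, Locus, NickaseVariant, revcomp
from .geometry import EfficacyCall, Overhang, classify_efficacy, overhang as pair_overhang

DEFAULT_MAX_MM = 4
DEFAULT_PAIR_SPAN = 200


@dataclass(frozen=True)
class OffTargetHit:
    locus_name: str
    start: int  # leftmost plus-strand base of the 20-mer footprint
    strand: str
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 1..20 from the PAM-distal end
    pam: str  # read on the hit strand

    @property
    def end(self) -> int:
        return self.start + PROTOSPACER_LEN


def mismatch_annotation(protospacer: str, site: str) -> tuple[int, tuple[int, ...]]:
    """Per-position comparison of a protospacer and a candidate site.

    Both sequences read 5'->3' on their own strand, so index 0 is the
    PAM-distal end; returns (count, 1-based positions from that end).
    """
    if len(protospacer) != len(site):
        raise ValueError(
            f"length mismatch: protospacer {len(protospacer)} nt vs site {len(site)} nt"
        )
    positions = tuple(
        i + 1 for i, (p, s) in enumerate(zip(protospacer.upper(), site.upper())) if p != s
    )
    return len(positions), positions


def _scan_locus(locus: Locus, protospacer: str, max_mm: int) -> list[OffTargetHit]:
    seq = locus.seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    L = len(seq)
    if L < PROTOSPACER_LEN + 3:
        return []
    proto = np.frombuffer(protospacer.encode(), dtype="S1")
    rcproto = np.frombuffer(revcomp(protospacer).encode(), dtype="S1")
    hits: list[OffTargetHit] = []

    # plus strand: window [s, s+20), PAM GG at s+21, s+22
    n_win = L - PROTOSPACER_LEN - 2
    mm = np.zeros(n_win, dtype=np.int16)
    for j in range(PROTOSPACER_LEN):
        mm += arr[j : j + n_win] != proto[j]
    pam_ok = (arr[21 : 21 + n_win] == b"G") & (arr[22 : 22 + n_win] == b"G")
    for s in np.nonzero((mm <= max_mm) & pam_ok)[0]:
        s = int(s)
        window = seq[s : s + PROTOSPACER_LEN]
        _, pos = mismatch_annotation(protospacer, window)
        hits.append(OffTargetHit(locus.name, s, PLUS, len(pos), pos, seq[s + 20 : s + 23]))

    # minus strand: window [s, s+20) with plus-strand CC at s-3, s-2;
    # the site read on its own strand is revcomp(window), so Hamming
    # distance equals distance of the plus window to revcomp(protospacer).
    mm = np.zeros(n_win, dtype=np.int16)
    for j in range(PROTOSPACER_LEN):
        mm += arr[3 + j : 3 + j + n_win] != rcproto[j]
    pam_ok = (arr[0:n_win] == b"C") & (arr[1 : 1 + n_win] == b"C")
    for s3 in np.nonzero((mm <= max_mm) & pam_ok)[0]:
        s = int(s3) + 3
        site = revcomp(seq[s : s + PROTOSPACER_LEN])
        _, pos = mismatch_annotation(protospacer, site)
        hits.append(
            OffTargetHit(locus.name, s, MINUS, len(pos), pos, revcomp(seq[s - 3 : s]))
        )
    return hits


def find_offtargets(
    genome: Locus | list[Locus],
    g: Guide | str,
    max_mm: int = DEFAULT_MAX_MM,
    exclude_on_target: bool = True,
) -> list[OffTargetHit]:
    """All mismatch-bounded NGG-adjacent sites of a guide in a genome.

    ``genome`` may be one locus or several.  When ``g`` is a located
    Guide and ``exclude_on_target`` is set, the perfect match at the
    guide's own placement is dropped.  Hits are sorted by
    (locus, start, strand).
    """
    loci = [genome] if isinstance(genome, Locus) else list(genome)
    if not loci:
        raise ValueError("genome is empty")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    protospacer = g.protospacer if isinstance(g, Guide) else g.upper()
    if len(protospacer) != PROTOSPACER_LEN:
        raise ValueError(f"protospacer must be {PROTOSPACER_LEN} nt")
    hits: list[OffTargetHit] = []
    for locus in loci:
        hits.extend(_scan_locus(locus, protospacer, max_mm))
    if exclude_on_target and isinstance(g, Guide):
        hits = [
            h
            for h in hits
            if not (h.mismatches == 0 and h.start == g.start and h.strand == g.strand)
        ]
    hits.sort(key=lambda h: (h.locus_name, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class PairedHit:
    hit_a: OffTargetHit
    hit_b: OffTargetHit
    offset: int
    overhang: Overhang
    efficacy: EfficacyCall


@dataclass(frozen=True)
class PairedScanResult:
    """Effective paired-nick configurations plus single-nick hit tallies.

    ``n_hits_a`` / ``n_hits_b`` count the single-guide off-target sites,
    so the specificity ratio (paired DSB-competent sites vs single-guide
    sites) is directly computable.
    """

    effective: tuple[PairedHit, ...]
    n_hits_a: int
    n_hits_b: int


def _hit_as_guide(h: OffTargetHit, genome: dict[str, Locus]) -> Guide:
    # geometry depends only on footprint and strand; normalize an N in the
    # PAM's free position so the Guide constructor accepts it
    seq = genome[h.locus_name].seq
    site = seq[h.start : h.end] if h.strand == PLUS else revcomp(seq[h.start : h.end])
    pam = h.pam if h.pam[0] in "ACGT" else "A" + h.pam[1:]
    return Guide(f"ot_{h.locus_name}_{h.start}_{h.strand}", site, h.strand, h.start, pam)


def paired_dsb_offtargets(
    genome: Locus | list[Locus],
    a: Guide | str,
    b: Guide | str,
    v: NickaseVariant,
    max_mm: int = DEFAULT_MAX_MM,
    pair_span: int = DEFAULT_PAIR_SPAN,
    exclude_on_target: bool = True,
) -> PairedScanResult:
    """DSB-competent off-target configurations of a nickase guide pair.

    Takes the union of both guides' off-target hits (each guide may also
    pair with its own hits), forms every opposite-strand hit pair on one
    locus whose footprints start within ``pair_span`` bp, and keeps the
    configurations the efficacy classifier calls effective under ``v``.
    """
    if v is NickaseVariant.WT:
        raise ValueError("paired-nick scan applies to nickase variants only")
    loci = [genome] if isinstance(genome, Locus) else list(genome)
    by_name = {l.name: l for l in loci}
    hits_a = find_offtargets(loci, a, max_mm, exclude_on_target)
    hits_b = find_offtargets(loci, b, max_mm, exclude_on_target)
    pool = sorted(set(hits_a) | set(hits_b), key=lambda h: (h.locus_name, h.start, h.strand))
    effective: list[PairedHit] = []
    for hx, hy in combinations(pool, 2):
        if hx.locus_name != hy.locus_name or hx.strand == hy.strand:
            continue
        if abs(hx.start - hy.start) > pair_span:
            continue
        gx, gy = _hit_as_guide(hx, by_name), _hit_as_guide(hy, by_name)
        call = classify_efficacy(gx, gy, v)
        if call.effective:
            plus_g = gx if gx.strand == PLUS else gy
            minus_g = gy if gx.strand == PLUS else gx
            effective.append(
                PairedHit(hx, hy, plus_g.start - minus_g.end, pair_overhang(gx, gy, v), call)
            )
    return PairedScanResult(tuple(effective), len(hits_a), len(hits_b))
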