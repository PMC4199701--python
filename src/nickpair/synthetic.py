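"""Synthetic inputs: mini-locus assembly, planted genomes, screen simulation.

No genomic accession exists for the published white-locus screen, but
six of its protospacers overlap each other enough (>= 9 nt) to force a
unique local reconstruction: chaining those overlaps yields a 50-nt
core contig on which the printed pair offsets are reproduced from
sequence alone.  PAM trinucleotides falling outside the assembled
evidence are synthesized as AGG — pair geometry depends only on
footprints and strands, not on PAM identity beyond NGG.

The remaining generators make reproducible test universes: random
genomes with off-target sites planted at exact mismatch counts, and
founder/F1 screens with binomial noise and beta-distributed germline
mosaicism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GuidePair
from .locus import Guide, Locus, MINUS, NickaseVariant, PLUS, revcomp
from .screen import ScreenRecord
from .tables import WHITE_GUIDES

MIN_OVERLAP = 9

#: Guides anchorable to one contig purely by >=9-nt protospacer overlaps.
ANCHORED_GUIDES = ("white-R", "white-D", "white-H", "white-I", "white-C", "white-A")


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class MiniLocusAssembly:
    locus: Locus
    guides: dict[str, Guide]
    placements: dict[str, tuple[str, int]]  # name -> (strand, start)
    evidence: tuple[tuple[str, str, int], ...]  # (placed, incoming, overlap nt)
    notes: tuple[str, ...]


def _best_merge(contig: str, seq: str) -> tuple[int, int] | None:
    """Best placement of seq against contig: (overlap length, contig offset).

    Considers containment and both suffix-prefix extensions; offsets may
    be negative (left extension).  None if no overlap >= MIN_OVERLAP.
    """
    pos = contig.find(seq)
    if pos != -1:
        return len(seq), pos
    best: tuple[int, int] | None = None
    for k in range(len(seq) - 1, MIN_OVERLAP - 1, -1):
        if contig.endswith(seq[:k]):  # extend right
            best = (k, len(contig) - k)
            break
    for k in range(len(seq) - 1, MIN_OVERLAP - 1, -1):
        if contig.startswith(seq[-k:]):  # extend left
            if best is None or k > best[0]:
                best = (k, k - len(seq))
            break
    return best


def reconstruct_white_minilocus(seed_guide: str = "white-R") -> MiniLocusAssembly:
    """Overlap-assemble the anchorable white protospacers into one mini-locus.

    The seed guide's protospacer strand defines the contig plus strand
    (an arbitrary global choice).  Guides are merged greedily by maximal
    overlap; a merge whose overlap evidence conflicts with the contig is
    an assembly error.  PAMs outside assembled evidence are synthesized
    as AGG so every placement validates as a Guide.
    """
    seqs = {name: WHITE_GUIDES[name] for name in ANCHORED_GUIDES}
    if seed_guide not in seqs:
        raise AssemblyError(f"seed {seed_guide!r} is not an anchorable guide")
    contig = seqs[seed_guide]
    placements: dict[str, tuple[str, int]] = {seed_guide: (PLUS, 0)}
    evidence: list[tuple[str, str, int]] = []
    remaining = [n for n in ANCHORED_GUIDES if n != seed_guide]
    while remaining:
        best: tuple[int, str, str, int] | None = None  # (overlap, name, strand, offset)
        for name in remaining:
            for strand, oriented in ((PLUS, seqs[name]), (MINUS, revcomp(seqs[name]))):
                m = _best_merge(contig, oriented)
                if m and (best is None or m[0] > best[0]):
                    best = (m[0], name, strand, m[1])
        if best is None:
            raise AssemblyError(
                f"no overlap >= {MIN_OVERLAP} nt links {sorted(remaining)} to the contig"
            )
        ov, name, strand, off = best
        oriented = seqs[name] if strand == PLUS else revcomp(seqs[name])
        if off < 0:  # left extension: shift existing placements
            contig = oriented[:-off] + contig
            placements = {n: (s, p - off) for n, (s, p) in placements.items()}
            off = 0
        elif off + len(oriented) > len(contig):
            overlap_part = contig[off:]
            if oriented[: len(overlap_part)] != overlap_part:
                raise AssemblyError(f"conflicting overlap merging {name!r}")
            contig = contig + oriented[len(overlap_part) :]
        if contig[off : off + len(oriented)] != oriented:
            raise AssemblyError(f"conflicting overlap merging {name!r}")
        placements[name] = (strand, off)
        evidence.append((_nearest_placed(placements, name, off), name, ov))
        remaining.remove(name)

    # synthesize PAM flanks where the PAM falls outside assembled evidence
    left_pad = 3 if any(s == MINUS and p < 3 for s, p in placements.values()) else 0
    right_pad = 3 if any(
        s == PLUS and p + 23 > len(contig) for s, p in placements.values()
    ) else 0
    seq = ("CCT" if left_pad else "") + contig + ("AGG" if right_pad else "")
    placements = {n: (s, p + left_pad) for n, (s, p) in placements.items()}

    locus = Locus("white-minilocus", seq)
    guides: dict[str, Guide] = {}
    for name, (strand, start) in placements.items():
        if strand == PLUS:
            pam = locus.seq[start + 20 : start + 23]
        else:
            pam = revcomp(locus.seq[start - 3 : start])
        g = Guide(name, seqs[name], strand, start, pam)
        g.validate(locus)
        guides[name] = g

    notes = (
        "PAM trinucleotides outside overlap evidence synthesized as AGG; "
        "geometry depends only on footprints.",
        "Guides E,F,S,K,L,M,N,P,Q,B,G,J,O lack >=9 nt overlap evidence and are "
        "not placed on this contig.",
        "Printed table lists the white-E/white-A pair at both offset 26 and "
        "offset 217; both cannot be sequence-true. The sequence-derived "
        "white-A placement here is the overlap-anchored one.",
    )
    return MiniLocusAssembly(locus, guides, placements, tuple(evidence), notes)


def _nearest_placed(placements: dict[str, tuple[str, int]], incoming: str, off: int) -> str:
    others = [(abs(p - off), n) for n, (_, p) in placements.items() if n != incoming]
    return min(others)[1]


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant an off-target site of a protospacer."""

    protospacer: str
    mismatches: int
    strand: str | None = None  # random if None
    position: int | None = None  # footprint start; random if None


@dataclass(frozen=True)
class PlantedSite:
    protospacer: str
    site: str  # site sequence 5'->3' on its own strand
    strand: str
    start: int  # footprint start (plus-strand frame)
    mismatches: int
    mismatch_positions: tuple[int, ...]


def _mutate(protospacer: str, k: int, rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    bases = "ACGT"
    positions = sorted(rng.choice(len(protospacer), size=k, replace=False).tolist())
    site = list(protospacer)
    for p in positions:
        site[p] = rng.choice([b for b in bases if b != protospacer[p]])
    return "".join(site), tuple(p + 1 for p in positions)


def random_genome(
    length: int,
    gc: float = 0.42,
    seed: int = 1234,
    planted: list[PlantSpec] | None = None,
) -> tuple[Locus, tuple[PlantedSite, ...]]:
    """Seeded random genome with off-target sites planted at exact distances.

    Each plant occupies a 23-nt block (20-nt site plus NGG PAM, or its
    minus-strand mirror CCN + site); blocks never overlap.  Returns the
    locus and the planted-truth manifest.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.array(list("ACGT")), size=length, p=p)
    manifest: list[PlantedSite] = []
    used: list[tuple[int, int]] = []
    for spec in planted or []:
        if len(spec.protospacer) != 20:
            raise ValueError("planted protospacer must be 20 nt")
        strand = spec.strand or rng.choice([PLUS, MINUS])
        site, positions = _mutate(spec.protospacer, spec.mismatches, rng)
        block = site + "AGG" if strand == PLUS else "CCT" + revcomp(site)
        if spec.position is not None:
            block_start = spec.position if strand == PLUS else spec.position - 3
        else:
            for _ in range(1000):
                block_start = int(rng.integers(0, length - len(block)))
                if all(
                    block_start + len(block) <= s or block_start >= e for s, e in used
                ):
                    break
            else:
                raise ValueError("could not place plant without overlap: genome overcrowded")
        if block_start < 0 or block_start + len(block) > length:
            raise ValueError("planted site does not fit in genome")
        if any(not (block_start + len(block) <= s or block_start >= e) for s, e in used):
            raise ValueError("planted sites overlap")
        used.append((block_start, block_start + len(block)))
        seq[block_start : block_start + len(block)] = list(block)
        start = block_start if strand == PLUS else block_start + 3
        manifest.append(
            PlantedSite(spec.protospacer, site, strand, start, spec.mismatches, positions)
        )
    return Locus(f"random_{length}_{seed}", "".join(seq)), tuple(manifest)


@dataclass(frozen=True)
class ScreenSimParams:
    """Founder/F1 screen simulation settings.

    Each fertile founder transmits edits to a germline fraction drawn
    from a beta distribution with mean equal to the transmission
    probability of the pair's efficacy class and concentration
    ``mosaicism_concentration`` (founder-to-founder germline mosaicism);
    F1 mutant counts are binomial in that fraction.
    """

    n_g0: int = 20
    p_fertile: float = 0.8
    mosaicism_concentration: float = 50.0
    transmission: dict = field(
        default_factory=lambda: {"effective": 0.1, "not_effective": 0.001}
    )
    f1_per_g0: int = 120
    seed: int = 1234

    def __post_init__(self) -> None:
        if not 0 <= self.p_fertile <= 1:
            raise ValueError("p_fertile must be a probability")
        if self.n_g0 <= 0 or self.f1_per_g0 <= 0:
            raise ValueError("counts must be positive")
        for k, v in self.transmission.items():
            if not 0 <= v <= 1:
                raise ValueError(f"transmission[{k!r}] must be a probability")


def _germline_fraction(p: float, kappa: float, rng: np.random.Generator) -> float:
    if p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    return float(rng.beta(kappa * p, kappa * (1 - p)))


def simulate_screen(
    params: ScreenSimParams,
    pairs: list[GuidePair],
    v: NickaseVariant,
) -> list[ScreenRecord]:
    """Simulate the germline screen of guide pairs under a nickase.

    Per founder: fertility is Bernoulli; a fertile founder's germline
    mutant fraction is beta-distributed around the class transmission
    probability; its F1 clutch is a fixed size with binomial mutant
    counts.  Only fertile founders contribute F1.
    """
    rng = np.random.default_rng(params.seed)
    records = []
    for pair in pairs:
        call = pair.efficacy(v)
        p_class = params.transmission[
            "effective" if call.effective else "not_effective"
        ]
        n_fertile = 0
        n_f1 = 0
        n_mut = 0
        for _ in range(params.n_g0):
            if rng.random() >= params.p_fertile:
                continue
            n_fertile += 1
            frac = _germline_fraction(p_class, params.mosaicism_concentration, rng)
            n_f1 += params.f1_per_g0
            n_mut += int(rng.binomial(params.f1_per_g0, frac))
        records.append(
            ScreenRecord(
                unit=f"{pair.guide_a.name}+{pair.guide_b.name}",
                variant=v,
                n_f1_total=n_f1,
                n_f1_mutant=n_mut,
                offset=pair.offset,
                n_g0_adults=params.n_g0,
                n_g0_fertile=n_fertile,
            )
        )
    return records
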