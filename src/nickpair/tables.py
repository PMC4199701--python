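"""Published white-locus screen tables as structured constants.

Heritable mutation rates here are wet-lab measurements of the paired
nickase screen in the fly germline; they are carried as printed (percent,
one decimal) and serve as golden reference cells for the reproduction
pipeline.  Cells printed as "<0.1%" are censored bounds, not
measurements, and cells marked ND were not assayed; both are excluded
from aggregate statistics but flagged distinctly.
"""

from __future__ import annotations

from dataclasses import dataclass

#: sgRNA protospacers targeting white (CG2759), 5'->3'.
WHITE_GUIDES: dict[str, str] = {
    "white-A": "CAATATGGACATCTTTGGGG",
    "white-B": "CAGGAGCTATTAATTCGCGG",
    "white-C": "GCACAATATGGACATCTTTG",
    "white-D": "AGGTGAGGTTCTCGGCTAGT",
    "white-E": "TAGTTGGCCGCTCCCTGAAC",
    "white-F": "CGCCGGAGGACTCCGGTTCA",
    "white-G": "AGCGACACATACCGGCGCCC",
    "white-H": "CACCTATGCCTGGCACAATA",
    "white-I": "GGCACAATATGGACATCTTT",
    "white-J": "CTGCGGCGATCGAAAGGCAA",
    "white-K": "GCTGCATTAACCAGGGCTTC",
    "white-L": "CCAAAAACTACGGCACGCTC",
    "white-M": "GCTCCGGCCACCCAGTCCGC",
    "white-N": "CCGGCCACCCAGTCCGCCGG",
    "white-O": "TTATCGGCTCCCTAACGGCC",
    "white-P": "CCTCCGGCGGACTGGGTGGC",
    "white-Q": "GATCCTCTTGGCCCATTGCC",
    "white-R": "CCGAGAACCTCACCTATGCC",
    "white-S": "GAGGACTCCGGTTCAGGGAG",
}

#: Sentinels for non-measurement cells.
CENSORED = "censored"  # printed "<0.1%": bound only
ND = "nd"              # not done


@dataclass(frozen=True)
class PairRow:
    """One paired-sgRNA row of a screen table."""

    offset: int          # printed PAM-distal offset (bp)
    sgrna_a: str
    sgrna_b: str
    rate_pct: float | str  # heritable rate (%) with both sgRNAs, or sentinel


#: Paired rates with Cas9 D10A (both sgRNAs co-injected).
D10A_PAIR_ROWS: tuple[PairRow, ...] = (
    PairRow(-364, "white-J", "white-F", 0.0),
    PairRow(-95, "white-E", "white-K", 0.0),
    PairRow(-68, "white-E", "white-L", 0.0),
    PairRow(-35, "white-E", "white-F", 0.0),
    PairRow(-15, "white-D", "white-R", 0.2),
    PairRow(-5, "white-D", "white-H", 0.0),
    PairRow(-1, "white-Q", "white-B", 3.2),
    PairRow(1, "white-E", "white-R", 15.9),
    PairRow(6, "white-D", "white-I", 6.6),
    PairRow(7, "white-D", "white-C", 21.2),
    PairRow(11, "white-E", "white-H", 11.3),
    PairRow(22, "white-E", "white-I", 16.9),
    PairRow(26, "white-E", "white-A", 3.6),
    PairRow(61, "white-F", "white-A", 0.0),
    PairRow(112, "white-E", "white-G", 0.0),
    PairRow(217, "white-E", "white-A", 0.0),
    PairRow(432, "white-E", "white-O", 0.0),
)

#: Paired rates with Cas9 H840A.
H840A_PAIR_ROWS: tuple[PairRow, ...] = (
    PairRow(-88, "white-K", "white-S", 0.8),
    PairRow(-84, "white-F", "white-L", 0.8),
    PairRow(-69, "white-K", "white-P", 0.8),
    PairRow(-68, "white-F", "white-M", 1.1),
    PairRow(-42, "white-S", "white-N", 1.0),
    PairRow(-35, "white-E", "white-F", 1.5),
    PairRow(-15, "white-D", "white-R", 0.0),
    PairRow(-5, "white-D", "white-H", 0.0),
    PairRow(-1, "white-Q", "white-B", 0.0),
    PairRow(1, "white-E", "white-R", 0.0),
    PairRow(7, "white-D", "white-C", 0.0),
    PairRow(11, "white-E", "white-H", 0.0),
    PairRow(22, "white-E", "white-I", 0.0),
)

#: Single-sgRNA heritable rates with WT Cas9 (%).
CAS9_SINGLE_RATES: dict[str, float] = {
    "white-A": 81.6,
    "white-B": 61.8,
    "white-C": 43.7,
    "white-D": 57.1,
    "white-E": 32.3,
    "white-F": 18.1,
    "white-G": 80.1,
    "white-H": 42.4,
    "white-I": 52.1,
    "white-J": 57.1,
    "white-K": 64.1,
    "white-L": 78.6,
    "white-M": 63.6,
    "white-N": 33.2,
    "white-O": 71.4,
    "white-P": 80.2,
    "white-Q": 52.6,
    "white-R": 58.6,
    "white-S": 78.5,
}

#: Single-sgRNA rates with D10A: never above 0.1%.
D10A_SINGLE_RATES: dict[str, float | str] = {
    "white-A": 0.0,
    "white-B": CENSORED,
    "white-C": 0.0,
    "white-D": CENSORED,
    "white-E": 0.0,
    "white-F": ND,
    "white-G": CENSORED,
    "white-H": ND,
    "white-I": 0.0,
    "white-J": ND,
    "white-K": ND,
    "white-L": 0.0,
    "white-O": ND,
    "white-Q": ND,
    "white-R": 0.0,
}


@dataclass(frozen=True)
class HDRCounts:
    """HDR screen counts for one Cas9 method (allele replacement at piwi)."""

    method: str
    n_embryos: int
    n_g0_adults: int
    n_g0_fertile: int
    n_hdr_yielding_g0: int
    n_g1_total: int
    n_g1_positive: int


HDR_SCREEN: dict[str, HDRCounts] = {
    "Cas9": HDRCounts("Cas9", 50, 7, 3, 2, 364, 111),
    "D10A": HDRCounts("D10A", 54, 8, 8, 1, 1021, 3),
}
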