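"""Mismatch-bounded off-target scan vs a brute-force window oracle."""

import numpy as np
import pytest

from nickpair.locus import Locus, MINUS, NickaseVariant, PLUS, place_guide, revcomp
from nickpair.offtargets import (
    find_offtargets,
    mismatch_annotation,
    paired_dsb_offtargets,
)
from nickpair.synthetic import PlantSpec, random_genome
from nickpair.tables import WHITE_GUIDES

from conftest import random_seq

PROTO = WHITE_GUIDES["white-D"]


def brute_force_hits(locus: Locus, proto: str, max_mm: int):
    """Per-base loop over every window on both strands."""
    s = locus.seq
    hits = set()
    for i in range(len(s) - 19):
        win = s[i : i + 20]
        if i + 23 <= len(s) and s[i + 21] == "G" and s[i + 22] == "G":
            mm = sum(a != b for a, b in zip(proto, win))
            if mm <= max_mm:
                hits.add((i, PLUS, mm))
        if i >= 3 and s[i - 3] == "C" and s[i - 2] == "C":
            mm = sum(a != b for a, b in zip(proto, revcomp(win)))
            if mm <= max_mm:
                hits.add((i, MINUS, mm))
    return hits


class TestMismatchAnnotation:
    def test_identity(self):
        g = WHITE_GUIDES["white-G"]
        assert mismatch_annotation(g, g) == (0, ())

    def test_two_mismatch_derivative(self):
        g = WHITE_GUIDES["white-G"]
        # synthetic two-mismatch derivative (positions 5 and 12 from the
        # PAM-distal end), mirroring the mismatched-sgRNA efficiency assay
        deriv = g[:4] + ("T" if g[4] != "T" else "A") + g[5:11] + (
            "T" if g[11] != "T" else "A") + g[12:]
        count, positions = mismatch_annotation(g, deriv)
        assert count == 2 and positions == (5, 12)

    def test_one_mismatch_derivative(self):
        g = WHITE_GUIDES["white-B"]
        deriv = g[:9] + ("C" if g[9] != "C" else "G") + g[10:]
        assert mismatch_annotation(g, deriv) == (1, (10,))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mismatch_annotation(PROTO, "ACGT")


class TestFindOfftargets:
    def test_planted_two_mismatch_site(self):
        genome, manifest = random_genome(
            5000, seed=21, planted=[PlantSpec(PROTO, 2, strand=PLUS)]
        )
        plant = manifest[0]
        hits = [h for h in find_offtargets(genome, PROTO, max_mm=4) if h.mismatches > 0]
        by_pos = {(h.start, h.strand): h for h in hits}
        h = by_pos[(plant.start, plant.strand)]
        assert h.mismatches == 2
        assert h.mismatch_positions == plant.mismatch_positions

    def test_five_mismatch_site_outside_budget(self):
        genome, manifest = random_genome(
            5000, seed=22, planted=[PlantSpec(PROTO, 5, strand=MINUS)]
        )
        plant = manifest[0]
        hits = find_offtargets(genome, PROTO, max_mm=4)
        assert (plant.start, plant.strand) not in {(h.start, h.strand) for h in hits}
        # found once the budget admits it
        hits5 = find_offtargets(genome, PROTO, max_mm=5)
        assert (plant.start, plant.strand) in {(h.start, h.strand) for h in hits5}

    @pytest.mark.parametrize("max_mm", [0, 2, 4])
    def test_oracle_equivalence(self, max_mm):
        genome, _ = random_genome(8000, seed=23, planted=[PlantSpec(PROTO, 1)])
        got = {(h.start, h.strand, h.mismatches) for h in find_offtargets(genome, PROTO, max_mm)}
        assert got == brute_force_hits(genome, PROTO, max_mm)

    def test_n_counts_as_mismatch_and_blocks_pam(self):
        seq = PROTO + "AGG" + "T" * 10 + PROTO[:7] + "N" + PROTO[8:] + "AGG"
        seq += "T" * 10 + PROTO + "GNG" + "TTT"
        genome = Locus("nfix", seq)
        hits = find_offtargets(genome, PROTO, max_mm=0, exclude_on_target=False)
        starts = {h.start for h in hits}
        assert 0 in starts  # clean site
        assert 33 not in starts  # N in window is a mismatch at mm=0
        hits1 = find_offtargets(genome, PROTO, max_mm=1, exclude_on_target=False)
        assert 33 in {h.start for h in hits1}
        # third copy has its PAM G replaced by N: never a site
        assert all(h.start != 66 for h in hits1)

    def test_monotonic_in_max_mm(self):
        genome, _ = random_genome(20_000, seed=24)
        counts = [len(find_offtargets(genome, PROTO, mm)) for mm in range(5)]
        assert counts == sorted(counts)

    def test_strand_symmetry(self):
        genome, _ = random_genome(6000, seed=25, planted=[PlantSpec(PROTO, 2)])
        L = len(genome)
        fwd = {(h.start, h.strand, h.mismatches) for h in find_offtargets(genome, PROTO, 4)}
        rev = {
            (L - 20 - h.start, MINUS if h.strand == PLUS else PLUS, h.mismatches)
            for h in find_offtargets(genome.reverse_complement(), PROTO, 4)
        }
        assert fwd == rev

    def test_on_target_excluded_for_located_guide(self):
        rng = np.random.default_rng(26)
        locus = Locus("t", random_seq(200, rng) + PROTO + "TGG" + random_seq(200, rng))
        g = place_guide(locus, "d", PROTO)
        with_self = find_offtargets(locus, g, max_mm=4, exclude_on_target=False)
        without = find_offtargets(locus, g, max_mm=4)
        assert {(h.start, h.strand) for h in with_self} - {
            (h.start, h.strand) for h in without
        } == {(g.start, g.strand)}

    def test_bad_protospacer_length(self):
        genome, _ = random_genome(1000, seed=27)
        with pytest.raises(ValueError, match="20"):
            find_offtargets(genome, "ACGT")


class TestPairedDsb:
    def test_planted_effective_configuration(self):
        """Two complementary off-target sites at offset 7, pam-out, D10A."""
        rng = np.random.default_rng(31)
        a_proto = random_seq(20, rng)
        b_proto = random_seq(20, rng)
        # minus-strand site for a at footprint [103,123), plus site for b at
        # [130,150): offset = 130 - 123 = 7
        block = "CCT" + revcomp(a_proto) + "T" * 7 + b_proto + "AGG"
        seq = random_seq(100, rng) + block + random_seq(100, rng)
        on_locus = Locus(
            "on", a_proto + "AGG" + "T" * 20 + b_proto + "CGG"
        )
        ga = place_guide(on_locus, "ga", a_proto)
        gb = place_guide(on_locus, "gb", b_proto)
        genome = Locus("g", seq)
        res = paired_dsb_offtargets(genome, ga, gb, NickaseVariant.D10A, max_mm=0)
        assert len(res.effective) == 1
        ph = res.effective[0]
        assert ph.offset == 7 and ph.efficacy.effective

    def test_sparse_on_random_genome(self):
        genome, _ = random_genome(100_000, seed=32)
        on_locus, _ = random_genome(1000, seed=33)
        from nickpair.locus import enumerate_guides

        guides = enumerate_guides(on_locus)
        ga, gb = guides[0], guides[1]
        res = paired_dsb_offtargets(genome, ga, gb, NickaseVariant.D10A, max_mm=2)
        assert len(res.effective) == 0
        assert res.n_hits_a >= 0 and res.n_hits_b >= 0

    def test_exhaustive_small_genome_oracle(self):
        """Brute-force re-derivation of every effective hit pair on 2 kb."""
        from itertools import combinations

        from nickpair.geometry import classify_efficacy
        from nickpair.locus import Guide

        genome, _ = random_genome(2000, seed=34, gc=0.6)
        proto_a, proto_b = random_seq(20, np.random.default_rng(35)), random_seq(
            20, np.random.default_rng(36)
        )
        res = paired_dsb_offtargets(genome, proto_a + "", proto_b + "",
                                    NickaseVariant.D10A, max_mm=4, pair_span=500)
        # oracle: brute-force hits of both guides, all pairs, efficacy call
        pool = sorted(
            brute_force_hits(genome, proto_a, 4) | brute_force_hits(genome, proto_b, 4)
        )
        expected = 0
        for (s1, st1, _), (s2, st2, _) in combinations(pool, 2):
            if st1 == st2 or abs(s1 - s2) > 500:
                continue
            g1 = Guide("x", "A" * 20, st1, s1, "AGG")
            g2 = Guide("y", "A" * 20, st2, s2, "AGG")
            if classify_efficacy(g1, g2, NickaseVariant.D10A).effective:
                expected += 1
        assert len(res.effective) == expected
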