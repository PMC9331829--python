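"""SSR, tandem and dispersed repeat scanners against brute-force oracles."""

import numpy as np
import pytest

from helpers import (brute_adjacent_match_pct, brute_dispersed, brute_ssrs,
                     dispersed_as_set, random_dna)
from mitostruct import (DEFAULT_SSR_THRESHOLDS, Genome, Molecule,
                        find_dispersed, find_ssrs, find_tandem,
                        longest_repeat, revcomp)


class TestSSR:
    def test_mono_run(self):
        recs = find_ssrs(Molecule("m", "CCCTTTTTTTTTTGGG"))
        assert len(recs) == 1
        r = recs[0]
        assert (r.motif, r.copies, r.start, r.end) == ("T", 10, 4, 13)

    def test_dimer_not_reported_as_mono(self):
        recs = find_ssrs(Molecule("m", "ATATATATATAT"))
        assert [(r.motif, r.unit_length, r.copies) for r in recs] == [("AT", 2, 6)]

    def test_canonical_motif_is_minimal_rotation(self):
        recs = find_ssrs(Molecule("m", "G" * 5 + "TA" * 7 + "G" * 5))
        assert recs[0].motif == "AT"

    def test_runs_split_at_n(self):
        recs = find_ssrs(Molecule("m", "T" * 6 + "N" + "T" * 6))
        assert recs == []  # neither side reaches the mono threshold

    def test_missing_threshold_rejected(self):
        with pytest.raises(ValueError):
            find_ssrs(Molecule("m", "ACGT"), {1: 10})

    def test_planted_motif_matches_brute_force(self):
        rng = np.random.default_rng(42)
        seq = random_dna(rng, 5000)
        pos = 2000
        seq = seq[:pos - 1] + "G" + "TA" * 8 + "G" + seq[pos + 17:]
        mol = Molecule("m", seq)
        got = {(r.start, r.end, r.unit_length, r.copies, r.motif)
               for r in find_ssrs(mol)}
        expect = brute_ssrs(seq, DEFAULT_SSR_THRESHOLDS)
        assert got == expect
        assert any(s == pos + 1 and c == 8 for s, e, u, c, m_ in got if u == 2)

    def test_no_overlap_with_longer_same_motif_report(self):
        # one maximal run only, never a shorter sub-window
        recs = find_ssrs(Molecule("m", "C" + "A" * 15 + "C"))
        assert len(recs) == 1
        assert recs[0].copies == 15


class TestTandem:
    def test_perfect_unit(self):
        recs = find_tandem(Molecule("m", "ACGTACGTACGT"), min_unit=2)
        assert len(recs) == 1
        r = recs[0]
        assert (r.unit_length, r.copy_number, r.match_pct) == (4, 3.0, 100.0)

    def test_one_substitution_match_pct_equals_adjacency_count(self):
        seq = "ACGTA" * 4
        seq = seq[:12] + "C" + seq[13:]  # substitution inside copy 3
        recs = [r for r in find_tandem(Molecule("m", seq), min_unit=2)
                if r.unit_length == 5]
        assert len(recs) == 1
        r = recs[0]
        expect = brute_adjacent_match_pct(seq, r.start, r.end, 5)
        assert r.match_pct == pytest.approx(expect, abs=0.1)
        assert r.match_pct == pytest.approx(100 * 13 / 15, abs=0.1)

    def test_random_sequence_mostly_empty_and_hits_verified(self):
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 1000)
        recs = find_tandem(Molecule("m", seq), min_unit=13, max_unit=30,
                           min_match_pct=80.0)
        recs = [r for r in recs if r.end - r.start + 1 >= 26]
        for r in recs:  # any survivor must verify against the brute count
            assert brute_adjacent_match_pct(seq, r.start, r.end,
                                            r.unit_length) >= 80.0

    def test_bad_unit_range_rejected(self):
        with pytest.raises(ValueError):
            find_tandem(Molecule("m", "ACGT"), min_unit=5, max_unit=2)


def planted_pair_genome(seed=1, n=2000, length=40, kind="direct"):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, n)
    unit = random_dna(rng, length)
    second = unit if kind == "direct" else revcomp(unit)
    seq = (seq[:300] + "G" + unit + "C" + seq[300 + length + 2:1200]
           + "T" + second + "A" + seq[1200 + length + 2:])
    return Genome([Molecule("m", seq)]), unit


class TestDispersed:
    def test_planted_direct_pair(self):
        g, _ = planted_pair_genome(kind="direct")
        reps = [r for r in find_dispersed(g, 30) if r.length >= 30]
        assert len(reps) == 1
        r = reps[0]
        assert r.kind == "direct" and r.length == 40
        assert r.occ1 == ("m", 302, 341, "+")
        assert r.occ2 == ("m", 1202, 1241, "+")

    def test_planted_palindromic_pair(self):
        g, _ = planted_pair_genome(kind="palindromic")
        reps = find_dispersed(g, 30)
        assert len(reps) == 1
        assert reps[0].kind == "palindromic"
        assert reps[0].occ1[3] == "+" and reps[0].occ2[3] == "-"

    def test_min_length_refused_below_8(self):
        g, _ = planted_pair_genome()
        with pytest.raises(ValueError):
            find_dispersed(g, 7)

    def test_occurrences_reextract_identically(self, bundle):
        for r in find_dispersed(bundle["genome"], 30):
            assert r.verify(bundle["genome"])

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(300, 601))
        seq = random_dna(rng, n)
        if seed % 2:  # plant a 15-mer pair so non-trivial cases occur
            u = random_dna(rng, 15)
            seq = seq[:50] + u + seq[65:200] + u + seq[215:]
        got = dispersed_as_set(find_dispersed(Genome([Molecule("m", seq)]), 12))
        assert got == brute_dispersed(seq, 12)

    def test_invariant_under_genome_revcomp(self):
        g, _ = planted_pair_genome(seed=5, kind="palindromic")
        n = g.molecules[0].length
        g_rc = Genome([Molecule("m", revcomp(g.molecules[0].seq))])
        fwd = find_dispersed(g, 30)
        rev = find_dispersed(g_rc, 30)
        assert [(r.kind, r.length) for r in fwd] == [(r.kind, r.length) for r in rev]
        # coordinates mirror: start' = n - end + 1
        mirrored = {(n - r.occ2[2] + 1, n - r.occ1[2] + 1) for r in fwd}
        assert {(r.occ1[1], r.occ2[1]) for r in rev} == mirrored

    def test_circular_wraparound_hit(self):
        rng = np.random.default_rng(9)
        core = random_dna(rng, 3000)
        u = random_dna(rng, 50)
        # one mid-molecule copy, one copy split across the origin
        seq = u[25:] + "C" + core[:950] + "G" + u + "C" + core[1002:2920] + "A" + u[:25]
        g = Genome([Molecule("c", seq, "circular")])
        reps = find_dispersed(g, 30)
        assert len(reps) == 1
        r = reps[0]
        assert r.length >= 50
        wrapped = [o for o in (r.occ1, r.occ2) if o[2] > g["c"].length]
        assert len(wrapped) == 1  # one occurrence wraps the origin
        assert r.verify(g)

    def test_cross_molecule_pair(self):
        rng = np.random.default_rng(13)
        u = random_dna(rng, 60)
        a = random_dna(rng, 800)
        b = random_dna(rng, 800)
        g = Genome([Molecule("m1", a[:400] + "G" + u + "C" + a[462:]),
                    Molecule("m2", b[:100] + "T" + u + "A" + b[162:])])
        reps = find_dispersed(g, 30)
        assert len(reps) == 1
        assert reps[0].occ1[0] == "m1" and reps[0].occ2[0] == "m2"


class TestLongest:
    def test_picks_maximum_length(self):
        rng = np.random.default_rng(21)
        seq = random_dna(rng, 4000)
        u1, u2 = random_dna(rng, 35), random_dna(rng, 120)
        seq = (seq[:200] + "A" + u1 + "C" + seq[237 + 2:900] + "G" + u2 + "T"
               + seq[1022 + 2:2000] + "T" + u1 + "G" + seq[2037 + 2:3000]
               + "C" + u2 + "A" + seq[3122 + 2:])
        g = Genome([Molecule("m", seq)])
        top = longest_repeat(g)
        assert top.length == 120

    def test_empty_genome_returns_none(self):
        g = Genome([Molecule("m", random_dna(np.random.default_rng(2), 500))])
        assert longest_repeat(g) is None

    def test_tie_broken_canonically(self):
        rng = np.random.default_rng(31)
        u1, u2 = random_dna(rng, 40), random_dna(rng, 40)
        base = random_dna(rng, 3000)
        seq = (base[:100] + "A" + u2 + "C" + base[142:600] + "G" + u1 + "T"
               + base[642:1500] + "T" + u2 + "G" + base[1542:2200] + "C" + u1
               + "A" + base[2242:])
        g = Genome([Molecule("m", seq)])
        top = longest_repeat(g)
        reps = find_dispersed(g, 30)
        forties = [r for r in reps if r.length == 40]
        assert len(forties) == 2
        assert top.occ1[1] == min(r.occ1[1] for r in forties)
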