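"""Conformation construction and spanning-read recombination genotyping."""

import numpy as np
import pytest

from helpers import random_dna
from mitostruct import (DispersedRepeat, Genome, Molecule, PlantedRepeatPair,
                        ReadModel, SimConfig, assign_read,
                        build_conformations, count_support,
                        recombination_screen, revcomp, simulate_genome,
                        simulate_reads)


def two_mol_pair(seed=1, length=300, kind="direct"):
    cfg = SimConfig(seed=seed,
                    molecules=[(20_000, "linear"), (12_000, "linear")],
                    planted_repeat_pairs=[
                        PlantedRepeatPair(length, kind, molecule1=0, pos1=6000,
                                          molecule2=1, pos2=4000)],
                    plant_margin=150)
    genome, truth = simulate_genome(cfg)
    return genome, truth.repeat_pairs[0]


class TestBuildConformations:
    def test_primary_refs_are_genome_slices(self):
        genome, rep = two_mol_pair()
        conf = build_conformations(genome, rep, flank_len=500)
        m1, m2 = genome["mol1"], genome["mol2"]
        assert conf.refs_primary[0][0] == m1.seq[6000 - 500:6000 + 300 + 500]
        assert conf.refs_primary[1][0] == m2.seq[4000 - 500:4000 + 300 + 500]

    def test_alternative_exchanges_downstream_flanks(self):
        genome, rep = two_mol_pair()
        conf = build_conformations(genome, rep, flank_len=500)
        l1 = genome["mol1"].seq[6000 - 500:6000]
        r2 = genome["mol2"].seq[4000 + 300:4000 + 300 + 500]
        assert conf.refs_alternative[0][0] == l1 + conf.unit + r2

    def test_unit_identical_across_all_references(self):
        genome, rep = two_mol_pair(kind="palindromic", seed=3)
        conf = build_conformations(genome, rep, flank_len=400)
        for seq, (us, ue) in conf.refs_primary + conf.refs_alternative:
            assert seq[us - 1:ue] == conf.unit

    def test_palindromic_occ2_flanks_reverse_complemented(self):
        genome, rep = two_mol_pair(kind="palindromic", seed=3)
        conf = build_conformations(genome, rep, flank_len=400)
        m2 = genome["mol2"]
        # occ2 unit orientation is the minus strand: its reference is the
        # reverse complement of the genomic window around the occurrence
        expect = revcomp(m2.seq[4000 - 400:4000 + 300 + 400])
        assert conf.refs_primary[1][0] == expect

    def test_flanks_truncated_at_linear_end(self):
        rng = np.random.default_rng(4)
        u = random_dna(rng, 100)
        tail = random_dna(rng, 2000)
        seq = u + "C" + tail[:800] + "T" + u + "A" + tail[802:1500]
        g = Genome([Molecule("m", seq)])
        rep = DispersedRepeat("R1", "direct", 100, ("m", 1, 100, "+"),
                              ("m", 903, 1002, "+"))
        conf = build_conformations(g, rep, flank_len=500)
        seq1, (us, ue) = conf.refs_primary[0]
        assert us == 1  # occurrence at the molecule start has no left flank
        assert len(seq1) == 100 + 500

    def test_close_occurrences_flagged_inseparable(self, caplog):
        rng = np.random.default_rng(5)
        u = random_dna(rng, 80)
        mid = random_dna(rng, 100)
        seq = random_dna(rng, 1500) + "G" + u + "C" + mid + "T" + u + "A" \
            + random_dna(rng, 1500)
        g = Genome([Molecule("m", seq)])
        s1 = 1502
        s2 = s1 + 80 + 1 + 100 + 1
        rep = DispersedRepeat("R1", "direct", 80, ("m", s1, s1 + 79, "+"),
                              ("m", s2, s2 + 79, "+"))
        with caplog.at_level("WARNING", logger="mitostruct"):
            conf = build_conformations(g, rep, flank_len=1000)
        assert conf.inseparable
        # facing flanks shrink to the 101 bp gap
        assert len(conf.refs_primary[0][0]) == 1000 + 80 + 102

    def test_mismatched_occurrences_rejected(self):
        g = Genome([Molecule("m", "ACGTACGTAAATTTGGGCCC" * 10)])
        rep = DispersedRepeat("bad", "direct", 10, ("m", 1, 10, "+"),
                              ("m", 21, 30, "-"))
        with pytest.raises(ValueError):
            build_conformations(g, rep)


@pytest.fixture(scope="module")
def conf():
    genome, rep = two_mol_pair(seed=7)
    return build_conformations(genome, rep, flank_len=1000)


class TestAssignRead:
    def test_identity_read_from_primary(self, conf):
        assert assign_read(conf.refs_primary[0][0], conf) == "primary"

    def test_identity_read_from_alternative(self, conf):
        assert assign_read(conf.refs_alternative[1][0], conf) == "alternative"

    def test_reverse_complement_read_same_label(self, conf):
        r = conf.refs_alternative[0][0]
        assert assign_read(revcomp(r), conf) == "alternative"

    def test_unit_plus_one_flank_is_nonspanning(self, conf):
        seq, (us, ue) = conf.refs_primary[0]
        read = seq[us - 1:]  # unit + right flank only
        assert assign_read(read, conf) == "nonspanning"

    def test_short_read_nonspanning_by_construction(self, conf):
        assert assign_read("ACGT" * 30, conf, anchor=100) == "nonspanning"

    def test_anchor_above_flank_rejected(self, conf):
        with pytest.raises(ValueError):
            assign_read("A" * 5000, conf, anchor=2000)


class TestCountSupport:
    def test_error_free_reads_all_labeled_none_ambiguous(self):
        genome, rep = two_mol_pair(seed=9)
        model = ReadModel(n_reads=120, mean_length=2500, min_length=600,
                          sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        reads, truth = simulate_reads(genome, rep, p=0.5, model=model,
                                      seed=17, spanning_only=True)
        conf = build_conformations(genome, rep)
        sup = count_support(reads, conf)
        assert sup.n_ambiguous == 0 and sup.n_nonspanning == 0
        assert sup.n_primary == truth.n_reads_labeled("primary")
        assert sup.n_alternative == truth.n_reads_labeled("alternative")

    def test_all_primary_gives_zero_frequency(self):
        genome, rep = two_mol_pair(seed=9)
        model = ReadModel(n_reads=40, mean_length=2500, min_length=600,
                          sub_rate=0.0, ins_rate=0.0, del_rate=0.0)
        reads, _ = simulate_reads(genome, rep, p=0.0, model=model, seed=5,
                                  spanning_only=True)
        sup = count_support(reads, build_conformations(genome, rep))
        assert sup.n_alternative == 0 and sup.frequency == 0.0

    def test_no_reads_frequency_undefined(self):
        genome, rep = two_mol_pair(seed=9)
        sup = count_support([], build_conformations(genome, rep))
        assert sup.frequency is None

    def test_occurrence_relabeling_leaves_counts_invariant(self):
        genome, rep = two_mol_pair(seed=9)
        swapped = DispersedRepeat(rep.repeat_id, rep.kind, rep.length,
                                  rep.occ2, rep.occ1)
        model = ReadModel(n_reads=60, mean_length=2500, min_length=600,
                          sub_rate=0.05, ins_rate=0.01, del_rate=0.01)
        reads, _ = simulate_reads(genome, rep, p=0.4, model=model, seed=23,
                                  spanning_only=True)
        sup1 = count_support(reads, build_conformations(genome, rep))
        sup2 = count_support(reads, build_conformations(genome, swapped))
        assert (sup1.n_primary, sup1.n_alternative) == \
               (sup2.n_primary, sup2.n_alternative)

    def test_strand_symmetry_of_whole_read_set(self):
        genome, rep = two_mol_pair(seed=9)
        model = ReadModel(n_reads=60, mean_length=2500, min_length=600)
        reads, _ = simulate_reads(genome, rep, p=0.5, model=model, seed=29,
                                  spanning_only=True)
        conf = build_conformations(genome, rep)
        flipped = [(n, revcomp(s)) for n, s in reads]
        s1, s2 = count_support(reads, conf), count_support(flipped, conf)
        assert (s1.n_primary, s1.n_alternative, s1.n_ambiguous) == \
               (s2.n_primary, s2.n_alternative, s2.n_ambiguous)


class TestScreen:
    def test_only_recombining_pair_flagged(self):
        cfg = SimConfig(seed=31,
                        molecules=[(30_000, "linear"), (15_000, "linear")],
                        planted_repeat_pairs=[
                            PlantedRepeatPair(400, "direct", 0, 5000, 1, 3000,
                                              recomb_freq=0.4),
                            PlantedRepeatPair(350, "direct", 0, 15000, 0,
                                              22000, recomb_freq=0.0)],
                        plant_margin=200)
        genome, truth = simulate_genome(cfg)
        active, silent = truth.repeat_pairs
        model = ReadModel(n_reads=150, mean_length=3000, min_length=600)
        reads, _ = simulate_reads(genome, active, p=0.4, model=model, seed=37)
        reps = [active, silent]
        results = recombination_screen(genome, reads, reps,
                                       min_repeat_len=300)
        flags = {rep.repeat_id: sup.flagged for rep, sup in results}
        assert flags[active.repeat_id] is True
        assert flags[silent.repeat_id] is False

    def test_empty_read_set_flags_nothing(self):
        genome, rep = two_mol_pair(seed=9)
        results = recombination_screen(genome, [], [rep], min_repeat_len=100)
        (r, sup), = results
        assert sup.frequency is None and not sup.flagged

    def test_short_repeats_excluded_by_length_filter(self):
        genome, rep = two_mol_pair(seed=9, length=80)
        assert recombination_screen(genome, [], [rep],
                                    min_repeat_len=100) == []


class TestFrequencyRecovery:
    def test_estimate_tracks_mixture_proportion(self):
        genome, rep = two_mol_pair(seed=41)
        model = ReadModel(n_reads=200, mean_length=2000, min_length=600,
                          sub_rate=0.05, ins_rate=0.0, del_rate=0.0)
        conf = build_conformations(genome, rep)
        for p in (0.2, 0.8):
            reads, truth = simulate_reads(genome, rep, p=p, model=model,
                                          seed=101, spanning_only=True)
            sup = count_support(reads, conf)
            n = sup.n_primary + sup.n_alternative
            se = (p * (1 - p) / n) ** 0.5
            assert abs(sup.frequency - p) <= 3 * se + 0.02
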