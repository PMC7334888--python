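"""Recombination engine: sampling, trimming, frame closure, assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vdjsim as vs
from vdjsim.engine import (
    FrameUnsatisfiableError,
    SimulationError,
    sample_single_insertion,
)
from vdjsim.germline import GermlineError, LengthDistribution


class TestSampleGene:
    def test_degenerate_table(self, rng):
        t = vs.FrequencyTable({"g1": 1.0}, "V")
        assert all(vs.sample_gene(t, rng) == "g1" for _ in range(50))

    def test_uniform_empirical_frequencies(self, rng):
        t = vs.FrequencyTable({g: 1.0 for g in "abcd"}, "V")
        draws = [vs.sample_gene(t, rng) for _ in range(40_000)]
        for g in "abcd":
            assert draws.count(g) / 40_000 == pytest.approx(0.25, abs=0.01)

    def test_biased_table_binomial_band(self, rng):
        t = vs.FrequencyTable({"g1": 0.9, "g2": 0.1}, "V")
        n1 = sum(vs.sample_gene(t, rng) == "g1" for _ in range(10_000))
        assert abs(n1 - 9000) <= 3 * np.sqrt(900)


class TestTrimSegment:
    def test_zero_trim_keeps_sequence(self, rng):
        d = vs.GermlineGene("d1", "D", "ACGTACGT")
        dist = LengthDistribution((0,), (1.0,), "d_trim_3")
        seq, t = vs.trim_segment(d, "3p", dist, rng)
        assert (seq, t) == ("ACGTACGT", 0)

    def test_three_prime_trim_is_string_suffix_removal(self, rng):
        d = vs.GermlineGene("d1", "D", "ACGTACGT")
        dist = LengthDistribution((3,), (1.0,), "d_trim_3")
        seq, t = vs.trim_segment(d, "3p", dist, rng)
        assert (seq, t) == ("ACGTA", 3)

    def test_five_prime_trim(self, rng):
        d = vs.GermlineGene("d1", "D", "ACGTACGT")
        dist = LengthDistribution((2,), (1.0,), "d_trim_5")
        assert vs.trim_segment(d, "5p", dist, rng) == ("GTACGT", 2)

    def test_v_anchor_always_survives(self, rng):
        # length 12, anchor at 6: admissible trims are exactly {0..3}
        v = vs.GermlineGene("v1", "V", "AAAAAATGTAAA", 6)
        dist = LengthDistribution(tuple(range(8)), [1 / 8] * 8, "v_trim")
        for _ in range(10_000):
            seq, t = vs.trim_segment(v, "3p", dist, rng)
            assert t <= 3
            assert seq[6:9] == "TGT"

    def test_unsatisfiable_support_is_an_error(self, rng):
        v = vs.GermlineGene("v1", "V", "AAAAAATGTAAA", 6)
        dist = LengthDistribution((5, 6), (0.5, 0.5), "v_trim")
        with pytest.raises(GermlineError, match="no admissible"):
            vs.trim_segment(v, "3p", dist, rng)


class TestChooseJTrim:
    def test_anchor_at_origin_forces_zero(self, rng):
        j = vs.GermlineGene("j1", "J", "TTTGGAAAAGGA", 0)
        dist = LengthDistribution.geometric(2.0, "j_trim")
        assert vs.choose_j_trim(j, dist, rng) == 0

    def test_restriction_renormalizes_uniformly(self, rng):
        # brute force: admissible set for anchor_offset=4 is {0..4}
        j = vs.GermlineGene("j1", "J", "AAAATTTGGAGGA", 4)
        dist = LengthDistribution(tuple(range(7)), [1 / 7] * 7, "j_trim")
        draws = np.array([vs.choose_j_trim(j, dist, rng)
                          for _ in range(10_000)])
        assert set(draws) == {0, 1, 2, 3, 4}
        freqs = np.bincount(draws) / len(draws)
        assert np.allclose(freqs, 0.2, atol=0.02)

    def test_empty_admissible_set_is_an_error(self, rng):
        j = vs.GermlineGene("j1", "J", "AAAATTTGGAGGA", 4)
        dist = LengthDistribution((5, 6), (0.5, 0.5), "j_trim")
        with pytest.raises(GermlineError, match="no admissible"):
            vs.choose_j_trim(j, dist, rng)


class TestSampleInsertions:
    def test_n2_restricted_to_frame_residue(self, rng):
        n1 = LengthDistribution((0,), (1.0,), "n1_len")
        n2 = LengthDistribution((0, 1, 2), [1 / 3] * 3, "n2_len")
        # template length 6 and n1=0: only n2 = 0 satisfies residue 0 (mod 3)
        for _ in range(100):
            s1, s2 = vs.sample_insertions(n1, n2, 6, rng)
            assert s1 == "" and s2 == ""

    def test_degenerate_n1_is_empty(self, rng):
        n1 = LengthDistribution((0,), (1.0,), "n1_len")
        n2 = LengthDistribution.geometric(4.0, "n2_len")
        s1, _ = vs.sample_insertions(n1, n2, 9, rng)
        assert s1 == ""

    def test_frame_unsatisfiable_signalled(self, rng):
        n1 = LengthDistribution((0,), (1.0,), "n1_len")
        n2 = LengthDistribution((1,), (1.0,), "n2_len")
        with pytest.raises(FrameUnsatisfiableError):
            vs.sample_insertions(n1, n2, 6, rng)  # needs n2 ≡ 0 (mod 3)

    def test_single_insertion_closes_frame(self, rng):
        dist = LengthDistribution.geometric(4.0, "n1_len")
        for template in (6, 7, 8):
            s = sample_single_insertion(dist, template, rng)
            assert (template + len(s)) % 3 == 0


class TestExtractJunction:
    def test_hand_assembled_toy_event(self):
        # V anchor TGT at 9, J anchor TTT at 21: junction = seq[9:24], 5 aa
        seq = "A" * 9 + "TGT" + "A" * 9 + "TTT" + "GGA"
        junction_nt, junction_aa = vs.extract_junction(seq, 9, 21)
        assert junction_nt == seq[9:24]
        assert junction_aa == "CKKKF"

    def test_tryptophan_anchor(self):
        seq = "A" * 9 + "TGT" + "A" * 9 + "TGG" + "GGA"
        _, junction_aa = vs.extract_junction(seq, 9, 21)
        assert junction_aa.endswith("W")

    def test_misaligned_anchor_is_internal_error(self):
        with pytest.raises(SimulationError, match="codon-aligned"):
            vs.extract_junction("A" * 30, 9, 20)


class TestRecombineOnce:
    def test_guaranteed_stop_codon_exhausts_with_cause(self):
        # a V gene with an in-frame TAA downstream of the anchor region is
        # impossible; force one via a germline with TAA right after position 0
        v = vs.GermlineGene("vStop", "V", "TGTTAAAAA", 0)
        gs = vs.GermlineSet(
            species="s", chain="IGK", v_genes=[v],
            j_genes=[vs.GermlineGene("j1", "J", "TTTGGAAAAGGA", 0)])
        cfg = vs.make_default_config(
            gs, 1, 3,
            v_trim_dist=LengthDistribution((0,), (1.0,), "v_trim"),
            max_attempts_per_sequence=50)
        from collections import Counter
        tally = Counter()
        with pytest.raises(SimulationError, match="stop_codon"):
            vs.recombine_once(cfg, np.random.default_rng(0), tally)
        assert tally["stop_codon"] == 50

    def test_fragments_reassemble_exactly(self, small_repertoire):
        gs = small_repertoire.germline_set
        for rec in small_repertoire:
            ev = rec.event
            assert ev.fragment_boundaries[0][0] == 0
            assert ev.fragment_boundaries[-1][1] == len(rec.sequence_nt)
            for (a, b), (c, d) in zip(ev.fragment_boundaries,
                                      ev.fragment_boundaries[1:]):
                assert b == c
            assert vs.replay_record(rec, gs) == rec.sequence_nt

    def test_seeded_determinism(self, germline_set):
        cfg = vs.make_default_config(germline_set, 1, 3)
        a = vs.recombine_once(cfg, np.random.default_rng(9))
        b = vs.recombine_once(cfg, np.random.default_rng(9))
        assert a == b


class TestSimulateRepertoire:
    def test_exact_size_and_record_invariants(self, small_repertoire):
        assert len(small_repertoire) == 150
        for rec in small_repertoire:
            assert len(rec.sequence_nt) % 3 == 0
            assert "*" not in rec.sequence_aa
            assert rec.junction_aa[0] == "C"
            assert rec.junction_aa[-1] in "FW"
            assert len(rec.junction_nt) == 3 * len(rec.junction_aa)
            start = rec.event.v_anchor_pos
            assert start % 3 == 0
            assert rec.sequence_nt[start:start + len(rec.junction_nt)] == \
                rec.junction_nt

    def test_same_seed_identical_different_seed_different(self, germline_set):
        cfg = vs.make_default_config(germline_set, 30, seed=5)
        a = vs.simulate_repertoire(cfg)
        b = vs.simulate_repertoire(cfg)
        assert [r.sequence_nt for r in a] == [r.sequence_nt for r in b]
        c = vs.simulate_repertoire(
            vs.make_default_config(germline_set, 30, seed=6))
        assert [r.junction_nt for r in a][:10] != \
               [r.junction_nt for r in c][:10]

    def test_no_d_chain_has_single_insertion(self, nolocus_set):
        rep = vs.simulate_repertoire(vs.make_default_config(nolocus_set, 60,
                                                            seed=2))
        for rec in rep:
            ev = rec.event
            assert rec.d_call is None and ev.d_id is None
            assert ev.n2_seq is None
            assert ev.d_trim_5p is None and ev.d_trim_3p is None
            assert len(ev.fragment_boundaries) == 3
        frac, offenders = vs.annotation_consistency(rep)
        assert frac == 1.0 and offenders == []

    @given(seed=st.integers(0, 2_000))
    def test_productivity_invariants_over_seeds(self, germline_set, seed):
        cfg = vs.make_default_config(germline_set, 5, seed=seed)
        for rec in vs.simulate_repertoire(cfg):
            assert "*" not in rec.sequence_aa
            assert len(rec.sequence_nt) % 3 == 0
            assert rec.junction_aa[0] == "C" and rec.junction_aa[-1] in "FW"


@pytest.fixture(scope="module")
def paired():
    ca = vs.make_default_config(
        vs.generate_synthetic_germline_set(5, 3, 2, seed=5, chain="TRB"),
        10, 1)
    cb = vs.make_default_config(
        vs.generate_synthetic_germline_set(5, 0, 2, seed=6, chain="TRA"),
        10, 1)
    return ca, cb


class TestSimulatePaired:
    def test_cells_share_ids_across_chains(self, paired):
        rep = vs.simulate_paired(*paired, n_cells=50, seed=99)
        assert len(rep) == 100
        cells = {}
        for rec in rep:
            cells.setdefault(rec.cell_id, set()).add(rec.chain)
        assert len(cells) == 50
        assert all(chains == {"TRA", "TRB"} for chains in cells.values())

    def test_invalid_pairing_rejected(self, paired, germline_set):
        igh = vs.make_default_config(germline_set, 10, 1)
        with pytest.raises(SimulationError, match="invalid chain pairing"):
            vs.simulate_paired(igh, paired[1], n_cells=5, seed=1)

    def test_seeded_determinism(self, paired):
        a = vs.simulate_paired(*paired, n_cells=10, seed=4)
        b = vs.simulate_paired(*paired, n_cells=10, seed=4)
        assert [r.sequence_nt for r in a] == [r.sequence_nt for r in b]
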