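"""Germline reference: loading, synthesis, frequency tables, distributions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import spearmanr

import vdjsim as vs
from vdjsim.germline import (
    GermlineError,
    LengthDistribution,
    read_frequency_table,
    read_length_distribution,
    write_frequency_table,
    write_germline_fasta,
    write_length_distribution,
)
from vdjsim._seq import CODON_TO_AA


class TestGermlineGene:
    def test_v_anchor_must_be_cysteine(self):
        with pytest.raises(GermlineError, match="not C"):
            vs.GermlineGene("v1", "V", "AAATGGAAA", 3)
        g = vs.GermlineGene("v1", "V", "AAATGTAAA", 3)
        assert g.anchor_codon == "TGT"

    def test_j_anchor_must_be_phe_or_trp(self):
        vs.GermlineGene("j1", "J", "TTTGGAAAAGGA", 0)
        vs.GermlineGene("j2", "J", "TGGGGAAAAGGA", 0)
        with pytest.raises(GermlineError, match="not F/W"):
            vs.GermlineGene("j3", "J", "AAAGGAAAAGGA", 0)

    def test_alphabet_and_range_checks(self):
        with pytest.raises(GermlineError):
            vs.GermlineGene("d1", "D", "ACGU")
        with pytest.raises(GermlineError):
            vs.GermlineGene("d1", "D", "")
        with pytest.raises(GermlineError, match="out of range"):
            vs.GermlineGene("v1", "V", "TGT", 1)


class TestLoadFasta:
    def test_valid_v_records_all_accepted(self, tmp_path):
        genes = [vs.GermlineGene("va", "V", "AAATGTAAA", 3),
                 vs.GermlineGene("vb", "V", "CCCTGCCCCTGA"[:9], 3)]
        p = tmp_path / "v.fasta"
        write_germline_fasta(genes, p)
        accepted, rejected = vs.load_germline_fasta(p, "V")
        assert len(accepted) == 2 and rejected == []

    def test_empty_fasta_is_an_error(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(GermlineError, match="empty FASTA"):
            vs.load_germline_fasta(p, "V")

    def test_duplicate_identifiers_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAAATGTAAA\n>a\nAAATGTAAA\n")
        with pytest.raises(GermlineError, match="duplicate"):
            vs.load_germline_fasta(p, "V")

    def test_non_acgt_characters_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nAAANGTAAA\n")
        with pytest.raises(GermlineError, match="non-ACGT"):
            vs.load_germline_fasta(p, "V")

    def test_v_without_cysteine_reported_not_dropped(self, tmp_path):
        # oracle: brute-force scan confirms no codon anywhere is TGT/TGC
        seq = "AAAGGGAAAGGG"
        assert all(seq[i:i + 3] not in ("TGT", "TGC")
                   for i in range(len(seq) - 2))
        p = tmp_path / "v.fasta"
        p.write_text(f">v1\n{seq}\n")
        accepted, rejected = vs.load_germline_fasta(p, "V")
        assert accepted == []
        assert rejected == [("v1", "no cysteine anchor")]

    def test_roundtrip_preserves_sequences_and_anchors(self, tmp_path,
                                                       germline_set):
        for cls, genes in (("V", germline_set.v_genes),
                           ("D", germline_set.d_genes),
                           ("J", germline_set.j_genes)):
            p = tmp_path / f"{cls}.fasta"
            write_germline_fasta(genes, p)
            loaded, rejected = vs.load_germline_fasta(p, cls)
            assert rejected == []
            assert [(g.gene_id, g.sequence_nt, g.anchor_offset)
                    for g in loaded] == \
                   [(g.gene_id, g.sequence_nt, g.anchor_offset)
                    for g in genes]


class TestSyntheticGermline:
    def test_counts_and_invariants(self):
        gs = vs.generate_synthetic_germline_set(5, 3, 2, seed=1)
        assert (len(gs.v_genes), len(gs.d_genes), len(gs.j_genes)) == (5, 3, 2)
        assert gs.has_d and gs.chain == "IGH"

    def test_seed_determinism(self):
        a = vs.generate_synthetic_germline_set(5, 3, 2, seed=1)
        b = vs.generate_synthetic_germline_set(5, 3, 2, seed=1)
        assert [g.sequence_nt for g in a.v_genes + a.d_genes + a.j_genes] == \
               [g.sequence_nt for g in b.v_genes + b.d_genes + b.j_genes]
        c = vs.generate_synthetic_germline_set(5, 3, 2, seed=2)
        assert [g.sequence_nt for g in a.v_genes] != \
               [g.sequence_nt for g in c.v_genes]

    def test_zero_v_or_j_is_an_error(self):
        with pytest.raises(GermlineError):
            vs.generate_synthetic_germline_set(0, 3, 2, seed=1)
        with pytest.raises(GermlineError):
            vs.generate_synthetic_germline_set(5, 3, 0, seed=1)

    def test_ranges_too_short_for_anchors(self):
        with pytest.raises(GermlineError, match="too short"):
            vs.generate_synthetic_germline_set(2, 0, 2, v_len=(6, 8), seed=1)
        with pytest.raises(GermlineError, match="J anchor"):
            vs.generate_synthetic_germline_set(2, 0, 2, j_len=(9, 11), seed=1)

    @given(seed=st.integers(0, 10_000))
    def test_invariants_hold_over_seeds(self, seed):
        gs = vs.generate_synthetic_germline_set(3, 2, 2, seed=seed)
        for g in gs.v_genes:
            assert CODON_TO_AA[g.anchor_codon] == "C"
            assert g.anchor_offset % 3 == 0
        for g in gs.j_genes:
            assert CODON_TO_AA[g.anchor_codon] in "FW"
            assert (len(g) - g.anchor_offset) % 3 == 0


class TestFrequencyTable:
    def test_uniform(self, germline_set):
        t = vs.uniform_frequency_table(germline_set.d_genes)
        assert np.allclose(t.probabilities, 0.25)

    def test_single_gene_degenerate(self, germline_set):
        t = vs.uniform_frequency_table(germline_set.v_genes[:1])
        assert t.probabilities.tolist() == [1.0]

    def test_counts_are_normalized(self):
        t = vs.FrequencyTable({"a": 2, "b": 1, "c": 1}, "V")
        assert np.allclose(t.probabilities, [0.5, 0.25, 0.25])

    def test_empty_is_an_error(self):
        with pytest.raises(GermlineError):
            vs.uniform_frequency_table([])

    def test_file_roundtrip(self, tmp_path, germline_set):
        t = vs.geometric_frequency_table(germline_set.v_genes)
        p = tmp_path / "freq.tsv"
        write_frequency_table(t, p)
        back = read_frequency_table(p, "V")
        assert back.gene_ids == t.gene_ids
        assert np.allclose(back.probabilities, t.probabilities)


class TestPerturbFrequencyTable:
    def test_zero_noise_is_identity(self, germline_set):
        t = vs.geometric_frequency_table(germline_set.v_genes)
        out = vs.perturb_frequency_table(t, 0.0, seed=1)
        assert out == t

    def test_deterministic_and_normalized(self, germline_set):
        t = vs.uniform_frequency_table(germline_set.v_genes)
        a = vs.perturb_frequency_table(t, 0.5, seed=3)
        b = vs.perturb_frequency_table(t, 0.5, seed=3)
        assert a == b
        assert np.isclose(a.probabilities.sum(), 1.0)

    def test_negative_noise_rejected(self, germline_set):
        t = vs.uniform_frequency_table(germline_set.v_genes)
        with pytest.raises(GermlineError):
            vs.perturb_frequency_table(t, -0.1, seed=1)

    def test_rank_agreement_decreases_with_noise(self):
        # Monte-Carlo oracle: mean Spearman to the input drops as noise grows
        t = vs.FrequencyTable({"a": 4, "b": 3, "c": 2, "d": 1}, "V")
        def mean_rho(sd):
            rhos = []
            for seed in range(1000):
                p = vs.perturb_frequency_table(t, sd, seed)
                rhos.append(spearmanr(t.probabilities,
                                      p.probabilities).statistic)
            return float(np.mean(rhos))
        low, high = mean_rho(0.1), mean_rho(2.0)
        assert high < low < 1.0 + 1e-12
        assert high < 1.0

    @given(seed=st.integers(0, 5000))
    def test_support_preserved(self, seed):
        t = vs.FrequencyTable({"a": 4, "b": 3, "c": 0, "d": 1}, "V")
        p = vs.perturb_frequency_table(t, 1.0, seed)
        assert (p.entries["c"] == 0) and all(
            p.entries[g] > 0 for g in "abd")


class TestLengthDistribution:
    def test_geometric_shape(self):
        d = LengthDistribution.geometric(2.0, "v_trim")
        assert d.support[0] == 0 and d.max_support == 15
        # untruncated geometric with mean 2 has success prob 1/3
        assert d.probabilities[1] / d.probabilities[0] == pytest.approx(2 / 3)

    def test_restrict_and_empty_restriction(self):
        d = LengthDistribution((5, 6), (0.5, 0.5), "j_trim")
        assert d.restrict(max_value=4) is None
        r = d.restrict(max_value=5)
        assert r.support == (5,) and r.probabilities.tolist() == [1.0]

    def test_strictly_increasing_support_required(self):
        with pytest.raises(GermlineError):
            LengthDistribution((0, 0, 1), (0.3, 0.3, 0.4), "v_trim")

    def test_file_roundtrip(self, tmp_path):
        d = LengthDistribution.geometric(4.0, "n1_len")
        p = tmp_path / "d.tsv"
        write_length_distribution(d, p)
        back = read_length_distribution(p, "n1_len")
        assert back.support == d.support
        assert np.allclose(back.probabilities, d.probabilities)
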