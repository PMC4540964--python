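"""PWM handling and homotypic-cluster scoring."""
import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmou.crmscore import (DEFAULT_PSEUDOCOUNT, PWM, crm_score, load_pwms,
                            pwm_from_counts, read_fasta_panel,
                            reverse_complement, score_orthologs)
from oracles import brute_force_crm_score

JASPAR_TEXT = """>MA0001.1 TEST1
A [ 8  2  0  0 ]
C [ 2  8  0  0 ]
G [ 0  0  8  2 ]
T [ 0  0  2  8 ]
>MA0002.1 TEST2
A [ 4 4 ]
C [ 4 4 ]
G [ 4 4 ]
T [ 4 4 ]
"""


class TestPWM:
    def test_uniform_counts_zero_information(self):
        pwm = pwm_from_counts("u", np.ones((8, 4)) * 5, 0.0)
        assert pwm.info_content == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_consensus_approaches_two_bits_per_position(self):
        counts = np.eye(4)[[0, 1, 2, 3]] * 100
        pwm = pwm_from_counts("c", counts, 1e-9)
        assert pwm.info_content == pytest.approx(8.0, abs=1e-5)

    def test_pseudocount_normalization_arithmetic(self):
        pwm = pwm_from_counts("p", [[8, 2, 0, 0]], 0.375)
        expected = np.array([8.375, 2.375, 0.375, 0.375]) / 11.5
        np.testing.assert_allclose(pwm.probs[0], expected, atol=5e-5)
        np.testing.assert_allclose(
            pwm.probs[0], [0.7283, 0.2065, 0.0326, 0.0326], atol=1e-4)

    def test_jaspar_parsing(self):
        pwms = load_pwms(io.StringIO(JASPAR_TEXT))
        assert [p.pwm_id for p in pwms] == ["MA0001.1", "MA0002.1"]
        assert pwms[0].length == 4
        assert pwms[1].info_content == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_position_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts("z", [[0, 0, 0, 0]], 0.0)

    def test_non_numeric_matrix_rejected(self):
        bad = ">M1 x\nA [ 1 a ]\nC [ 1 1 ]\nG [ 1 1 ]\nT [ 1 1 ]\n"
        with pytest.raises(ValueError):
            load_pwms(io.StringIO(bad))


class TestCrmScore:
    def test_zero_information_pwm_scores_zero(self):
        pwm = pwm_from_counts("u", np.ones((3, 4)), 0.1)
        s = crm_score("ACGTTGCAACGT", pwm, background="uniform")
        assert s.score == 0.0

    def test_empty_sequence_rejected(self):
        pwm = pwm_from_counts("c", [[9, 1, 1, 1]], 0.375)
        with pytest.raises(ValueError):
            crm_score("", pwm)

    def test_sequence_shorter_than_pwm_rejected(self):
        pwm = pwm_from_counts("c", np.tile([9.0, 1, 1, 1], (5, 1)), 0.375)
        with pytest.raises(ValueError):
            crm_score("ACG", pwm)

    def test_tandem_site_copies_increase_score(self):
        counts = np.array([[20, 0, 0, 0], [0, 20, 0, 0], [0, 0, 20, 0],
                           [0, 0, 0, 20], [20, 0, 0, 0], [0, 0, 20, 0]])
        pwm = pwm_from_counts("c", counts, 0.375)
        scores = [crm_score("TTTT" + "ACGTAG" * k + "TTTT", pwm,
                            background="uniform").score for k in (1, 2, 3)]
        assert scores[0] < scores[1] < scores[2]

    def test_matches_brute_force_enumeration(self, rng):
        for trial in range(40):
            L = int(rng.integers(1, 5))
            n = int(rng.integers(L, 13))
            seq = "".join(rng.choice(list("ACGT"), n))
            pwm = pwm_from_counts(
                "t", rng.integers(0, 9, size=(L, 4)).astype(float), 0.375)
            gap = float(rng.uniform(2, 50))
            bgmode = ["uniform", "region"][trial % 2]
            expected = brute_force_crm_score(seq, pwm, gap, bgmode)
            got = crm_score(seq, pwm, gap=gap, background=bgmode).score
            assert got == pytest.approx(expected, abs=1e-9)

    def test_n_bases_are_score_neutral(self):
        pwm = pwm_from_counts("c", np.tile([9.0, 1, 1, 1], (4, 1)), 0.375)
        # a pure-N sequence carries no evidence either way
        assert crm_score("N" * 20, pwm, background="uniform").score == 0.0
        # neutral N context never destroys a cluster: every parse of the
        # bare cluster is still available inside the N-flanked sequence
        bare = crm_score("AAAAAAAA", pwm, background="uniform").score
        masked = crm_score("NNNN" + "AAAAAAAA" + "NNNN", pwm,
                           background="uniform").score
        assert masked >= bare - 1e-9
        assert np.isfinite(masked)

    def test_hits_reported_inside_best_interval(self):
        counts = np.tile([20.0, 0, 0, 0], (5, 1))
        pwm = pwm_from_counts("a5", counts, 0.375)
        s = crm_score("TGCGT" + "AAAAA" + "CGTGC", pwm, background="uniform")
        assert s.score > 0
        assert any(h.pos == 5 and h.strand == "+" for h in s.hits)
        assert s.start <= 5 and s.end >= 10

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 30))
        pwm = pwm_from_counts(
            "r", rng.integers(0, 12, size=(4, 4)).astype(float), 0.375)
        fwd = crm_score(seq, pwm, background="region").score
        rev = crm_score(reverse_complement(seq), pwm, background="region").score
        assert fwd == pytest.approx(rev, abs=1e-9)


class TestScoreOrthologs:
    @pytest.fixture()
    def pwm(self):
        return pwm_from_counts("c", np.tile([12.0, 1, 1, 1], (4, 1)), 0.375)

    def test_identical_sequences_identical_scores(self, pwm):
        panel = {"sp1": {"r1": "TTAAAATT"}, "sp2": {"r1": "TTAAAATT"}}
        mat = score_orthologs(panel, pwm)
        assert mat.loc["r1", "sp1"] == mat.loc["r1", "sp2"]

    def test_absent_ortholog_is_missing_not_zero(self, pwm):
        panel = {"sp1": {"r1": "TTAAAATT", "r2": "CCCGGGCC"},
                 "sp2": {"r1": "TTAAAATT"}}
        mat = score_orthologs(panel, pwm)
        assert "r2" in mat.index
        assert np.isnan(mat.loc["r2", "sp2"])
        assert mat.loc["r2", "sp1"] >= 0

    def test_duplicate_region_in_fasta_rejected(self, tmp_path):
        fa = tmp_path / "sp1.fa"
        fa.write_text(">r1|sp1\nACGT\n>r1|sp1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta_panel({"sp1": str(fa)})

    def test_fasta_panel_roundtrip(self, tmp_path, pwm):
        fa = tmp_path / "spX.fa"
        fa.write_text(">regA|spX\nTTAAAATT\n>regB|spX\nGGGGCCCC\n")
        panel = read_fasta_panel({"spX": str(fa)})
        assert panel["spX"]["regA"] == "TTAAAATT"
        mat = score_orthologs(panel, pwm)
        assert set(mat.index) == {"regA", "regB"}
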