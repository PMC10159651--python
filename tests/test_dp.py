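"""DP kernels against brute-force path enumeration, and path algebra."""

import math

import numpy as np
import pytest

import profhmm as P
from profhmm import dp

from oracles import forward_oracle, msv_oracle, viterbi_oracle

_LN2 = math.log(2.0)


def _random_instance(rng, mode=None):
    M = int(rng.integers(1, 4))
    L = int(rng.integers(1, 5))
    mode = mode or ("multihit" if rng.random() < 0.5 else "unihit")
    h = P.random_hmm(M, seed=int(rng.integers(1 << 30)))
    prof = P.configure(h, mode=mode, L=L)
    seq = P.random_sequences(1, L, seed=int(rng.integers(1 << 30)))[0]
    return prof, seq


class TestOracleEquivalence:
    def test_forward_and_viterbi_match_enumeration(self):
        rng = np.random.default_rng(101)
        for _ in range(80):
            prof, seq = _random_instance(rng)
            assert P.forward_score(prof, seq) == pytest.approx(
                forward_oracle(prof, seq), abs=1e-6)
            assert P.viterbi(prof, seq)[0] == pytest.approx(
                viterbi_oracle(prof, seq), abs=1e-9)

    def test_msv_matches_diagonal_enumeration(self):
        rng = np.random.default_rng(202)
        for _ in range(40):
            M = int(rng.integers(1, 5))
            L = int(rng.integers(1, 7))
            h = P.random_hmm(M, seed=int(rng.integers(1 << 30)))
            mode = "multihit" if rng.random() < 0.5 else "unihit"
            prof = P.configure(h, mode=mode, L=L)
            seq = P.random_sequences(1, L, seed=int(rng.integers(1 << 30)))[0]
            assert P.msv_score(prof, seq) == pytest.approx(
                msv_oracle(prof, seq), abs=1e-9)

    def test_single_node_msv_is_best_single_residue_placement(self):
        h = P.random_hmm(1, seed=4)
        prof = P.configure(h, L=5)
        seq = P.random_sequences(1, 5, seed=6)[0]
        assert P.msv_score(prof, seq) == pytest.approx(
            msv_oracle(prof, seq), abs=1e-9)


class TestScoreInequalities:
    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            M = int(rng.integers(1, 30))
            L = int(rng.integers(1, 60))
            h = P.random_hmm(M, seed=int(rng.integers(1 << 30)))
            prof = P.configure(h, L=L)
            seq = P.random_sequences(1, L, seed=int(rng.integers(1 << 30)))[0]
            assert P.forward_score(prof, seq) >= P.viterbi(prof, seq)[0] - 1e-9

    def test_multihit_forward_at_least_unihit(self):
        # The unihit path ensemble is an equal-weight subset of the
        # multihit one (E->C stays 0.5 in both modes), so this is exact.
        rng = np.random.default_rng(8)
        for _ in range(20):
            M = int(rng.integers(1, 20))
            L = int(rng.integers(1, 50))
            h = P.random_hmm(M, seed=int(rng.integers(1 << 30)))
            seq = P.random_sequences(1, L, seed=int(rng.integers(1 << 30)))[0]
            multi = P.forward_score(P.configure(h, mode="multihit", L=L), seq)
            uni = P.forward_score(P.configure(h, mode="unihit", L=L), seq)
            assert multi >= uni - 1e-9

    def test_scores_do_not_depend_on_database_context(self, calibrated_hmm):
        prof = P.configure(calibrated_hmm, L=40)
        seq = P.random_sequences(1, 40, seed=9)[0]
        once = P.forward_score(prof, seq)
        # scoring other sequences in between must not change anything
        for other in P.random_sequences(5, 40, seed=10):
            P.forward_score(prof, other)
        assert P.forward_score(prof, seq) == once


class TestDegenerateCases:
    def test_empty_sequence_scores_through_flanks_only(self, small_hmm, amino):
        prof = P.configure(small_hmm, L=10)
        empty = P.DigitalSequence(name="e", residues=np.array([], dtype=np.int16),
                                  alphabet=amino)
        f = P.forward_score(prof, empty)
        v, path = P.viterbi(prof, empty)
        assert math.isfinite(f) and math.isfinite(v)
        assert [s[0] for s in path.steps] == ["S", "N", "C", "T"]
        assert P.domains_from_path(prof, empty, path) == []

    def test_single_forced_path_makes_viterbi_equal_forward(self, amino):
        # M=1 against L=1 in unihit mode admits exactly one path.
        em = np.zeros((1, 20)); em[0, 0] = 1.0
        h = P.HMM(name="point", match_emissions=em,
                  insert_emissions=np.tile(P.Background.amino().frequencies, (1, 1)),
                  transitions=np.array([[1.0, 0, 0, 1.0, 0, 1.0, 0]]))
        prof = P.configure(h, mode="unihit", L=1)
        seq = P.digitize("A", amino, name="a")
        assert P.forward_score(prof, seq) == pytest.approx(
            P.viterbi(prof, seq)[0], abs=1e-12)

    def test_msv_equals_viterbi_when_inserts_and_deletes_zeroed(self, amino):
        rng = np.random.default_rng(12)
        M = 4
        em = rng.dirichlet(np.full(20, 0.5), size=M)
        trans = np.tile((1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0), (M, 1))
        h = P.HMM(name="nogaps", match_emissions=em,
                  insert_emissions=np.tile(P.Background.amino().frequencies, (M, 1)),
                  transitions=trans)
        prof = P.configure(h, mode="multihit", L=8)
        seq = P.random_sequences(1, 8, seed=13)[0]
        assert P.msv_score(prof, seq) == pytest.approx(
            P.viterbi(prof, seq)[0], abs=1e-9)


class TestPathAlgebra:
    def _profile_and_path(self, seed, M=8, L=30, mode="multihit"):
        h = P.random_hmm(M, seed=seed)
        prof = P.configure(h, mode=mode, L=L)
        seq = P.random_sequences(1, L, seed=seed + 1)[0]
        score, path = P.viterbi(prof, seq)
        return prof, seq, score, path

    def test_path_rescoring_reproduces_viterbi_score(self):
        for seed in (21, 22, 23, 24):
            prof, seq, score, path = self._profile_and_path(seed)
            assert P.path_score(prof, seq, path) == pytest.approx(score, abs=1e-9)

    def test_path_structure_invariants(self):
        prof, seq, _, path = self._profile_and_path(31)
        states = [s[0] for s in path.steps]
        assert states[0] == "S" and states[-1] == "T"
        consumed = [s[2] for s in path.steps]
        assert consumed[-1] == len(seq)
        for (s1, _, c1), (s2, _, c2) in zip(path.steps, path.steps[1:]):
            assert c2 - c1 in (0, 1)
            if s2 in ("M", "I"):
                assert c2 == c1 + 1  # match/insert always consume

    def test_unihit_path_has_exactly_one_segment(self):
        prof, seq, _, path = self._profile_and_path(41, mode="unihit")
        assert len(P.domains_from_path(prof, seq, path)) == 1

    def test_segments_ordered_and_non_overlapping(self):
        for seed in (51, 52, 53):
            prof, seq, _, path = self._profile_and_path(seed, M=5, L=60)
            segs = P.domains_from_path(prof, seq, path)
            assert segs
            for a, b in zip(segs, segs[1:]):
                assert a.seq_to < b.seq_from

    def test_segment_recomposition_equals_viterbi(self):
        """Segment scores plus the special-state costs (recomputed here
        from the profile's own parameters, independently of the DP)
        reproduce the full Viterbi score."""
        for seed in (61, 62, 63, 64):
            prof, seq, score, path = self._profile_and_path(seed, M=6, L=50)
            segs = P.domains_from_path(prof, seq, path)
            specials = 0.0
            in_excursion = False
            for (s1, _, c1), (s2, _, c2) in zip(path.steps, path.steps[1:]):
                if s1 == "B":
                    in_excursion = True
                if s2 == "E":
                    in_excursion = False
                    continue
                if in_excursion:
                    continue
                emitted = c2 == c1 + 1
                specials += {
                    ("S", "N"): 0.0,
                    ("N", "N"): prof.xN_loop,
                    ("N", "B"): 0.0,  # counted inside the segment
                    ("E", "J"): prof.xE_J,
                    ("E", "C"): prof.xE_C,
                    ("J", "J"): prof.xJ_loop,
                    ("J", "B"): 0.0,
                    ("C", "C"): prof.xC_loop,
                    ("C", "T"): prof.xC_move,
                }[(s1, s2)]
            # N->B and J->B moves are part of neither segment nor the
            # loop terms above; count them per excursion boundary.
            n_b_moves = sum(1 for s, _, _ in path.steps if s == "B")
            first_from_n = path.steps[[s[0] for s in path.steps].index("B") - 1][0] == "N"
            specials += prof.xN_move + (n_b_moves - 1) * prof.xJ_move
            assert first_from_n
            total = sum(s.score_bits * _LN2 for s in segs) + specials
            assert (total - prof.null_score) / _LN2 == pytest.approx(score, abs=1e-9)

    def test_alphabet_mismatch_rejected(self, small_hmm):
        other = P.Alphabet("ACDEFGHIKLMNPQRSTVW")  # 19 letters
        seq = P.DigitalSequence(name="x", residues=np.array([0, 1]), alphabet=other)
        prof = P.configure(small_hmm, L=2)
        with pytest.raises(ValueError, match="alphabet"):
            P.forward_score(prof, seq)
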