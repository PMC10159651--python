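"""Model invariants, profile configuration, and HMMER3 file round trips."""

import io
import math

import numpy as np
import pytest

import profhmm as P
from profhmm.hmmfile import HmmFormatError
from profhmm.model import ModelError

from conftest import roundtrip_text

# A minimal hand-written single-node record: the match state emits A
# with probability 1 (stored -ln 1 = 0, everything else "*").
MINIMAL_HMM = """HMMER3/f [test]
NAME  mini
LENG  1
ALPH  amino
HMM      A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
         m->m     m->i     m->d     i->m     i->i     d->m     d->d
      1  0.00000  *  *  *  *  *  *  *  *  *  *  *  *  *  *  *  *  *  *  *
         2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573  2.99573
         0.00000  *  *  0.00000  *  0.00000  *
//
"""


class TestValidation:
    def test_random_model_is_valid(self, small_hmm):
        small_hmm.validate()

    def test_bad_emission_row_rejected(self, small_hmm):
        bad = P.HMM(
            name="bad",
            match_emissions=small_hmm.match_emissions * 0.5,
            insert_emissions=small_hmm.insert_emissions,
            transitions=small_hmm.transitions,
        )
        with pytest.raises(ModelError, match="match emission"):
            bad.validate()

    def test_bad_transition_group_rejected(self, small_hmm):
        t = small_hmm.transitions.copy()
        t[2, 0] += 0.2
        bad = P.HMM(name="bad", match_emissions=small_hmm.match_emissions,
                    insert_emissions=small_hmm.insert_emissions, transitions=t)
        with pytest.raises(ModelError, match="M-state transitions"):
            bad.validate()


class TestCutoffs:
    def test_set_and_roundtrip(self, small_hmm):
        h = P.random_hmm(4, seed=9)
        P.set_cutoffs(h, "GA", 25.0, 22.0)
        back = next(P.read_hmm_file(io.StringIO(roundtrip_text([h]))))
        assert back.cutoffs["GA"] == (25.0, 22.0)

    def test_clear_removes_line(self):
        h = P.random_hmm(4, seed=9)
        P.set_cutoffs(h, "TC", 30.0, 28.0)
        P.clear_cutoffs(h, "TC")
        assert "\nTC" not in roundtrip_text([h])

    def test_domain_above_sequence_warns_not_rejects(self):
        h = P.random_hmm(4, seed=9)
        with pytest.warns(UserWarning, match="exceeds"):
            P.set_cutoffs(h, "NC", 10.0, 12.0)
        assert h.cutoffs["NC"] == (10.0, 12.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ModelError):
            P.set_cutoffs(P.random_hmm(2, seed=1), "XX", 1.0, 1.0)


class TestConfigure:
    def test_referential_transparency(self, small_hmm, background):
        p1 = P.configure(small_hmm, background, "multihit", 50)
        p2 = P.configure(small_hmm, background, "multihit", 50)
        assert np.array_equal(p1.msc, p2.msc)
        assert all(np.array_equal(p1.t[k], p2.t[k]) for k in p1.t)
        assert p1.xN_loop == p2.xN_loop

    def test_length_changes_only_flank_scores(self, small_hmm, background):
        p10 = P.configure(small_hmm, background, "multihit", 10)
        p1000 = P.configure(small_hmm, background, "multihit", 1000)
        assert p10.xN_loop != p1000.xN_loop
        assert np.array_equal(p10.msc, p1000.msc)
        assert np.array_equal(p10.isc, p1000.isc)

    def test_mode_controls_ej_only(self, small_hmm, background):
        multi = P.configure(small_hmm, background, "multihit", 50)
        uni = P.configure(small_hmm, background, "unihit", 50)
        assert multi.xE_J == pytest.approx(math.log(0.5))
        assert uni.xE_J == -math.inf
        assert multi.xE_C == uni.xE_C

    def test_unknown_mode_rejected(self, small_hmm):
        with pytest.raises(ModelError):
            P.configure(small_hmm, mode="glocal")

    def test_uniform_entry(self, small_hmm, background):
        prof = P.configure(small_hmm, background, "multihit", 50)
        assert prof.entry[1:] == pytest.approx(-math.log(small_hmm.M))

    def test_degenerate_score_is_background_weighted_mixture(self, small_hmm, background):
        prof = P.configure(small_hmm, background)
        abc = small_hmm.alphabet
        b = abc.encode_char("B")
        d, n = abc.encode_char("D"), abc.encode_char("N")
        f = background.frequencies
        for k in (1, small_hmm.M):
            expected = math.log(
                (f[d] * math.exp(prof.msc[k, d]) + f[n] * math.exp(prof.msc[k, n]))
                / (f[d] + f[n])
            )
            assert prof.msc[k, b] == pytest.approx(expected, abs=1e-12)


class TestHmmFile:
    def test_minimal_fixture_parses(self, amino):
        h = next(P.read_hmm_file(io.StringIO(MINIMAL_HMM), amino))
        assert h.name == "mini" and h.M == 1
        assert h.match_emissions[0, 0] == pytest.approx(1.0)
        assert h.match_emissions[0, 1:].sum() == pytest.approx(0.0)
        # stored -ln 0.00000 decodes to probability exactly 1
        assert h.transitions[0, 0] == 1.0

    def test_roundtrip_field_equality(self):
        # stored precision: 5 decimals on -ln(p), i.e. |Δ(-ln p)| <= 5e-6
        for seed in range(20):
            h = P.random_hmm(int(np.random.default_rng(seed).integers(1, 12)), seed=seed)
            if seed % 3 == 0:
                P.set_cutoffs(h, "GA", 20.0 + seed, 18.0)
            if seed % 4 == 0:
                h.stats = P.EvalueParams(-3.1, 0.7, -4.2, 0.71, 2.5, math.log(2))
            back = next(P.read_hmm_file(io.StringIO(roundtrip_text([h]))))
            for a, b in (
                (h.match_emissions, back.match_emissions),
                (h.insert_emissions, back.insert_emissions),
                (h.transitions, back.transitions),
            ):
                mask = a > 0
                assert np.allclose(-np.log(a[mask]), -np.log(b[mask]), atol=5e-6)
                assert np.array_equal(a == 0, b == 0)
            assert back.cutoffs == h.cutoffs
            if h.stats is not None:
                for f in ("msv_mu", "msv_lambda", "vit_mu", "vit_lambda",
                          "fwd_tau", "fwd_lambda"):
                    assert getattr(back.stats, f) == pytest.approx(
                        getattr(h.stats, f), abs=5e-6)

    def test_write_read_write_is_byte_idempotent(self):
        h = P.random_hmm(7, seed=13)
        text = roundtrip_text([h])
        back = next(P.read_hmm_file(io.StringIO(text)))
        assert roundtrip_text([back]) == text

    def test_empty_model_list_gives_valid_empty_file(self):
        buf = io.StringIO()
        assert P.write_hmm_file([], buf) == 0
        assert list(P.read_hmm_file(io.StringIO(buf.getvalue()))) == []

    def test_calibrated_model_has_three_stats_lines(self):
        h = P.random_hmm(3, seed=2)
        h.stats = P.EvalueParams(-3.0, 0.7, -4.0, 0.7, 2.0, math.log(2))
        text = roundtrip_text([h])
        assert text.count("STATS LOCAL") == 3
        for kind in ("MSV", "VITERBI", "FORWARD"):
            assert f"STATS LOCAL {kind}" in text

    def test_header_lines_freely_ordered(self):
        h = P.random_hmm(3, seed=2)
        lines = roundtrip_text([h]).splitlines(keepends=True)
        # swap NAME and LENG lines (both in the freely-ordered header)
        i = next(k for k, l in enumerate(lines) if l.startswith("NAME"))
        j = next(k for k, l in enumerate(lines) if l.startswith("LENG"))
        lines[i], lines[j] = lines[j], lines[i]
        back = next(P.read_hmm_file(io.StringIO("".join(lines))))
        assert back.name == h.name and back.M == h.M

    def test_missing_terminator_fails(self):
        h = P.random_hmm(3, seed=2)
        text = roundtrip_text([h]).replace("//\n", "")
        with pytest.raises(HmmFormatError, match="//"):
            next(P.read_hmm_file(io.StringIO(text)))

    def test_missing_mandatory_key_fails_with_name(self):
        h = P.random_hmm(3, seed=2)
        text = "\n".join(
            l for l in roundtrip_text([h]).splitlines() if not l.startswith("NAME")
        )
        with pytest.raises(HmmFormatError, match="NAME"):
            next(P.read_hmm_file(io.StringIO(text)))

    def test_leng_node_count_mismatch_fails(self):
        h = P.random_hmm(3, seed=2)
        text = roundtrip_text([h]).replace("LENG  3", "LENG  4")
        with pytest.raises(HmmFormatError, match="4 nodes"):
            next(P.read_hmm_file(io.StringIO(text)))

    def test_multi_record_file_preserves_order(self):
        models = [P.random_hmm(3, seed=s, name=f"m{s}") for s in range(4)]
        back = list(P.read_hmm_file(io.StringIO(roundtrip_text(models))))
        assert [h.name for h in back] == [h.name for h in models]

    def test_independent_parser_accepts_our_files(self, tmp_path):
        """Cross-check the dialect against the reference HMMER3 parser."""
        pyhmmer = pytest.importorskip("pyhmmer")
        h = P.random_hmm(6, seed=3)
        P.set_cutoffs(h, "GA", 25.0, 22.0)
        h.stats = P.EvalueParams(-3.1, 0.7, -4.2, 0.71, 2.5, math.log(2))
        path = tmp_path / "model.hmm"
        P.write_hmm_file([h], path)
        with pyhmmer.plan7.HMMFile(str(path)) as fh:
            ref = next(iter(fh))
        assert ref.name == h.name
        assert ref.M == h.M
        ref_match = np.asarray(ref.match_emissions)[1:]
        assert np.allclose(ref_match, h.match_emissions, atol=1e-4)
        assert ref.cutoffs.gathering == (25.0, 22.0)
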