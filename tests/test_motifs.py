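"""PWM scoring, k-mer counts, the PAS builder, U1 scorers and shuffling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpascan.motifs import (
    DSE_KMERS,
    KmerCountFeature,
    MotifError,
    MotifRegistry,
    PWM,
    Splice5Scorer,
    U1DuplexScorer,
    build_weighted_pas_pwm,
    default_baseline_registry,
    kmer_count_score,
    load_registry,
    pwm_from_consensus,
    pwm_odds_scores,
    read_pwm_file,
    shuffle_pwm,
    write_pwm_file,
)


def uniform_pwm(length=3):
    return PWM("uniform", np.full((length, 4), 0.25))


def brute_force_odds(seq, pwm, background=None, pseudocount=1e-3):
    """Independent per-offset enumeration of the odds product."""
    bg = [0.25] * 4 if background is None else list(background)
    idx = {b: i for i, b in enumerate("ACGU")}
    L = len(pwm)
    probs = (pwm.matrix + pseudocount) / (1 + 4 * pseudocount)
    out = []
    for off in range(len(seq) - L + 1):
        v = 1.0
        for j in range(L):
            b = idx[seq[off + j]]
            v *= probs[j, b] / bg[b]
        out.append(v)
    return np.array(out)


class TestPwmOdds:
    def test_uniform_pwm_scores_one_everywhere(self):
        scores = pwm_odds_scores("ACGUACGUA", uniform_pwm())
        assert np.allclose(scores, 1.0)

    def test_single_base_match_odds(self):
        pwm = PWM("a_only", np.array([[1.0, 0, 0, 0]]))
        score = pwm_odds_scores("A", pwm, pseudocount=0.0)[0]
        assert score == pytest.approx(4.0)

    def test_matches_brute_force_enumeration(self):
        pwm = pwm_from_consensus("ug", "UG", strength=0.8)
        seq = "AUGA"
        scores = pwm_odds_scores(seq, pwm)
        expected = brute_force_odds(seq, pwm)
        assert np.allclose(scores, expected)
        assert scores.argmax() == 1  # the UG at offset 1

    def test_short_sequence_gives_empty(self):
        assert pwm_odds_scores("AC", uniform_pwm(3)).size == 0

    def test_invalid_base_rejected(self):
        with pytest.raises(MotifError):
            pwm_odds_scores("ACGT", uniform_pwm())

    @settings(deadline=None, max_examples=40)
    @given(seq=st.text(alphabet="ACGU", min_size=4, max_size=30))
    def test_brute_force_property(self, seq):
        pwm = pwm_from_consensus("ugua", "UGUA", strength=0.9)
        assert np.allclose(pwm_odds_scores(seq, pwm), brute_force_odds(seq, pwm))


class TestKmerCounts:
    DSE = KmerCountFeature("dse_kmers", DSE_KMERS)

    @pytest.mark.parametrize(
        "seq,feat,expected",
        [
            ("GU", DSE, 3),  # G, U, GU
            ("AAAA", DSE, 0),
            ("GGG", KmerCountFeature("gg", frozenset({"GG"})), 2),  # overlaps
            ("UGUG", DSE, 7),  # U,G,U,G + UG,GU,UG
        ],
    )
    def test_counts(self, seq, feat, expected):
        assert kmer_count_score(seq, feat) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(MotifError):
            KmerCountFeature("empty", frozenset())


class TestWeightedPasPwm:
    def test_single_hexamer_is_consensus(self):
        pwm = build_weighted_pas_pwm({"AAUAAA": 10})
        assert pwm.consensus == "AAUAAA"
        assert np.allclose(pwm.matrix.max(axis=1), 1.0)

    def test_two_variant_mixture(self):
        pwm = build_weighted_pas_pwm({"AAUAAA": 1, "AUUAAA": 1})
        # position 1 splits A/U evenly, all others are degenerate
        assert pwm.matrix[1, 0] == pytest.approx(0.5)
        assert pwm.matrix[1, 3] == pytest.approx(0.5)
        for j in (0, 2, 3, 4, 5):
            assert pwm.matrix[j].max() == pytest.approx(1.0)

    def test_empty_or_zero_counts_rejected(self):
        with pytest.raises(MotifError):
            build_weighted_pas_pwm({})
        with pytest.raises(MotifError):
            build_weighted_pas_pwm({"AAUAAA": 0})


class TestU1Duplex:
    scorer = U1DuplexScorer()

    def test_perfect_complement_attains_maximum(self):
        consensus = "CAGGUAAGU"  # antiparallel complement of the U1 5' end
        assert self.scorer.score(consensus) == pytest.approx(self.scorer.max_score)

    def test_poly_a_scores_below_maximum(self):
        scores = self.scorer.per_offset_scores("A" * 30)
        assert scores.max() < self.scorer.max_score

    def test_single_mismatch_never_increases(self):
        consensus = "CAGGUAAGU"
        best = self.scorer.score(consensus)
        for i in range(9):
            for b in "ACGU":
                if b == consensus[i]:
                    continue
                mut = consensus[:i] + b + consensus[i + 1 :]
                assert self.scorer.score(mut) <= best

    def test_flanking_sequence_invariance(self):
        core = "CAGGUAAGU"
        assert self.scorer.score("AAAA" + core + "CCCC") == self.scorer.score(core)

    def test_too_short_raises(self):
        with pytest.raises(MotifError):
            self.scorer.score("ACGUACG")


class TestSplice5:
    scorer = Splice5Scorer()

    def test_consensus_attains_table_maximum(self):
        assert self.scorer.score(self.scorer.consensus) == pytest.approx(
            self.scorer.max_score
        )

    def test_reverse_complement_scores_below_maximum(self):
        from cpascan.sequence_io import reverse_complement

        rc = reverse_complement(self.scorer.consensus)
        assert self.scorer.score(rc) < self.scorer.max_score

    def test_window_shorter_than_word_raises(self):
        with pytest.raises(MotifError):
            self.scorer.score("ACGUACGU")

    def test_missing_table_file_raises(self, tmp_path):
        with pytest.raises(MotifError):
            Splice5Scorer.from_table_file(tmp_path / "absent.tsv")

    def test_external_table_round_trip(self, tmp_path):
        p = tmp_path / "donor.tsv"
        np.savetxt(p, self.scorer.frequencies)
        loaded = Splice5Scorer.from_table_file(p)
        assert loaded.score("CAGGUAAGU") == pytest.approx(self.scorer.score("CAGGUAAGU"))


class TestShufflePwm:
    def test_length_one_unchanged(self):
        pwm = PWM("one", np.array([[0.7, 0.1, 0.1, 0.1]]))
        assert np.array_equal(shuffle_pwm(pwm, 3).matrix, pwm.matrix)

    def test_column_multiset_preserved(self):
        pwm = pwm_from_consensus("x", "ACGUA", strength=0.8)
        shuf = shuffle_pwm(pwm, 11)
        orig = sorted(map(tuple, pwm.matrix))
        after = sorted(map(tuple, shuf.matrix))
        assert orig == after

    def test_deterministic_per_seed(self):
        pwm = pwm_from_consensus("x", "ACGUACG", strength=0.8)
        a, b = shuffle_pwm(pwm, 5), shuffle_pwm(pwm, 5)
        assert np.array_equal(a.matrix, b.matrix)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_entropy_multiset_invariant(self, seed):
        pwm = pwm_from_consensus("x", "AACGUU", strength=0.77)

        def entropies(m):
            p = m + 1e-12
            return sorted(-(p * np.log(p)).sum(axis=1))

        assert np.allclose(entropies(pwm.matrix), entropies(shuffle_pwm(pwm, seed).matrix))


class TestRegistry:
    def test_default_registry_has_fifteen_entries(self):
        assert len(default_baseline_registry()) == 15

    def test_duplicate_ids_rejected(self):
        with pytest.raises(MotifError):
            MotifRegistry([uniform_pwm(), uniform_pwm()])

    def test_pwm_file_round_trip(self, tmp_path):
        pwm = pwm_from_consensus("ugua", "UGUA", strength=0.9)
        p = tmp_path / "ugua.pwm"
        write_pwm_file(pwm, p)
        back = read_pwm_file(p)
        assert back.name == "ugua"
        assert np.allclose(back.matrix, pwm.matrix, atol=1e-6)

    def test_yaml_registry_loading(self, tmp_path):
        pwm = pwm_from_consensus("ugua", "UGUA", strength=0.9)
        write_pwm_file(pwm, tmp_path / "ugua.pwm")
        (tmp_path / "registry.yaml").write_text(
            "representations:\n"
            "  - {id: ugua, kind: pwm, file: ugua.pwm}\n"
            "  - {id: pas, kind: pwm, consensus: AAUAAA, strength: 0.8}\n"
            "  - {id: dse_kmers, kind: kmers, kmers: [G, U, GU]}\n"
            "  - {id: u1, kind: u1}\n"
            "  - {id: splice5, kind: splice5}\n"
        )
        reg = load_registry(tmp_path / "registry.yaml")
        assert reg.ids == ["ugua", "pas", "dse_kmers", "u1", "splice5"]

    def test_pwm_row_sum_validated(self):
        with pytest.raises(MotifError):
            PWM("bad", np.array([[0.5, 0.5, 0.5, 0.5]]))
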