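import math
from itertools import product

import numpy as np
import pytest

from argbox import iimodel
from argbox.iimodel import (
    build_model,
    build_model_from_sequences,
    build_pfm,
    consensus,
    load_model,
    logo_data,
    ri_score,
    save_model,
    small_sample_correction,
)
from argbox.seqio import ALPHABET, NucleotideSequence, reverse_complement

from conftest import toy_model


def brute_force_e(n: int) -> float:
    """Mean plug-in entropy bias over all 4^n draws (independent oracle)."""
    total = 0.0
    for draw in product(range(4), repeat=n):
        counts = np.bincount(draw, minlength=4)
        f = counts / n
        total += -np.sum(np.where(f > 0, f * np.log2(np.where(f > 0, f, 1)), 0))
    return 2.0 - total / 4**n


class TestSmallSampleCorrection:
    def test_single_draw_is_two_bits(self):
        assert small_sample_correction(1) == pytest.approx(2.0, abs=1e-12)

    def test_two_draws(self):
        # 16 outcomes: 4 identical pairs (H=0), 12 distinct (H=1); 2 - 12/16
        assert small_sample_correction(2) == pytest.approx(1.25, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_exhaustive_enumeration(self, n):
        assert small_sample_correction(n) == pytest.approx(brute_force_e(n), abs=1e-12)

    def test_strictly_decreasing_to_one_hundred(self):
        values = [small_sample_correction(n) for n in range(1, 101)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert 0 < values[36] < values[1]

    def test_vanishes_for_large_n(self):
        e = small_sample_correction(10**6, method="monte_carlo", n_samples=500, seed=1)
        assert 0 < e < 1e-5

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            small_sample_correction(0)


class TestPfm:
    def test_pure_columns(self):
        pfm = build_pfm(["AAAA", "AAAA"])
        assert np.allclose(pfm.frequencies[0], 1.0)

    def test_column_sums_equal_n(self, rng):
        for _ in range(100):
            n, L = int(rng.integers(2, 12)), int(rng.integers(1, 15))
            seqs = [
                "".join(ALPHABET[b] for b in rng.integers(0, 4, L)) for _ in range(n)
            ]
            pfm = build_pfm(seqs)
            assert np.all(pfm.counts.sum(axis=0) == n)
            assert np.allclose(pfm.frequencies.sum(axis=0), 1.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="alignment"):
            build_pfm(["ACGT", "ACG"])

    def test_non_acgt_rejected(self):
        with pytest.raises(Exception, match="non-ACGT"):
            build_pfm(["ACGN", "ACGT"])


class TestModel:
    def test_training_pfm_dimensions(self, plain_model):
        assert plain_model.pfm.n == 37 and plain_model.width == 20

    def test_uniform_columns_score_minus_le(self):
        seqs = ["AAcc".upper(), "CCGG", "GGTT", "TTAA"]  # every column uniform
        m = build_model_from_sequences(seqs)
        assert np.allclose(m.entropies, 2.0)
        assert m.rsequence == pytest.approx(-4 * m.e_n, abs=1e-12)

    def test_random_alignment_scores_near_zero(self, rng):
        seqs = [
            "".join(ALPHABET[b] for b in rng.integers(0, 4, 20)) for _ in range(1000)
        ]
        m = build_model_from_sequences(seqs)
        # H_obs fluctuation over 20 columns: SD ~ 0.03 bits at n=1000
        assert abs(m.rsequence) < 0.3

    def test_mean_training_ri_equals_rsequence(self, training, plain_model, arg_model):
        seqs = [r.sequence for r in training]
        for model in (plain_model, arg_model):
            mean_ri = np.mean([ri_score(model, s) for s in seqs])
            assert mean_ri == pytest.approx(model.rsequence, abs=1e-9)

    def test_rsequence_invariant_under_row_permutation(self, training, rng):
        seqs = [r.sequence for r in training]
        m1 = build_model_from_sequences(seqs)
        shuffled = [seqs[i] for i in rng.permutation(len(seqs))]
        m2 = build_model_from_sequences(shuffled)
        assert m1.rsequence == pytest.approx(m2.rsequence, abs=1e-12)

    def test_palindromic_model_is_strand_symmetric(self, arg_model, training):
        f = arg_model.pfm.frequencies
        assert np.allclose(f, f[::-1, ::-1], atol=1e-12)
        s = training[0].sequence
        assert ri_score(arg_model, s) == pytest.approx(
            ri_score(arg_model, reverse_complement(s)), abs=1e-9
        )

    def test_zero_count_scores_minus_infinity(self):
        m = build_model_from_sequences(["AAAA", "AAAA", "AAAC"])
        assert ri_score(m, "GAAA") == -np.inf

    def test_pseudocount_policy_scores_finite(self):
        m = build_model_from_sequences(
            ["AAAA", "AAAA", "AAAC"], zero_count_policy="pseudocount"
        )
        assert np.isfinite(ri_score(m, "GAAA"))


class TestConsensus:
    def test_duplicated_sequence_is_its_own_consensus(self):
        m = build_model_from_sequences(["ACGTACGT", "ACGTACGT"])
        assert consensus(m).residues == "ACGTACGT"

    def test_consensus_ri_is_sum_of_column_maxima(self, arg_model):
        expected = np.max(arg_model.weights, axis=0).sum()
        assert ri_score(arg_model, consensus(arg_model)) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("width,seed", [(5, 0), (6, 1), (8, 2)])
    def test_consensus_dominates_all_kmers_exhaustively(self, width, seed):
        m = toy_model(width=width, n=10, seed=seed)
        best = ri_score(m, consensus(m))
        scores = [
            ri_score(m, "".join(ALPHABET[b] for b in kmer))
            for kmer in product(range(4), repeat=width)
        ]
        assert best == pytest.approx(max(scores), abs=1e-9)

    def test_tie_positions_reported(self):
        m = build_model_from_sequences(["AC", "CA"])
        seq, ties = consensus(m, with_ties=True)
        assert seq.residues == "AA" and ties == [0, 1]


class TestLogo:
    def test_uniform_column_clamps_to_zero(self):
        m = build_model_from_sequences(["AA", "CC", "GG", "TT"])
        assert all(not stack for stack in logo_data(m))

    def test_pure_column_approaches_two_bits(self):
        m = build_model_from_sequences(["A" * 4] * 200)
        height = sum(h for _, h in logo_data(m)[0])
        assert height == pytest.approx(2.0 - m.e_n, abs=1e-12)

    def test_stack_heights_sum_to_clamped_rsequence(self, arg_model):
        total = sum(sum(h for _, h in stack) for stack in logo_data(arg_model))
        clamped = np.sum(
            np.maximum(0.0, 2.0 - arg_model.entropies - arg_model.e_n)
        )
        assert total == pytest.approx(clamped, abs=1e-9)
        # clamping can only raise the total above Rsequence
        assert total >= arg_model.rsequence - 1e-9


class TestSerialization:
    def test_round_trip_bit_exact(self, arg_model, tmp_path):
        p = tmp_path / "model.txt"
        save_model(arg_model, p)
        back = load_model(p)
        assert back.e_n == arg_model.e_n
        assert back.rsequence == arg_model.rsequence
        assert np.array_equal(back.weights, arg_model.weights)
        assert np.array_equal(back.pfm.counts, arg_model.pfm.counts)
        s = "CTTTGCATGGTCATGCGTAA"
        assert ri_score(back, s) == ri_score(arg_model, s)

    def test_minus_infinity_cells_survive(self, tmp_path):
        m = build_model_from_sequences(["AAAA", "AAAA", "AAAC"])
        save_model(m, tmp_path / "m.txt")
        back = load_model(tmp_path / "m.txt")
        assert ri_score(back, "GAAA") == -np.inf

    def test_rejects_foreign_file(self, tmp_path):
        p = tmp_path / "junk.txt"
        p.write_text("not a model\n")
        with pytest.raises(ValueError):
            load_model(p)


class TestScoringErrors:
    def test_width_mismatch(self, arg_model):
        with pytest.raises(iimodel.ScoringError):
            ri_score(arg_model, "ACGT")

    def test_record_and_string_agree(self, arg_model):
        s = "CTTTGCATGGTCATGCGTAA"
        assert ri_score(arg_model, s) == ri_score(
            arg_model, NucleotideSequence("x", s)
        )
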