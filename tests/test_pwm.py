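import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_best_window, oracle_score
from pol3scan.pwm import (
    PWM,
    anchor_windows,
    best_window,
    build_promoter_model,
    build_pwm,
    calibrate_threshold,
    consensus_iupac,
    load_model,
    save_model,
    score_window,
)
from pol3scan.seqs import random_dna

FOUR_SEQS = ["TATA", "TACA", "TATA", "AATA"]


class TestBuildPwm:
    def test_identical_sequences_zero_pseudocount_give_certainty(self):
        pwm = build_pwm(["TATAAA"] * 4, pseudocount=0.0)
        for i, base in enumerate("TATAAA"):
            assert pwm.probs[i, "ACGT".index(base)] == pytest.approx(1.0)

    def test_counts_with_pseudocount_hand_arithmetic(self):
        pwm = build_pwm(FOUR_SEQS, pseudocount=0.25)
        # position 1 has three T's among four sequences
        assert pwm.probs[0, "ACGT".index("T")] == pytest.approx((3 + 0.25) / 5)
        assert pwm.probs[0, "ACGT".index("A")] == pytest.approx((1 + 0.25) / 5)
        assert pwm.probs[2, "ACGT".index("C")] == pytest.approx((1 + 0.25) / 5)

    def test_n_contributes_fractionally(self):
        pwm = build_pwm(["AN", "AN"], pseudocount=0.0)
        assert pwm.probs[1] == pytest.approx([0.25] * 4)

    @pytest.mark.parametrize("bad", [[], ["TATA", "TAT"]])
    def test_empty_or_ragged_input_rejected(self, bad):
        with pytest.raises(ValueError):
            build_pwm(bad)

    @given(
        seqs=st.lists(
            st.text(alphabet="ACGTN", min_size=5, max_size=5), min_size=1, max_size=12
        ),
        pc=st.floats(0.0, 2.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_rows_always_normalized(self, seqs, pc):
        pwm = build_pwm(seqs, pseudocount=pc)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_pseudocount_shrinks_probability_spread(self):
        spreads = []
        for pc in (0.0, 0.25, 1.0, 5.0):
            pwm = build_pwm(FOUR_SEQS, pseudocount=pc)
            spreads.append(float((pwm.probs.max(1) - pwm.probs.min(1)).max()))
        assert spreads == sorted(spreads, reverse=True)
        assert spreads[0] > spreads[-1]


class TestConsensusIupac:
    def test_unanimous_columns_stay_literal(self):
        assert consensus_iupac(build_pwm(["TATAAA"] * 3, pseudocount=0.0)) == "TATAAA"

    def test_even_split_becomes_degenerate_code(self):
        pwm = build_pwm(["A", "G"], pseudocount=0.0)
        assert consensus_iupac(pwm, inclusion_fraction=1.0) == "R"

    def test_matches_per_column_oracle(self):
        pwm = build_pwm(FOUR_SEQS, pseudocount=0.25)
        got = consensus_iupac(pwm, inclusion_fraction=0.5)
        from Bio.Data.IUPACData import ambiguous_dna_values

        code_of = {frozenset(v): k for k, v in ambiguous_dna_values.items() if k != "X"}
        expected = ""
        for row in pwm.probs:
            cutoff = 0.5 * row.max()
            expected += code_of[
                frozenset(b for i, b in enumerate("ACGT") if row[i] >= cutoff)
            ]
        assert got == expected


class TestScoring:
    def test_consensus_against_certain_pwm_closed_form(self):
        pwm = build_pwm(["TATAAA"] * 4, pseudocount=0.0)
        assert score_window(pwm, "TATAAA", 0) == pytest.approx(6 * math.log2(4))

    def test_single_window_matches_hand_arithmetic(self):
        pwm = build_pwm(FOUR_SEQS, pseudocount=0.25)
        expected = oracle_score(pwm.probs, pwm.background, "TACA", 0)
        assert score_window(pwm, "TACA", 0) == pytest.approx(expected)

    def test_out_of_range_window_raises(self, tata_pwm):
        with pytest.raises(IndexError):
            score_window(tata_pwm, "TATA", 0)
        with pytest.raises(IndexError):
            score_window(tata_pwm, "TATAAAC", 2)

    def test_n_in_sequence_is_neutral(self, tata_pwm):
        with_n = score_window(tata_pwm, "TANAAA", 0)
        without = score_window(tata_pwm, "TATAAA", 0)
        per_site = score_window(tata_pwm, "TATAAA", 0) / 6
        assert with_n == pytest.approx(without - per_site)

    def test_best_window_equals_exhaustive_enumeration(self, rng):
        pwm = build_pwm(FOUR_SEQS, pseudocount=0.25)
        for _ in range(50):
            seq = random_dna(rng, int(rng.integers(10, 60)))
            assert best_window(pwm, seq) == pytest.approx(
                oracle_best_window(pwm.probs, pwm.background, seq)
            )


class TestCalibration:
    def test_identical_training_margin_zero(self, tata_pwm):
        seqs = ["CCTATAAACC"] * 5
        thr = calibrate_threshold(tata_pwm, seqs, margin=0.0)
        assert thr == pytest.approx(best_window(tata_pwm, seqs[0])[1])

    def test_every_training_sequence_passes_its_own_model(self, rng):
        seqs = [random_dna(rng, 40) for _ in range(15)]
        pwm = build_pwm([s[:8] for s in seqs], pseudocount=0.25)
        thr = calibrate_threshold(pwm, seqs, margin=0.0)
        assert all(best_window(pwm, s)[1] >= thr for s in seqs)

    def test_margin_shifts_threshold_linearly(self, tata_pwm):
        seqs = ["GGTATAAAGG", "CCTATCAACC"]
        t0 = calibrate_threshold(tata_pwm, seqs, margin=0.0)
        assert calibrate_threshold(tata_pwm, seqs, margin=2.0) == pytest.approx(t0 - 2)

    def test_training_shorter_than_pwm_rejected(self, tata_pwm):
        with pytest.raises(ValueError):
            calibrate_threshold(tata_pwm, ["TAT"])


class TestModelBuilding:
    def test_anchoring_recovers_planted_windows(self, rng):
        consensus = "CTCACCCTAACTCA"
        seqs = []
        for _ in range(10):
            left = random_dna(rng, int(rng.integers(5, 20)))
            right = random_dna(rng, int(rng.integers(5, 20)))
            seqs.append(left + consensus + right)
        assert anchor_windows(seqs, consensus) == [consensus] * 10

    def test_model_roundtrips_through_serialization(self, clean_species, tmp_path):
        model = build_promoter_model(clean_species.training_promoters)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.allclose(back.pse.probs, model.pse.probs, atol=5e-6)
        assert back.pse_threshold == pytest.approx(model.pse_threshold, abs=1e-5)
        assert back.tata_offset_window == model.tata_offset_window

    def test_unnormalized_pwm_rejected(self, tata_pwm):
        with pytest.raises(ValueError):
            PWM(probs=[[0.5, 0.5, 0.1, 0.1]])
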