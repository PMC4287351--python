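import itertools

import pytest

from oracles import (
    oracle_best_window,
    oracle_first_polyT,
    oracle_internal_promoter,
)
from pol3scan.pwm import PromoterModel, best_window, build_pwm, calibrate_threshold
from pol3scan.scan import (
    MotifHit,
    assemble_polIII_evidence,
    scan_best_hit,
    scan_internal_promoter,
    scan_locus,
    scan_polyT,
    scan_tata_positioned,
    tata_gap,
)
from pol3scan.seqs import random_dna, revcomp


def small_model(tata_pwm):
    """TATA-only promoter model over a quiet (low-scoring) background."""
    pse_pwm = build_pwm(["CTCACCCTAACTCA"] * 4, pseudocount=0.25)
    return PromoterModel(
        pse=pse_pwm,
        tata=tata_pwm,
        pse_threshold=calibrate_threshold(pse_pwm, ["CTCACCCTAACTCA"]),
        tata_threshold=calibrate_threshold(tata_pwm, ["TATAAA"]),
    )


def upstream_with_tata(gap: int, length: int = 120) -> str:
    """C-background upstream sequence with one TATAAA at the given gap."""
    assert gap + 6 <= length
    seq = ["C"] * length
    start = length - gap - 6
    seq[start : start + 6] = "TATAAA"
    return "".join(seq)


class TestScanBestHit:
    def test_planted_consensus_found_at_exact_position(self, tata_pwm):
        seq = "C" * 30 + "TATAAA" + "C" * 10
        hit = scan_best_hit(tata_pwm, seq, threshold=5.0, window=(0, 40))
        assert (hit.start, hit.motif_length) == (30, 6)

    def test_threshold_above_everything_gives_absent(self, tata_pwm, rng):
        seq = random_dna(rng, 60)
        assert scan_best_hit(tata_pwm, seq, threshold=1e6, window=(0, 50)) is None

    def test_equal_scoring_copies_resolve_to_smaller_start(self, tata_pwm):
        seq = "C" * 5 + "TATAAA" + "C" * 5 + "TATAAA" + "C" * 5
        hit = scan_best_hit(tata_pwm, seq, threshold=0.0, window=(0, len(seq) - 6))
        start, score = oracle_best_window(
            tata_pwm.probs, tata_pwm.background, seq
        )
        assert hit.start == start == 5
        assert hit.score == pytest.approx(score)

    def test_empty_window_rejected(self, tata_pwm):
        with pytest.raises(ValueError):
            scan_best_hit(tata_pwm, "TATAAA" * 4, threshold=0.0, window=(5, 4))


class TestTataPositioning:
    @pytest.mark.parametrize("gap,positioned", [(24, True), (21, True), (27, True),
                                                (20, False), (28, False), (40, False)])
    def test_gap_window_is_inclusive_21_to_27(self, tata_pwm, gap, positioned):
        model = small_model(tata_pwm)
        up = upstream_with_tata(gap)
        hit, flag = scan_tata_positioned(up, model)
        assert hit is not None and tata_gap(hit, len(up)) == gap
        assert flag is positioned

    def test_positioned_hit_wins_over_better_outside_hit(self, tata_pwm):
        # exact TATAAA at gap 40, degraded TATAAC at gap 24: the positioned
        # (weaker) hit must set the flag
        model = small_model(tata_pwm)
        up = list(upstream_with_tata(40))
        start = len(up) - 24 - 6
        up[start : start + 6] = "TATAAC"
        model = PromoterModel(
            pse=model.pse,
            tata=model.tata,
            pse_threshold=model.pse_threshold,
            tata_threshold=0.0,
        )
        hit, flag = scan_tata_positioned("".join(up), model)
        assert flag is True
        assert tata_gap(hit, len(up)) == 24

    def test_short_upstream_names_required_length(self, tata_pwm):
        model = small_model(tata_pwm)
        with pytest.raises(ValueError, match="33"):
            scan_tata_positioned("C" * 20, model)


class TestPolyT:
    def test_minimum_run_at_zero_offset(self):
        call = scan_polyT("TTTTGAAACC")
        assert (call.run_start, call.run_length, call.proximal) == (0, 4, True)

    def test_run_of_three_is_not_a_terminator(self):
        assert scan_polyT("TTTACCCGGG") is None

    def test_distal_run_reported_but_not_proximal(self):
        seq = "A" * 50 + "TTTTT" + "A" * 10
        call = scan_polyT(seq, proximal_window=30)
        assert (call.run_start, call.run_length, call.proximal) == (50, 5, False)

    def test_first_run_agrees_with_regex_oracle(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=40, p=[0.2, 0.1, 0.1, 0.6]))
            call = scan_polyT(seq, min_run=4, proximal_window=10)
            expected = oracle_first_polyT(seq, 4)
            if expected is None:
                assert call is None
            else:
                assert (call.run_start, call.run_length) == expected
                assert call.proximal is (expected[0] <= 10)

    def test_empty_downstream_absent(self):
        assert scan_polyT("") is None


class TestInternalPromoter:
    def test_planted_aboxes_in_order_found(self):
        seq = "CC" + "TGGCGGAGTGG" + "AAAA" + "GTTCGAAAC" + "CC"
        flag, positions = scan_internal_promoter(seq)
        assert flag is True
        assert positions == (2, 17)

    def test_bbox_before_abox_does_not_count(self):
        seq = "CC" + "GTTCGAAAC" + "AAAA" + "TGGCGGAGTGG" + "CC"
        flag, _ = scan_internal_promoter(seq)
        assert flag is False

    def test_agrees_with_match_pair_oracle_on_random_sequences(self, rng):
        # AT-rich alphabet raises the chance of partial motif matches
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=120, p=[0.3, 0.15, 0.25, 0.3]))
            flag, _ = scan_internal_promoter(seq, "TGGCNNAGTGG", "GTTCGANNC")
            assert flag == oracle_internal_promoter(seq, "TGGCNNAGTGG", "GTTCGANNC")

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            scan_internal_promoter("ACGT", abox="TGZ", bbox="GTTCGANNC")


class TestVerdictAssembly:
    def test_full_type3_architecture_is_positive(self, tata_pwm):
        pse = MotifHit(0, 20.0, 14)
        tata = MotifHit(40, 10.0, 6)
        from pol3scan.scan import TerminatorCall

        status = assemble_polIII_evidence(pse, tata, True, TerminatorCall(2, 4, True), False)
        assert status.verdict == "polIII_positive"

    def test_distal_polyT_alone_stays_negative(self):
        from pol3scan.scan import TerminatorCall

        status = assemble_polIII_evidence(None, None, False, TerminatorCall(50, 5, False), False)
        assert status.verdict == "polIII_negative"
        assert status.terminator.run_length == 5

    def test_truth_table_over_all_evidence_combinations(self):
        pse = MotifHit(0, 20.0, 14)
        tata = MotifHit(40, 10.0, 6)
        from pol3scan.scan import TerminatorCall

        term = TerminatorCall(0, 4, True)
        for has_pse, positioned, has_term, internal in itertools.product(
            [False, True], repeat=4
        ):
            status = assemble_polIII_evidence(
                pse if has_pse else None,
                tata,
                positioned,
                term if has_term else None,
                internal,
            )
            expected = "polIII_positive" if (has_pse and positioned) else "polIII_negative"
            assert status.verdict == expected
            # terminator and internal promoter are evidence only
            assert (status.terminator is not None) == has_term
            assert status.internal_promoter == internal


class TestStrandSymmetry:
    def test_minus_strand_scan_equals_revcomp_plus_scan(self, clean_species, clean_model):
        from dataclasses import replace

        chrom = clean_species.chrom
        seq = clean_species.genome[chrom]
        flipped_genome = {chrom: revcomp(seq)}
        for locus in clean_species.loci:
            mirrored = replace(
                locus,
                start=len(seq) - locus.end,
                end=len(seq) - locus.start,
                strand="-" if locus.strand == "+" else "+",
            )
            direct = scan_locus(clean_species.genome, locus, clean_model)
            mirror = scan_locus(flipped_genome, mirrored, clean_model)
            assert direct == mirror
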