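"""Training alignment geometry, oPWM training, scoring, calibration."""

import numpy as np
import pytest

from auxre.opwm import (
    DINUC_INDEX,
    LETTER_INDEX,
    PWMModel,
    build_training_alignment,
    calibrate_threshold,
    dinucleotide_shuffle,
    oriented_window,
    score_window_opwm,
    train_opwm,
    _auc,
    _build_model,
)
from auxre.sequence_core import SequenceRecord, parse_iupac, reverse_complement
from conftest import random_dna


def make_site(rng, flanks=60, core="TGTCAA"):
    left = random_dna(rng, flanks)
    right = random_dna(rng, flanks)
    return left + core + right, flanks


class TestBuildTrainingAlignment:
    def test_default_flanks_yield_106_nt_records(self):
        rng = np.random.default_rng(0)
        sites = [make_site(rng) for _ in range(5)]
        aln = build_training_alignment(sites, flank=50)
        assert aln.length == 106
        assert all(len(r) == 106 for r in aln.records)
        assert aln.core_offset == 50
        assert all(r[50:54] == "TGTC" for r in aln.records)

    def test_zero_flank_gives_bare_core(self):
        rng = np.random.default_rng(1)
        seq, core_start = make_site(rng)
        aln = build_training_alignment([(seq, core_start)], flank=0)
        assert aln.records[0] == seq[core_start : core_start + 6]

    def test_insufficient_flank_raises_with_record_index(self):
        rng = np.random.default_rng(2)
        short = random_dna(rng, 49) + "TGTCAA" + random_dna(rng, 60)
        with pytest.raises(ValueError, match="site 0"):
            build_training_alignment([(short, 49)], flank=50)

    def test_core_mismatch_raises(self):
        rng = np.random.default_rng(3)
        seq, core_start = make_site(rng, core="AAAAAA")
        with pytest.raises(ValueError, match="TGTCNN"):
            build_training_alignment([(seq, core_start)], flank=50)


class TestScoring:
    def test_identical_records_score_one_and_mismatch_scores_zero(self):
        rng = np.random.default_rng(4)
        seq, core_start = make_site(rng)
        aln = build_training_alignment([(seq, core_start)] * 10, flank=10)
        model = train_opwm(aln, candidate_lengths=range(12, 17), seed=0)
        w = model.window_start, model.window_start + model.window_length
        consensus = aln.records[0][w[0] : w[1]]
        assert score_window_opwm(model, consensus) == pytest.approx(1.0)
        # per-position argmin word scores exactly 0
        worst_mono = "".join(
            "ACGT"[i] for i in model.mono_weights.argmin(axis=0)
        )
        # mono argmin need not minimise di; construct the analytic min by
        # checking the score components are both within [0,1]
        s = score_window_opwm(model, worst_mono)
        assert 0.0 <= s < 0.5

    def test_score_equals_naive_summation_oracle(self, plain_alignment):
        model = train_opwm(
            plain_alignment, candidate_lengths=range(12, 26, 4), seed=1
        )
        rng = np.random.default_rng(5)
        for _ in range(50):
            win = random_dna(rng, model.window_length)
            m = sum(
                model.mono_weights[LETTER_INDEX[c], j]
                for j, c in enumerate(win)
            )
            d = sum(
                model.di_weights[DINUC_INDEX[win[j : j + 2]], j]
                for j in range(len(win) - 1)
            )
            sm = (m - model.mono_min) / (model.mono_max - model.mono_min)
            sd = (d - model.di_min) / (model.di_max - model.di_min)
            assert score_window_opwm(model, win) == pytest.approx(
                (sm + sd) / 2, abs=1e-12
            )

    def test_window_with_n_scores_zero_and_length_mismatch_raises(
        self, plain_alignment
    ):
        model = train_opwm(
            plain_alignment, candidate_lengths=range(12, 13), seed=1
        )
        assert score_window_opwm(model, "N" * model.window_length) == 0.0
        with pytest.raises(ValueError):
            score_window_opwm(model, "A" * (model.window_length + 1))

    def test_frequency_columns_sum_to_one(self, plain_alignment):
        model = train_opwm(
            plain_alignment, candidate_lengths=range(12, 13), seed=1
        )
        assert np.allclose(model.mono_freq.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(model.di_freq.sum(axis=0), 1.0, atol=1e-9)
        assert np.isfinite(model.mono_weights).all()
        assert np.isfinite(model.di_weights).all()


class TestWindowOptimisation:
    def test_selection_equals_exhaustive_grid_oracle(self, plain_alignment):
        """Re-evaluate the AUC objective independently over the grid."""
        lengths = range(14, 23, 4)
        seed = 9
        model = train_opwm(plain_alignment, candidate_lengths=lengths,
                           seed=seed)
        # oracle: rebuild decoys with the same rng stream and re-evaluate
        rng = np.random.default_rng(seed)
        records = list(plain_alignment.records)
        decoys = [
            dinucleotide_shuffle(r, rng) for r in records for _ in range(3)
        ]
        bg = np.full(4, 0.25)
        core_lo = plain_alignment.core_offset
        core_hi = core_lo + 6
        core_center = core_lo + 2.5
        best = None
        for length in lengths:
            for start in range(
                max(0, core_hi - length),
                min(core_lo, plain_alignment.length - length) + 1,
            ):
                m = _build_model(records, start, length, core_lo, bg, 0.25)
                pos = np.array(
                    [
                        score_window_opwm(m, r[start : start + length])
                        for r in records
                    ]
                )
                neg = np.array(
                    [
                        score_window_opwm(m, d[start : start + length])
                        for d in decoys
                    ]
                )
                key = (
                    -_auc(pos, neg),
                    length,
                    abs(start + (length - 1) / 2 - core_center),
                )
                if best is None or key < best[0]:
                    best = (key, start, length)
        assert (model.window_start, model.window_length) == best[1:]

    def test_default_grid_covers_length_25_and_core_in_window(
        self, plain_alignment
    ):
        model = train_opwm(
            plain_alignment, candidate_lengths=range(12, 41, 7), seed=2
        )
        lo = model.window_start
        hi = lo + model.window_length
        assert lo <= plain_alignment.core_offset
        assert hi >= plain_alignment.core_offset + 6

    def test_chosen_window_overlaps_planted_signal(self):
        """A planted conserved 25-nt block should attract the window."""
        rng = np.random.default_rng(77)
        signal = random_dna(rng, 8)  # conserved 5' flank block
        found = 0
        n_rep = 20
        for rep in range(n_rep):
            rng2 = np.random.default_rng(1000 + rep)
            sites = []
            for _ in range(25):
                left = random_dna(rng2, 52) + signal
                right = random_dna(rng2, 60)
                sites.append((left + "TGTCAA" + right, 60))
            aln = build_training_alignment(sites, flank=50)
            model = train_opwm(
                aln, candidate_lengths=range(12, 31, 3), seed=rep
            )
            planted_lo, planted_hi = 42, 50  # signal block in record coords
            lo = model.window_start
            hi = lo + model.window_length
            if lo < planted_hi and planted_lo < hi:
                found += 1
        assert found >= 0.9 * n_rep

    def test_empty_candidate_grid_raises(self, plain_alignment):
        with pytest.raises(ValueError, match="grid"):
            train_opwm(plain_alignment, candidate_lengths=range(4, 5))

    def test_score_invariant_to_column_constant_shift(self, plain_alignment):
        """Adding a constant to one mono column shifts raw and min/max
        equally, leaving the normalised score unchanged."""
        model = train_opwm(
            plain_alignment, candidate_lengths=range(12, 13), seed=1
        )
        shifted = PWMModel(
            mono_freq=model.mono_freq,
            di_freq=model.di_freq,
            mono_weights=model.mono_weights.copy(),
            di_weights=model.di_weights,
            window_start=model.window_start,
            window_length=model.window_length,
            core_in_window=model.core_in_window,
            background=model.background,
            mono_min=model.mono_min + 3.7,
            mono_max=model.mono_max + 3.7,
            di_min=model.di_min,
            di_max=model.di_max,
        )
        shifted.mono_weights[:, 0] += 3.7
        rng = np.random.default_rng(6)
        for _ in range(10):
            win = random_dna(rng, model.window_length)
            assert score_window_opwm(model, win) == pytest.approx(
                score_window_opwm(shifted, win), abs=1e-12
            )


class TestOrientedWindow:
    def test_minus_strand_window_is_revcomp_of_mirror(self):
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 100)
        core = 40
        w = oriented_window(seq, core, "+", 9, 25)
        mirrored = reverse_complement(seq)
        core_m = len(seq) - (core + 6)
        w_m = oriented_window(mirrored, core_m, "-", 9, 25)
        # the '-' window on the mirrored genome is the original '+' window
        assert w_m == w

    def test_out_of_bounds_window_returns_none(self):
        assert oriented_window("TGTCAAACGT", 0, "+", 9, 25) is None


class TestCalibration:
    @staticmethod
    def _regions_with_model(seed=13, n=20):
        rng = np.random.default_rng(seed)
        sites = [make_site(rng) for _ in range(25)]
        aln = build_training_alignment(sites, flank=50)
        model = train_opwm(aln, candidate_lengths=range(12, 17, 4), seed=0)
        regions = []
        for i in range(n):
            seq = random_dna(rng, 300) + "TGTCAA" + random_dna(rng, 300)
            regions.append(SequenceRecord(f"r{i}", seq))
        return model, regions

    def test_target_one_returns_min_of_region_maxima(self):
        model, regions = self._regions_with_model()
        t = calibrate_threshold(model, regions, 1.0)
        anchor = parse_iupac("TGTCNN")
        from auxre.sequence_core import scan_consensus

        maxima = []
        for r in regions:
            scores = []
            for h in scan_consensus(r, anchor):
                win = oriented_window(
                    r.seq, h.start, h.strand, model.core_in_window,
                    model.window_length,
                )
                if win is not None:
                    scores.append(score_window_opwm(model, win))
            maxima.append(max(scores))
        assert t == pytest.approx(min(maxima))

    def test_monotone_coverage_in_threshold(self):
        model, regions = self._regions_with_model()
        thresholds = [calibrate_threshold(model, regions, f)
                      for f in (0.25, 0.5, 0.75, 1.0)]
        assert thresholds == sorted(thresholds, reverse=True)

    def test_planted_strong_regions_pass_exactly(self):
        """Regions with a planted training-consensus site outrank the rest."""
        rng = np.random.default_rng(21)
        site_word = random_dna(rng, 40) + "TGTCAA" + random_dna(rng, 40)
        sites = [(site_word, 40)] * 12 + [make_site(rng) for _ in range(13)]
        aln = build_training_alignment(sites, flank=30)
        model = train_opwm(aln, candidate_lengths=range(12, 17, 4), seed=0)
        strong_win = site_word[
            40 - model.core_in_window : 40 - model.core_in_window
            + model.window_length
        ]
        regions = []
        planted = set()
        for i in range(20):
            filler = random_dna(rng, 150).replace("TGTC", "AAAA")
            if i < 6:  # 30% planted with the exact strong window
                seq = filler + strong_win + filler
                planted.add(f"r{i}")
            else:
                seq = filler + "TGTCAA" + filler
            regions.append(SequenceRecord(f"r{i}", seq))
        t = calibrate_threshold(model, regions, 0.30)
        anchor = parse_iupac("TGTCNN")
        from auxre.sequence_core import scan_consensus

        passing = set()
        for r in regions:
            for h in scan_consensus(r, anchor):
                win = oriented_window(
                    r.seq, h.start, h.strand, model.core_in_window,
                    model.window_length,
                )
                if win is not None and score_window_opwm(model, win) >= t:
                    passing.add(r.id)
                    break
        assert passing == planted

    def test_no_anchors_anywhere_raises(self):
        model, _ = self._regions_with_model()
        regions = [SequenceRecord("r", "A" * 200)]
        with pytest.raises(ValueError, match="anchor"):
            calibrate_threshold(model, regions, 0.5)
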