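"""Regulation calls, arcsine proportion test, binomial trial, meta-analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from auxre.association import (
    ExpressionExperiment,
    arcsine_proportion_test,
    binomial_tail,
    call_regulation,
    consensus_regulated_genes,
    meta_association,
    resolve_min_experiments,
    summarize_association,
    validate_experiment,
)


def make_experiment(deltas, sd=0.05, reps=4, seed=0, exp_id="E1"):
    """Genes shifted by `deltas` log2 units between treatment and control."""
    rng = np.random.default_rng(seed)
    n = len(deltas)
    base = rng.normal(8, 1, size=n)
    treat = base[:, None] + np.asarray(deltas)[:, None] + rng.normal(
        0, sd, size=(n, reps)
    )
    ctrl = base[:, None] + rng.normal(0, sd, size=(n, reps))
    t_ids = [f"T{i}" for i in range(reps)]
    c_ids = [f"C{i}" for i in range(reps)]
    mat = pd.DataFrame(
        np.hstack([treat, ctrl]),
        index=[f"g{i}" for i in range(n)],
        columns=t_ids + c_ids,
    )
    return ExpressionExperiment(exp_id, mat, t_ids, c_ids, replicated=True)


class TestCallRegulation:
    def test_two_fold_low_noise_gene_called_up(self):
        exp = make_experiment([1.0, 0.0], sd=0.05)
        calls = call_regulation(exp)
        assert calls.loc["g0", "direction"] == "up"
        assert calls.loc["g1", "direction"] == "none"

    def test_fold_change_gate_blocks_small_shifts(self):
        # 1.32-fold (0.4 log2) is below the 1.5-fold gate however small p
        exp = make_experiment([0.4], sd=0.01)
        calls = call_regulation(exp)
        assert calls.loc["g0", "direction"] == "none"
        assert calls.loc["g0", "p_value"] < 1e-6

    def test_down_call_symmetric(self):
        exp = make_experiment([-1.0], sd=0.05)
        assert call_regulation(exp).loc["g0", "direction"] == "down"

    def test_t_statistic_matches_textbook_pooled_oracle(self):
        rng = np.random.default_rng(5)
        exp = make_experiment(rng.normal(0, 0.5, size=50), sd=0.3, seed=6)
        calls = call_regulation(exp)
        t = exp.matrix[exp.treatment].to_numpy()
        c = exp.matrix[exp.control].to_numpy()
        for i in range(50):
            x, y = t[i], c[i]
            n1, n2 = len(x), len(y)
            sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (
                n1 + n2 - 2
            )
            tstat = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
            p = 2 * stats.t.sf(abs(tstat), n1 + n2 - 2)
            assert calls.iloc[i]["p_value"] == pytest.approx(p, abs=1e-10)

    def test_single_replicate_uses_fold_change_only(self):
        mat = pd.DataFrame(
            {"T1": [9.0, 8.2], "C1": [8.0, 8.0]}, index=["g0", "g1"]
        )
        exp = ExpressionExperiment("E", mat, ["T1"], ["C1"],
                                   replicated=False)
        calls = call_regulation(exp)
        assert calls.loc["g0", "direction"] == "up"
        assert calls.loc["g1", "direction"] == "none"
        assert calls["p_value"].isna().all()

    def test_replicated_flag_with_one_sample_raises(self):
        mat = pd.DataFrame({"T1": [9.0], "C1": [8.0]}, index=["g0"])
        exp = ExpressionExperiment("E", mat, ["T1"], ["C1"], replicated=True)
        with pytest.raises(ValueError):
            call_regulation(exp)


class TestValidation:
    @pytest.mark.parametrize("n_reg,expected", [(99, False), (100, True)])
    def test_hundred_gene_boundary(self, n_reg, expected):
        calls = pd.DataFrame(
            {"direction": ["up"] * n_reg + ["none"] * 50}
        )
        assert validate_experiment(calls) is expected

    def test_planted_responders_validate(self):
        exp = make_experiment([1.2] * 150 + [0.0] * 500, sd=0.1, seed=7)
        assert validate_experiment(call_regulation(exp))


class TestConsensus:
    @staticmethod
    def _panel(up_counts, n_experiments=16):
        """gene gi is 'up' in up_counts[i] experiments."""
        frames = []
        for e in range(n_experiments):
            direction = [
                "up" if e < k else "none" for k in up_counts
            ]
            frames.append(
                pd.DataFrame(
                    {"direction": direction},
                    index=[f"g{i}" for i in range(len(up_counts))],
                )
            )
        return frames

    def test_three_vs_four_experiment_boundary(self):
        frames = self._panel([3, 4, 16])
        up, down = consensus_regulated_genes(frames, min_experiments=4)
        assert up == {"g1", "g2"}
        assert down == set()

    def test_gene_can_be_in_both_lists(self):
        idx = ["g0"]
        frames = [
            pd.DataFrame({"direction": ["up"]}, index=idx)
        ] * 4 + [
            pd.DataFrame({"direction": ["down"]}, index=idx)
        ] * 4
        up, down = consensus_regulated_genes(frames, 4)
        assert up == down == {"g0"}

    def test_lists_shrink_as_threshold_grows(self):
        rng = np.random.default_rng(8)
        frames = self._panel(list(rng.integers(0, 17, size=200)))
        sizes = [
            len(consensus_regulated_genes(frames, k)[0])
            for k in range(1, 9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_counts_match_recount_oracle(self):
        rng = np.random.default_rng(9)
        counts = list(rng.integers(0, 17, size=300))
        frames = self._panel(counts)
        up, _ = consensus_regulated_genes(frames, 4)
        assert len(up) == sum(1 for k in counts if k >= 4)


class TestArcsineTest:
    def test_equal_proportions_give_z_zero_p_half(self):
        r = arcsine_proportion_test(10, 100, 30, 300)
        assert r.z_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(0.5)

    def test_published_style_proportions(self):
        """Subset 191/1779 vs genome 1965/21098: z ~ 1.92, one-sided
        p ~ 0.027 (significant at 0.05 one-sided, not two-sided)."""
        r = arcsine_proportion_test(191, 1779, 1965, 21098)
        z = (2 * math.asin(math.sqrt(191 / 1779))
             - 2 * math.asin(math.sqrt(1965 / 21098))) / math.sqrt(
            1 / 1779 + 1 / 21098
        )
        assert r.z_statistic == pytest.approx(z)
        assert r.z_statistic == pytest.approx(1.92, abs=0.02)
        assert r.p_value == pytest.approx(0.027, abs=0.003)
        assert r.significant
        assert 2 * r.p_value > 0.05  # two-sided would not be significant

    def test_antisymmetry(self):
        a = arcsine_proportion_test(30, 200, 10, 150)
        b = arcsine_proportion_test(10, 150, 30, 200)
        assert a.z_statistic == pytest.approx(-b.z_statistic)

    def test_zero_group_size_raises(self):
        with pytest.raises(ValueError):
            arcsine_proportion_test(0, 0, 1, 10)

    def test_type_i_error_calibration(self):
        """Null simulation: both groups draw from p=0.1; the one-sided
        rejection rate at alpha 0.05 must sit in [0.04, 0.06]."""
        rng = np.random.default_rng(10)
        n_sim = 10_000
        n1, n2, p = 500, 5000, 0.1
        k1 = rng.binomial(n1, p, size=n_sim)
        k2 = rng.binomial(n2, p, size=n_sim)
        rejections = sum(
            arcsine_proportion_test(int(a), n1, int(b), n2).significant
            for a, b in zip(k1, k2)
        )
        assert 0.04 <= rejections / n_sim <= 0.06


class TestBinomialTrial:
    def test_sixteen_choose_four_at_five_percent(self):
        p = binomial_tail(16, 4, 0.05)
        assert p == pytest.approx(0.00700, abs=5e-5)
        assert p < 0.01

    def test_k_zero_is_one(self):
        assert binomial_tail(12, 0, 0.3) == 1.0

    def test_matches_cumulative_sum_complement(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            N = int(rng.integers(1, 31))
            k = int(rng.integers(0, N + 1))
            p = float(rng.random())
            lower = sum(
                math.comb(N, j) * p**j * (1 - p) ** (N - j)
                for j in range(0, k)
            )
            assert binomial_tail(N, k, p) == pytest.approx(1 - lower,
                                                           abs=1e-14)

    def test_monotone_in_k_and_p(self):
        tails = [binomial_tail(16, k, 0.05) for k in range(17)]
        assert tails == sorted(tails, reverse=True)
        ps = [binomial_tail(16, 4, p) for p in np.linspace(0, 1, 11)]
        assert ps == sorted(ps)

    def test_default_threshold_resolves_to_four_for_sixteen(self):
        assert resolve_min_experiments(16, 0.05) == 4


class TestMetaAssociation:
    @staticmethod
    def _panel_with_subset(
        n_genes=400, subset_size=80, up_rate_subset=0.4, up_rate_bg=0.1,
        n_experiments=16, n_enriched=16, seed=0,
    ):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        subset = set(genes[:subset_size])
        calls = []
        for e in range(n_experiments):
            rate_s = up_rate_subset if e < n_enriched else up_rate_bg
            direction = [
                "up"
                if rng.random() < (rate_s if g in subset else up_rate_bg)
                else "none"
                for g in genes
            ]
            calls.append(
                (f"E{e}", pd.DataFrame({"direction": direction},
                                       index=genes))
            )
        return subset, calls

    def test_enriched_subset_flagged_influential(self):
        subset, calls = self._panel_with_subset(n_enriched=8, seed=1)
        meta = meta_association(subset, calls)
        assert meta.min_experiments == 4
        assert meta.n_significant >= 4
        assert meta.influential

    def test_null_subsets_rarely_influential(self):
        rng = np.random.default_rng(2)
        _, calls = self._panel_with_subset(
            up_rate_subset=0.1, up_rate_bg=0.1, seed=3
        )
        genes = list(calls[0][1].index)
        flagged = 0
        n_rep = 200
        for _ in range(n_rep):
            subset = set(rng.choice(genes, size=80, replace=False))
            if meta_association(subset, calls).influential:
                flagged += 1
        assert flagged / n_rep < 0.05

    def test_planted_enrichment_recovery_rate(self):
        """Subset up-rate 0.2 vs background 0.1, n_subset 300: influential
        in >= 90% of seeded replicates."""
        flagged = 0
        n_rep = 50
        for rep in range(n_rep):
            subset, calls = self._panel_with_subset(
                n_genes=3000, subset_size=300, up_rate_subset=0.2,
                up_rate_bg=0.1, seed=100 + rep,
            )
            flagged += meta_association(subset, calls).influential
        assert flagged >= 0.9 * n_rep

    def test_empty_subset_raises(self):
        _, calls = self._panel_with_subset()
        with pytest.raises(ValueError):
            meta_association(set(), calls)


class TestSummary:
    def test_printed_percentage_arithmetic(self):
        s = summarize_association(1779, 191, 158)
        assert (s.pct_up, s.pct_up_conserved) == (10.7, 82.7)
        s = summarize_association(12635, 1221, 927)
        assert (s.pct_up, s.pct_up_conserved) == (9.7, 75.9)

    def test_zero_numerator_and_denominator_handling(self):
        s = summarize_association(10, 0, 0)
        assert s.pct_up == 0.0
        assert s.pct_up_conserved is None

    def test_ordering_violation_raises(self):
        with pytest.raises(ValueError):
            summarize_association(10, 5, 7)
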