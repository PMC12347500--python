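import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tvclahe.stats import (
    DegenerateInputError,
    RatingMatrix,
    bonferroni,
    build_benchmark_report,
    friedman,
    icc_2k,
    shapiro_gate,
    wilcoxon_signed_rank,
)
from tvclahe.phantom import simulate_ratings


# ---------------------------------------------------------------------------
# independent oracles

def enumerate_wilcoxon_p(diffs: np.ndarray) -> float:
    """Exact two-sided p by explicit iteration over all 2^n sign patterns."""
    d = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(d))
    w_plus_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_small = min(w_plus_obs, total - w_plus_obs)
    hits = 0
    n = len(ranks)
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if w_plus <= w_small + 1e-9 or w_plus >= total - w_small - 1e-9:
            hits += 1
    return hits / 2 ** n


def anova_icc_oracle(scores: np.ndarray) -> float:
    """ICC(2,k) from explicitly accumulated sums of squares."""
    n, k = scores.shape
    grand = scores.sum() / (n * k)
    ss_rows = sum(k * (scores[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (scores[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((scores[i, j] - grand) ** 2
                 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


# ---------------------------------------------------------------------------

class TestShapiroGate:
    def test_bimodal_sample_rejects(self, rng):
        x = np.concatenate([np.zeros(25), np.ones(25)])
        x += rng.normal(0, 1e-3, 50)
        results, non_normal = shapiro_gate([x])
        assert results[0].p_value < 0.05 and non_normal

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate([np.ones(10)])

    def test_type_one_error_rate(self):
        rejections = 0
        for seed in range(200):
            x = np.random.default_rng(seed).standard_normal(50)
            _, non_normal = shapiro_gate([x])
            rejections += non_normal
        lo, hi = sps.binom.ppf([0.025, 0.975], 200, 0.05)
        assert lo <= rejections <= hi


class TestWilcoxon:
    def test_worked_example_three_positive(self):
        res = wilcoxon_signed_rank(np.array([2.0, 3.0, 4.0]),
                                   np.array([1.0, 1.0, 1.0]))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.25, abs=1e-12)

    def test_all_zero_differences_rejected(self):
        a = np.arange(5, dtype=float)
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank(a, a)

    def test_exact_p_matches_full_enumeration(self, rng):
        """DP-computed exact p equals brute force over 2^10 sign patterns."""
        for _ in range(10):
            a = rng.integers(0, 8, 10).astype(float)
            b = rng.integers(0, 8, 10).astype(float)
            d = a - b
            if np.all(d == 0) or np.count_nonzero(d) < 3:
                continue
            res = wilcoxon_signed_rank(a, b)
            assert res.p_value == pytest.approx(enumerate_wilcoxon_p(d),
                                                abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        res = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, mode="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation(self, rng):
        a = rng.standard_normal(60)
        b = rng.standard_normal(60) + 0.4
        res = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, correction=True, mode="approx")
        assert res.extra["method"] == "normal-approximation"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_null_type_one_error_rate(self):
        rejections = 0
        for seed in range(200):
            g = np.random.default_rng(1000 + seed)
            a = g.standard_normal(20)
            b = g.standard_normal(20)
            rejections += wilcoxon_signed_rank(a, b).p_value < 0.05
        lo, hi = sps.binom.ppf([0.025, 0.975], 200, 0.05)
        assert lo <= rejections <= hi


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.01]).tolist() == [0.01]
        out = bonferroni([0.01, 0.2, 0.4, 0.02, 0.03, 0.005])
        assert out[0] == pytest.approx(0.06)
        assert out[2] == 1.0  # capped

    def test_never_decreases_and_caps(self, rng):
        p = rng.random(20)
        out = bonferroni(p)
        assert np.all(out >= p) and np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])


class TestFriedman:
    def test_worked_rank_matrix(self):
        res = friedman(np.array([[1, 2, 3], [1, 2, 3], [1, 3, 2]]))
        assert res.statistic == pytest.approx(4.667, abs=5e-4)
        assert res.df == 2

    def test_identical_columns_give_zero(self):
        m = np.tile(np.arange(5)[:, None], (1, 4)).astype(float)
        res = friedman(m)
        assert res.statistic == 0.0

    def test_matches_scipy_with_and_without_ties(self, rng):
        for _ in range(10):
            cont = rng.standard_normal((10, 4))
            tied = rng.integers(1, 6, (10, 4)).astype(float)
            for m in (cont, tied):
                ref = sps.friedmanchisquare(*m.T)
                res = friedman(m)
                assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
                assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_monotone_row_transform(self, rng):
        m = rng.random((8, 4)) + 0.1
        res1 = friedman(m)
        res2 = friedman(m ** 3)  # strictly increasing on positives
        assert res1.statistic == pytest.approx(res2.statistic, abs=1e-9)

    def test_too_few_treatments_rejected(self, rng):
        with pytest.raises(ValueError):
            friedman(rng.random((5, 2)))

    def test_null_type_one_error_rate(self):
        rejections = 0
        for seed in range(200):
            m = np.random.default_rng(5000 + seed).standard_normal((20, 4))
            rejections += friedman(m).p_value < 0.05
        lo, hi = sps.binom.ppf([0.025, 0.975], 200, 0.05)
        assert lo <= rejections <= hi


class TestIcc:
    def test_perfect_agreement(self):
        res = icc_2k(np.array([[1, 1], [2, 2], [3, 3]], dtype=float))
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_absolute_agreement_penalizes_rater_shift(self):
        base = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        m = np.column_stack([base, base + 2.0])
        res = icc_2k(m)
        # consistency-model ICC would be 1 here (MSE = 0)
        msr, _, mse = (res.extra["msr"], res.extra["msc"], res.extra["mse"])
        consistency = (msr - mse) / msr
        assert consistency == pytest.approx(1.0, abs=1e-12)
        assert res.statistic < consistency

    def test_matches_sums_of_squares_oracle(self, rng):
        for _ in range(10):
            m = rng.standard_normal((10, 4)) * 2 + 3
            assert icc_2k(m).statistic == pytest.approx(
                anova_icc_oracle(m), abs=1e-9)

    def test_matches_pingouin_value_and_ci(self, rng):
        import pingouin

        m = rng.standard_normal((12, 4)) + 3
        n, k = m.shape
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        })
        table = pingouin.intraclass_corr(df, "subject", "rater", "score")
        ref = table.set_index("Type").loc["ICC(A,k)"]
        res = icc_2k(m)
        assert res.statistic == pytest.approx(ref["ICC"], abs=1e-9)
        lo, hi = res.extra["ci95"]
        assert lo == pytest.approx(ref["CI95"][0], abs=5e-3)
        assert hi == pytest.approx(ref["CI95"][1], abs=5e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            icc_2k(np.full((4, 3), 2.0))

    def test_rating_matrix_csv_round_trip(self, tmp_path):
        rm = RatingMatrix(np.array([[1, 2], [3, 4], [5, 5]], dtype=float))
        rm.to_csv(tmp_path / "r.csv")
        back = RatingMatrix.from_csv(tmp_path / "r.csv")
        assert np.array_equal(back.scores, rm.scores)


class TestBenchmarkReport:
    @staticmethod
    def _metric_df():
        rows = []
        rng = np.random.default_rng(0)
        for img in range(5):
            rows.append(dict(image_id=f"i{img}", method="original",
                             psnr=float("inf"), snr=2.2 + 0.01 * img,
                             shannon_entropy=7.3, renyi_entropy=6.7,
                             ssim=1.0))
            rows.append(dict(image_id=f"i{img}", method="clahe",
                             psnr=20.0 + img, snr=2.3 + 0.01 * img,
                             shannon_entropy=7.5 + 0.01 * img,
                             renyi_entropy=7.0, ssim=0.82 + 0.001 * img))
        return pd.DataFrame(rows)

    def test_means_and_sds_match_hand_calculation(self):
        report = build_benchmark_report(self._metric_df())
        row = report["metrics"].set_index("method").loc["clahe"]
        vals = np.array([20.0, 21, 22, 23, 24])
        assert row["psnr"].startswith(
            f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})")

    def test_original_ssim_column_is_one(self):
        report = build_benchmark_report(self._metric_df())
        row = report["metrics"].set_index("method").loc["original"]
        assert row["ssim"] == "1.00 (0.00)"
        assert not row["ssim_significant"]

    def test_missing_original_rejected(self):
        df = self._metric_df()
        with pytest.raises(ValueError):
            build_benchmark_report(df[df["method"] != "original"])

    def test_rating_medians_follow_injected_effects(self):
        mats = simulate_ratings(30, ["he", "clahe", "tv-clahe"], np.zeros(4),
                                np.array([2.0, 3.0, 4.5]), noise_sd=0.3,
                                seed=6)
        report = build_benchmark_report(self._metric_df(), ratings=mats)
        med = report["ratings"].set_index("method")["global_median"]
        assert med["he"] < med["clahe"] < med["tv-clahe"]
        assert report["friedman"].p_value < 0.05
        assert "icc" in report
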