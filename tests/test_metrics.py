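"""ROI statistics and the test-retest reliability framework.

Brute-force oracles (explicit sums of squares, closed-form Pearson) are
implemented here, independently of the library code they check.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from diffseg.image import BinaryMask, Volume
from diffseg.metrics import (
    bootstrap_icc,
    cov_percent,
    cov_table,
    exclude_tracts,
    icc_consistency,
    pairwise_visit_correlation,
    roi_stats,
    tukey_nonadditivity,
)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def icc31_oracle(x):
    """ICC(3,1) from explicit two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    gm = x.mean()
    ssr = sum(k * (x[i].mean() - gm) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - gm) ** 2 for j in range(k))
    sst = ((x - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


def tukey_oracle(x):
    """Textbook one-degree-of-freedom non-additivity F statistic."""
    x = np.asarray(x, float)
    r, c = x.shape
    gm = x.mean()
    a = x.mean(axis=1) - gm
    b = x.mean(axis=0) - gm
    num = 0.0
    for i in range(r):
        for j in range(c):
            num += x[i, j] * a[i] * b[j]
    ss_n = num**2 / ((a**2).sum() * (b**2).sum())
    resid = x - gm - a[:, None] - b[None, :]
    ss_rem = (resid**2).sum() - ss_n
    df2 = (r - 1) * (c - 1) - 1
    return ss_n / (ss_rem / df2)


def pearson_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())


# ---------------------------------------------------------------------------
# ROI statistics
# ---------------------------------------------------------------------------

class TestRoiStats:
    def test_uniform_mask(self):
        fa = Volume(np.full((5, 5, 5), 0.5), np.eye(4))
        mask = BinaryMask(np.zeros((5, 5, 5), bool), np.eye(4))
        mask.data[0, 0, :10] = True
        mask.data[0, 0, :] = True
        mask.data[0, 1, :5] = True
        m = roi_stats(fa, mask, subject="s", visit="v", tract="t")
        assert m.mean_fa == 0.5 and m.sd_fa == 0.0 and m.n_voxels == 10

    def test_hand_arithmetic(self):
        fa = Volume(np.zeros((3, 1, 1)), np.eye(4))
        fa.data[:, 0, 0] = [0.2, 0.4, 0.6]
        mask = BinaryMask(np.ones((3, 1, 1), bool), np.eye(4))
        m = roi_stats(fa, mask)
        assert m.mean_fa == pytest.approx(0.4)
        assert m.sd_fa == pytest.approx(0.2)  # sample SD
        assert m.volume_mm3 == pytest.approx(3.0)
        assert m.hist_counts.sum() == 3

    def test_empty_mask_flagged_not_poisoned(self):
        fa = Volume(np.zeros((3, 3, 3)), np.eye(4))
        mask = BinaryMask(np.zeros((3, 3, 3), bool), np.eye(4))
        m = roi_stats(fa, mask)
        assert m.undefined and m.n_voxels == 0
        row = m.as_row()
        assert row["undefined"] is True


class TestCov:
    def test_examples(self):
        assert cov_percent([0.7, 0.7, 0.7]) == pytest.approx(0.0, abs=1e-9)
        assert cov_percent([0.48, 0.50, 0.52]) == pytest.approx(4.0)

    @given(st.floats(0.1, 100.0), st.integers(0, 10**6))
    def test_scale_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.5, 1.5, 5)
        assert cov_percent(k * x) == pytest.approx(cov_percent(x), rel=1e-9)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            cov_percent([-1.0, 1.0])

    def test_cov_table_hand_oracle(self):
        rows = []
        values = {
            ("s1", "t1"): [0.50, 0.52, 0.48],
            ("s2", "t1"): [0.60, 0.60, 0.60],
            ("s1", "t2"): [0.30, 0.33, 0.27],
            ("s2", "t2"): [0.40, 0.44, 0.36],
        }
        for (s, t), vals in values.items():
            for v, x in enumerate(vals):
                rows.append(
                    {"subject": s, "visit": f"v{v}", "tract": t, "mean_fa": x}
                )
        table, summary = cov_table(pd.DataFrame(rows))
        def cv(vals):
            return np.std(vals, ddof=1) / np.mean(vals) * 100
        exp_t1 = (cv(values[("s1", "t1")]) + cv(values[("s2", "t1")])) / 2
        exp_t2 = (cv(values[("s1", "t2")]) + cv(values[("s2", "t2")])) / 2
        got = dict(zip(table["tract"], table["mean_cov"]))
        assert got["t1"] == pytest.approx(exp_t1)
        assert got["t2"] == pytest.approx(exp_t2)
        assert summary["grand_mean_cov"] == pytest.approx((exp_t1 + exp_t2) / 2)

    def test_cov_table_matches_jitter_model(self):
        # additive per-visit jitter sigma -> expected COV ~ 100*sigma/mu
        rng = np.random.default_rng(11)
        mu, sigma = 0.6, 0.012
        rows = [
            {"subject": f"s{s}", "visit": f"v{v}", "tract": "t",
             "mean_fa": mu + rng.normal(0, sigma)}
            for s in range(200) for v in range(3)
        ]
        table, _ = cov_table(pd.DataFrame(rows))
        got = table["mean_cov"].iloc[0]
        # E[sample SD of 3 normals] = sigma * c4(3); c4 = sqrt(2/(n-1))G(n/2)/G((n-1)/2)
        from math import gamma, sqrt
        c4 = sqrt(2 / 2) * gamma(1.5) / gamma(1.0)
        assert got == pytest.approx(100 * sigma * c4 / mu, rel=0.1)

    def test_missing_visits_dropped(self):
        rows = [
            {"subject": "s1", "visit": "v1", "tract": "t", "mean_fa": 0.5},
            {"subject": "s2", "visit": "v1", "tract": "t", "mean_fa": 0.5},
            {"subject": "s2", "visit": "v2", "tract": "t", "mean_fa": 0.6},
        ]
        table, summary = cov_table(pd.DataFrame(rows))
        assert summary["dropped"] == [("t", "s1")]
        assert table["n_subjects"].iloc[0] == 1


class TestICC:
    def test_identical_raters_icc_one(self):
        x = np.tile(np.array([[0.3], [0.5], [0.7]]), (1, 4))
        out = icc_consistency(x)
        assert out["icc"] == pytest.approx(1.0, abs=1e-12)
        assert out["degenerate"]

    def test_additive_shift_ignored(self):
        base = np.array([0.3, 0.5, 0.7, 0.9])
        x = np.column_stack([base, base + 0.05, base - 0.02])
        out = icc_consistency(x)
        assert out["icc"] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 0.1, (6, 4))
        out = icc_consistency(x)
        assert out["icc"] == pytest.approx(icc31_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc3(self):
        # independent library route: pingouin's two-way mixed single-measure
        # consistency ICC on the same long-format data
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x = rng.normal(0.5, 0.1, (8, 4))
        rows = [
            {"target": i, "rater": j, "score": x[i, j]}
            for i in range(8) for j in range(4)
        ]
        res = pingouin.intraclass_corr(
            data=pd.DataFrame(rows), targets="target", raters="rater",
            ratings="score",
        )
        ref = float(res.loc[res["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert icc_consistency(x)["icc"] == pytest.approx(ref, abs=1e-8)

    def test_f_and_ci_sane(self):
        rng = np.random.default_rng(1)
        targets = rng.normal(0, 3, (10, 1))
        x = targets + rng.normal(0, 1, (10, 5))
        out = icc_consistency(x)
        lo, hi = out["ci"]
        assert lo < out["icc"] < hi
        assert out["p"] < 0.01


class TestBootstrapICC:
    def test_zero_noise_ci_collapses(self):
        x = np.tile(np.array([[0.3], [0.5], [0.7], [0.9]]), (1, 3))
        out = bootstrap_icc(x, n_boot=200, seed=0)
        assert out["ci"] == (1.0, 1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.5, 0.1, (8, 5))
        a = bootstrap_icc(x, n_boot=300, seed=77)
        b = bootstrap_icc(x, n_boot=300, seed=77)
        assert a["ci"] == b["ci"]
        assert bootstrap_icc(x, n_boot=300, seed=78)["ci"] != a["ci"]

    def test_seed_mandatory(self):
        with pytest.raises(ValueError):
            bootstrap_icc(np.ones((3, 3)), n_boot=10)

    def test_ci_covers_analytic_icc(self):
        # variance components sigma2_target = 9 * sigma2_error -> ICC 0.9
        cover = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            t = rng.normal(0, 3.0, (20, 1))
            x = t + rng.normal(0, 1.0, (20, 6))
            lo, hi = bootstrap_icc(x, n_boot=1000, seed=rep)["ci"]
            cover += lo <= 0.9 <= hi
        assert cover >= 90

    def test_ci_width_shrinks_with_table_size(self):
        rng = np.random.default_rng(3)
        def width(n, k, seed):
            t = rng.normal(0, 2.0, (n, 1))
            x = t + rng.normal(0, 1.0, (n, k))
            lo, hi = bootstrap_icc(x, n_boot=500, seed=seed)["ci"]
            return hi - lo
        small = np.mean([width(6, 3, s) for s in range(5)])
        large = np.mean([width(40, 10, s) for s in range(5)])
        assert large < small


class TestPairwiseCorrelation:
    @staticmethod
    def frame(values_by_visit):
        rows = []
        for visit, vals in values_by_visit.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"subject": f"s{i % 3}", "tract": f"t{i // 3}",
                     "visit": visit, "mean_fa": v, "n_voxels": 10 + i}
                )
        return pd.DataFrame(rows)

    def test_identical_visits_r_one(self):
        vals = [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]
        df = self.frame({"v1": vals, "v2": vals})
        out = pairwise_visit_correlation(df)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_visit_r_minus_one(self):
        vals = np.array([0.1, 0.3, 0.5, 0.6, 0.8, 0.9])
        df = self.frame({"v1": vals, "v2": (-vals + 1.0)})
        out = pairwise_visit_correlation(df)
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_table_matches_closed_form(self):
        a = [0.2, 0.4, 0.5, 0.7, 0.9, 0.3]
        b = [0.25, 0.38, 0.55, 0.66, 0.88, 0.35]
        df = self.frame({"v1": a, "v2": b})
        out = pairwise_visit_correlation(df)
        assert out["r"].iloc[0] == pytest.approx(pearson_oracle(a, b), abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(stats.pearsonr(a, b)[1], abs=1e-12)

    def test_constant_visit_flagged(self):
        df = self.frame({"v1": [0.5] * 6, "v2": [0.1, 0.3, 0.5, 0.6, 0.8, 0.9]})
        out = pairwise_visit_correlation(df)
        assert out["degenerate"].iloc[0]
        assert np.isnan(out["r"].iloc[0])


class TestTukey:
    def test_additive_table_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 6)
        b = rng.normal(0, 1, 5)
        x = 5.0 + a[:, None] + b[None, :]
        out = tukey_nonadditivity(x)
        assert out["p"] > 0.9

    def test_multiplicative_table_detected(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(1, 3, 10)
        b = rng.uniform(1, 3, 10)
        x = np.outer(a, b) + rng.normal(0, 0.01, (10, 10))
        out = tukey_nonadditivity(x)
        assert out["p"] < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (5, 5))
        out = tukey_nonadditivity(x)
        F = tukey_oracle(x)
        assert out["F"] == pytest.approx(F, abs=1e-10)
        df2 = (5 - 1) * (5 - 1) - 1
        assert out["p"] == pytest.approx(stats.f.sf(F, 1, df2), abs=1e-12)

    def test_small_table_rejected(self):
        with pytest.raises(ValueError):
            tukey_nonadditivity(np.ones((2, 5)))


class TestExclusionRule:
    def test_rule_applications(self):
        df = pd.DataFrame(
            {
                "tract": ["a", "b", "c", "d"],
                "cov_erode1": [2.0, 4.9, 5.0, 5.2],
                "cov_erode2": [2.0, 5.1, 5.0, 1.0],
            }
        )
        kept, excluded = exclude_tracts(df)
        # strict >5 in either condition excludes; exactly 5.0 in both is kept
        assert excluded == ["b", "d"]
        assert kept == ["a", "c"]

    def test_single_condition_with_warning(self):
        df = pd.DataFrame({"tract": ["a", "b"], "cov_erode1": [2.0, 6.0]})
        with pytest.warns(UserWarning):
            kept, excluded = exclude_tracts(df)
        assert kept == ["a"] and excluded == ["b"]
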