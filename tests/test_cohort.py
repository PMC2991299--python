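"""Overlap, variability, Mann-Whitney, Pearson and ROC statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcmr import (PcmrError, ValidationError, cohort_analysis, mann_whitney,
                  overlap_percentage, pearson, roc, variability_pct)


class TestOverlapPercentage:
    @pytest.mark.parametrize("a, b, expected", [
        (np.ones((4, 4), bool), np.ones((4, 4), bool), 100.0),
        (np.eye(4, dtype=bool), ~np.eye(4, dtype=bool), 0.0),
        (np.zeros((4, 4), bool), np.zeros((4, 4), bool), 100.0),
    ])
    def test_examples(self, a, b, expected):
        assert overlap_percentage(a, b) == expected

    def test_half_overlap(self):
        a = np.zeros((4, 4), bool); a[0, :] = True          # |A| = 4
        b = np.zeros((4, 4), bool); b[0, :2] = b[1, :2] = True  # |B| = 4
        assert overlap_percentage(a, b) == 50.0              # |A^B| = 2

    def test_symmetric_and_bounded_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.random((8, 8)) < 0.4
            b = rng.random((8, 8)) < 0.4
            d1, d2 = overlap_percentage(a, b), overlap_percentage(b, a)
            assert d1 == d2 and 0.0 <= d1 <= 100.0
            iou = overlap_percentage(a, b, method="iou")
            assert iou <= d1  # IoU never exceeds Dice

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            overlap_percentage(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestVariabilityPct:
    @pytest.mark.parametrize("x1, x2, expected", [
        (10.0, 10.0, 0.0), (9.0, 11.0, 20.0), (0.0, 0.0, 0.0),
        (185.0, 190.0, 100 * 5 / 187.5),
    ])
    def test_examples(self, x1, x2, expected):
        assert variability_pct(x1, x2) == pytest.approx(expected)

    def test_zero_mean_with_nonzero_difference_rejected(self):
        with pytest.raises(PcmrError):
            variability_pct(-3.0, 3.0)


def oracle_exact_p(a, b):
    """Two-sided exact p by direct pairwise-count U over all assignments."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)

    def u_of(idx):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        return sum((x > y) + 0.5 * (x == y) for x in grp for y in rest)

    u_obs = u_of(range(na))
    lim = na * (n - na)
    lo = min(u_obs, lim - u_obs)
    hits = total = 0
    for comb in itertools.combinations(range(n), na):
        u = u_of(comb)
        total += 1
        hits += min(u, lim - u) <= lo + 1e-9
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of 20 assignments as extreme

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_branch_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            na, nb = rng.integers(2, 6), rng.integers(2, 6)
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pooled[:na], pooled[na:]
            u, p = mann_whitney(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == ref.statistic
            assert p == pytest.approx(ref.pvalue)

    def test_exact_branch_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.integers(0, 4, na).astype(float)
            b = rng.integers(0, 4, nb).astype(float)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(oracle_exact_p(a, b))

    def test_large_separated_gaussians_highly_significant(self):
        rng = np.random.default_rng(4)
        controls = rng.normal(185, 35, 35)   # DT-like values, ~2 SD apart
        patients = rng.normal(300, 40, 18)
        _, p = mann_whitney(controls, patients)
        assert p < 0.0001
        ref = stats.mannwhitneyu(controls, patients, alternative="two-sided",
                                 method="asymptotic")
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_positive_line(self):
        r, slope, intercept = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(0.0)

    def test_perfect_negative_line(self):
        r, slope, intercept = pearson([0, 1, 2], [5, 4, 3])
        assert r == pytest.approx(-1.0)
        assert slope == pytest.approx(-1.0) and intercept == pytest.approx(5.0)

    def test_hand_computed_example(self):
        r, _, _ = pearson([1, 2, 3], [1, 2, 4])
        # cov = 1.5, sd_x = 1, sd_y = sqrt(7/3)
        assert r == pytest.approx(1.5 / np.sqrt(7 / 3), abs=1e-12)
        assert r == pytest.approx(0.982, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1, 1, 1], [1, 2, 3])


def oracle_auc(values, positive):
    """Pairwise concordance probability (ties count half)."""
    pos = values[positive]
    neg = values[~positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], ["c"] * 3 + ["p"] * 3, "p")
        assert r.auc == 1.0
        assert r.sensitivity == r.specificity == r.accuracy == 1.0
        assert 3 < r.optimal_threshold < 10

    def test_interleaved_example(self):
        r = roc([1, 3, 2, 4], ["c", "c", "p", "p"], "p")
        assert r.auc == pytest.approx(0.75)

    def test_sign_flip_keeps_reported_auc_via_orientation(self):
        vals = np.array([1.0, 3, 2, 4, 5, 0.5])
        labels = np.array(["c", "c", "c", "p", "p", "p"])
        r_hi = roc(vals, labels, "p")
        r_lo = roc(-vals, labels, "p")
        assert r_hi.auc == pytest.approx(r_lo.auc)
        assert r_hi.orientation == -r_lo.orientation

    def test_auc_matches_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            values = rng.integers(0, 10, n).astype(float)
            labels = rng.choice(["c", "p"], n)
            if len(set(labels)) < 2 or np.unique(values).size < 2:
                continue
            positive = labels == "p"
            want = max(oracle_auc(values, positive), 1 - oracle_auc(values, positive))
            got = roc(values, labels, "p").auc
            assert got == pytest.approx(want, abs=1e-12)

    def test_operating_point_is_on_the_sweep(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, 30)
        labels = np.where(rng.random(30) < 0.5, "c", "p")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "c", "p"
        r = roc(values, labels, "p")
        assert r.optimal_threshold in r.thresholds
        assert 0 <= r.auc <= 1

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, 40) + np.repeat([0.0, 1.0], 20)
        labels = np.repeat(["c", "p"], 20)
        r = roc(values, labels, "p")
        assert r.auc == pytest.approx(roc_auc_score(labels == "p", values))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc([1, 2, 3], ["c", "c", "c"], "c")

    def test_effect_size_monotonicity(self):
        """Bigger standardized group separation -> non-decreasing median AUC
        (common random numbers across effect sizes, 10 seeds)."""
        draws = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            draws.append((rng.normal(0, 1, 35), rng.normal(0, 1, 18)))
        # deltas start at 0.5: the reported AUC is orientation-folded to
        # >= 0.5, which inflates the zero-effect case by construction
        medians = []
        for delta in (0.5, 1.0, 2.0, 3.0):
            aucs = [roc(np.r_[c, p + delta],
                        np.r_[["c"] * 35, ["p"] * 18], "p").auc
                    for c, p in draws]
            medians.append(np.median(aucs))
        assert all(m2 >= m1 for m1, m2 in zip(medians, medians[1:]))


class TestCohortAnalysis:
    def _table(self):
        rng = np.random.default_rng(10)
        n_c, n_p = 35, 18
        return pd.DataFrame({
            "group": ["control"] * n_c + ["patient"] * n_p,
            "EA_ratio": np.r_[rng.normal(1.33, 0.40, n_c),
                              rng.normal(0.74, 0.27, n_p)],
            "DT_MR_ms": np.r_[rng.normal(185, 35, n_c), rng.normal(260, 40, n_p)],
        })

    def test_one_row_per_parameter_with_roc_columns(self):
        out = cohort_analysis(self._table(), "group", "patient")
        assert list(out["parameter"]) == ["EA_ratio", "DT_MR_ms"]
        for col in ("control_mean", "patient_mean", "p_value", "Sensitivity",
                    "Specificity", "NPV", "PPV", "Accuracy", "ROC threshold",
                    "AUC"):
            assert col in out.columns
        assert (out["p_value"] < 0.001).all()
        assert (out["AUC"] > 0.8).all()

    def test_missing_values_dropped_per_parameter(self):
        t = self._table()
        t.loc[0, "EA_ratio"] = np.nan
        out = cohort_analysis(t, "group", "patient")
        assert np.isfinite(out["p_value"]).all()

    def test_non_binary_groups_rejected(self):
        t = self._table()
        t.loc[0, "group"] = "other"
        with pytest.raises(ValidationError, match="binary"):
            cohort_analysis(t, "group", "patient")
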