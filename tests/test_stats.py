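"""Comparison battery: effect sizes, ROC/AUC, cut-offs, Bland-Altman,
descriptives and density shifts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from srscat.errors import ClassMissingError, SrsCatError, UndefinedEffectError
from srscat.stats import (
    bland_altman,
    cohens_d,
    compare_auc,
    cutoff_metrics,
    density_shift_summary,
    descriptive_table,
    roc_auc,
)


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair counting: (concordant + ties/2) / (m*n)."""
    x = scores[labels]
    y = scores[~labels]
    wins = ties = 0
    for xi in x:
        for yj in y:
            wins += xi > yj
            ties += xi == yj
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestCohensD:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert cohens_d(a, a) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(2, 1, 50), rng.normal(0, 1, 50)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_simulated_effect_of_two(self):
        rng = np.random.default_rng(1)
        a = rng.normal(2, 1, 100_000)
        b = rng.normal(0, 1, 100_000)
        assert cohens_d(a, b) == pytest.approx(2.0, abs=0.02)

    def test_pooled_weights_by_hand(self):
        a, b = np.array([0.0, 2.0]), np.array([1.0, 1.0, 4.0])
        pooled = np.sqrt(((2 - 1) * 2.0 + (3 - 1) * 3.0) / 3)
        assert cohens_d(a, b) == pytest.approx((1.0 - 2.0) / pooled)

    def test_zero_pooled_sd(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d(np.ones(5), np.ones(4))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.0, 1, 2, 10, 11, 12])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        roc = roc_auc(scores, labels)
        assert roc.auc == 1.0
        assert roc.n_cases == roc.n_controls == 3

    def test_null_auc(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.01)

    def test_toy_tie_matches_pair_counting(self):
        scores = np.array([1.0, 2, 2, 3, 4, 5])
        labels = np.array([0, 0, 1, 0, 1, 1], bool)
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(brute_force_auc(scores, labels))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_rank_estimator_equals_pair_counting(self, data):
        n = data.draw(st.integers(4, 50))
        scores = np.array(
            data.draw(
                st.lists(
                    st.integers(0, 12), min_size=n, max_size=n
                )
            ),
            dtype=float,
        )
        labels = np.array(
            data.draw(
                st.lists(st.booleans(), min_size=n, max_size=n).filter(
                    lambda l: 0 < sum(l) < len(l)
                )
            )
        )
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.4
        roc = roc_auc(scores, labels)
        order = np.argsort(roc.thresholds)
        assert np.all(np.diff(roc.sensitivities[order]) <= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ClassMissingError):
            roc_auc(np.arange(5.0), np.ones(5, bool))

    def test_binormal_link_d2_gives_092(self):
        """Equal-variance binormal scores at separation d=2 have theoretical
        AUC Phi(2/sqrt(2)) = 0.921."""
        rng = np.random.default_rng(6)
        scores = np.concatenate([rng.normal(2, 1, 10_000), rng.normal(0, 1, 10_000)])
        labels = np.repeat([True, False], 10_000)
        assert norm.cdf(2 / np.sqrt(2)) == pytest.approx(0.921, abs=5e-4)
        assert roc_auc(scores, labels).auc == pytest.approx(0.92, abs=0.01)


class TestCompareAUC:
    def test_self_comparison_paired(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        roc = roc_auc(scores, labels)
        res = compare_auc(roc, roc, paired=True)
        assert res.chi_square == 0.0
        assert res.p_value == 1.0

    def test_type_one_error_calibration(self):
        """Unpaired chi-squared AUC test holds its nominal 5% level under the
        null (two arms of n=70, identical true AUC)."""
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            pvals = []
            rocs = []
            for _arm in range(2):
                labels = np.repeat([True, False], 35)
                scores = rng.normal(size=70) + labels  # same true AUC both arms
                rocs.append(roc_auc(scores, labels))
            res = compare_auc(rocs[0], rocs[1], paired=False)
            rejections += res.p_value < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_mirrors_female_stratum_contrast(self):
        """Two diagnostics with true AUCs 0.99 vs 0.84 at the female-stratum
        sample size are distinguished in most replicates at alpha=0.05."""
        rng = np.random.default_rng(9)
        d_hi = norm.ppf(0.99) * np.sqrt(2)
        d_lo = norm.ppf(0.84) * np.sqrt(2)
        hits = 0
        reps = 200
        for _ in range(reps):
            labels = np.concatenate([np.ones(12, bool), np.zeros(46, bool)])
            s_a = rng.normal(size=58) + d_hi * labels
            s_b = rng.normal(size=58) + d_lo * labels
            res = compare_auc(
                roc_auc(s_a, labels), roc_auc(s_b, labels), paired=False
            )
            hits += res.p_value < 0.05
        assert hits / reps > 0.5

    def test_paired_needs_pair_data(self):
        rng = np.random.default_rng(10)
        l1 = rng.random(40) < 0.5
        l2 = rng.random(44) < 0.5
        roc_a = roc_auc(rng.normal(size=40), l1)
        roc_b = roc_auc(rng.normal(size=44), l2)
        if l1.sum() != l2.sum():
            with pytest.raises(SrsCatError):
                compare_auc(roc_a, roc_b, paired=True)


class TestCutoffs:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2, 3, 10, 11, 12])
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        table, optimal = cutoff_metrics(roc_auc(scores, labels))
        row = table[table["cutoff"] == optimal].iloc[0]
        assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0
        assert 3 < optimal <= 10

    def test_constant_scores_zero_j(self):
        scores = np.full(8, 5.0)
        labels = np.array([0, 1] * 4, bool)
        table, optimal = cutoff_metrics(roc_auc(scores, labels))
        assert np.allclose(table["youden_j"], 0.0)
        assert optimal == 5.0

    def test_matches_exhaustive_confusion_matrices(self):
        scores = np.array([3.0, 5, 5, 7, 8, 8, 9, 11])
        labels = np.array([0, 0, 1, 0, 1, 1, 0, 1], bool)
        table, optimal = cutoff_metrics(roc_auc(scores, labels))
        m, n = labels.sum(), (~labels).sum()
        best_j, best_cut = -np.inf, None
        for cut in sorted(np.unique(scores)):
            sens = np.sum(scores[labels] >= cut) / m
            spec = np.sum(scores[~labels] < cut) / n
            j = sens + spec - 1
            for _, row in table.iterrows():
                # roc_curve thresholds use >=; match where cutoffs coincide
                if row["cutoff"] == cut:
                    assert row["sensitivity"] == pytest.approx(sens)
                    assert row["specificity"] == pytest.approx(spec)
            if j > best_j:
                best_j, best_cut = j, cut
        finite = table[np.isfinite(table["cutoff"])]
        assert finite["youden_j"].max() == pytest.approx(best_j)
        assert optimal == best_cut


class TestBlandAltman:
    def test_identical_vectors(self):
        a = np.arange(10.0)
        res = bland_altman(a, a)
        assert res.mean_difference == 0.0
        assert res.pct_within == 100.0

    def test_normal_theory_coverage(self):
        rng = np.random.default_rng(11)
        b = rng.normal(size=10_000)
        a = b + rng.normal(0, 1, 10_000)
        res = bland_altman(a, b)
        assert res.pct_within == pytest.approx(95.4, abs=1.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        base = bland_altman(a, b)
        shifted = bland_altman(a + 3.0, b)
        assert shifted.mean_difference == pytest.approx(base.mean_difference + 3.0)
        assert (shifted.limits[1] - shifted.limits[0]) == pytest.approx(
            base.limits[1] - base.limits[0]
        )

    def test_label_exchange_invariance(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=150)
        b = a + rng.normal(0, 0.5, 150)
        assert bland_altman(a, b).pct_within == bland_altman(b, a).pct_within

    def test_length_mismatch(self):
        with pytest.raises(SrsCatError):
            bland_altman(np.arange(5.0), np.arange(6.0))


def score_frame():
    rng = np.random.default_rng(14)
    n = 120
    return pd.DataFrame(
        {
            "site": rng.choice(["clinical", "general"], n),
            "arm": rng.choice(["full", "short"], n),
            "diagnosis": rng.choice(["ASD", "non-ASD"], n),
            "scaled_score": rng.normal(60, 25, n),
        }
    )


class TestDescriptives:
    def test_single_group_matches_overall(self):
        df = score_frame()
        df["g"] = "all"
        out = descriptive_table(df, "g")
        assert out.loc[0, "n"] == len(df)
        assert out.loc[0, "median"] == pytest.approx(df["scaled_score"].median())
        assert out.loc[0, "mean"] == pytest.approx(df["scaled_score"].mean())

    def test_singleton_group_suppressed(self):
        df = pd.DataFrame(
            {"g": ["a", "a", "b"], "scaled_score": [1.0, 2.0, 3.0]}
        )
        out = descriptive_table(df, "g").set_index("g")
        assert bool(out.loc["b", "suppressed"])
        assert np.isnan(out.loc["b", "median"])
        assert not bool(out.loc["a", "suppressed"])

    def test_seven_value_group_by_sorting(self):
        vals = [11.0, 3, 7, 19, 5, 7, 13]
        df = pd.DataFrame({"g": "x", "scaled_score": vals})
        out = descriptive_table(df, "g")
        srt = np.sort(vals)
        assert out.loc[0, "median"] == srt[3]
        q1, q3 = np.percentile(vals, [25, 75])
        assert out.loc[0, "iqr"] == pytest.approx(q3 - q1)


class TestDensityShift:
    def test_identical_arms(self):
        df = score_frame()
        df2 = df.copy()
        df2["arm"] = df["arm"].map({"full": "short", "short": "full"})
        both = pd.concat([df, df2])
        out = density_shift_summary(both, "full", "short")
        assert out.loc[0, "shift_sd"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "overlap"] == pytest.approx(1.0)

    def test_two_sd_separation_overlap(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {
                "arm": np.repeat(["full", "short"], 50_000),
                "scaled_score": np.concatenate(
                    [rng.normal(0, 1, 50_000), rng.normal(2, 1, 50_000)]
                ),
            }
        )
        out = density_shift_summary(df, "full", "short")
        assert out.loc[0, "shift_sd"] == pytest.approx(2.0, abs=0.03)
        assert out.loc[0, "overlap"] == pytest.approx(2 * norm.cdf(-1), abs=0.01)
        assert 2 * norm.cdf(-1) == pytest.approx(0.317, abs=5e-4)

    def test_antisymmetric_under_arm_swap(self):
        df = score_frame()
        fwd = density_shift_summary(df, "full", "short")
        rev = density_shift_summary(df, "short", "full")
        assert fwd.loc[0, "shift_sd"] == pytest.approx(-rev.loc[0, "shift_sd"])
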