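"""Confusion rates, ROC/AUC, ANOVA and Duncan grouping against oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from saffronvision.evaluate import (
    ConfusionMatrix,
    anova_oneway,
    class_rates,
    confusion,
    duncan_groups,
    roc_auc,
)


def brute_force_auc(scores, labels, positive):
    """Concordance probability over all positive/negative pairs (midrank ties)."""
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array(["Pushal", "Negin", "Sargol", "Pushal"])
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))
        assert cm.accuracy == 1.0

    def test_small_two_class_example(self):
        cm = confusion(["A", "A", "B"], ["A", "B", "B"], classes=["A", "B"])
        assert np.array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_trace_over_total_is_accuracy(self, rng):
        y = rng.choice(["Pushal", "Negin", "Sargol"], 50)
        p = rng.choice(["Pushal", "Negin", "Sargol"], 50)
        cm = confusion(y, p)
        assert cm.accuracy == pytest.approx(np.mean(y == p))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["A"], ["B"], classes=["A"])


class TestClassRates:
    def test_rate_identities_on_fuzzed_matrices(self, rng):
        for _ in range(200):
            counts = rng.integers(1, 50, (3, 3))
            cm = ConfusionMatrix(counts=counts, classes=("Pushal", "Negin", "Sargol"))
            rt = class_rates(cm)
            assert np.allclose(rt.tp_rate + rt.fn_rate, 100.0)
            assert np.allclose(rt.pp_rate + rt.fd_rate, 100.0)
            assert np.all((rt.tp_rate >= 0) & (rt.tp_rate <= 100))

    def test_perfect_matrix(self):
        cm = ConfusionMatrix(counts=np.diag([5, 6, 7]), classes=("Pushal", "Negin", "Sargol"))
        rt = class_rates(cm)
        assert np.allclose(rt.tp_rate, 100) and np.allclose(rt.pp_rate, 100)
        assert np.allclose(rt.fn_rate, 0) and np.allclose(rt.fd_rate, 0)

    def test_absent_class_reported_missing(self):
        counts = np.array([[3, 0, 0], [1, 0, 2], [0, 0, 4]])  # nothing predicted Negin
        cm = ConfusionMatrix(counts=counts, classes=("Pushal", "Negin", "Sargol"))
        with pytest.warns(UserWarning):
            rt = class_rates(cm)
        assert np.isnan(rt.pp_rate[1])


class TestRocAuc:
    def test_perfect_separation(self):
        labels = np.array(["pos"] * 5 + ["neg"] * 5)
        scores = np.array([0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.05, 0.3, 0.15])
        _, auc = roc_auc(scores, labels, "pos")
        assert auc == pytest.approx(1.0)

    def test_uninformative_scores(self):
        labels = np.array(["pos"] * 4 + ["neg"] * 4)
        _, auc = roc_auc(np.full(8, 0.5), labels, "pos")
        assert auc == pytest.approx(0.5)

    def test_negation_symmetry(self, rng):
        labels = rng.choice(["pos", "neg"], 30)
        while len(set(labels)) < 2:
            labels = rng.choice(["pos", "neg"], 30)
        scores = rng.normal(size=30)
        _, a1 = roc_auc(scores, labels, "pos")
        _, a2 = roc_auc(-scores, labels, "pos")
        assert a1 + a2 == pytest.approx(1.0)

    def test_equals_concordance_probability(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 51))
            labels = rng.choice(["pos", "neg"], n)
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding makes ties
            _, auc = roc_auc(scores, labels, "pos")
            assert auc == pytest.approx(brute_force_auc(scores, labels, "pos"), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.array(["pos"] * 4), "pos")


class TestAnova:
    def test_identical_groups_f_zero(self):
        F, *_ = anova_oneway([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert F == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self, rng):
        g1 = 0.0 + rng.normal(0, 1e-3, 10)
        g2 = 10.0 + rng.normal(0, 1e-3, 10)
        F, _, _, _, p = anova_oneway([g1, g2])
        assert p < 1e-6

    def test_sum_of_squares_identity(self, rng):
        groups = [rng.normal(i, 2.0, 12) for i in range(4)]
        F, dfb, dfw, ems, p = anova_oneway(groups)
        allv = np.concatenate(groups)
        ss_total = ((allv - allv.mean()) ** 2).sum()
        ss_between = sum(len(g) * (g.mean() - allv.mean()) ** 2 for g in groups)
        ss_within = ems * dfw
        assert ss_between + ss_within == pytest.approx(ss_total, abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i * 0.5, 1.0, 10) for i in range(5)]
        F, _, _, _, p = anova_oneway(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_degenerate_all_constant(self):
        with pytest.warns(UserWarning):
            F, *_ = anova_oneway([np.array([5.0, 5.0]), np.array([5.0, 5.0])])
        assert np.isnan(F)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.array([1.0, 2.0])])


class TestDuncan:
    def test_equal_means_single_letter(self):
        means = {f"g{i}": 50.0 for i in range(6)}
        res = duncan_groups(means, n_per_group=10, error_mean_square=1.0, df_within=54)
        assert set(res.letters) == {"a"}

    def test_two_far_clusters_two_letters(self):
        means = {"a1": 90.0, "a2": 90.2, "b1": 50.0, "b2": 50.3}
        res = duncan_groups(means, n_per_group=10, error_mean_square=0.5, df_within=36)
        top = {res.letters[res.names.index(n)] for n in ("a1", "a2")}
        bottom = {res.letters[res.names.index(n)] for n in ("b1", "b2")}
        assert top == {"a"} and bottom == {"b"}

    def test_critical_range_against_brute_force_quantile(self):
        """A stretch of r means is split iff its range exceeds
        q(protection, r, df) * sqrt(EMS/n), with protection 1-(1-a)^(r-1)."""
        ems, n, df, alpha = 2.0, 10, 18, 0.05
        crit2 = sps.studentized_range.ppf((1 - alpha) ** 1, 2, df) * np.sqrt(ems / n)
        gap = crit2 * 1.05
        res = duncan_groups({"hi": 50.0 + gap, "lo": 50.0}, n, ems, df, alpha)
        assert res.letters[0] != res.letters[1]
        res = duncan_groups({"hi": 50.0 + 0.95 * crit2, "lo": 50.0}, n, ems, df, alpha)
        assert res.letters[0] == res.letters[1]

    def test_letters_are_order_preserving(self, rng):
        means = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(40, 90, 8))}
        res = duncan_groups(means, n_per_group=10, error_mean_square=4.0, df_within=72)
        # every letter spans a contiguous stretch of the sorted means
        for letter in set("".join(res.letters)):
            idx = [i for i, ls in enumerate(res.letters) if letter in ls]
            assert idx == list(range(min(idx), max(idx) + 1))

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            duncan_groups({"a": 1.0, "b": 2.0}, n_per_group=1, error_mean_square=1, df_within=5)
        with pytest.raises(ValueError):
            duncan_groups({"a": 1.0}, n_per_group=5, error_mean_square=1, df_within=5)
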