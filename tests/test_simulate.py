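import itertools

import numpy as np
import pytest
from scipy import stats

from rosie.simulate import (
    apply_expression_shift,
    apply_label_switch,
    evaluate_roc,
    generate_base_dataset,
    make_scenario,
)


def pair_counting_auc(scores, truth):
    """All-pairs concordance oracle (ties count one half)."""
    pos = scores[truth]
    neg = scores[~truth]
    total = wins = 0.0
    for a, b in itertools.product(pos, neg):
        total += 1
        wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / total


class TestGenerateBase:
    def test_reproducible_and_balanced(self):
        X1, y1 = generate_base_dataset(n=40, p=30, seed=5)
        X2, _ = generate_base_dataset(n=40, p=30, seed=5)
        np.testing.assert_array_equal(X1.values, X2.values)
        assert y1.y.sum() == 20

    def test_huge_effect_separates_classes(self):
        X, y = generate_base_dataset(
            n=4, p=2, n_informative=1, effect_size=100.0, seed=0
        )
        assert X.values[y.y == 1, 0].min() > X.values[y.y == 0, 0].max()

    def test_null_effect_t_statistics(self):
        """With effect_size=0 the per-feature two-sample t-statistics
        behave as under the null: ~5% beyond |t|=2."""
        X, y = generate_base_dataset(n=60, p=2000, effect_size=0.0, seed=11)
        t, _ = stats.ttest_ind(X.values[y.y == 1], X.values[y.y == 0])
        frac = (np.abs(t) > 2).mean()
        assert 0.02 < frac < 0.08


class TestLabelSwitch:
    @pytest.mark.parametrize("fraction,expected", [(0.05, 10), (0.15, 30)])
    def test_exact_flip_counts(self, fraction, expected):
        _, y = generate_base_dataset(n=200, p=10, seed=1)
        y_obs, truth = apply_label_switch(y, fraction, seed=2)
        assert truth.sum() == expected
        assert (y_obs.y != y.y).sum() == expected
        assert ((y_obs.y != y.y) == truth).all()

    def test_involution(self):
        _, y = generate_base_dataset(n=50, p=5, seed=1)
        once, _ = apply_label_switch(y, 0.2, seed=7)
        twice, _ = apply_label_switch(once, 0.2, seed=7)
        np.testing.assert_array_equal(twice.y, y.y)

    def test_fraction_bounds(self):
        _, y = generate_base_dataset(n=20, p=5, seed=1)
        with pytest.raises(ValueError):
            apply_label_switch(y, 0.6)


class TestExpressionShift:
    def test_shift_counts_at_study_scale(self):
        X, _ = generate_base_dataset(n=200, p=3200, seed=3)
        Xc, truth = apply_expression_shift(X, seed=4)
        changed_features = (Xc.values != X.values).any(axis=0).sum()
        assert changed_features == 480  # 15% of 3200
        assert truth.sum() == 10  # 5% of 200

    def test_zero_multiplier_leaves_matrix_untouched(self):
        X, _ = generate_base_dataset(n=40, p=50, seed=3)
        Xc, truth = apply_expression_shift(X, multiplier=0.0, seed=4)
        np.testing.assert_array_equal(Xc.values, X.values)
        assert truth.sum() == 2

    def test_unchosen_cells_bit_identical(self):
        X, _ = generate_base_dataset(n=40, p=50, seed=3)
        Xc, truth = apply_expression_shift(X, seed=4)
        feats = (Xc.values != X.values).any(axis=0)
        untouched_rows = ~truth
        assert (Xc.values[untouched_rows] == X.values[untouched_rows]).all()
        assert (Xc.values[:, ~feats] == X.values[:, ~feats]).all()

    def test_scenarios_reproducible(self):
        a = make_scenario("expression_shift", n=30, p=40, seed=6)
        b = make_scenario("expression_shift", n=30, p=40, seed=6)
        np.testing.assert_array_equal(a.X.values, b.X.values)
        np.testing.assert_array_equal(a.outlier_truth, b.outlier_truth)
        assert a.y_observed.y is not None
        np.testing.assert_array_equal(a.y_observed.y, a.y_true.y)


class TestEvaluateRoc:
    def test_perfect_ranking(self):
        roc = evaluate_roc(
            np.array([5.0, 4.0, 1.0, 0.5]), np.array([True, True, False, False])
        )
        assert roc.auc == 1.0

    def test_three_quarters_concordant(self):
        roc = evaluate_roc(
            np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0], dtype=bool)
        )
        assert roc.auc == pytest.approx(0.75)

    def test_curve_shape(self):
        rng = np.random.default_rng(2)
        roc = evaluate_roc(rng.random(30), rng.random(30) < 0.4)
        assert roc.fpr[0] == 0 and roc.fpr[-1] == 1
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_roc(np.array([1.0, 2.0]), np.array([True, True]))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            truth = rng.random(n) < 0.4
            if truth.all() or not truth.any():
                continue
            roc = evaluate_roc(scores, truth)
            assert roc.auc == pytest.approx(
                pair_counting_auc(scores, truth), abs=1e-12
            )

    def test_supervised_methods_beat_rskc_on_label_switch(
        self, simulation_study_table
    ):
        """Label-flip outliers are invisible to the unsupervised member:
        in most seeded replicates each supervised method's AUC exceeds
        RSKC's by at least 0.1 on the label-switch scenarios."""
        tab = simulation_study_table
        for scen in ("label_switch_5", "label_switch_15"):
            wide = (
                tab[tab.scenario == scen]
                .pivot(index="seed", columns="method", values="auc")
            )
            for method in ("sprm", "enetlts"):
                wins = (wide[method] - wide["rskc"] >= 0.1).sum()
                assert wins > len(wide) / 2

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(31)
        aucs = [
            evaluate_roc(
                rng.random(40), np.r_[np.ones(20, bool), np.zeros(20, bool)]
            ).auc
            for _ in range(1000)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02
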