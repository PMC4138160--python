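"""Hedges's g and effect-size-based PC ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitsep import (
    CovariancePCA,
    EffectSizePrefixSelector,
    effect_size_label,
    hedges_g,
    hedges_g_from_summary,
    prefix_scores,
    rank_by_effect_size,
    rank_by_variance,
)

finite_floats = st.floats(-50, 50, allow_nan=False)


def exact_moment_sample(mean, sd, n, rng):
    """A sample whose mean and sample SD equal the targets exactly."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestHedgesG:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=20)
        assert hedges_g(x, x) == 0.0

    def test_equal_means_unequal_sds_zero(self, rng):
        a = exact_moment_sample(5.0, 1.0, 30, rng)
        b = exact_moment_sample(5.0, 4.0, 25, rng)
        assert hedges_g(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_published_summary_worked_value(self):
        g = hedges_g_from_summary(11.45, 4.03, 263, 9.50, 4.30, 220, correction=False)
        assert g == pytest.approx(0.4693, abs=1e-4)
        g_corr = hedges_g_from_summary(11.45, 4.03, 263, 9.50, 4.30, 220, correction=True)
        assert g_corr == pytest.approx(0.4686, abs=1e-4)

    def test_raw_and_summary_paths_agree(self, rng):
        a, b = rng.normal(2, 3, 41), rng.normal(0, 1, 28)
        for corr in (True, False):
            expected = hedges_g_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size, corr
            )
            assert hedges_g(a, b, correction=corr) == pytest.approx(
                expected, rel=1e-14, abs=1e-15
            )

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        a, b = rng.normal(1, 2, 35), rng.normal(0, 2, 50)
        ours = hedges_g(a, b, correction=True)
        ref = pingouin.compute_effsize(a, b, eftype="hedges")
        assert ours == pytest.approx(ref, abs=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        shift=finite_floats,
        scale=st.floats(0.1, 20, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_antisymmetry_and_affine_invariance(self, shift, scale, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(1, 2, 15), r.normal(0, 1, 12)
        g = hedges_g(a, b)
        assert hedges_g(b, a) == pytest.approx(-g, rel=1e-12)
        assert hedges_g(scale * a + shift, scale * b + shift) == pytest.approx(
            g, rel=1e-9, abs=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hedges_g(np.array([1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="pooled SD"):
            hedges_g(np.array([1.0, 1.0]), np.array([1.0, 1.0]))

    @pytest.mark.parametrize(
        "g,label", [(0.85, "large"), (-0.9, "large"), (0.56, "medium"),
                    (0.49, "medium"), (0.45, "medium"), (0.44, "small"), (0.0, "small")]
    )
    def test_magnitude_labels(self, g, label):
        assert effect_size_label(g) == label


class TestEffectRanking:
    def test_known_g_values_sorted_by_magnitude(self, rng):
        # columns built with exact g of 0.1, 0.8 and 0.5 (uncorrected scale)
        n = 200
        cols_a = [exact_moment_sample(g, 1.0, n, rng) for g in (0.1, 0.8, 0.5)]
        cols_b = [exact_moment_sample(0.0, 1.0, n, rng) for _ in range(3)]
        X = np.vstack([np.column_stack(cols_a), np.column_stack(cols_b)])
        y = np.array(["A"] * n + ["B"] * n)
        sel = EffectSizePrefixSelector(n_select=3, group_order=("A", "B")).fit(X, y)
        assert list(sel.order_) == [1, 2, 0]
        expected = np.array([0.1, 0.8, 0.5]) * (1 - 3 / (4 * 400 - 9))
        np.testing.assert_allclose(np.abs(sel.g_), expected, rtol=1e-6)

    def test_planted_eigen_direction_ranks_first_by_g_not_by_variance(self, rng):
        n, p, axis = 400, 12, 7  # plant along the 8th-largest-variance axis
        lam = 2.0 * 0.8 ** np.arange(p)
        Q, _ = np.linalg.qr(rng.normal(size=(p, p)))
        S = rng.normal(size=(n, p)) * np.sqrt(lam)
        y = np.array(["m"] * (n // 2) + ["f"] * (n // 2))
        S[y == "f", axis] += 1.5 * np.sqrt(lam[axis])
        X = S @ Q.T
        pca = CovariancePCA().fit(X)
        ranking = rank_by_effect_size(pca, y, group_order=("f", "m"))
        # the planted direction: PC whose scores correlate most with the shift
        planted = int(np.argmax(np.abs(pca.scores_.T @ (y == "f"))))
        assert ranking.order[0] == planted
        assert planted >= 4  # deep in the variance ordering

    def test_ranking_invariant_to_eigenvector_sign_flips(self, rng):
        X = rng.normal(size=(60, 6))
        y = rng.choice(["a", "b"], size=60)
        pca = CovariancePCA().fit(X)
        r1 = rank_by_effect_size(pca, y)
        flipped = CovariancePCA().fit(X)
        flipped.components_ = -flipped.components_
        flipped.scores_ = -flipped.scores_
        r2 = rank_by_effect_size(flipped, y)
        np.testing.assert_array_equal(r1.order, r2.order)
        np.testing.assert_allclose(r1.key_values, r2.key_values)

    def test_permutation_null_keeps_g_small(self, rng):
        n = 2000
        X = rng.normal(size=(n, 10))
        y = rng.permutation(np.array(["a", "b"] * (n // 2)))
        pca = CovariancePCA().fit(X)
        ranking = rank_by_effect_size(pca, y)
        assert ranking.key_values[0] < 3 / np.sqrt(n) * 2.5

    def test_one_empty_group_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        pca = CovariancePCA().fit(X)
        with pytest.raises(ValueError):
            rank_by_effect_size(pca, np.array(["a"] * 10))


class TestPrefixScores:
    @pytest.fixture()
    def fitted(self, general_cohort):
        from gaitsep import VARIABLE_NAMES

        pca = CovariancePCA().fit(general_cohort[list(VARIABLE_NAMES)])
        ranking = rank_by_effect_size(pca, general_cohort["gender"].to_numpy())
        return pca, ranking

    def test_full_prefix_is_column_permutation(self, fitted):
        pca, ranking = fitted
        scores, cumvar, min_key = prefix_scores(pca, ranking, len(ranking.order))
        np.testing.assert_array_equal(scores, pca.scores_[:, ranking.order])
        assert cumvar == pytest.approx(1.0, abs=1e-8)
        assert min_key == ranking.key_values[-1]

    def test_single_prefix_is_top_g_column(self, fitted):
        pca, ranking = fitted
        scores, _, min_key = prefix_scores(pca, ranking, 1)
        np.testing.assert_array_equal(scores.ravel(), pca.scores_[:, ranking.order[0]])
        assert min_key == ranking.key_values[0]

    def test_selected_set_variance_is_additive(self, fitted):
        pca, ranking = fitted
        _, cumvar, _ = prefix_scores(pca, ranking, 10)
        expected = pca.explained_variance_ratio_[ranking.order[:10]].sum()
        assert cumvar == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_k_rejected(self, fitted):
        pca, ranking = fitted
        with pytest.raises(ValueError):
            prefix_scores(pca, ranking, 0)
        with pytest.raises(ValueError):
            prefix_scores(pca, ranking, len(ranking.order) + 1)
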