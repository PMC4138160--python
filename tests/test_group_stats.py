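"""t-tests, Holm step-down adjustment and PC-variable correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gaitsep import (
    CovariancePCA,
    VARIABLE_NAMES,
    holm_adjust,
    pc_variable_correlations,
    two_sample_tests,
)
from gaitsep.group_stats import correlation_category


def manual_holm(p):
    """Independent oracle: explicit step-down with monotonicity enforcement."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


class TestHolm:
    @pytest.mark.parametrize(
        "p,expected,n_reject",
        [
            ([0.001, 0.01, 0.03], [0.003, 0.02, 0.03], 3),
            ([0.04, 0.04], [0.08, 0.08], 0),
            ([0.2], [0.2], 0),
        ],
    )
    def test_worked_examples(self, p, expected, n_reject):
        adjusted, reject = holm_adjust(p, alpha=0.05)
        np.testing.assert_allclose(adjusted, expected, atol=1e-12)
        assert reject.sum() == n_reject

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_manual_step_down(self, p):
        adjusted, _ = holm_adjust(p)
        np.testing.assert_allclose(adjusted, manual_holm(p), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_never_more_conservative_than_bonferroni(self, p):
        adjusted, _ = holm_adjust(p)
        bonf = np.minimum(np.asarray(p) * len(p), 1.0)
        assert (adjusted <= bonf + 1e-12).all()
        i = int(np.argmin(p))
        assert adjusted[i] == pytest.approx(bonf[i], abs=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=40)
        adjusted, _ = holm_adjust(p)
        assert (adjusted >= p - 1e-15).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.2])


def _table(values_a, values_b, var="L_hip_frontal_maxpeak"):
    n_a, n_b = len(values_a), len(values_b)
    df = pd.DataFrame({v: np.zeros(n_a + n_b) for v in VARIABLE_NAMES})
    df[var] = np.concatenate([values_a, values_b])
    df.insert(0, "gender", ["male"] * n_a + ["female"] * n_b)
    # give the untested columns some spread so the t-test is defined
    r = np.random.default_rng(0)
    for v in VARIABLE_NAMES:
        if v != var:
            df[v] = r.normal(size=n_a + n_b)
    return df


class TestTwoSampleTests:
    def test_identical_groups_give_null_result(self, rng):
        x = rng.normal(size=12)
        df = _table(x, x)
        out = two_sample_tests(df, variables=["L_hip_frontal_maxpeak"])
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_raw"] == pytest.approx(1.0)

    def test_pooled_t_worked_example(self):
        df = _table([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out = two_sample_tests(df, variables=["L_hip_frontal_maxpeak"])
        assert out.loc[0, "t"] == pytest.approx(-3.6742, abs=1e-4)
        assert out.loc[0, "df"] == 4
        assert out.loc[0, "p_raw"] == pytest.approx(0.0214, abs=5e-4)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(1, 2, 18)
        out1 = two_sample_tests(_table(a, b), variables=["L_hip_frontal_maxpeak"])
        out2 = two_sample_tests(_table(2 * a, 2 * b), variables=["L_hip_frontal_maxpeak"])
        assert out1.loc[0, "t"] == pytest.approx(out2.loc[0, "t"], rel=1e-12)
        assert out1.loc[0, "p_raw"] == pytest.approx(out2.loc[0, "p_raw"], rel=1e-12)

    def test_family_is_all_tested_variables(self, general_cohort):
        out = two_sample_tests(general_cohort)
        assert len(out) == 72
        np.testing.assert_allclose(
            out["p_holm"], manual_holm(out["p_raw"].to_numpy()), atol=1e-12
        )

    def test_welch_variant_changes_df(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 40)
        pooled = two_sample_tests(_table(a, b), variables=["L_hip_frontal_maxpeak"])
        welch = two_sample_tests(_table(a, b), welch=True, variables=["L_hip_frontal_maxpeak"])
        assert pooled.loc[0, "df"] == 48
        assert welch.loc[0, "df"] != 48

    def test_large_n_t_matches_normal_limit(self, rng):
        n = 100_000
        a, b = rng.normal(0.01, 1, n), rng.normal(0, 1, n)
        out = two_sample_tests(_table(a, b), variables=["L_hip_frontal_maxpeak"])
        z = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / n + b.var(ddof=1) / n)
        p_norm = 2 * stats.norm.sf(abs(z))
        assert out.loc[0, "t"] == pytest.approx(z, rel=1e-6)
        assert out.loc[0, "p_raw"] == pytest.approx(p_norm, abs=1e-4)

    def test_tiny_group_rejected(self, rng):
        df = _table([1.0], rng.normal(size=5))
        with pytest.raises(ValueError):
            two_sample_tests(df)


class TestCorrelations:
    @pytest.mark.parametrize(
        "r,category",
        [(0.36, "moderate"), (0.35, "weak"), (0.67, "moderate"), (0.68, "strong"),
         (-0.7, "strong"), (0.0, "weak")],
    )
    def test_category_boundaries(self, r, category):
        assert correlation_category(r) == category

    def test_rank_one_variable_loads_on_single_pc(self, rng):
        # two orthogonal latent factors; each column follows exactly one
        n = 300
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        df = pd.DataFrame({v: np.zeros(n) for v in VARIABLE_NAMES})
        df["gender"] = ["male", "female"] * (n // 2)
        r = np.random.default_rng(5)
        for v in VARIABLE_NAMES:
            df[v] = r.normal(size=n) * 0.001
        # a six-column factor block keeps its eigenvalue (6) well clear of
        # the Marchenko-Pastur noise bulk (~2.2) at p/n = 72/300
        for col, scale in [
            ("L_hip_frontal_maxpeak", 2.0),
            ("R_hip_frontal_maxpeak", -1.0),
            ("L_hip_frontal_toeoff", 1.0),
            ("R_hip_frontal_toeoff", -2.0),
            ("L_knee_frontal_maxpeak", 1.5),
            ("R_knee_frontal_maxpeak", 1.0),
        ]:
            df[col] = scale * f1
        df["L_knee_sagittal_toeoff"] = f2
        pca = CovariancePCA().fit(df[list(VARIABLE_NAMES)])
        out = pc_variable_correlations(pca, [1, 2], df)
        row = out.set_index("variable").loc["L_hip_frontal_maxpeak"]
        assert max(row["r_PC1"], row["r_PC2"]) > 0.99
        assert min(row["r_PC1"], row["r_PC2"]) < 0.05

    def test_uncorrelated_noise_is_weak(self, general_cohort):
        r = np.random.default_rng(8)
        df = general_cohort.copy()
        pca = CovariancePCA().fit(df[list(VARIABLE_NAMES)])
        noise_col = VARIABLE_NAMES[0]
        df[noise_col] = r.normal(size=len(df))
        out = pc_variable_correlations(pca, [1], df, variables=[noise_col])
        assert out.loc[0, "category_PC1"] == "weak"
        assert out.loc[0, "r_PC1"] < 0.15

    def test_missing_pc_rejected(self, general_cohort):
        pca = CovariancePCA().fit(general_cohort[list(VARIABLE_NAMES)])
        with pytest.raises(ValueError):
            pc_variable_correlations(pca, [99], general_cohort)
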