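"""Univariate battery: normality, variance homogeneity, Games-Howell,
binomial gender test, Kendall/Hochberg correlation matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import triroc as tr
from triroc.stats import hochberg_adjust

from conftest import brute_force_hochberg, brute_force_kendall_tau


class TestAndersonDarling:
    # statistic/P frozen from R nortest::ad.test on the same vectors
    R_CASES = [
        ("normal_quantiles", 0.0207720167, 0.9999888195),
        ("small_sample", 0.2557420219, 0.6586498362),
        ("squares", 0.6251512842, 0.0888068322),
    ]

    def _vector(self, name):
        if name == "normal_quantiles":
            return sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        if name == "small_sample":
            return np.array(
                [1.1, 2.3, 0.4, 5.6, 2.2, 3.3, 0.9, 1.7, 2.8, 4.1, 0.2, 1.5]
            )
        return np.arange(1, 21, dtype=float) ** 2

    @pytest.mark.parametrize("name, stat, p", R_CASES)
    def test_matches_reference_implementation(self, name, stat, p):
        a2, pv = tr.anderson_darling_normality(self._vector(name))
        assert a2 == pytest.approx(stat, abs=1e-8)
        assert pv == pytest.approx(p, abs=1e-8)

    def test_perfectly_normal_shape_large_p(self):
        _, p = tr.anderson_darling_normality(
            sps.norm.ppf((np.arange(1, 101) - 0.5) / 100)
        )
        assert p > 0.99

    def test_exponential_rejected(self):
        x = np.random.default_rng(1).exponential(1.0, 5000)
        _, p = tr.anderson_darling_normality(x)
        assert p < 0.001

    def test_nominal_size(self):
        """Under normal data the test rejects at roughly its level."""
        rng = np.random.default_rng(10)
        rejections = sum(
            tr.anderson_darling_normality(rng.normal(0, 1, 500))[1] < 0.05
            for _ in range(200)
        )
        assert 0.03 <= rejections / 200 <= 0.07 or abs(
            rejections / 200 - 0.05
        ) <= 0.02

    def test_validation(self):
        with pytest.raises(tr.ValidationError):
            tr.anderson_darling_normality(np.ones(20))
        with pytest.raises(tr.ValidationError):
            tr.anderson_darling_normality(np.arange(5.0))


class TestFlignerKilleen:
    def test_size_under_null(self):
        rng = np.random.default_rng(3)
        ps = [
            tr.fligner_killeen(
                [rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
            )[1]
            for _ in range(200)
        ]
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) <= 0.04

    def test_power_against_variance_ratio(self):
        rng = np.random.default_rng(4)
        _, p = tr.fligner_killeen(
            [rng.normal(0, 1, 50), rng.normal(0, 5, 50)]
        )
        assert p < 0.01

    def test_label_symmetry(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, s, 20) for s in (1, 2, 3)]
        s1, _ = tr.fligner_killeen(groups)
        s2, _ = tr.fligner_killeen(groups[::-1])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_validation(self):
        with pytest.raises(tr.ValidationError):
            tr.fligner_killeen([np.ones(5), np.ones(5)])
        with pytest.raises(tr.ValidationError):
            tr.fligner_killeen([np.arange(5.0)])


class TestGamesHowell:
    def test_identical_groups(self):
        v = np.arange(10.0)
        out = tr.games_howell({"a": v, "b": v.copy()})
        row = out.iloc[0]
        assert row.t == 0.0 and row.p == 1.0

    def test_reduces_to_welch_for_two_groups(self):
        """With k=2 the studentized-range reference collapses to the
        two-sided Welch t distribution (Q_{2,df} = |t| sqrt(2))."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.normal(0, 1, rng.integers(5, 30))
            b = rng.normal(0.5, 2, rng.integers(5, 30))
            ours = tr.games_howell({"a": a, "b": b}).iloc[0]
            welch = sps.ttest_ind(a, b, equal_var=False)
            assert ours.p == pytest.approx(welch.pvalue, abs=1e-6)

    def test_converges_to_tukey_when_homoscedastic(self):
        """Equal variances and equal n: Games-Howell approaches Tukey's
        HSD (pooled-df studentized range) as the balance is exact."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(7)
        n = 2000
        data = np.concatenate(
            [rng.normal(m, 1.0, n) for m in (0.0, 0.15, 0.3)]
        )
        labels = np.repeat(["a", "b", "c"], n)
        ours = tr.games_howell(
            {g: data[labels == g] for g in ("a", "b", "c")}
        )
        tukey = pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose(
            ours.p.to_numpy(), tukey.pvalues, atol=1e-3
        )

    def test_group_order_symmetry(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(i, i + 1, 15) for i, g in enumerate("abc")}
        fwd = tr.games_howell(groups)
        rev = tr.games_howell(dict(reversed(groups.items())))
        for _, row in fwd.iterrows():
            match = rev[
                (rev.group1.isin([row.group1, row.group2]))
                & (rev.group2.isin([row.group1, row.group2]))
            ].iloc[0]
            assert abs(match.t) == pytest.approx(abs(row.t), rel=1e-12)
            assert match.p == pytest.approx(row.p, rel=1e-9)

    def test_zero_variance_pair_flagged_not_fatal(self):
        out = tr.games_howell(
            {
                "a": np.full(5, 1.0),
                "b": np.full(5, 2.0),
                "c": np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
            }
        )
        ab = out[(out.group1 == "a") & (out.group2 == "b")].iloc[0]
        assert np.isnan(ab.p)
        rest = out[~((out.group1 == "a") & (out.group2 == "b"))]
        assert rest.p.notna().all()

    def test_validation(self):
        with pytest.raises(tr.ValidationError):
            tr.games_howell({"a": np.arange(5.0)})
        with pytest.raises(tr.ValidationError):
            tr.games_howell({"a": np.array([1.0]), "b": np.arange(3.0)})


class TestGenderBinomial:
    def test_printed_counts(self):
        """22 males / 4 females: exact two-sided binomial P rounds to
        0.0005 at the printed precision."""
        p = tr.gender_binomial_test((22, 4))
        assert round(p, 4) == 0.0005

    def test_balanced_counts(self):
        assert tr.gender_binomial_test((10, 10)) == 1.0

    def test_one_sided_extreme_closed_form(self):
        assert tr.gender_binomial_test((20, 0)) == pytest.approx(
            2.0 * 0.5**20, rel=1e-12
        )

    def test_validation(self):
        with pytest.raises(tr.ValidationError):
            tr.gender_binomial_test((0, 0))


class TestKendallHochberg:
    def test_perfectly_concordant_pair(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8],
                           "c": [1.0, 3, 2, 4]})
        cm = tr.kendall_hochberg_matrix(df)
        assert cm.tau.loc["a", "b"] == pytest.approx(1.0)

    def test_brute_force_pair_counting(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([3.0, 1, 2, 5, 4])
        df = pd.DataFrame({"x": x, "y": y, "z": np.arange(5.0)})
        cm = tr.kendall_hochberg_matrix(df)
        assert cm.tau.loc["x", "y"] == pytest.approx(0.4, abs=1e-12)
        assert brute_force_kendall_tau(x, y) == pytest.approx(0.4)

    def test_single_pair_adjustment_is_identity(self):
        df = pd.DataFrame(
            {"a": np.random.default_rng(0).normal(size=10),
             "b": np.random.default_rng(1).normal(size=10)}
        )
        cm = tr.kendall_hochberg_matrix(df)
        assert cm.p_adjusted.loc["a", "b"] == pytest.approx(
            cm.p_raw.loc["a", "b"]
        )

    def test_matrix_invariants(self, default_cohort):
        cm = tr.kendall_hochberg_matrix(default_cohort)
        tau = cm.tau.to_numpy()
        assert np.allclose(tau, tau.T, equal_nan=True)
        assert np.nanmax(np.abs(tau)) <= 1.0
        off = ~np.eye(tau.shape[0], dtype=bool)
        assert np.all(
            cm.p_adjusted.to_numpy()[off] >= cm.p_raw.to_numpy()[off] - 1e-12
        )

    def test_constant_variable_flagged(self):
        df = pd.DataFrame(
            {"a": np.arange(6.0), "b": np.ones(6), "c": np.arange(6.0)[::-1]}
        )
        cm = tr.kendall_hochberg_matrix(df)
        assert cm.degenerate == ["b"]
        assert np.isnan(cm.tau.loc["b", "a"])
        assert cm.tau.loc["a", "c"] == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=25
        )
    )
    def test_hochberg_matches_stepup_definition(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(
            hochberg_adjust(p), brute_force_hochberg(p), atol=1e-12
        )

    def test_sample_order_invariance(self, default_cohort):
        shuffled = default_cohort.copy()
        shuffled.data = shuffled.data.sample(
            frac=1.0, random_state=1
        ).reset_index(drop=True)
        a = tr.kendall_hochberg_matrix(default_cohort)
        b = tr.kendall_hochberg_matrix(shuffled)
        np.testing.assert_allclose(
            a.tau.to_numpy(), b.tau.to_numpy(), atol=1e-12
        )


def test_pairwise_battery_shapes(default_cohort):
    out = tr.pairwise_battery(
        default_cohort, variables=default_cohort.metabolites[:4]
    )
    assert list(out.normality_p.columns) == list(default_cohort.class_order)
    assert len(out.pairwise_p) == 4
    for tab in out.pairwise_p.values():
        assert len(tab) == 3  # three pairwise comparisons
        assert ((tab.p.dropna() >= 0) & (tab.p.dropna() <= 1)).all()
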