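"""Correlation-structure comparison and the association battery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from retvasc.stats import (CorrelationMatrix, association_battery,
                           compare_correlation_sets, correlation_matrix)


def _matrix_from_offdiag(values, k, labels=None):
    """Build a symmetric unit-diagonal matrix from an upper-triangle vector."""
    m = np.eye(k)
    iu = np.triu_indices(k, 1)
    m[iu] = values
    m[(iu[1], iu[0])] = values
    labels = labels or [f"p{i}" for i in range(k)]
    return CorrelationMatrix(values=pd.DataFrame(m, index=labels,
                                                 columns=labels))


class TestCorrelationMatrix:
    def test_duplicate_and_negated_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        m = correlation_matrix(df).values
        assert m.loc["a", "b"] == pytest.approx(1.0)
        assert m.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m), 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((10_000, 5)),
                          columns=list("abcde"))
        m = correlation_matrix(df).values.to_numpy()
        off = m[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_insufficient_pairs_missing(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, np.nan, np.nan]})
        m = correlation_matrix(df, min_pairs=3).values
        assert np.isnan(m.loc["a", "b"])

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2, 3]}))


class TestCompareCorrelationSets:
    def test_17_phenotypes_give_136_pairs_df_135(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(-0.5, 0.5, 136)
        rg = _matrix_from_offdiag(v + 0.05, 17)
        rp = _matrix_from_offdiag(v, 17)
        cmp_ = compare_correlation_sets(rg, rp, n_perm=1000, seed=0)
        assert cmp_.n_pairs == 136
        assert cmp_.df == 135

    def test_identical_matrices(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(-0.6, 0.6, 45)
        rg = _matrix_from_offdiag(v, 10)
        rp = _matrix_from_offdiag(v.copy(), 10)
        cmp_ = compare_correlation_sets(rg, rp, n_perm=500, seed=1)
        assert cmp_.d == pytest.approx(0.0, abs=1e-12)
        assert cmp_.corr_of_corr == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_closed_form_d(self):
        # off-diagonals with sample SD exactly 0.2; +0.1 shift -> d = 0.5
        rng = np.random.default_rng(4)
        v = rng.standard_normal(136)
        v = (v - v.mean()) / v.std(ddof=1) * 0.2
        rg = _matrix_from_offdiag(v + 0.1, 17)
        rp = _matrix_from_offdiag(v, 17)
        cmp_ = compare_correlation_sets(rg, rp, n_perm=100, seed=0)
        assert cmp_.d == pytest.approx(0.5, abs=1e-9)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(-0.7, 0.7, 45)
        b = a + rng.normal(0, 0.1, 45)
        rg, rp = _matrix_from_offdiag(a, 10), _matrix_from_offdiag(b, 10)
        fwd = compare_correlation_sets(rg, rp, n_perm=200, seed=7)
        rev = compare_correlation_sets(rp, rg, n_perm=200, seed=7)
        assert rev.d == pytest.approx(-fwd.d, rel=1e-12)
        assert rev.t == pytest.approx(-fwd.t, rel=1e-9)
        assert rev.corr_of_corr == pytest.approx(fwd.corr_of_corr, rel=1e-12)

    def test_permutation_p_bounds_and_reproducibility(self):
        rng = np.random.default_rng(6)
        a = rng.uniform(-0.7, 0.7, 45)
        b = a + rng.normal(0, 0.05, 45)
        rg, rp = _matrix_from_offdiag(a, 10), _matrix_from_offdiag(b, 10)
        c1 = compare_correlation_sets(rg, rp, n_perm=999, seed=3)
        c2 = compare_correlation_sets(rg, rp, n_perm=999, seed=3)
        assert c1.permutation_p == c2.permutation_p
        assert 1.0 / 1000 <= c1.permutation_p <= 1.0

    def test_printed_denominator_available(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(-0.4, 0.4, 45)
        spread = (v - v.mean()) * 1.5 + v.mean() + 0.1  # larger SD + shift
        rg, rp = _matrix_from_offdiag(spread, 10), _matrix_from_offdiag(v, 10)
        pooled = compare_correlation_sets(rg, rp, n_perm=10, seed=0)
        printed = compare_correlation_sets(rg, rp, n_perm=10, seed=0,
                                           denominator="printed")
        sd_g, sd_p = np.std(spread, ddof=1), np.std(v, ddof=1)
        assert printed.d == pytest.approx(
            0.1 / np.sqrt((sd_g**2 - sd_p**2) / 2), rel=1e-9)
        assert printed.d != pytest.approx(pooled.d, rel=1e-3)

    def test_label_mismatch_rejected(self):
        rg = _matrix_from_offdiag([0.1, 0.2, 0.3], 3, labels=list("abc"))
        rp = _matrix_from_offdiag([0.1, 0.2, 0.3], 3, labels=list("abd"))
        with pytest.raises(ValueError):
            compare_correlation_sets(rg, rp, n_perm=10)


class TestAssociationBattery:
    def test_linear_effect_recovery(self):
        rng = np.random.default_rng(0)
        n = 2000
        x = rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        res = association_battery(pd.DataFrame({"idp": x}),
                                  pd.DataFrame({"trait": y}))
        expected = 0.5 * x.std() / y.std()
        assert res.loc[0, "beta"] == pytest.approx(expected, abs=0.05)
        assert res.loc[0, "tier"] == "**"

    def test_bonferroni_threshold_arithmetic(self):
        # 17 x 20 tests: tier-1 threshold 0.05/340; a p-value just above it
        # must stay 'ns' while one below 0.001/340 earns '**'
        rng = np.random.default_rng(1)
        n = 5000
        idps = pd.DataFrame(rng.standard_normal((n, 17)),
                            columns=[f"i{k}" for k in range(17)])
        traits = pd.DataFrame(rng.standard_normal((n, 20)),
                              columns=[f"t{k}" for k in range(20)])
        traits["t0"] = 0.5 * idps["i0"] + rng.standard_normal(n)
        res = association_battery(idps, traits)
        strong = res[(res.idp == "i0") & (res.trait == "t0")].iloc[0]
        assert strong.tier == "**"
        assert strong.p < 0.001 / 340
        nulls = res[~((res.idp == "i0") & (res.trait == "t0"))]
        assert (nulls.p[nulls.tier == "ns"] >= 0.05 / 340).all()

    def test_logistic_odds_ratio_direction(self):
        rng = np.random.default_rng(2)
        n = 3000
        x = rng.standard_normal(n)
        p = 1 / (1 + np.exp(-(x - 0.5)))
        y = rng.binomial(1, p)
        res = association_battery(pd.DataFrame({"idp": x}),
                                  pd.DataFrame({"disease": y}),
                                  model="logistic")
        assert res.loc[0, "effect"] == pytest.approx(np.e, rel=0.15)
        assert res.loc[0, "tier"] == "**"

    def test_single_class_trait_missing(self):
        rng = np.random.default_rng(3)
        res = association_battery(
            pd.DataFrame({"idp": rng.standard_normal(100)}),
            pd.DataFrame({"disease": np.zeros(100)}), model="logistic")
        assert np.isnan(res.loc[0, "p"])
        assert res.loc[0, "tier"] == "ns"

    def test_null_p_values_uniform(self):
        # permuted-label battery: p-values should be U(0,1)
        rng = np.random.default_rng(4)
        n = 400
        pvals = []
        for _ in range(4):
            idps = pd.DataFrame(rng.standard_normal((n, 17)),
                                columns=[f"i{k}" for k in range(17)])
            traits = pd.DataFrame(rng.standard_normal((n, 15)),
                                  columns=[f"t{k}" for k in range(15)])
            res = association_battery(idps, traits)
            pvals.extend(res.p.dropna())
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.05
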