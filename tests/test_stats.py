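import math

import numpy as np
import pandas as pd
import pytest

from mcsf import (correlate, group_compare, label_significance, mann_whitney,
                  occurrence_test, pca_profile, plsda_profile,
                  timecourse_test, trial_compare, wilcoxon_paired)
from mcsf.errors import DegenerateInputError, UsageError
from conftest import make_table
from oracles import (fisher_enum_p, mann_whitney_enum_p, pca_eigen_oracle,
                     wilcoxon_enum_p)


class TestSignificanceLabels:
    @pytest.mark.parametrize("p, label", [
        (0.049, "significant"), (0.05, "significant"),
        (0.0500001, "trend"), (0.1, "trend"), (0.1001, "ns"), (0.9, "ns")])
    def test_boundaries(self, p, label):
        assert label_significance(p) == label


class TestMannWhitney:
    def test_identical_groups(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p == pytest.approx(1.0)

    def test_fully_separated_5v5_exact(self):
        r = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert r.statistic == 0
        assert r.extra["method"] == "exact"
        assert r.p == pytest.approx(2 / 252)

    def test_matches_enumeration(self, rng):
        for m, n in ((3, 3), (4, 5), (6, 6), (5, 8)):
            x = rng.normal(size=m)
            y = rng.normal(loc=0.8, size=n)
            r = mann_whitney(x, y)
            assert r.p == pytest.approx(mann_whitney_enum_p(x, y), abs=1e-12)

    def test_ties_use_corrected_normal(self):
        r = mann_whitney([1, 1, 2, 3], [2, 3, 3, 4])
        assert r.extra["method"] == "normal_tie_corrected"
        assert 0 < r.p <= 1

    def test_degenerate_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            mann_whitney([1.0], [2.0, 3.0])
        with pytest.raises(DegenerateInputError):
            mann_whitney([np.nan, np.nan, np.nan], [1.0, 2.0, 3.0])

    def test_group_compare_excludes_missing(self):
        tab = make_table({"p": [1.0, 2.0, np.nan, 5.0, 6.0, 7.0]},
                         ["A"] * 3 + ["B"] * 3)
        r = group_compare(tab, "p")
        assert r.extra["n"] == (2, 3)


class TestWilcoxon:
    def test_identical_trials(self):
        r = wilcoxon_paired([1, 2, 3], [1, 2, 3])
        assert r.p == 1.0

    def test_all_positive_n6_exact(self):
        r = wilcoxon_paired([1, 2, 3, 4, 5, 6], [2, 4, 7, 11, 16, 22])
        assert r.extra["method"] == "exact"
        assert r.p == pytest.approx(2 / 64)

    def test_matches_sign_enumeration(self, rng):
        for n in (6, 8, 10):
            d = rng.normal(loc=0.5, size=n)
            r = wilcoxon_paired(np.zeros(n), d)
            assert r.p == pytest.approx(wilcoxon_enum_p(d), abs=1e-12)

    def test_tied_differences_match_enumeration(self):
        d = [1.0, 1.0, -1.0, 2.0, 2.0, 3.0]
        r = wilcoxon_paired(np.zeros(6), d)
        assert r.p == pytest.approx(wilcoxon_enum_p(d), abs=1e-12)

    def test_trial_compare_uses_imputed_latencies(self, arena):
        # an unvisited-zone latency imputed at the session duration is a
        # real pair, not a missing one
        vals = [100.0, 150.0, 120.0, 90.0, 1800.0, 1800.0,
                110.0, 140.0, 130.0, 95.0, 200.0, 250.0]
        tab = make_table({"LAT_dcr": vals[:6] + vals[6:]}, ["A"] * 6,
                         trials=("1", "2"))
        r = trial_compare(tab, "LAT_dcr", group="A")
        assert r.extra["n_pairs"] == 6


class TestFriedman:
    def test_identical_bins(self):
        df = pd.DataFrame(np.tile([4.0, 4.0, 4.0], (6, 1)),
                          columns=["b1", "b2", "b3"])
        r = timecourse_test(df)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_strictly_decreasing_closed_form(self):
        """12 rats, 3 bins, all strictly decreasing: chi2 = 12*2 = 24."""
        base = np.array([30.0, 20.0, 10.0])
        df = pd.DataFrame(base + np.arange(12)[:, None], columns=list("abc"))
        r = timecourse_test(df)
        assert r.statistic == pytest.approx(24.0)
        assert r.df == 2
        assert all(v["p_adj"] <= 1 for v in r.extra["dunn"].values())

    def test_missing_bin_excludes_rat_with_warning(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)),
                          columns=["b1", "b2", "b3"])
        df.iloc[2, 2] = np.nan
        with pytest.warns(UserWarning, match="excluding 1 rat"):
            r = timecourse_test(df)
        assert r.extra["n"] == 5


class TestFisher:
    def test_symmetric_table(self):
        assert occurrence_test([[6, 6], [6, 6]]).p == pytest.approx(1.0)

    def test_cross_table_matches_enumeration(self):
        r = occurrence_test([[10, 2], [2, 10]])
        assert r.p == pytest.approx(fisher_enum_p([[10, 2], [2, 10]]),
                                    abs=1e-12)
        assert r.p == pytest.approx(0.00332895, abs=1e-7)

    def test_zero_margin(self):
        assert occurrence_test([[0, 0], [5, 7]]).p == 1.0

    def test_random_tables_match_enumeration(self, rng):
        for _ in range(100):
            tab = rng.integers(0, 11, size=(2, 2))
            assert occurrence_test(tab).p == pytest.approx(
                fisher_enum_p(tab.tolist()), abs=1e-9)


class TestCorrelate:
    def test_identity_very_strong(self):
        r = correlate([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.statistic == pytest.approx(1.0)
        assert r.extra["strength"] == "very strong"
        assert r.extra["sign"] == "positive"

    @pytest.mark.parametrize("r, strength", [
        (-0.65, "strong"), (0.45, "moderate"), (0.2, "weak/none"),
        (0.85, "very strong"), (0.6, "strong"), (0.4, "moderate")])
    def test_bands(self, r, strength):
        from mcsf.stats import correlation_strength
        assert correlation_strength(r) == strength

    def test_constant_input_flagged(self):
        r = correlate([1, 1, 1, 1], [1, 2, 3, 4])
        assert r.extra["constant_input"]
        assert math.isnan(r.statistic)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateInputError):
            correlate([1, 2, 3], [1, 2, 3])


class TestPCA:
    def _table(self, X):
        idx = pd.MultiIndex.from_tuples(
            [(f"r{i}", "A" if i < len(X) // 2 else "B", "1")
             for i in range(len(X))], names=["rat_id", "group", "trial"])
        return pd.DataFrame(X, index=idx,
                            columns=[f"p{j}" for j in range(X.shape[1])])

    def test_matches_eigen_oracle_6x4(self, rng):
        X = rng.normal(size=(6, 4))
        X[:, 0] = 3 * X[:, 1] + rng.normal(scale=0.1, size=6)  # dominant axis
        tab = self._table(X)
        res = pca_profile(tab, tab.columns)
        evr, evecs = pca_eigen_oracle(X)
        np.testing.assert_allclose(res.r2x, evr[:len(res.r2x)], atol=1e-10)
        for j in range(2):
            v1 = res.loadings.iloc[:, j].to_numpy()
            v2 = evecs[:, j]
            assert abs(abs(v1 @ v2) - 1) < 1e-8  # same axis up to sign

    def test_duplicated_column_equal_loadings(self, rng):
        X = rng.normal(size=(8, 3))
        X = np.c_[X, X[:, 0]]
        res = pca_profile(self._table(X), ["p0", "p1", "p2", "p3"])
        informative = res.r2x > 1e-12  # the null-space component is arbitrary
        np.testing.assert_allclose(res.loadings.loc["p0"][informative],
                                   res.loadings.loc["p3"][informative],
                                   atol=1e-10)

    def test_r2x_sums_below_one_and_nonincreasing(self, rng):
        res = pca_profile(self._table(rng.normal(size=(10, 5))),
                          [f"p{j}" for j in range(5)])
        assert res.r2x.sum() <= 1 + 1e-9
        assert all(np.diff(res.r2x) <= 1e-12)

    def test_zero_variance_column_dropped(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_profile(self._table(X), ["p0", "p1", "p2"])
        assert res.dropped == ["p1"]

    def test_reconstruction_with_all_components(self, rng):
        X = rng.normal(size=(7, 4))
        tab = self._table(X)
        res = pca_profile(tab, tab.columns)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Xs, atol=1e-10)


class TestPLSDA:
    def _table(self, X, n_a):
        idx = pd.MultiIndex.from_tuples(
            [(f"r{i}", "A" if i < n_a else "B", "1")
             for i in range(len(X))], names=["rat_id", "group", "trial"])
        return pd.DataFrame(X, index=idx,
                            columns=[f"p{j}" for j in range(X.shape[1])])

    def test_planted_parameter_has_top_weight(self, rng):
        X = rng.normal(size=(24, 8))
        X[12:, 5] += 3.0
        res = plsda_profile(self._table(X, 12), [f"p{j}" for j in range(8)])
        assert res.w["LV1"].abs().idxmax() == "p5"

    def test_groups_on_opposite_sides(self, rng):
        X = rng.normal(size=(24, 6))
        X[12:, 2] += 4.0
        res = plsda_profile(self._table(X, 12), [f"p{j}" for j in range(6)])
        s = res.scores["LV1"]
        ga = s[s.index.get_level_values("group") == "A"].mean()
        gb = s[s.index.get_level_values("group") == "B"].mean()
        assert ga * gb < 0

    def test_label_permutation_collapses_separation(self, rng):
        X = rng.normal(size=(24, 6))
        X[12:, 2] += 4.0
        cols = [f"p{j}" for j in range(6)]
        res = plsda_profile(self._table(X, 12), cols)
        s = res.scores["LV1"]
        g = np.asarray(s.index.get_level_values("group") == "A")
        sep_true = abs(s[g].mean() - s[~g].mean())
        seps = []
        for _ in range(30):
            Xp = X[rng.permutation(24)]
            rp = plsda_profile(self._table(Xp, 12), cols)
            sp = rp.scores["LV1"]
            gp = np.asarray(sp.index.get_level_values("group") == "A")
            seps.append(abs(sp[gp].mean() - sp[~gp].mean()))
        # PLS chases even permuted labels, but the real structure is
        # clearly stronger than the permutation distribution's mean
        assert np.mean(seps) < 0.75 * sep_true

    def test_null_labels_give_small_y_weights(self, rng):
        X = rng.normal(size=(30, 5))
        res = plsda_profile(self._table(X, 15), [f"p{j}" for j in range(5)])
        # with labels independent of the data the explained Y-covariance
        # on each component is weak: scores barely separate the groups
        s = res.scores["LV1"]
        g = np.asarray(s.index.get_level_values("group") == "A")
        assert abs(s[g].mean() - s[~g].mean()) < 2.0

    def test_single_group_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        idx = pd.MultiIndex.from_tuples(
            [(f"r{i}", "A", "1") for i in range(6)],
            names=["rat_id", "group", "trial"])
        tab = pd.DataFrame(X, index=idx, columns=["p0", "p1", "p2"])
        with pytest.raises(UsageError):
            plsda_profile(tab, ["p0", "p1", "p2"])
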