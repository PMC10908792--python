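"""Volcano, ANOVA/Tukey, PLS-DA, random forest and the Venn consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from breathomics.stats import (
    ConsensusThresholds,
    anova_tukey,
    benjamini_hochberg,
    consensus,
    fold_change,
    mtry_rule,
    plsda_fit,
    rf_classify,
    venn_partition,
    volcano,
)
from conftest import make_table


def _two_group_table(n_feat=20, n_per=10, seed=0, shift_features=(), shift=1.0):
    """Raw-intensity table with optional planted log10 shifts in group B."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(6.0, 8.0, size=n_feat)
    log_vals = base[:, None] + rng.normal(0, 0.1, size=(n_feat, 2 * n_per))
    for f in shift_features:
        log_vals[f, n_per:] += shift
    cols = [f"a{j}" for j in range(n_per)] + [f"b{j}" for j in range(n_per)]
    groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
    return make_table(10.0**log_vals, columns=cols), groups


class TestFoldChange:
    def test_identical_groups_unity(self):
        t, groups = _two_group_table(seed=1)
        t.values.iloc[:, 10:] = t.values.iloc[:, :10].to_numpy()
        fc = fold_change(t, groups, "B", "A")
        assert np.allclose(fc, 1.0)

    def test_doubled_group_gives_two(self):
        t, groups = _two_group_table(seed=2)
        t.values.iloc[:, 10:] = 2.0 * t.values.iloc[:, :10].to_numpy()
        fc = fold_change(t, groups, "B", "A")
        assert np.allclose(fc, 2.0)
        assert fc.name == "B/A"

    def test_orientation_inverts(self):
        t, groups = _two_group_table(seed=3)
        ab = fold_change(t, groups, "A", "B")
        ba = fold_change(t, groups, "B", "A")
        assert np.allclose(ab * ba, 1.0)


class TestBenjaminiHochberg:
    def test_worked_example(self):
        # p = (.01,.02,.03,.04), n=4: p_(i) * n/i = .04 for every rank
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_equals_stepup_definition_on_random_vectors(self):
        """BH equals the brute-force step-up formula."""
        rng = np.random.default_rng(4)
        for _ in range(60):
            p = rng.random(int(rng.integers(1, 400)))
            adj = benjamini_hochberg(p)
            n = p.size
            order = np.argsort(p)
            stepup = p[order] * n / np.arange(1, n + 1)
            stepup = np.minimum.accumulate(stepup[::-1])[::-1]
            expected = np.empty(n)
            expected[order] = np.minimum(stepup, 1.0)
            assert np.allclose(adj, expected)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(5)
        p = rng.random(200)
        assert (benjamini_hochberg(p) >= p - 1e-12).all()


class TestVolcano:
    def test_identical_groups_nothing_significant(self):
        t, groups = _two_group_table(seed=6)
        t.values.iloc[:, 10:] = t.values.iloc[:, :10].to_numpy() * (
            1 + 1e-6
        )  # epsilon apart, FC gate can never pass
        v = volcano(t, groups)
        assert v.significant == set()

    def test_planted_shift_detected(self):
        t, groups = _two_group_table(seed=7, shift_features=(0, 1, 2), shift=0.7)
        v = volcano(t, groups)
        assert {"f0", "f1", "f2"} <= v.significant
        assert len(v.significant) == 3

    def test_invariant_to_column_order_and_label_names(self):
        t, groups = _two_group_table(seed=8, shift_features=(3,), shift=0.8)
        v1 = volcano(t, groups)
        perm = list(np.random.default_rng(0).permutation(t.values.columns))
        t2 = t.subset_samples(perm)
        v2 = volcano(t2, groups)
        assert v1.significant == v2.significant
        relabeled = {c: ("G1" if g == "A" else "G2") for c, g in groups.items()}
        v3 = volcano(t, relabeled)
        assert v1.significant == v3.significant

    def test_group_too_small_errors(self):
        t, groups = _two_group_table(n_per=2)
        groups = dict(groups)
        bad = {c: g for c, g in groups.items() if not (g == "B" and c != "b0")}
        with pytest.raises(ValueError):
            volcano(t.subset_samples(list(bad)), bad)


class TestAnovaTukey:
    def test_equal_groups_empty(self):
        rng = np.random.default_rng(9)
        vals = np.tile(rng.uniform(1e6, 1e7, size=(10, 1)), (1, 9))
        cols = [f"s{j}" for j in range(9)]
        t = make_table(vals, columns=cols)
        groups = {c: f"G{j % 3}" for j, c in enumerate(cols)}
        res = anova_tukey(t, groups)
        assert not res["significant"].any()

    def test_two_groups_reduce_to_pooled_t_test(self):
        """With k=2 the studentized range collapses to the pooled t-test."""
        t, groups = _two_group_table(n_feat=10, seed=10, shift_features=(0,), shift=0.4)
        res = anova_tukey(t, groups)
        logged = np.log10(t.values.to_numpy())
        a = logged[:, :10]
        b = logged[:, 10:]
        _, p_pooled = sstats.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(res["p_tukey_min"], p_pooled, atol=1e-6)

    def test_planted_three_group_effect_found(self):
        rng = np.random.default_rng(11)
        log_vals = 7.0 + rng.normal(0, 0.1, size=(5, 15))
        log_vals[0, 10:] += 1.0  # third group elevated in feature 0
        cols = [f"s{j}" for j in range(15)]
        t = make_table(10.0**log_vals, columns=cols)
        groups = {c: f"G{j // 5}" for j, c in enumerate(cols)}
        res = anova_tukey(t, groups)
        assert res.loc["f0", "significant"]
        assert "G2" in res.loc["f0", "best_pair"]

    def test_singleton_group_errors(self):
        t, _ = _two_group_table(n_per=3)
        groups = {c: ("A" if j else "solo") for j, c in enumerate(t.values.columns)}
        with pytest.raises(ValueError):
            anova_tukey(t, groups)


class TestPlsda:
    def _blobs(self, n=40, p=30, sep=5.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        X[y == "B", :5] += sep
        return pd.DataFrame(X), list(y)

    def test_separable_blobs_high_r2y(self):
        X, y = self._blobs()
        m = plsda_fit(X, y, n_components=5, seed=0)
        assert m.r2y >= 0.9
        assert m.q2y >= 0.8

    def test_permuted_labels_low_q2y(self):
        X, y = self._blobs(sep=0.0, seed=1)
        rng = np.random.default_rng(2)
        q2s = [
            plsda_fit(X, list(rng.permutation(y)), n_components=3, seed=s).q2y
            for s in range(3)
        ]
        assert all(q <= 0.2 for q in q2s)

    def test_vip_identity(self):
        """Sum of squared VIP over features equals the feature count."""
        X, y = self._blobs(seed=3)
        m = plsda_fit(X, y, n_components=4, seed=0)
        assert np.sum(m.vip**2) == pytest.approx(X.shape[1], abs=1e-8)

    def test_r2y_monotone_in_components(self):
        X, y = self._blobs(sep=1.0, seed=4)
        m = plsda_fit(X, y, n_components=6, seed=0)
        assert np.all(np.diff(m.r2y_per_component) >= -1e-12)

    def test_too_many_components_rejected(self):
        X, y = self._blobs(n=8, p=3)
        with pytest.raises(ValueError):
            plsda_fit(X, y, n_components=10)

    def test_single_class_rejected(self):
        X, _ = self._blobs()
        with pytest.raises(ValueError):
            plsda_fit(X, ["A"] * len(X), n_components=2)


class TestMtryRule:
    @pytest.mark.parametrize("n,expected", [(2656, 52), (100, 10), (2, 1), (1, 1)])
    def test_values(self, n, expected):
        assert mtry_rule(n) == expected

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            mtry_rule(0)


class TestRandomForest:
    def _data(self, n=60, p=25, sep=3.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        X[y == "B", :4] += sep
        return pd.DataFrame(X, columns=[f"f{j}" for j in range(p)]), list(y)

    def test_separable_data_low_oob(self):
        X, y = self._data()
        res = rf_classify(X, y, n_trees=200, seed=0)
        assert res.oob_error <= 0.05
        assert res.n_predictors == mtry_rule(X.shape[1])

    def test_informative_features_top_importance(self):
        X, y = self._data(seed=1)
        res = rf_classify(X, y, n_trees=200, seed=0)
        top4 = set(res.importance.sort_values(ascending=False).index[:4])
        assert top4 == {"f0", "f1", "f2", "f3"}

    def test_permuted_labels_near_chance(self):
        X, y = self._data(sep=0.0, seed=2)
        res = rf_classify(X, y, n_trees=200, seed=0)
        assert abs(res.oob_error - 0.5) <= 0.15

    def test_seeded_determinism(self):
        X, y = self._data(seed=3)
        a = rf_classify(X, y, n_trees=50, seed=42)
        b = rf_classify(X, y, n_trees=50, seed=42)
        assert a.oob_error == b.oob_error
        assert np.array_equal(a.importance, b.importance)

    def test_confusion_rows_sum_to_class_sizes(self):
        X, y = self._data(seed=4)
        res = rf_classify(X, y, n_trees=300, seed=0)
        # with enough trees every sample gets OOB votes
        sizes = pd.Series(y).value_counts()
        assert (res.confusion.sum(axis=1) == sizes[res.class_labels]).all()

    def test_tree_cap_enforced(self):
        X, y = self._data(n=20, p=5)
        res = rf_classify(X, y, n_trees=2000, seed=0)
        assert res.n_trees == 1000 or res.n_trees <= 1000

    def test_single_class_rejected(self):
        X, _ = self._data(n=10)
        with pytest.raises(ValueError):
            rf_classify(X, ["A"] * len(X), n_trees=10)


class TestVenn:
    def test_worked_example(self):
        counts = venn_partition({1, 2, 3}, {2, 3, 4}, {3, 4, 5})
        assert counts == {
            "A_only": 1, "B_only": 0, "C_only": 1,
            "AB_only": 1, "AC_only": 0, "BC_only": 1, "ABC": 1,
        }

    def test_disjoint_sets(self):
        counts = venn_partition({1}, {2}, {3, 4})
        assert counts["ABC"] == 0
        assert counts["A_only"] == 1 and counts["C_only"] == 2

    def test_identical_sets_all_in_core(self):
        s = {1, 2, 3}
        counts = venn_partition(s, s, s)
        assert counts["ABC"] == 3
        assert sum(counts.values()) == 3

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = set(rng.integers(0, 30, size=10).tolist())
            b = set(rng.integers(0, 30, size=10).tolist())
            c = set(rng.integers(0, 30, size=10).tolist())
            counts = venn_partition(a, b, c)
            assert sum(counts.values()) == len(a | b | c)
            assert counts["AB_only"] + counts["ABC"] == len(a & b)
            assert counts["AC_only"] + counts["ABC"] == len(a & c)
            assert counts["BC_only"] + counts["ABC"] == len(b & c)


class TestConsensus:
    def test_infinite_thresholds_empty_everything(self):
        t, groups = _two_group_table(seed=14, shift_features=(0,), shift=1.0)
        th = ConsensusThresholds(vip=np.inf, mda=np.inf, alpha=0.0)
        res = consensus(t, groups, thresholds=th, n_trees=20, seed=0)
        assert all(len(s) == 0 for s in res.sets.values())
        assert all(v == 0 for v in res.venn.values())

    def test_strong_marker_lands_in_core(self):
        t, groups = _two_group_table(
            n_feat=30, n_per=15, seed=15, shift_features=(0, 1, 2, 3), shift=1.0
        )
        res = consensus(t, groups, n_trees=200, seed=0)
        assert res.venn["ABC"] >= 2
        assert set(res.consensus.index) <= {"f0", "f1", "f2", "f3"} | set(
            res.consensus.index
        )
        assert {"f0", "f1", "f2", "f3"} & set(res.consensus.index)
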