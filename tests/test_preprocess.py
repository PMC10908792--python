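"""Normalization, merging, replicate consensus and filtering rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from breathomics.peaks import PeakList
from breathomics.preprocess import (
    batch_correct,
    build_feature_table,
    deduplicate,
    impute_missing,
    log_pareto,
    median_normalize,
    merge_modes,
    merge_modes_bruteforce,
    pqn_normalize,
    prevalence_filter,
    qc_rsd_report,
    replicate_consensus,
)
from conftest import make_table


def _pl(sample, mzs, intens, subject=None, rep=1, qc=False):
    return PeakList(
        sample_id=sample, subject_id=subject or sample, replicate_index=rep,
        mode="positive", method="small", batch="B1",
        mz=np.asarray(mzs, dtype=float), intensity=np.asarray(intens, dtype=float),
        is_qc=qc,
    )


class TestBuildFeatureTable:
    def test_shared_mass_one_row_two_columns(self):
        a = _pl("S1", [150.0], [1e7], subject="S1")
        b = _pl("S2", [150.0 + 150e-7], [2e7], subject="S2")  # ~0.07 ppm apart
        t = build_feature_table([a, b])
        assert t.n_features == 1
        assert (t.values.iloc[0] > 0).all()

    def test_binning_resolution(self):
        # 0.5 ppm apart -> one bin; 3 ppm apart -> two bins
        close = build_feature_table(
            [_pl("S1", [200.0], [1e7]), _pl("S2", [200.0 * (1 + 0.5e-6)], [1e7], subject="S2")]
        )
        assert close.n_features == 1
        far = build_feature_table(
            [_pl("S1", [200.0], [1e7]), _pl("S2", [200.0 * (1 + 3e-6)], [1e7], subject="S2")]
        )
        assert far.n_features == 2

    def test_empty_acquisition_gives_zero_column(self):
        a = _pl("S1", [150.0], [1e7])
        empty = _pl("S2", [], [], subject="S2")
        t = build_feature_table([a, empty])
        assert (t.values["S2_r1"] == 0).all()

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError):
            build_feature_table([_pl("S1", [150.0], [1e7]), _pl("S1", [151.0], [1e7])])


class TestPqn:
    def test_exact_recovery_of_scalar_dilution(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(1e6, 1e8, size=12)
        t = make_table(np.column_stack([ref, 2.0 * ref]), columns=["A", "B"])
        out, rep = pqn_normalize(t, reference=ref)
        assert rep.sample_factors["B"] == pytest.approx(2.0, rel=1e-12)
        assert np.allclose(out.values["B"], out.values["A"])

    def test_all_equal_reference_all_factors_one(self):
        ref = np.linspace(1e6, 1e7, 15)
        t = make_table(np.column_stack([ref, ref, ref]), columns=list("ABC"))
        _, rep = pqn_normalize(t, reference=ref)
        assert all(f == pytest.approx(1.0) for f in rep.sample_factors.values())

    def test_qc_median_reference_default(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1e6, 1e8, size=20)
        vals = np.column_stack([base, base * 3.0, base, base])
        t = make_table(
            vals, columns=["QC1", "S1", "QC2", "QC3"],
            is_qc=[True, False, True, True],
        )
        out, rep = pqn_normalize(t)
        assert rep.sample_factors["S1"] == pytest.approx(3.0, rel=1e-9)

    def test_disjoint_sample_errors(self):
        ref = np.concatenate([np.ones(10), np.zeros(10)])
        v = np.concatenate([np.zeros(10), np.ones(10)])
        t = make_table(v.reshape(-1, 1), columns=["A"])
        with pytest.raises(ValueError):
            pqn_normalize(t, reference=ref)


class TestMedianNormalize:
    def test_two_samples_scaled_to_common_median(self):
        t = make_table(np.array([[10.0, 20.0], [10.0, 20.0], [10.0, 20.0]]))
        out = median_normalize(t)
        med = [np.median(out.values[c][out.values[c] > 0]) for c in out.values.columns]
        assert med[0] == pytest.approx(med[1])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        t = make_table(rng.uniform(1, 100, size=(8, 4)))
        once = median_normalize(t)
        twice = median_normalize(once)
        assert np.allclose(once.values, twice.values)

    def test_single_sample_unchanged(self):
        t = make_table(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(median_normalize(t).values, t.values)

    def test_all_zero_sample_errors(self):
        t = make_table(np.array([[1.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            median_normalize(t)


class TestBatchCorrect:
    def test_uniform_batch_shift_removed(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(1e6, 1e7, size=10)
        cols = ["QA", "A1", "A2", "QB", "B1", "B2"]
        vals = np.column_stack([base, base, base, 1.5 * base, 1.5 * base, 1.5 * base])
        t = make_table(
            vals, columns=cols,
            is_qc=[True, False, False, True, False, False],
            batches=["X", "X", "X", "Y", "Y", "Y"],
        )
        out, rep = batch_correct(t)
        assert rep.batch_factors["Y"] / rep.batch_factors["X"] == pytest.approx(1.5)
        assert np.allclose(out.values["B1"], out.values["A1"])

    def test_single_batch_identity_up_to_global_scale(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1e6, 1e7, size=(10, 3))
        t = make_table(vals, is_qc=[True, False, False])
        out, rep = batch_correct(t)
        assert len(rep.batch_factors) == 1
        ratio = out.values.to_numpy() / vals
        assert np.allclose(ratio, ratio.flat[0])

    def test_batch_without_qc_warns_and_falls_back(self):
        vals = np.abs(np.random.default_rng(5).normal(1e6, 1e5, size=(6, 4)))
        t = make_table(
            vals, is_qc=[True, False, False, False],
            batches=["X", "X", "Y", "Y"],
        )
        with pytest.warns(UserWarning):
            batch_correct(t)


class TestMergeModes:
    def _mode_pair(self, pos_vals, neg_vals, formulas):
        cols = [f"s{j}" for j in range(pos_vals.shape[1])]
        pos = make_table(pos_vals, formulas=formulas, columns=cols, mode="positive")
        neg = make_table(neg_vals, formulas=formulas, columns=cols, mode="negative")
        return pos, neg

    def test_higher_detection_count_wins(self):
        """Worked example: detected 91x positive vs 81x negative -> keep
        the positive-mode values."""
        rng = np.random.default_rng(6)
        n = 101
        pos_row = rng.uniform(1e6, 1e7, size=n)
        pos_row[91:] = 0.0  # 91 detections
        neg_row = rng.uniform(1e6, 1e7, size=n)
        neg_row[81:] = 0.0  # 81 detections
        pos, neg = self._mode_pair(
            pos_row.reshape(1, -1), neg_row.reshape(1, -1), ["C5H9NO2"]
        )
        merged = merge_modes(pos, neg)
        assert merged.n_features == 1
        assert merged.features.iloc[0]["mode"] == "positive"
        assert np.allclose(merged.values.iloc[0], pos_row)

    def test_tie_broken_by_total_intensity(self):
        pos_row = np.array([1e9, 1e8, 0.0, 0.0])
        neg_row = np.array([0.0, 0.0, 1e9, 1e9])  # same count, higher total
        pos, neg = self._mode_pair(
            pos_row.reshape(1, -1), neg_row.reshape(1, -1), ["C6H12O6"]
        )
        merged = merge_modes(pos, neg)
        assert merged.features.iloc[0]["mode"] == "negative"

    def test_single_mode_formula_passes_through(self):
        pos = make_table(np.array([[1e7, 1e7]]), formulas=["C5H9NO2"], mode="positive")
        neg = make_table(np.array([[2e7, 2e7]]), formulas=["C6H12O6"], mode="negative")
        merged = merge_modes(pos, neg)
        assert merged.n_features == 2
        assert set(merged.features["formula"]) == {"C5H9NO2", "C6H12O6"}

    def test_differing_sample_sets_rejected(self):
        pos = make_table(np.ones((1, 2)), columns=["a", "b"], mode="positive")
        neg = make_table(np.ones((1, 2)), columns=["a", "c"], mode="negative")
        with pytest.raises(ValueError):
            merge_modes(pos, neg)

    def test_matches_bruteforce_on_random_tables(self):
        """Optimized merge equals direct enumeration on random tables."""
        rng = np.random.default_rng(7)
        formulas_pool = ["C2H5NO2", "C3H6O3", "C4H6O4", "C5H9NO2", "C6H12O6", ""]
        for _ in range(300):
            nf, ns = rng.integers(1, 6), rng.integers(1, 5)
            cols = [f"s{j}" for j in range(ns)]
            fa = list(rng.choice(formulas_pool[:-1], size=nf, replace=False))
            fb = list(rng.choice(formulas_pool[:-1], size=nf, replace=False))
            va = rng.integers(0, 4, size=(nf, ns)) * rng.uniform(1e5, 1e6)
            vb = rng.integers(0, 4, size=(nf, ns)) * rng.uniform(1e5, 1e6)
            pos = make_table(va, formulas=fa, columns=cols, mode="positive")
            neg = make_table(vb, formulas=fb, columns=cols, mode="negative")
            fast = merge_modes(pos, neg)
            slow = merge_modes_bruteforce(pos, neg)
            fkey = lambda t: sorted(
                (t.features.loc[f, "formula"], t.features.loc[f, "mode"],
                 tuple(t.values.loc[f, cols]))
                for f in t.features.index
            )
            assert fkey(fast) == fkey(slow)


class TestDeduplicate:
    def test_highest_total_intensity_survives(self):
        t = make_table(
            np.array([[3e8, 2e8], [4e8, 3e8]]),  # totals 5e8 vs 7e8
            formulas=["C5H9NO2", "C5H9NO2"],
        )
        out = deduplicate(t)
        assert out.n_features == 1
        assert out.values.iloc[0].sum() == pytest.approx(7e8)

    def test_no_duplicates_identity(self):
        t = make_table(np.ones((3, 2)), formulas=["A" and "C2H5NO2", "C3H6O3", ""])
        assert deduplicate(t).n_features == 3

    def test_three_way_duplicate_single_survivor(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(1e6, 1e8, size=(3, 4))
        t = make_table(vals, formulas=["C6H12O6"] * 3)
        out = deduplicate(t)
        assert out.n_features == 1
        assert out.values.iloc[0].sum() == pytest.approx(vals.sum(axis=1).max())


class TestReplicateConsensus:
    def _triple(self, a, b, c):
        t = make_table(
            np.array([[a, b, c]], dtype=float),
            columns=["S1_r1", "S1_r2", "S1_r3"],
            subjects=["S1", "S1", "S1"],
            replicates=[1, 2, 3],
        )
        return replicate_consensus(t).values.iloc[0, 0]

    def test_two_of_three_mean_of_nonzero(self):
        assert self._triple(1e7, 1.2e7, 0.0) == pytest.approx(1.1e7)

    def test_single_detection_is_not_detected(self):
        assert self._triple(5e6, 0.0, 0.0) == 0.0

    def test_all_three_full_mean(self):
        assert self._triple(3.0, 6.0, 9.0) == pytest.approx(6.0)

    def test_biconditional_on_exhaustive_patterns(self):
        """Output nonzero <=> at least 2 of 3 replicates nonzero, for every
        detection pattern."""
        for pattern in itertools.product([0.0, 1e7], repeat=3):
            got = self._triple(*pattern)
            n_detected = sum(1 for x in pattern if x > 0)
            assert (got > 0) == (n_detected >= 2)
            if n_detected >= 2:
                assert got == pytest.approx(
                    np.mean([x for x in pattern if x > 0])
                )

    def test_subject_with_single_replicate_errors(self):
        t = make_table(np.ones((2, 1)), columns=["S1_r1"], subjects=["S1"])
        with pytest.raises(ValueError):
            replicate_consensus(t)

    def test_qc_columns_dropped(self):
        t = make_table(
            np.ones((1, 4)),
            columns=["S1_r1", "S1_r2", "S1_r3", "QC1"],
            subjects=["S1", "S1", "S1", "QC1"],
            is_qc=[False, False, False, True],
        )
        out = replicate_consensus(t)
        assert list(out.values.columns) == ["S1"]


class TestPrevalenceFilter:
    def test_absent_feature_removed(self):
        t = make_table(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert prevalence_filter(t, 0.05).n_features == 1

    def test_ceiling_boundary_at_15_percent_of_101(self):
        """With 101 subjects the 15% cut requires ceil(15.15) = 16."""
        n = 101
        row16 = np.zeros(n); row16[:16] = 1e7
        row15 = np.zeros(n); row15[:15] = 1e7
        t = make_table(np.vstack([row16, row15]))
        out = prevalence_filter(t, 0.15)
        assert list(out.values.index) == ["f0"]

    def test_zero_fraction_identity(self):
        t = make_table(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert prevalence_filter(t, 0.0).n_features == 2

    def test_monotone_nesting(self):
        rng = np.random.default_rng(9)
        t = make_table((rng.random((30, 20)) < 0.3) * 1e7)
        strict = set(prevalence_filter(t, 0.15).values.index)
        loose = set(prevalence_filter(t, 0.05).values.index)
        assert strict <= loose


class TestImputeAndScale:
    def test_fifth_of_lod(self):
        t = make_table(np.array([[0.0, 3e6]]))
        out = impute_missing(t)
        assert out.values.iloc[0, 0] == pytest.approx(200000.0)
        assert out.values.iloc[0, 1] == pytest.approx(3e6)

    def test_all_zero_row_becomes_constant(self):
        t = make_table(np.zeros((1, 3)))
        assert (impute_missing(t, lod=1e6, fraction=0.2).values == 2e5).all().all()

    def test_log_pareto_centres_features(self):
        rng = np.random.default_rng(10)
        t = make_table(rng.uniform(1e5, 1e8, size=(6, 9)))
        out = log_pareto(t)
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)

    def test_pareto_variance_equals_log_sd(self):
        """Var(scaled) = sd(logged): the defining identity of Pareto scaling."""
        rng = np.random.default_rng(11)
        t = make_table(rng.uniform(1e5, 1e8, size=(5, 12)))
        logged = np.log10(t.values.to_numpy())
        out = log_pareto(t)
        got = out.values.to_numpy().var(axis=1, ddof=1)
        want = logged.std(axis=1, ddof=1)
        assert np.allclose(got, want, rtol=1e-10)

    def test_constant_feature_stays_zero(self):
        t = make_table(np.full((1, 4), 5e6))
        assert (log_pareto(t).values == 0.0).all().all()

    def test_nonpositive_values_rejected(self):
        t = make_table(np.array([[0.0, 1.0]]))
        with pytest.raises(ValueError):
            log_pareto(t)


class TestQcRsd:
    def test_identical_qcs_zero_rsd(self):
        t = make_table(
            np.column_stack([np.ones(5) * 1e7] * 3 + [np.ones(5) * 2e7]),
            columns=["Q1", "Q2", "Q3", "S1"],
            is_qc=[True, True, True, False],
        )
        rep = qc_rsd_report(t)
        assert rep.qc_rsd["median"] == pytest.approx(0.0, abs=1e-12)

    def test_known_noise_level_recovered(self):
        rng = np.random.default_rng(12)
        sd = 0.10
        base = rng.uniform(1e6, 1e8, size=400)
        qcs = np.column_stack(
            [base * np.exp(rng.normal(0, sd, size=400)) for _ in range(8)]
        )
        t = make_table(
            qcs, columns=[f"Q{j}" for j in range(8)], is_qc=[True] * 8
        )
        rep = qc_rsd_report(t)
        assert rep.qc_rsd["median"] == pytest.approx(sd, rel=0.2)

    def test_single_qc_errors(self):
        t = make_table(np.ones((3, 2)), is_qc=[True, False])
        with pytest.raises(ValueError):
            qc_rsd_report(t)
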