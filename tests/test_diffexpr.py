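"""Differential-expression statistics: MBFC, variance filter, Welch t,
BH-FDR, the full table, and marker selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mirlink import SimulationConfig, simulate_expression
from mirlink.diffexpr import (
    bh_fdr,
    differential_table,
    median_fold_change,
    select_top_markers,
    variance_filter,
    welch_t_test,
)
from mirlink.io_annotation import ExpressionMatrix
from mirlink.preprocess import preprocess_pipeline


class TestMedianFoldChange:
    def test_hand_computed_ratio(self):
        assert median_fold_change([2, 4, 6], [1, 2, 3]) == pytest.approx(2.0)

    def test_identical_groups_give_one(self):
        assert median_fold_change([3, 5, 7], [3, 5, 7]) == pytest.approx(1.0)

    def test_down_threshold_classification(self):
        # a 0.35-fold feature sits well below the 0.8 down bound
        assert median_fold_change([0.35, 0.35, 0.35], [1, 1, 1]) < 0.8

    def test_insensitive_to_single_outlier(self):
        base = median_fold_change([2, 4, 6], [1, 2, 3])
        blown = median_fold_change([2, 4, 6e9], [1, 2, 3])
        assert blown == pytest.approx(base)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            median_fold_change([], [1.0])


class TestVarianceFilter:
    @staticmethod
    def _matrix_with_variances(variances):
        rows = []
        for v in variances:
            d = np.sqrt(v)
            rows.append([5.0 - d, 5.0, 5.0 + d])  # sample variance d^2 with n=3, ddof=1
        df = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                          columns=["s0", "s1", "s2"])
        return ExpressionMatrix(df, "linear")

    def test_first_quartile_cut(self):
        m = self._matrix_with_variances([0, 1, 2, 3])
        out = variance_filter(m)  # Q1 = 0.75 by linear interpolation; keep var > 0.75
        assert out.feature_ids == ["f1", "f2", "f3"]

    def test_constant_feature_dropped(self):
        m = self._matrix_with_variances([0, 2, 3, 4, 5])
        assert "f0" not in variance_filter(m).feature_ids

    def test_all_equal_variances_kept(self):
        m = self._matrix_with_variances([2, 2, 2, 2])
        assert variance_filter(m).feature_ids == m.feature_ids


class TestWelchT:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        t, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_group_swap_flips_sign_only(self):
        t1, p1 = welch_t_test([1, 2, 3], [4, 5, 7])
        t2, p2 = welch_t_test([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_scipy_on_random_cases(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            x = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(3, 20))
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(3, 20))
            t, p = welch_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.04, 0.03, 0.002]), [0.02, 0.04, 0.04, 0.008]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0] * 5), 1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, size=10_000) ** 2
        np.testing.assert_allclose(bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_family_size_override_matches_manual_step_up(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, size=50)
        m = 400
        order = np.argsort(p)
        expected = np.empty_like(p)
        running = 1.0
        for rank in range(len(p), 0, -1):  # step-up from the largest p
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        np.testing.assert_allclose(bh_fdr(p, m_total=m), expected, atol=1e-12)

    def test_monotone_under_single_p_increase(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, size=30)
        base = bh_fdr(p)
        bumped = p.copy()
        bumped[7] = min(1.0, bumped[7] + 0.3)
        assert (bh_fdr(bumped) >= base - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=60))
    def test_step_up_properties_on_arbitrary_vectors(self, p):
        from statsmodels.stats.multitest import multipletests

        adj = bh_fdr(p)
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0)).all()
        np.testing.assert_allclose(adj, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@pytest.fixture(scope="module")
def de_cohort():
    cfg = SimulationConfig(
        n_mirna=50, n_gene=625, group_sizes={"cPTC": 40, "fvPTC": 40},
        n_regulations=0, de_fraction=0.1, de_effect=2.0, seed=21,
    )
    mirna, mrna, annot, truth = simulate_expression(cfg)
    mrna_pp = preprocess_pipeline(mrna, annot)
    records = differential_table(mrna_pp, annot, "cPTC", "fvPTC")
    return truth, records


class TestDifferentialTable:

    def test_planted_features_recovered(self, de_cohort):
        truth, records = de_cohort
        planted = {f for f, _, _ in truth.de_features if f.startswith("GENE")}
        assert len(planted) == 50
        called = {r.feature_id for r in records if r.significant}
        assert len(planted & called) >= 45

    def test_null_positive_rate_controlled(self, de_cohort):
        truth, records = de_cohort
        planted = {f for f, _, _ in truth.de_features}
        nulls = [r for r in records if r.feature_id not in planted]
        fp = sum(1 for r in nulls if r.significant)
        assert fp / len(nulls) <= 0.05

    def test_planted_direction_reported(self, de_cohort):
        truth, records = de_cohort
        by_id = {r.feature_id: r for r in records}
        checked = 0
        for fid, _pair, direction in truth.de_features:
            r = by_id.get(fid)
            if r is not None and r.significant:
                assert r.direction == direction
                checked += 1
        assert checked >= 40

    def test_shuffled_labels_yield_few_calls(self):
        rng = np.random.default_rng(30)
        cfg = SimulationConfig(
            n_mirna=50, n_gene=400, group_sizes={"cPTC": 40, "fvPTC": 40},
            n_regulations=0, de_fraction=0.1, de_effect=2.0, seed=22,
        )
        mirna, mrna, annot, truth = simulate_expression(cfg)
        shuffled = annot.table.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        from mirlink.io_annotation import SampleAnnotation

        mrna_pp = preprocess_pipeline(mrna, SampleAnnotation(shuffled))
        records = differential_table(mrna_pp, SampleAnnotation(shuffled), "cPTC", "fvPTC")
        frac = sum(r.significant for r in records) / len(records)
        assert frac <= 0.05

    def test_sorted_by_fdr(self, de_cohort):
        _, records = de_cohort
        fdrs = [r.fdr for r in records]
        assert fdrs == sorted(fdrs)


class TestSelectTopMarkers:
    @staticmethod
    def _record(fid, fdr, mbfc=2.0, significant=True):
        from mirlink.diffexpr import DiffExprRecord

        return DiffExprRecord(fid, mbfc, 1.0, fdr / 2, fdr, significant,
                              "up" if mbfc >= 1 else "down")

    def test_k_lowest_fdr_among_significant(self):
        records = [self._record(f"f{i}", fdr=0.001 * (i + 1)) for i in range(10)]
        records += [self._record("ns", fdr=1e-9, significant=False)]
        assert select_top_markers(records, k=8) == [f"f{i}" for i in range(8)]

    def test_fewer_than_k_returns_all(self):
        records = [self._record(f"f{i}", fdr=0.01) for i in range(3)]
        assert sorted(select_top_markers(records, k=8)) == ["f0", "f1", "f2"]

    def test_fdr_ties_broken_by_effect_size(self):
        records = [
            self._record("weak", fdr=0.01, mbfc=1.5),
            self._record("strong", fdr=0.01, mbfc=8.0),
        ]
        assert select_top_markers(records, k=1) == ["strong"]
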