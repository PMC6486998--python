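import numpy as np
import pytest
from scipy import stats

import beadsig as bs
from beadsig.preprocess import BinarizationRule, BinaryReactivityMatrix, CenteredMatrix
from conftest import fisher_2x2_oracle


def _binary(values, ids=None):
    values = np.asarray(values, dtype=int)
    n, m = values.shape
    return BinaryReactivityMatrix(
        [f"s{i}" for i in range(n)], ids or [f"b{j}" for j in range(m)],
        values, BinarizationRule.SAB_FIXED, np.full(n, 1000.0))


class TestPerBeadFisher:
    def test_fully_separating_bead(self):
        # positive in all 10 ACR, none of 10 controls: p = 2 / C(20,10)
        values = np.r_[np.ones((10, 1)), np.zeros((10, 1))].astype(int)
        labels = [1] * 10 + [-1] * 10
        res = bs.per_bead_fisher(_binary(values), labels)[0]
        from math import comb
        assert res.p_raw == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_equal_proportions_give_p_one(self):
        values = np.array([[1], [0], [1], [0]])
        res = bs.per_bead_fisher(_binary(values), [1, 1, -1, -1])[0]
        assert res.p_raw == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 2, size=(14, 6))
        labels = np.array([1] * 8 + [-1] * 6)
        results = bs.per_bead_fisher(_binary(values), labels)
        for r in results:
            assert r.p_raw == pytest.approx(fisher_2x2_oracle(r.contingency), abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(9)
        values = rng.integers(0, 2, size=(12, 5))
        labels = np.array([1] * 5 + [-1] * 7)
        p1 = [r.p_raw for r in bs.per_bead_fisher(_binary(values), labels)]
        p2 = [r.p_raw for r in bs.per_bead_fisher(_binary(values), -labels)]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_bh_adjustment_properties(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 2, size=(20, 15))
        labels = np.array([1] * 11 + [-1] * 9)
        results = bs.per_bead_fisher(_binary(values), labels)
        raw = np.array([r.p_raw for r in results])
        adj = np.array([r.p_adjusted for r in results])
        assert np.all(adj >= raw - 1e-15)
        assert np.all(np.diff(adj[np.argsort(raw)]) >= -1e-12)  # order preserved

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bs.per_bead_fisher(_binary(np.ones((3, 2), dtype=int)), [1, 1, 1])


class TestFisherExactRxC:
    # expected values frozen from R's fisher.test (classic probability
    # ordering with 1e-7 relative tolerance)
    @pytest.mark.parametrize("table, expected", [
        ([[3, 20, 11], [7, 9, 2]], 0.0252701123),
        ([[11, 18, 5], [9, 8, 1]], 0.3460547466),
        ([[2, 1, 5, 2], [3, 4, 0, 2]], 0.0885275715),
        ([[5, 2], [1, 7]], 0.0405594406),
    ])
    def test_matches_r_convention(self, table, expected):
        assert bs.fisher_exact_rxc(table) == pytest.approx(expected, rel=1e-7)

    def test_2x2_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = rng.integers(0, 12, size=(2, 2))
            if t.sum() == 0:
                continue
            assert bs.fisher_exact_rxc(t) == pytest.approx(
                stats.fisher_exact(t)[1], rel=1e-9)

    def test_transpose_invariance(self):
        t = np.array([[3, 20, 11], [7, 9, 2]])
        assert bs.fisher_exact_rxc(t) == pytest.approx(bs.fisher_exact_rxc(t.T), rel=1e-9)


def _meta_from_table(table, variable):
    """Build metadata whose categorical counts reproduce an ACR/control table."""
    meta = []
    i = 0
    for label, row in zip((1, -1), table):
        for level, count in enumerate(row):
            for _ in range(count):
                meta.append(bs.SampleMetadata(f"s{i}", label, {variable: str(level)}))
                i += 1
    return meta


class TestCohortCompare:
    def test_hla_dr_mismatch_table(self):
        # ACR 3/20/11 vs control 7/9/2 across 0/1/2 mismatches
        meta = _meta_from_table([[3, 20, 11], [7, 9, 2]], "mm_hla_dr")
        out = bs.cohort_compare(meta, [("mm_hla_dr", "categorical", "fisher")])[0]
        assert round(out.p_value, 2) == 0.03

    def test_identical_groups_p_one(self):
        meta = _meta_from_table([[4, 5], [4, 5]], "grp")
        comp = bs.cohort_compare(meta, [("grp", "categorical", "fisher"),
                                        ("grp", "categorical", "chi2")])
        assert comp[0].p_value == pytest.approx(1.0)
        assert comp[1].p_value == pytest.approx(1.0)

    def test_mannwhitney_matches_exact_enumeration(self):
        from itertools import combinations
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        c = rng.normal(size=5)
        meta = [bs.SampleMetadata(f"a{i}", 1, {"v": float(x)}) for i, x in enumerate(a)]
        meta += [bs.SampleMetadata(f"c{i}", -1, {"v": float(x)}) for i, x in enumerate(c)]
        out = bs.cohort_compare(meta, [("v", "metric", "mannwhitney")])[0]
        # exact permutation null of the U statistic over all label assignments
        pooled = np.concatenate([a, c])
        ranks = stats.rankdata(pooled)
        n1 = len(a)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * len(c) / 2
        null = []
        for idx in combinations(range(len(pooled)), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            null.append(abs(u - mu) >= abs(u_obs - mu) - 1e-9)
        assert out.p_value == pytest.approx(np.mean(null), abs=1e-9)

    def test_unknown_variable_raises(self):
        meta = [bs.SampleMetadata("s1", 1, {"age": 50.0}),
                bs.SampleMetadata("s2", -1, {"age": 60.0})]
        with pytest.raises(KeyError):
            bs.cohort_compare(meta, [("bmi", "metric", "mannwhitney")])


class TestConfounderScan:
    def test_covariate_equal_to_bead_gives_r_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(15, 4))
        centered = CenteredMatrix([f"s{i}" for i in range(15)],
                                  [f"b{j}" for j in range(4)], vals)
        scan = bs.confounder_scan(centered, vals[:, 2])
        assert scan.per_bead_r[2] == pytest.approx(1.0)

    def test_constant_covariate_flagged(self):
        centered = CenteredMatrix(["s1", "s2", "s3"], ["b1"],
                                  np.array([[1.0], [2.0], [3.0]]))
        scan = bs.confounder_scan(centered, [5.0, 5.0, 5.0])
        assert scan.degenerate
        np.testing.assert_array_equal(scan.per_bead_r, [0.0])

    def test_independent_covariate_mean_near_zero(self):
        # white-noise covariate: mean Spearman r across beads stays near 0
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = rng.normal(size=(40, 50))
            centered = CenteredMatrix([f"s{i}" for i in range(40)],
                                      [f"b{j}" for j in range(50)], vals)
            means.append(bs.confounder_scan(centered, rng.normal(size=40)).mean_r)
        assert abs(np.mean(means)) < 0.1
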