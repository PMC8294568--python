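import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from mmpkit.mmp import (
    MmpMatrix,
    binarize_high_low,
    build_mmp_matrix,
    dendrogram_newick,
    fisher_exact_2x2,
    inverse_zscore,
    stability_contingency,
    stability_test,
    upgma_cluster,
    zscore_columns,
)


def matrix(values, index=None, zscored=False):
    df = pd.DataFrame(values, index=index)
    df.columns = [f"c{i}" for i in range(df.shape[1])]
    return MmpMatrix(values=df, zscored=zscored)


def brute_force_fisher(table):
    """Independent oracle: enumerate all 2x2 tables with the observed
    margins and sum hypergeometric probabilities <= the observed one."""
    t = np.asarray(table)
    M, n1, K = t.sum(), t[0].sum(), t[:, 0].sum()
    if M == 0:
        return 1.0  # degenerate margins: single admissible table
    rv = hypergeom(M, K, n1)
    support = np.arange(max(0, n1 + K - M), min(n1, K) + 1)
    pmf = rv.pmf(support)
    obs = rv.pmf(t[0, 0])
    return float(pmf[pmf <= obs * (1 + 1e-12)].sum())


class TestZscore:
    def test_two_point_column(self):
        z = zscore_columns(matrix([[1.0], [3.0]]))
        np.testing.assert_allclose(
            z.values["c0"], [-1 / np.sqrt(2), 1 / np.sqrt(2)]
        )

    def test_columns_have_zero_mean_unit_sd(self, cohort):
        from mmpkit.rates import rate_table

        z = zscore_columns(build_mmp_matrix(rate_table(cohort.series[1])))
        assert abs(z.values.mean()).max() < 1e-12
        assert abs(z.values.std(ddof=1) - 1).max() < 1e-12

    def test_constant_column_flagged_and_zeroed(self):
        z = zscore_columns(matrix([[2.0, 1.0], [2.0, 3.0]]))
        assert z.constant_columns == ["c0"]
        assert (z.values["c0"] == 0).all()

    def test_inverse_recovers_raw(self):
        raw = matrix([[1.0, 5.0], [3.0, 2.0], [4.0, 9.0]])
        back = inverse_zscore(zscore_columns(raw))
        pd.testing.assert_frame_equal(back.values, raw.values)

    def test_single_donor_rejected(self):
        with pytest.raises(ValueError, match=">= 2 donors"):
            zscore_columns(matrix([[1.0]]))

    def test_double_zscore_rejected(self):
        with pytest.raises(ValueError, match="already"):
            zscore_columns(zscore_columns(matrix([[1.0], [3.0]])))


class TestBinarize:
    def test_boundary_zero_is_high(self):
        z = matrix([[0.0], [-0.01]], zscored=True)
        calls = binarize_high_low(z)
        assert calls["c0"].tolist() == [True, False]

    def test_two_donor_column_splits_one_each(self):
        z = zscore_columns(matrix([[1.0], [3.0]]))
        calls = binarize_high_low(z)
        assert calls["c0"].sum() == 1

    def test_raw_matrix_rejected(self):
        with pytest.raises(ValueError, match="z-scored"):
            binarize_high_low(matrix([[1.0], [3.0]]))


class TestUpgma:
    def test_duplicate_pairs_merge_at_height_zero(self, examples):
        m = MmpMatrix(values=examples["two_block_mmp"], zscored=False)
        linkage, labels = upgma_cluster(m, k=2)
        assert np.allclose(sorted(linkage[:2, 2]), [0.0, 0.0])
        assert labels["A"] == labels["B"]
        assert labels["C"] == labels["D"]
        assert labels["A"] != labels["C"]

    def test_three_point_hand_oracle(self):
        # d(AB)=2, d(AC)=d(BC)=4: AB merges at 2, (AB)-C at mean(4,4)=4
        pts = pd.DataFrame(
            [[0.0, 0.0], [2.0, 0.0], [1.0, np.sqrt(15.0)]],
            index=["A", "B", "C"], columns=["x", "y"],
        )
        linkage, _ = upgma_cluster(MmpMatrix(values=pts), k=2)
        np.testing.assert_allclose(linkage[:, 2], [2.0, 4.0], atol=1e-12)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = matrix(rng.standard_normal((12, 6)))
            linkage, _ = upgma_cluster(m, k=2)
            assert (np.diff(linkage[:, 2]) >= -1e-12).all()

    def test_missing_values_rejected(self):
        m = matrix([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            upgma_cluster(m, k=2)

    def test_height_cut(self, examples):
        m = MmpMatrix(values=examples["two_block_mmp"])
        _, labels = upgma_cluster(m, k=None, height=1.0)
        assert labels.nunique() == 2

    def test_k_and_height_mutually_exclusive(self, examples):
        m = MmpMatrix(values=examples["two_block_mmp"])
        with pytest.raises(ValueError, match="exactly one"):
            upgma_cluster(m, k=2, height=1.0)

    def test_planted_types_recovered(self, cohort):
        from sklearn.metrics import rand_score

        from mmpkit.rates import rate_table

        z = zscore_columns(build_mmp_matrix(rate_table(cohort.series[1])))
        _, labels = upgma_cluster(z, k=2)
        truth = cohort.truth.type_labels.loc[labels.index]
        assert rand_score(truth, labels) >= 0.9

    def test_newick_export_contains_all_donors(self, examples):
        m = MmpMatrix(values=examples["two_block_mmp"])
        linkage, _ = upgma_cluster(m, k=2)
        nwk = dendrogram_newick(linkage, list(m.values.index))
        assert nwk.endswith(";")
        for donor in m.values.index:
            assert donor in nwk


class TestStability:
    def binary(self, arr, donors=None):
        df = pd.DataFrame(np.asarray(arr, dtype=bool))
        if donors:
            df.index = donors
        df.columns = [f"c{i}" for i in range(df.shape[1])]
        return df

    def test_identical_visits_are_fully_concordant(self):
        rng = np.random.default_rng(1)
        v = self.binary(rng.integers(0, 2, (8, 6)))
        ct = stability_contingency(v, v)
        assert ct.table[0, 1] == 0 and ct.table[1, 0] == 0
        assert ct.table.sum() == 48

    def test_inverted_visits_are_fully_discordant(self):
        rng = np.random.default_rng(2)
        v = self.binary(rng.integers(0, 2, (8, 6)))
        ct = stability_contingency(v, ~v)
        assert ct.table[0, 0] == 0 and ct.table[1, 1] == 0

    def test_donor_mismatch_rejected(self):
        a = self.binary([[1, 0]], donors=["X"])
        b = self.binary([[1, 0]], donors=["Y"])
        with pytest.raises(ValueError, match="donor"):
            stability_contingency(a, b)

    def test_planted_concordance_recovered(self):
        # 200 donors, persistence rho: diagonal fraction ~ concordance
        rng = np.random.default_rng(3)
        rho = 0.8
        v1 = rng.integers(0, 2, (200, 6)).astype(bool)
        flip = rng.random((200, 6)) > rho
        v2 = v1 ^ flip
        ct = stability_contingency(self.binary(v1), self.binary(v2))
        concordant = (ct.table[0, 0] + ct.table[1, 1]) / ct.table.sum()
        assert concordant == pytest.approx(rho, abs=0.05)

    def test_persistent_visits_give_significant_stability(self, cohort):
        from mmpkit.rates import rate_table

        z1 = zscore_columns(build_mmp_matrix(rate_table(cohort.series[1])))
        z2 = zscore_columns(build_mmp_matrix(rate_table(cohort.series[2])))
        _, p = stability_test(binarize_high_low(z1), binarize_high_low(z2))
        assert p < 0.05

    def test_independent_visits_give_null_p_distribution(self):
        # size control and approximate uniformity; mid-p transform used for
        # the KS check because exact-test p-values are discrete and
        # conservative
        rng = np.random.default_rng(7)
        ps, mid_ps = [], []
        for _ in range(200):
            a = self.binary(rng.standard_normal((40, 6)) >= 0)
            b = self.binary(rng.standard_normal((40, 6)) >= 0)
            ct = stability_contingency(a, b)
            ps.append(fisher_exact_2x2(ct.table))
            t = ct.table
            rv = hypergeom(t.sum(), t[:, 0].sum(), t[0].sum())
            mid_ps.append(ps[-1] - 0.5 * rv.pmf(t[0, 0]))
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.10
        assert 0.35 <= ps.mean() <= 0.65
        assert kstest(mid_ps, "uniform").pvalue > 0.001


class TestFisherExact:
    def test_balanced_table_p_is_one(self):
        assert fisher_exact_2x2([[2, 2], [2, 2]]) == pytest.approx(1.0)

    def test_enumeration_value(self):
        # margins (4,4,4,4): 5 candidate tables, hand enumeration gives
        # p = (16 + 16 + 1 + 1) / 70 = 0.485714...
        assert fisher_exact_2x2([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_symmetry_under_transpose_and_swaps(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            t = rng.integers(0, 12, (2, 2))
            p = fisher_exact_2x2(t)
            assert fisher_exact_2x2(t.T) == pytest.approx(p)
            assert fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p)

    def test_matches_brute_force_enumeration_small_totals(self):
        # exhaustive over a representative band; the full <=40 sweep runs in
        # the acceptance suite
        for total in (1, 5, 12, 17):
            for a in range(total + 1):
                for b in range(total + 1 - a):
                    for c in range(total + 1 - a - b):
                        d = total - a - b - c
                        t = [[a, b], [c, d]]
                        assert fisher_exact_2x2(t) == pytest.approx(
                            brute_force_fisher(t), abs=1e-10
                        )
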