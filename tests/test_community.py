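import numpy as np
import pandas as pd
import pytest

from mmpkit.community import (
    RelAbundanceTable,
    collapse_taxonomy,
    filter_low_depth,
    jensen_shannon_distance,
    rarefy,
    relative_abundance,
    shannon_diversity,
    train_high_low_classifier,
)
from mmpkit.data_io import OtuTable


def otu_table(counts, taxonomy=None):
    counts = np.asarray(counts)
    return OtuTable(
        sample_ids=[f"S{i}" for i in range(counts.shape[0])],
        otu_ids=[f"O{j}" for j in range(counts.shape[1])],
        counts=counts,
        taxonomy=taxonomy,
    )


class TestFilterLowDepth:
    def test_strict_boundary(self):
        t = otu_table([[4999], [5000], [12000]])
        kept, dropped = filter_low_depth(t, 5000)
        assert dropped == ["S0"]
        assert kept.sample_ids == ["S1", "S2"]

    def test_zero_threshold_is_identity(self):
        t = otu_table([[3, 4], [0, 1]])
        kept, dropped = filter_low_depth(t, 0)
        assert dropped == []
        assert np.array_equal(kept.counts, t.counts)

    def test_all_dropped_rejected(self):
        with pytest.raises(ValueError, match="all"):
            filter_low_depth(otu_table([[1], [2]]), 10)

    def test_planted_shallow_fraction_recovered(self):
        from mmpkit.simulate import CohortConfig, OtuSpec, generate_cohort

        cohort = generate_cohort(
            CohortConfig(seed=4, n_donors=40,
                         otu_spec=OtuSpec(shallow_fraction=0.05))
        )
        t = OtuTable(
            sample_ids=list(cohort.otu_counts.index),
            otu_ids=list(cohort.otu_counts.columns),
            counts=cohort.otu_counts.to_numpy(),
        )
        _, dropped = filter_low_depth(t, 5000)
        assert sorted(dropped) == cohort.truth.shallow_samples
        assert len(dropped) == pytest.approx(0.05 * 40, abs=1)


class TestRarefy:
    def test_sample_at_target_depth_unchanged(self):
        t = otu_table([[2, 3, 5], [10, 10, 0]])
        out = rarefy(t, depth=10, seed=0)
        assert np.array_equal(out.counts[0], [2, 3, 5])

    def test_all_samples_at_common_depth(self):
        rng = np.random.default_rng(8)
        t = otu_table(rng.integers(0, 50, (5, 12)))
        out = rarefy(t, seed=1)
        assert (out.depths == t.depths.min()).all()

    def test_depth_above_sample_rejected(self):
        with pytest.raises(ValueError, match="below target"):
            rarefy(otu_table([[1, 1], [50, 50]]), depth=10)

    def test_deterministic_per_seed(self):
        t = otu_table([[30, 20, 50], [10, 60, 30]])
        a = rarefy(t, depth=40, seed=7)
        b = rarefy(t, depth=40, seed=7)
        assert np.array_equal(a.counts, b.counts)

    def test_hypergeometric_expectation(self):
        # E[count_i] = depth * c_i / C
        counts = np.array([[40, 30, 20, 10]])
        depth = 50
        means = np.zeros(4)
        n_seeds = 1000
        for seed in range(n_seeds):
            means += rarefy(otu_table(counts), depth=depth, seed=seed).counts[0]
        means /= n_seeds
        expected = depth * counts[0] / counts.sum()
        # hypergeometric variance, se of the Monte-Carlo mean
        N, n = counts.sum(), depth
        var = n * (counts[0] / N) * (1 - counts[0] / N) * (N - n) / (N - 1)
        se = np.sqrt(var / n_seeds)
        assert (np.abs(means - expected) < 2.5 * se + 1e-9).all()


class TestRelativeAbundance:
    def test_simple_normalization(self):
        rel = relative_abundance(otu_table([[2, 3, 5]]))
        np.testing.assert_allclose(rel.values.iloc[0], [0.2, 0.3, 0.5])

    def test_single_otu_sample(self):
        rel = relative_abundance(otu_table([[7]]))
        assert rel.values.iloc[0, 0] == 1.0

    def test_scale_invariance(self):
        a = relative_abundance(otu_table([[2, 3, 5]]))
        b = relative_abundance(otu_table([[20, 30, 50]]))
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="zero-depth"):
            relative_abundance(otu_table([[0, 0]]))


class TestCollapseTaxonomy:
    def rel(self):
        tax = {
            "O0": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia;sp",
            "O1": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Roseburia;sp",
            "O2": "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;unassigned;unassigned",
            "O3": "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella;copri",
        }
        table = RelAbundanceTable(
            pd.DataFrame([[0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.25, 0.25]],
                         columns=list(tax), index=["S1", "S2"])
        )
        return table, tax

    def test_family_collapse_sums_members(self):
        table, tax = self.rel()
        fam = collapse_taxonomy(table, tax, "family")
        lachno = [c for c in fam.values.columns if c.endswith("Lachnospiraceae")]
        assert len(lachno) == 1
        assert fam.values.loc["S1", lachno[0]] == pytest.approx(0.6)

    def test_row_sums_preserved(self):
        table, tax = self.rel()
        for rank in ("phylum", "family", "genus"):
            out = collapse_taxonomy(table, tax, rank)
            np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_unassigned_genus_kept_distinct_from_assigned(self):
        # an unassigned-genus Lachnospiraceae OTU must not merge into
        # Blautia or Roseburia at the genus rank
        table, tax = self.rel()
        gen = collapse_taxonomy(table, tax, "genus")
        unassigned = [c for c in gen.values.columns
                      if c.endswith("unassigned") and "Lachnospiraceae" in c]
        assert len(unassigned) == 1
        assert gen.values.loc["S1", unassigned[0]] == pytest.approx(0.3)
        assert any(c.endswith("Blautia") for c in gen.values.columns)

    def test_unknown_rank_rejected(self):
        table, tax = self.rel()
        with pytest.raises(ValueError, match="unknown rank"):
            collapse_taxonomy(table, tax, "tribe")


class TestDiversity:
    def test_uniform_maximizes_shannon(self):
        assert shannon_diversity([0.25] * 4) == pytest.approx(np.log(4))

    def test_single_taxon_is_zero(self):
        assert shannon_diversity([1.0, 0.0, 0.0]) == 0.0

    def test_zero_features_do_not_contribute(self):
        assert shannon_diversity([0.5, 0.5, 0.0, 0.0]) == pytest.approx(
            shannon_diversity([0.5, 0.5])
        )

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            shannon_diversity([1.5, -0.5])

    def test_jsd_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_distance(p, p) == 0.0

    def test_jsd_disjoint_supports_is_one(self):
        assert jensen_shannon_distance(
            [1.0, 0.0], [0.0, 1.0]
        ) == pytest.approx(1.0)

    def test_jsd_symmetric(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            assert jensen_shannon_distance(p, q) == pytest.approx(
                jensen_shannon_distance(q, p)
            )

    def test_jsd_triangle_inequality(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            p, q, r = rng.dirichlet(np.ones(5), 3)
            assert jensen_shannon_distance(p, r) <= (
                jensen_shannon_distance(p, q)
                + jensen_shannon_distance(q, r)
                + 1e-12
            )

    def test_jsd_mismatched_features_rejected(self):
        with pytest.raises(ValueError, match="feature"):
            jensen_shannon_distance([0.5, 0.5], [0.2, 0.3, 0.5])


class TestClassifier:
    def test_perfectly_separating_feature_gives_auc_one(self):
        X = pd.DataFrame({"f": [0.0] * 10 + [1.0] * 10})
        X["g"] = 1 - X["f"]
        rel = RelAbundanceTable(X)
        y = pd.Series([False] * 10 + [True] * 10, index=X.index)
        report = train_high_low_classifier(rel, y, seed=0, n_estimators=50)
        assert report.mean_auc == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(0)
        X = rng.dirichlet(np.ones(30), 200)
        rel = RelAbundanceTable(
            pd.DataFrame(X, index=[f"S{i}" for i in range(200)])
        )
        y = pd.Series(rng.permutation([True] * 100 + [False] * 100),
                      index=rel.values.index)
        report = train_high_low_classifier(rel, y, seed=1, n_estimators=200)
        assert 0.4 <= report.mean_auc <= 0.6

    def test_single_class_rejected(self):
        X = RelAbundanceTable(pd.DataFrame({"f": [1.0] * 4}))
        y = pd.Series([True] * 4, index=X.values.index)
        with pytest.raises(ValueError, match="single class"):
            train_high_low_classifier(X, y)

    def test_importances_normalized(self, cohort):
        from mmpkit.mmp import binarize_high_low, build_mmp_matrix, zscore_columns
        from mmpkit.rates import rate_table

        z = zscore_columns(build_mmp_matrix(rate_table(cohort.series[1])))
        labels = binarize_high_low(z)["inulin:propionate"]
        t = OtuTable(
            sample_ids=list(cohort.otu_counts.index),
            otu_ids=list(cohort.otu_counts.columns),
            counts=cohort.otu_counts.to_numpy(),
        )
        report = train_high_low_classifier(
            relative_abundance(t), labels, seed=0, n_estimators=100
        )
        assert (report.importances >= 0).all()
        assert report.importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(10), 30)
        rel = RelAbundanceTable(pd.DataFrame(X))
        y = pd.Series(rng.integers(0, 2, 30).astype(bool), index=rel.values.index)
        a = train_high_low_classifier(rel, y, seed=5, n_estimators=50)
        b = train_high_low_classifier(rel, y, seed=5, n_estimators=50)
        assert a.fold_aucs == b.fold_aucs
        np.testing.assert_array_equal(a.mean_tpr, b.mean_tpr)
        pd.testing.assert_series_equal(a.importances, b.importances)
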