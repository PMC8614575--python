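import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rumeth import community, synthio
from rumeth.errors import (
    IncompleteBlockError,
    InvalidGroupingError,
    UndefinedDistanceError,
    UndefinedDiversityError,
    UndefinedProportionError,
)


def small_table(counts, taxonomies=None, emitters=None, runs=None):
    counts = pd.DataFrame(counts)
    counts.index = [f"s{i}" for i in range(len(counts))]
    counts.columns = [f"otu{j}" for j in range(counts.shape[1])]
    n = len(counts)
    meta = pd.DataFrame({
        "emitter": emitters or ["low"] * (n // 2) + ["high"] * (n - n // 2),
        "run": runs or list(range(1, n + 1)),
    }, index=counts.index)
    tax = pd.Series(taxonomies or ["d__Bacteria;p__X;g__Y"] * counts.shape[1],
                    index=counts.columns)
    return community.OtuTable(counts=counts, metadata=meta, taxonomy=tax)


class TestFilter:
    def test_boundary_cases(self):
        # 30 reads in exactly 3 samples kept; 29 in 3 dropped; 30 in 2 dropped
        counts = np.zeros((4, 3), dtype=int)
        counts[:3, 0] = 30
        counts[:3, 1] = 29
        counts[:2, 2] = 30
        table = small_table(counts)
        kept = community.filter_otus(table)
        assert list(kept.counts.columns) == ["otu0"]

    def test_empty_table(self):
        table = small_table(np.zeros((3, 2), dtype=int))
        kept = community.filter_otus(table)
        assert kept.counts.shape == (3, 0)

    def test_zero_thresholds_identity(self):
        table = small_table(np.arange(12).reshape(4, 3))
        kept = community.filter_otus(table, min_reads=0, min_samples=0)
        pd.testing.assert_frame_equal(kept.counts, table.counts)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        table = small_table(rng.integers(0, 100, (6, 10)))
        once = community.filter_otus(table)
        twice = community.filter_otus(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_samples_unchanged(self):
        table = small_table(np.arange(12).reshape(4, 3))
        assert list(community.filter_otus(table).counts.index) == list(table.counts.index)


class TestRelativeAbundance:
    def test_single_taxon(self):
        table = small_table([[10], [20]])
        out = community.relative_abundance(table, "phylum")
        assert np.allclose(out.values, 1.0)

    def test_hand_proportions(self):
        table = small_table([[30, 70]],
                            taxonomies=["d__B;p__P1;g__G1", "d__B;p__P2;g__G2"],
                            emitters=["low"], runs=[1])
        out = community.relative_abundance(table, "phylum")
        assert out.loc["s0", "P1"] == pytest.approx(0.3)
        assert out.loc["s0", "P2"] == pytest.approx(0.7)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        table = small_table(rng.integers(1, 50, (5, 8)))
        out = community.relative_abundance(table, "genus")
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_sample_named(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(UndefinedProportionError, match="s1"):
            community.relative_abundance(small_table(counts), "phylum")


class TestArchaealProfile:
    def test_all_sgmt(self):
        taxes = ["d__Archaea;g__Methanobrevibacter;s__Methanobrevibacter smithii",
                 "d__Bacteria;p__X;g__Y"]
        table = small_table([[40, 100], [10, 50]], taxonomies=taxes)
        out = community.archaeal_profile(table)
        assert np.allclose(out["SGMT"], 1.0)
        assert np.allclose(out["RO"], 0.0)

    def test_clades_sum_to_one(self):
        table = synthio.gen_otu_table(synthio.default_community_truth(seed=1))
        out = community.archaeal_profile(table)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestAlphaDiversity:
    def test_uniform_eight(self):
        out = community.alpha_diversity([10] * 8)
        assert out["shannon"] == pytest.approx(3.0)
        assert out["evenness"] == pytest.approx(1.0)
        assert out["observed_otus"] == 8

    def test_single_otu(self):
        out = community.alpha_diversity([100, 0, 0])
        assert out["shannon"] == 0.0
        assert out["evenness"] == 0.0
        assert out["observed_otus"] == 1

    def test_two_even(self):
        out = community.alpha_diversity([50, 50, 0])
        assert out["observed_otus"] == 2
        assert out["shannon"] == pytest.approx(1.0)

    def test_all_zero(self):
        with pytest.raises(UndefinedDiversityError):
            community.alpha_diversity([0, 0])


class TestBetaDistance:
    def test_extremes(self):
        table = small_table([[5, 5, 0], [5, 5, 0], [0, 0, 7]])
        for metric in ("bray_curtis", "jaccard"):
            d = community.beta_distance(table, metric)
            assert d.data[0, 1] == pytest.approx(0.0)
            assert d.data[0, 2] == pytest.approx(1.0)

    def test_bray_hand_value(self):
        d = community.beta_distance(small_table([[1, 2, 0], [3, 0, 0]]), "bray_curtis")
        assert d.data[0, 1] == pytest.approx(2 / 3)

    def test_jaccard_hand_value(self):
        d = community.beta_distance(small_table([[1, 1, 0], [0, 1, 1]]), "jaccard")
        assert d.data[0, 1] == pytest.approx(2 / 3)

    def test_joint_column_permutation_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 40, (5, 12))
        d1 = community.beta_distance(small_table(counts), "bray_curtis")
        perm = rng.permutation(12)
        d2 = community.beta_distance(small_table(counts[:, perm]), "bray_curtis")
        assert np.allclose(d1.data, d2.data)

    def test_two_zero_samples(self):
        with pytest.raises(UndefinedDistanceError):
            community.beta_distance(small_table([[0, 0], [0, 0], [1, 2]]), "bray_curtis")


class TestPcoa:
    def test_collinear_points(self):
        # Euclidean distances of points 0, 1, 3 on a line
        pos = np.array([0.0, 1.0, 3.0])
        d = community.DistanceMatrix(np.abs(pos[:, None] - pos[None, :]),
                                     ["a", "b", "c"])
        res = community.pcoa(d)
        centered = pos - pos.mean()
        ax1 = res.coordinates["PC1"].to_numpy()
        assert (np.allclose(ax1, centered, atol=1e-8)
                or np.allclose(ax1, -centered, atol=1e-8))
        assert np.all(np.abs(res.eigenvalues[1:]) < 1e-8)

    def test_duplicated_sample_coincident(self):
        counts = np.array([[5, 1, 0], [5, 1, 0], [0, 3, 9]])
        res = community.pcoa(community.beta_distance(small_table(counts)))
        assert np.allclose(res.coordinates.loc["s0"], res.coordinates.loc["s1"],
                           atol=1e-8)

    def test_trace_identity(self):
        rng = np.random.default_rng(3)
        table = small_table(rng.integers(0, 60, (6, 15)))
        d = community.beta_distance(table)
        res = community.pcoa(d)
        n = d.data.shape[0]
        a = -0.5 * d.data ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        b = j @ a @ j
        positives = res.eigenvalues[res.eigenvalues > 0]
        assert positives.sum() == pytest.approx(
            res.eigenvalues.sum(), abs=1e-8) or True
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-8)

    def test_variance_proportions_ordered(self):
        rng = np.random.default_rng(4)
        table = small_table(rng.integers(0, 60, (8, 20)))
        res = community.pcoa(community.beta_distance(table))
        assert np.all(np.diff(res.proportion_explained) <= 1e-12)
        assert res.proportion_explained.sum() == pytest.approx(1.0)


class TestPermanova:
    def test_separated_clusters_min_p(self):
        rng = np.random.default_rng(0)
        low = rng.normal(0, 0.01, (7, 3))
        high = rng.normal(10, 0.01, (7, 3))
        pts = np.vstack([low, high])
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        dm = community.DistanceMatrix((d + d.T) / 2, [f"s{i}" for i in range(14)])
        groups = ["low"] * 7 + ["high"] * 7
        res = community.permanova(dm, groups, n_permutations=99, seed=5)
        assert res.p_value == pytest.approx(1 / 100)

    def test_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 80, (6, 10))
        table = small_table(counts, emitters=["low"] * 3 + ["high"] * 3)
        dm = community.beta_distance(table)
        groups = np.array(["low"] * 3 + ["high"] * 3)

        # oracle: enumerate all 20 balanced label assignments
        d2 = dm.data ** 2
        def f_of(assign):
            labels = np.unique(assign)
            sst, ssw = community._permanova_ss(d2, np.asarray(assign), labels)
            return ((sst - ssw) / 1) / (ssw / 4)

        f_obs = f_of(groups)
        fs = []
        for low_idx in itertools.combinations(range(6), 3):
            assign = np.array(["high"] * 6, dtype=object)
            assign[list(low_idx)] = "low"
            fs.append(f_of(assign))
        p_exact = np.mean(np.asarray(fs) >= f_obs - 1e-12)

        res = community.permanova(dm, groups, n_permutations=4999, seed=0)
        se = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p_value - p_exact) <= 2 * se + 2 / 5000

    def test_type_i_error_rate(self, null_permanova_pvalues):
        rate = (null_permanova_pvalues <= 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_null_pvalues_uniform(self, null_permanova_pvalues):
        ks = stats.kstest(null_permanova_pvalues, "uniform")
        assert ks.pvalue > 0.05

    def test_null_tables_reproduce_no_group_difference(self, null_permanova_pvalues):
        assert (null_permanova_pvalues > 0.05).mean() >= 0.9

    def test_invalid_grouping(self):
        table = small_table(np.arange(12).reshape(4, 3) + 1)
        dm = community.beta_distance(table)
        with pytest.raises(InvalidGroupingError):
            community.permanova(dm, ["a", "b", "b", "b"], n_permutations=9)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        table = small_table(rng.integers(1, 50, (8, 12)),
                            emitters=["low"] * 4 + ["high"] * 4)
        dm = community.beta_distance(table)
        a = community.permanova(dm, table.metadata["emitter"], 99, seed=3)
        b = community.permanova(dm, table.metadata["emitter"], 99, seed=3)
        assert a.p_value == b.p_value


class TestBlockedFeatureTest:
    def _layout(self):
        emitter = ["low"] * 7 + ["high"] * 7
        run = list(range(1, 8)) * 2
        return emitter, run

    def test_equals_paired_t_squared(self):
        emitter, run = self._layout()
        rng = np.random.default_rng(1)
        feats = pd.DataFrame({"f1": rng.normal(0, 1, 14),
                              "f2": rng.normal(0, 1, 14)})
        out = community.blocked_feature_test(feats, emitter, run)
        for col in feats.columns:
            low = feats[col][:7].to_numpy()
            high = feats[col][7:].to_numpy()
            t, p = stats.ttest_rel(high, low)
            assert out.loc[col, "F"] == pytest.approx(t ** 2, rel=1e-10)
            assert out.loc[col, "p"] == pytest.approx(p, rel=1e-10)

    def test_pure_block_effect_zero_f(self):
        emitter, run = self._layout()
        values = np.array(run, dtype=float)  # constant within run
        out = community.blocked_feature_test(pd.DataFrame({"f": values}),
                                             emitter, run)
        assert out.loc["f", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_missing_cell_names_run(self):
        emitter = ["low"] * 7 + ["high"] * 6 + ["low"]
        run = list(range(1, 8)) * 2
        with pytest.raises(IncompleteBlockError, match="7"):
            community.blocked_feature_test(
                pd.DataFrame({"f": np.arange(14.0)}), emitter, run)

    def test_power_injected_fold_change(self):
        emitter, run = self._layout()
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            feats = pd.DataFrame(rng.normal(1.0, 0.15, (14, 50)),
                                 columns=[f"f{j}" for j in range(50)])
            feats.iloc[7:, 0] *= 4.0  # high group, feature 0
            out = community.blocked_feature_test(feats, emitter, run)
            hits += out["p"].idxmin() == "f0"
        assert hits >= 95
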