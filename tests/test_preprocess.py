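"""CPM normalization, expression filtering, differential expression, BH
adjustment and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import ppbc


def _counts(values, samples=None):
    arr = np.atleast_2d(np.asarray(values))
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples)


def _groups(labels, samples=None):
    samples = samples or [f"s{j}" for j in range(len(labels))]
    return pd.Series(labels, index=samples)


class TestCpm:
    def test_hand_values(self):
        counts = _counts([[3], [1]])
        cpm = ppbc.compute_cpm(counts)
        assert np.allclose(cpm["s0"], [750000, 250000])

    def test_columns_sum_to_a_million(self, small_cohort):
        cpm = ppbc.compute_cpm(small_cohort.counts)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_library_names_sample(self):
        counts = _counts([[3, 0], [1, 0]])
        with pytest.raises(ValueError, match="s1"):
            ppbc.compute_cpm(counts)


class TestFilter:
    def test_group_rule(self):
        # gene passes in 3 of A but only 2 of B -> dropped; all-zero dropped;
        # ubiquitous gene kept
        counts = pd.DataFrame(
            {
                "a1": [10, 0, 5], "a2": [10, 0, 5], "a3": [10, 0, 5],
                "b1": [10, 0, 5], "b2": [10, 0, 5], "b3": [0, 0, 5],
            },
            index=["borderline", "allzero", "ubiquitous"],
        )
        groups = _groups(["A"] * 3 + ["B"] * 3, list(counts.columns))
        kept = ppbc.filter_expressed(counts, groups, cpm_threshold=0.05)
        assert list(kept.index) == ["ubiquitous"]

    def test_monotone_in_threshold(self, small_cohort):
        loose = ppbc.filter_expressed(small_cohort.counts, small_cohort.meta, cpm_threshold=0.05)
        tight = ppbc.filter_expressed(small_cohort.counts, small_cohort.meta, cpm_threshold=5.0)
        assert set(tight.index) <= set(loose.index)

    def test_small_group_rejected(self):
        counts = _counts([[1, 1, 1, 1]])
        groups = _groups(["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer than"):
            ppbc.filter_expressed(counts, groups)


class TestDeTest:
    @staticmethod
    def _two_level_counts():
        """Group means exactly 10 vs 100 CPM for the focal gene."""
        n = 4
        focal_a, focal_b = 10, 100
        cols = {}
        for j in range(n):
            cols[f"a{j}"] = [focal_a, 10**6 - focal_a]
            cols[f"b{j}"] = [focal_b, 10**6 - focal_b]
        counts = pd.DataFrame(cols, index=["focal", "filler"])
        groups = pd.Series(
            ["A" if c.startswith("a") else "B" for c in counts.columns],
            index=counts.columns,
        )
        return counts, groups

    def test_log2fc_of_pseudocounted_means(self):
        counts, groups = self._two_level_counts()
        de = ppbc.de_test(counts, groups, contrast=("B", "A"))
        assert de.loc["focal", "log2fc"] == pytest.approx(np.log2(101 / 11), abs=1e-9)

    def test_identical_groups_are_null(self):
        base = np.array([[5, 9, 13, 2], [50, 40, 30, 20]])
        counts = _counts(np.hstack([base, base]))
        groups = _groups(["A"] * 4 + ["B"] * 4)
        de = ppbc.de_test(counts, groups, contrast=("B", "A"))
        assert np.allclose(de["stat"], 0.0)
        assert np.allclose(de["p"], 1.0)

    def test_group_swap_antisymmetry(self, small_cohort):
        counts = ppbc.filter_expressed(small_cohort.counts, small_cohort.meta)
        fwd = ppbc.de_test(counts, small_cohort.meta, contrast=("PPBC", "NPBC"))
        rev = ppbc.de_test(counts, small_cohort.meta, contrast=("NPBC", "PPBC"))
        assert np.allclose(fwd["log2fc"], -rev["log2fc"])
        assert np.allclose(fwd["stat"], -rev["stat"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_type_i_error_calibrated_under_null(self):
        cfg = ppbc.SimConfig(
            n_samples_per_group=10, n_genes=2000, program_effect_log2fc=0.0, seed=7
        )
        out = ppbc.simulate_cohort(cfg)
        de = ppbc.de_test(ppbc.filter_expressed(out.counts, out.meta), out.meta)
        assert 0.03 <= (de["p"] < 0.05).mean() <= 0.07

    def test_power_on_planted_genes(self):
        """>=80% of planted log2FC=2 genes reach BH FDR < 0.1 at n=10/group."""
        cfg = ppbc.SimConfig(n_samples_per_group=10, n_genes=2000, seed=7)
        out = ppbc.simulate_cohort(cfg)
        de = ppbc.de_test(ppbc.filter_expressed(out.counts, out.meta), out.meta)
        planted = [g for g in out.truth["gene"] if g in de.index]
        assert (de.loc[planted, "padj"] < 0.1).mean() >= 0.8


class TestBH:
    def test_step_up_by_hand(self):
        assert np.allclose(ppbc.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_edge_cases(self):
        assert ppbc.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(ppbc.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ppbc.bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_p_and_is_permutation_equivariant(self, p):
        padj = ppbc.bh_adjust(p)
        assert np.all(padj >= np.asarray(p) - 1e-12)
        assert np.all(padj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(np.asarray(padj)[perm], ppbc.bh_adjust(np.asarray(p)[perm]))


class TestClustering:
    def test_duplicated_samples_merge_first(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=20)
        expr = pd.DataFrame(
            {"A": col, "A2": col, "B": col + rng.normal(scale=3, size=20)},
            index=[f"g{i}" for i in range(20)],
        )
        linkage, order = ppbc.cluster_samples(expr, zscore=False)
        assert linkage[0, 2] == 0.0  # A and A2 merge at distance zero
        assert abs(order.index("A") - order.index("A2")) == 1

    def test_average_linkage_hand_heights(self):
        expr = pd.DataFrame([[0.0, 1.0, 3.0]], index=["g"], columns=["A", "B", "C"])
        linkage, _ = ppbc.cluster_samples(expr, zscore=False)
        assert np.allclose(sorted(linkage[:, 2]), [1.0, 2.5])

    def test_requires_two_samples(self):
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["A"])
        with pytest.raises(ValueError):
            ppbc.cluster_samples(expr)

    def test_missing_requested_gene(self, small_cohort):
        expr = np.log2(ppbc.compute_cpm(small_cohort.counts) + 1)
        with pytest.raises(KeyError):
            ppbc.cluster_samples(expr, genes=["NOT_A_GENE"])
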