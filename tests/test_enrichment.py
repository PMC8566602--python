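"""Weighted-KS enrichment score, permutation GSEA, single-sample scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import ppbc
from ppbc.enrichment import _es_from_hit_positions


def _sig(scores, prefix="gene"):
    return pd.Series(
        np.asarray(scores, dtype=float),
        index=[f"{prefix}{i + 1}" for i in range(len(scores))],
    )


def brute_force_es(sig: pd.Series, members, weight_p=1.0):
    """Independent re-derivation of the running-sum ES (naive loop)."""
    sig = ppbc.enrichment.rank_signature(sig)
    hits = [g in members for g in sig.index]
    n, k = len(sig), sum(hits)
    wsum = sum(abs(s) ** weight_p for s, h in zip(sig, hits) if h)
    run, best = 0.0, 0.0
    for s, h in zip(sig, hits):
        run += (abs(s) ** weight_p) / wsum if h else -1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichmentScore:
    def test_worked_five_gene_example(self):
        sig = _sig([3, 2, 1, -1, -2])
        es, running = ppbc.enrichment_score(sig, ppbc.GeneSet("s", frozenset(["gene1", "gene3"])))
        assert es == pytest.approx(0.75)
        assert np.allclose(running, [0.75, 0.41667, 0.66667, 0.33333, 0.0], atol=1e-4)

    def test_top_gene_set_maximally_enriched(self):
        sig = _sig([5, 4, 3, 2, 1])
        es, _ = ppbc.enrichment_score(sig, ppbc.GeneSet("s", frozenset(["gene1"])))
        assert es == pytest.approx(1.0)

    def test_bottom_set_depleted(self):
        sig = _sig([5, 4, 3, 2, 1])
        es, _ = ppbc.enrichment_score(sig, ppbc.GeneSet("s", frozenset(["gene4", "gene5"])))
        assert es < 0

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="no overlap"):
            ppbc.enrichment_score(_sig([1, 2]), ppbc.GeneSet("s", frozenset(["x"])))

    def test_unweighted_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(1)
        sig = _sig(rng.normal(size=200))
        members = frozenset(rng.choice(sig.index, 20, replace=False))
        _, running = ppbc.enrichment_score(sig, ppbc.GeneSet("s", members), weight_p=0.0)
        assert abs(running[-1]) < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_stays_in_range(self, seed):
        rng = np.random.default_rng(seed)
        sig = _sig(rng.normal(size=50))
        members = frozenset(rng.choice(sig.index, 8, replace=False))
        es, _ = ppbc.enrichment_score(sig, ppbc.GeneSet("s", members))
        assert es == pytest.approx(brute_force_es(sig, members), abs=1e-12)
        assert -1 <= es <= 1

    @pytest.mark.parametrize("seed", range(5))
    def test_fast_permutation_path_matches_full_profile(self, seed):
        """The O(k) hit-position ES equals the full running-sum ES."""
        rng = np.random.default_rng(seed)
        sig = ppbc.enrichment.rank_signature(_sig(rng.normal(size=100)))
        pos = np.sort(rng.choice(100, size=12, replace=False))
        members = frozenset(sig.index[pos])
        es_full, _ = ppbc.enrichment_score(sig, ppbc.GeneSet("s", members))
        weights = np.abs(sig.to_numpy())
        assert _es_from_hit_positions(pos, weights, 100) == pytest.approx(es_full, abs=1e-12)


class TestGsea:
    def test_planted_top_genes_are_significant(self):
        rng = np.random.default_rng(0)
        sig = _sig(np.sort(rng.normal(size=2000))[::-1])
        members = frozenset(sig.index[:30])
        res = ppbc.gsea(sig, ppbc.GeneSet("planted", members), n_perm=1000, seed=1)
        assert res.p_nominal < 0.01
        assert res.nes > 1.5
        assert set(res.leading_edge) <= members

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        sig = _sig(rng.normal(size=500))
        gs = ppbc.GeneSet("s", frozenset(rng.choice(sig.index, 25, replace=False)))
        a = ppbc.gsea(sig, gs, n_perm=200, seed=9)
        b = ppbc.gsea(sig, gs, n_perm=200, seed=9)
        assert (a.es, a.nes, a.p_nominal) == (b.es, b.nes, b.p_nominal)

    def test_relabeling_symmetry_of_null(self):
        """Permuting gene labels leaves the |ES| null distribution unchanged."""
        rng = np.random.default_rng(3)
        scores = rng.normal(size=400)
        sig = _sig(scores)
        relabeled = pd.Series(scores, index=rng.permutation(sig.index))
        weights = np.abs(np.sort(scores)[::-1])

        def null(sig_, seed):
            r = np.random.default_rng(seed)
            return [
                abs(_es_from_hit_positions(np.sort(r.choice(400, 20, replace=False)), weights, 400))
                for _ in range(300)
            ]

        ks = st.ks_2samp(null(sig, 5), null(relabeled, 6))
        assert ks.pvalue > 0.01

    def test_phenotype_mode_needs_groups_and_size(self, small_cohort):
        expr = np.log2(ppbc.compute_cpm(small_cohort.counts) + 1)
        sig = _sig(np.arange(10, 0, -1))
        gs = ppbc.GeneSet("s", frozenset(["gene1"]))
        with pytest.raises(ValueError, match="requires expr"):
            ppbc.gsea(sig, gs, perm_mode="phenotype")
        tiny = expr.iloc[:, [0, 1, 10, 11]]
        groups = small_cohort.meta["parity"]
        de = ppbc.de_test(ppbc.filter_expressed(small_cohort.counts, groups), groups)
        with pytest.raises(ValueError, match="gene_set"):
            ppbc.gsea(
                de["stat"], ppbc.GeneSet("s", frozenset(de.index[:20])),
                perm_mode="phenotype", expr=tiny, groups=groups,
            )

    def test_collection_adds_sign_stratified_fdr(self):
        rng = np.random.default_rng(4)
        sig = _sig(np.sort(rng.normal(size=500))[::-1])
        sets = [
            ppbc.GeneSet("top", frozenset(sig.index[:20])),
            ppbc.GeneSet("bottom", frozenset(sig.index[-20:])),
            ppbc.GeneSet("random", frozenset(rng.choice(sig.index, 20, replace=False))),
        ]
        table = ppbc.gsea_collection(sig, sets, n_perm=200, seed=0)
        assert table.loc["top", "es"] > 0 > table.loc["bottom", "es"]
        assert table["fdr_q"].between(0, 1).all()


class TestSignatureScore:
    def test_single_gene_z_scores(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=["a", "b", "c"])
        score = ppbc.signature_score(expr, ppbc.GeneSet("s", frozenset(["g1"])))
        assert np.allclose(score, [-1, 0, 1])

    def test_constant_gene_contributes_zero(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [7.0, 7.0, 7.0]], index=["g1", "g2"], columns=["a", "b", "c"]
        )
        score = ppbc.signature_score(expr, ppbc.GeneSet("s", frozenset(["g1", "g2"])))
        assert np.allclose(score, [-0.5, 0, 0.5])

    def test_scores_center_on_zero(self, small_cohort):
        expr = np.log2(ppbc.compute_cpm(small_cohort.counts) + 1)
        gs = next(g for g in small_cohort.gene_sets if g.name == "CELL_CYCLE")
        score = ppbc.signature_score(expr, gs)
        assert abs(score.mean()) < 1e-10

    def test_invariant_to_gene_order(self, small_cohort):
        expr = np.log2(ppbc.compute_cpm(small_cohort.counts) + 1)
        gs = small_cohort.gene_sets[0]
        shuffled = expr.sample(frac=1, random_state=0)
        pd.testing.assert_series_equal(
            ppbc.signature_score(expr, gs), ppbc.signature_score(shuffled, gs)
        )

    def test_planted_program_higher_in_ppbc(self, small_cohort):
        expr = np.log2(ppbc.compute_cpm(small_cohort.counts) + 1)
        gs = next(g for g in small_cohort.gene_sets if g.name == "IMMUNITY")
        score = ppbc.signature_score(expr, gs)
        grp = small_cohort.meta["parity"]
        assert score[grp == "PPBC"].mean() > score[grp == "NPBC"].mean()
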