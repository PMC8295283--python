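import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from cardioscreen import chip, integrate as integ, simulate as sim
from cardioscreen.chip import StageDesign
from cardioscreen.integrate import GeneSet

from oracles import fisher_two_sided, gsea_es_bruteforce


def _nb_counts(rng, mean, reps, tag):
    return pd.DataFrame(
        {f"{tag}{r}": rng.poisson(mean) for r in range(reps)},
        index=[f"g{i}" for i in range(len(mean))],
    )


class TestMaturationalFc:
    def test_equal_means_give_near_zero_lfc(self):
        rng = np.random.default_rng(0)
        mean = rng.uniform(1000, 5000, 300)
        a = _nb_counts(rng, mean, 3, "p1_")
        b = _nb_counts(rng, mean, 3, "p28_")
        res = integ.maturational_fc(a, b)
        ok = res["status"] == "ok"
        assert res.loc[ok, "log2fc"].abs().median() < 0.1

    def test_planted_twofold_gene_recovered(self):
        rng = np.random.default_rng(1)
        mean = np.full(300, 2000.0)
        a = _nb_counts(rng, mean, 3, "p1_")
        mean2 = mean.copy()
        mean2[17] *= 2
        b = _nb_counts(rng, mean2, 3, "p28_")
        res = integ.maturational_fc(a, b)
        assert res.iloc[17]["log2fc"] == pytest.approx(1.0, abs=0.3)

    def test_all_zero_gene_flagged_na(self):
        rng = np.random.default_rng(2)
        mean = np.full(50, 500.0)
        a = _nb_counts(rng, mean, 3, "p1_")
        b = _nb_counts(rng, mean, 3, "p28_")
        a.iloc[0] = 0
        b.iloc[0] = 0
        res = integ.maturational_fc(a, b)
        assert res.iloc[0]["status"] == "all_zero"
        assert np.isnan(res.iloc[0]["log2fc"])

    def test_single_replicate_rejected(self):
        rng = np.random.default_rng(3)
        mean = np.full(10, 100.0)
        a = _nb_counts(rng, mean, 1, "p1_")
        b = _nb_counts(rng, mean, 3, "p28_")
        with pytest.raises(integ.IntegrationError):
            integ.maturational_fc(a, b)


class TestStageGeneSets:
    def test_sets_match_independent_sort(self):
        rng = np.random.default_rng(4)
        fc = pd.Series(rng.normal(size=300), index=[f"g{i:03d}" for i in range(300)])
        table = pd.DataFrame(dict(log2fc=fc))
        adult, neonatal = integ.make_stage_gene_sets(table, k=50)
        ranked = sorted(fc.index, key=lambda g: (-fc[g], g))
        assert list(adult.members) == ranked[:50]
        assert set(neonatal.members) == set(ranked[-50:])
        assert not set(adult.members) & set(neonatal.members)

    def test_default_k_is_one_hundred(self):
        rng = np.random.default_rng(5)
        fc = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
        adult, neonatal = integ.make_stage_gene_sets(pd.DataFrame(dict(log2fc=fc)))
        assert len(adult) == 100 and len(neonatal) == 100

    def test_boundary_ties_resolved_by_gene_id(self):
        fc = pd.Series(
            [3.0, 2.0, 2.0, 2.0, 1.0, -1.0, -2.0, -2.0, -2.0, -3.0],
            index=list("abcdefghij"),
        )
        adult, neonatal = integ.make_stage_gene_sets(
            pd.DataFrame(dict(log2fc=fc)), k=3
        )
        assert list(adult.members) == ["a", "b", "c"]
        assert list(neonatal.members) == ["h", "i", "j"]

    def test_too_few_genes_rejected(self):
        fc = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(integ.IntegrationError):
            integ.make_stage_gene_sets(pd.DataFrame(dict(log2fc=fc)), k=5)


class TestGsea:
    def test_top_ranked_set_scores_near_one(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(
            np.sort(rng.normal(size=500))[::-1], index=[f"g{i:03d}" for i in range(500)]
        )
        top = GeneSet("top", tuple(scores.index[:40]))
        res = integ.gsea_preranked(scores, top, n_perm=200, seed=0)
        assert res.es > 0.9
        assert res.nes > 0
        # smallest achievable value given the same-sign null pool
        assert 1 / 201 <= res.nominal_p <= 0.02

    def test_size_floor_enforced(self):
        scores = pd.Series(np.arange(100.0)[::-1], index=[f"g{i}" for i in range(100)])
        small = GeneSet("small", tuple(scores.index[:10]))
        with pytest.raises(integ.IntegrationError, match="floor"):
            integ.gsea_preranked(scores, small, n_perm=10, seed=0)

    def test_es_matches_bruteforce_on_tiny_universe(self):
        # universe of 8, set of 3; the size floor is waived for the check
        rng = np.random.default_rng(7)
        for trial in range(20):
            vals = rng.normal(size=8)
            scores = pd.Series(vals, index=[f"g{i}" for i in range(8)])
            members = tuple(rng.choice(scores.index, size=3, replace=False))
            res = integ.gsea_preranked(
                scores, GeneSet("tiny", members), n_perm=10, seed=0, min_size=0
            )
            ref = gsea_es_bruteforce(scores.to_dict(), set(members))
            assert res.es == pytest.approx(ref)

    def test_null_nominal_p_approximately_uniform(self):
        rng = np.random.default_rng(8)
        n = 200
        pvals = []
        for trial in range(200):
            scores = pd.Series(
                rng.normal(size=n), index=[f"g{i:03d}" for i in range(n)]
            )
            members = tuple(rng.choice(scores.index, size=30, replace=False))
            res = integ.gsea_preranked(
                scores, GeneSet("r", members), n_perm=200, seed=trial
            )
            pvals.append(res.nominal_p)
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_sign_convention_matches_gseapy(self):
        """Cross-check ES against the reference preranked implementation."""
        import gseapy

        rng = np.random.default_rng(9)
        genes = [f"G{i:03d}" for i in range(300)]
        scores = pd.Series(rng.normal(size=300), index=genes)
        members = list(rng.choice(genes, size=40, replace=False))
        rnk = scores.sort_values(ascending=False).reset_index()
        rnk.columns = ["gene_name", "rank"]
        ref = gseapy.prerank(
            rnk=rnk,
            gene_sets={"set": members},
            permutation_num=50,
            min_size=5,
            max_size=500,
            weight=1.0,
            seed=0,
            threads=1,
            outdir=None,
        ).res2d
        mine = integ.gsea_preranked(
            scores, GeneSet("set", tuple(members)), n_perm=200, seed=0
        )
        assert mine.es == pytest.approx(float(ref["ES"].iloc[0]), abs=0.02)


class TestBinDeltaSummary:
    def _table(self, rng, n=2000, coupling=0.4):
        cov = np.array([[1.0, coupling], [coupling, 1.0]])
        d = rng.multivariate_normal([0, 0], cov, size=n)
        return pd.DataFrame(
            dict(
                rna_log2fc_maturation=d[:, 0],
                h2bub_delta=d[:, 1],
                h2bub_p1=rng.lognormal(size=n),
            ),
            index=[f"g{i}" for i in range(n)],
        )

    def test_single_bin_conserves_gene_count(self):
        rng = np.random.default_rng(10)
        t = self._table(rng, 500)
        out = integ.bin_delta_summary(t, [-10, 10])
        n = out[out["variable"] == "h2bub_delta"]["n"].sum()
        assert n == 500

    def test_coupled_simulation_gives_monotone_bin_medians(self):
        rng = np.random.default_rng(11)
        t = self._table(rng, 4000, coupling=0.4)
        out = integ.bin_delta_summary(t, [-4, -2, -1, 0, 1, 2, 4])
        med = out[out["variable"] == "h2bub_delta"]["median"].to_numpy()
        assert (np.diff(med) >= 0).all()

    def test_uncoupled_simulation_uncorrelated(self):
        rng = np.random.default_rng(12)
        t = self._table(rng, 4000, coupling=0.0)
        r = np.corrcoef(t["rna_log2fc_maturation"], t["h2bub_delta"])[0, 1]
        assert abs(r) < 0.05

    def test_bins_left_open_right_closed(self):
        t = pd.DataFrame(
            dict(
                rna_log2fc_maturation=[-1.0, 0.0, 0.5],
                h2bub_delta=[1.0, 2.0, 3.0],
                h2bub_p1=[1.0, 1.0, 1.0],
            )
        )
        out = integ.bin_delta_summary(t, [-1, 0, 1])
        counts = dict(
            zip(
                out[out["variable"] == "h2bub_delta"]["bin"],
                out[out["variable"] == "h2bub_delta"]["n"],
            )
        )
        # -1.0 falls outside (-1, 0]; 0.0 inside it; 0.5 in (0, 1]
        assert counts["(-1, 0]"] == 1
        assert counts["(0, 1]"] == 1


class TestQuadrants:
    def _toy(self):
        # hand-built 12-gene table
        rows = [
            # rna, h2bub, ko_lfc, ko_padj -> quadrant, call
            (+2.0, +1.0, -2.0, 0.001),  # UR, down
            (+1.5, +0.5, -1.5, 0.001),  # UR, down
            (+1.0, +2.0, +1.5, 0.001),  # UR, up
            (-1.0, +1.0, -1.2, 0.001),  # UL, down
            (-2.0, +0.5, +1.4, 0.001),  # UL, up
            (+1.0, -1.0, +2.0, 0.001),  # LR, up
            (+0.5, -0.5, -3.0, 0.001),  # LR, down
            (-1.0, -1.0, +2.5, 0.001),  # LL, up
            (-0.5, -2.0, +1.1, 0.001),  # LL, up
            (-0.5, -2.0, -1.1, 0.001),  # LL, down
            (+1.0, +1.0, +0.5, 0.001),  # ns: |lfc| <= 1
            (+1.0, +1.0, +3.0, 0.500),  # ns: padj above threshold
        ]
        return pd.DataFrame(
            rows,
            columns=["rna_log2fc_maturation", "h2bub_delta", "ko_log2fc", "ko_adj_p"],
            index=[f"g{i:02d}" for i in range(12)],
        )

    def test_toy_counts_match_hand_enumeration(self):
        labeled, summaries = integ.quadrant_classify(self._toy())
        assert (labeled["quadrant"] == "UR").sum() == 3
        assert (labeled["quadrant"] == "UL").sum() == 2
        assert (labeled["quadrant"] == "LR").sum() == 2
        assert (labeled["quadrant"] == "LL").sum() == 3
        assert (labeled["quadrant"] == "none").sum() == 2
        assert summaries["UR"]["ko_down"]["table"] == [[2, 1], [3, 4]]
        # outside LL: UR(down,down,up) + UL(down,up) + LR(up,down) = 3 up, 4 other
        assert summaries["LL"]["ko_up"]["table"] == [[2, 1], [3, 4]]

    def test_definition_case_ur_ko_down(self):
        t = pd.DataFrame(
            dict(
                rna_log2fc_maturation=[0.7],
                h2bub_delta=[0.2],
                ko_log2fc=[-1.5],
                ko_adj_p=[0.001],
            ),
            index=["g"],
        )
        labeled, summaries = integ.quadrant_classify(t)
        assert labeled.loc["g", "quadrant"] == "UR"
        assert labeled.loc["g", "ko_call"] == "down"
        assert summaries["UR"]["ko_down"]["table"][0][0] == 1

    def test_quadrants_partition_classified_genes(self):
        rng = np.random.default_rng(13)
        n = 500
        t = pd.DataFrame(
            dict(
                rna_log2fc_maturation=rng.normal(size=n),
                h2bub_delta=rng.normal(size=n),
                ko_log2fc=rng.normal(scale=1.5, size=n),
                ko_adj_p=rng.uniform(size=n),
            ),
            index=[f"g{i}" for i in range(n)],
        )
        labeled, summaries = integ.quadrant_classify(t)
        n_classified = (labeled["quadrant"] != "none").sum()
        assert sum(s["n"] for s in summaries.values()) == n_classified

    def test_no_gene_passing_filter_gives_empty_summaries(self):
        t = pd.DataFrame(
            dict(
                rna_log2fc_maturation=[1.0, -1.0],
                h2bub_delta=[1.0, -1.0],
                ko_log2fc=[0.1, -0.2],
                ko_adj_p=[0.9, 0.9],
            ),
            index=["a", "b"],
        )
        labeled, summaries = integ.quadrant_classify(t)
        assert (labeled["quadrant"] == "none").all()
        assert all(s["n"] == 0 for s in summaries.values())


class TestFisher:
    def test_identical_proportions_give_p_one_or_one(self):
        res = integ.fisher_quadrant([[5, 5], [5, 5]])
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_matches_exhaustive_hypergeometric_enumeration(self):
        tables = [
            [[3, 2], [1, 4]],
            [[10, 2], [3, 9]],
            [[0, 7], [5, 2]],
            [[12, 30], [25, 18]],
        ]
        for t in tables:
            res = integ.fisher_quadrant(t)
            assert res.p_two_sided == pytest.approx(fisher_two_sided(t), rel=1e-6)

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        t = [[12, 5], [3, 20]]
        swapped = [[20, 3], [5, 12]]
        a = integ.fisher_quadrant(t)
        b = integ.fisher_quadrant(swapped)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)
        assert a.odds_ratio == pytest.approx(b.odds_ratio)

    def test_one_sided_tails_cover_distribution(self):
        t = [[8, 4], [3, 9]]
        res = integ.fisher_quadrant(t)
        p_obs = sstats.hypergeom(24, 12, 11).pmf(8)
        assert res.p_greater + res.p_less >= 1.0 - 1e-9
        assert res.p_greater + res.p_less == pytest.approx(1.0 + p_obs)

    def test_zero_cell_uses_haldane_odds_ratio(self):
        res = integ.fisher_quadrant([[0, 10], [5, 5]])
        assert res.odds_ratio == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(integ.IntegrationError):
            integ.fisher_quadrant([[1, -2], [3, 4]])
        with pytest.raises(integ.IntegrationError):
            integ.fisher_quadrant([[1.5, 2], [3, 4]])


class TestCoupledPipeline:
    def test_planted_ur_quadrant_ko_down_enrichment(self, coupled_multiomics):
        cfg, omx = coupled_multiomics
        stages = {
            s: StageDesign(tuple(c), i) for s, (c, i) in omx.h2bub_stages.items()
        }
        sig = chip.h2bub_gene_signal(omx.h2bub_counts, stages, omx.gene_lengths)
        mat = integ.maturational_fc(omx.rna_p1, omx.rna_p28)
        ko = integ.maturational_fc(omx.rna_ctrl, omx.rna_ko)
        table = pd.DataFrame(
            dict(
                rna_log2fc_maturation=mat["log2fc"],
                h2bub_delta=sig["delta"],
                ko_log2fc=ko["log2fc"],
                ko_adj_p=ko["bh_adj_p"],
            )
        )
        _, summaries = integ.quadrant_classify(table)
        fisher = summaries["UR"]["ko_down"]["fisher"]
        assert fisher["p_two_sided"] < 0.001
        assert fisher["odds_ratio"] > 1

    def test_adult_set_depleted_in_ko_ranking(self, coupled_multiomics):
        # genes that gain expression during maturation are down in the KO
        cfg, omx = coupled_multiomics
        mat = integ.maturational_fc(omx.rna_p1, omx.rna_p28)
        ko = integ.maturational_fc(omx.rna_ctrl, omx.rna_ko)
        adult, neonatal = integ.make_stage_gene_sets(mat, k=100)
        ranking = ko["log2fc"].dropna()
        adult_in = GeneSet("adult", tuple(g for g in adult.members if g in ranking.index))
        res = integ.gsea_preranked(ranking, adult_in, n_perm=1000, seed=3)
        assert res.es < 0 and res.nes < 0
        neo_in = GeneSet("neo", tuple(g for g in neonatal.members if g in ranking.index))
        res_n = integ.gsea_preranked(ranking, neo_in, n_perm=1000, seed=3)
        assert res_n.es > 0 and res_n.nes > 0
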