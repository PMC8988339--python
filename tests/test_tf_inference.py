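import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from findit.calc_rp import RPConfig, calc_rp_region
from findit.fixtures import make_mara_fixture
from findit import tf_inference as tfi


def hypergeom_tail_oracle(k, total, marked, drawn):
    """Direct summation P(X >= k) with exact integer combinatorics."""
    num = 0
    for i in range(k, min(marked, drawn) + 1):
        num += math.comb(marked, i) * math.comb(total - marked, drawn - i)
    return num / math.comb(total, drawn)


class TestInverseNormalZ:
    def test_middle_rank_maps_to_zero(self):
        z = tfi.inverse_normal_z([3], n=5)
        assert z[0] == pytest.approx(0.0)

    def test_rank_one_of_three(self):
        # Phi^-1(2.5/3), computed from the standard normal quantile
        z = tfi.inverse_normal_z([1], n=3)
        assert z[0] == pytest.approx(stats.norm.ppf(2.5 / 3))
        assert z[0] == pytest.approx(0.9674, abs=1e-4)

    def test_reversing_ranks_negates_z(self):
        ranks = np.array([1, 2, 3, 4, 5], dtype=float)
        fwd = tfi.inverse_normal_z(ranks)
        rev = tfi.inverse_normal_z(ranks[::-1])
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)


class TestWilcoxGreater:
    def test_all_tied_gives_p_one(self):
        z, p = tfi.wilcox_greater(np.zeros(5), np.zeros(7))
        assert p == 1.0

    def test_clean_separation_exact_enumeration(self):
        # query {3,4,5} beats background {1,2} in 1 of C(5,2)=10 arrangements
        z, p = tfi.wilcox_greater(np.array([3.0, 4, 5]), np.array([1.0, 2]))
        assert p == pytest.approx(0.1)

    def test_tied_small_sample_matches_permutation_oracle(self):
        x, y = np.array([2.0, 2, 3]), np.array([0.0, 1])
        _, p = tfi.wilcox_greater(x, y)
        combined = np.concatenate([x, y])
        ranks = stats.rankdata(combined)
        obs = ranks[:3].sum()
        hits = total = 0
        for idx in itertools.combinations(range(5), 3):
            total += 1
            hits += ranks[list(idx)].sum() >= obs - 1e-9
        assert p == pytest.approx(hits / total)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_path_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(20.0))[:6]
        y = np.setdiff1d(np.arange(20.0), x)[:8]
        _, p = tfi.wilcox_greater(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(ref, rel=1e-12)

    def test_normal_approx_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.0, 1.0, 40)
        y = rng.normal(0.0, 1.0, 60)
        _, p = tfi.wilcox_greater(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestEnrichFisher:
    def test_matches_hypergeometric_summation_oracle(self):
        # 2x2 table (80, 20, 90, 810): universe 1000, 170 hits, query 100
        universe = {f"x{i}" for i in range(1000)}
        ids = sorted(universe)
        query = set(ids[:100])
        hits = {"TF": set(ids[:80]) | set(ids[100:190])}
        out = tfi.findit_enrich_fisher(query, universe, hits)
        expected = hypergeom_tail_oracle(80, 1000, 170, 100)
        assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)

    def test_no_query_overlap_never_outranks_positive_overlap(self):
        ids = [f"x{i}" for i in range(100)]
        universe = set(ids)
        query = set(ids[:20])
        hits = {
            "TF_zero": set(ids[20:60]),           # 0 query hits, many background
            "TF_pos": set(ids[:10]) | set(ids[20:25]),
        }
        out = tfi.findit_enrich_fisher(query, universe, hits).set_index("tf_id")
        assert out.loc["TF_pos", "rank"] < out.loc["TF_zero", "rank"]
        assert out.loc["TF_zero", "p"] > 0.5

    def test_query_equal_universe_rejected(self):
        ids = {f"x{i}" for i in range(10)}
        with pytest.raises(ValueError, match="background"):
            tfi.findit_enrich_fisher(ids, ids, {"TF": set()})

    def test_exhaustive_small_tables_match_oracle(self):
        """Every 2x2 table with margins <= 12 agrees with direct summation."""
        for total in range(2, 13):
            for marked in range(0, total + 1):
                for drawn in range(1, total):
                    for k in range(max(0, marked + drawn - total), min(marked, drawn) + 1):
                        got = tfi.hypergeom_sf_geq(k, total, marked, drawn)
                        expected = hypergeom_tail_oracle(k, total, marked, drawn)
                        assert got == pytest.approx(expected, rel=1e-10, abs=1e-300)


class TestEnrichWilcox:
    def test_identical_distributions_give_p_one(self):
        ids = [f"x{i}" for i in range(30)]
        out = tfi.findit_enrich_wilcox(set(ids[:10]), set(ids), {"TF": set()})
        assert out.iloc[0]["p"] == 1.0

    def test_signal_matrix_input(self):
        ids = [f"x{i}" for i in range(12)]
        scores = pd.DataFrame({"TF": np.r_[np.full(6, 5.0), np.zeros(6)]}, index=ids)
        out = tfi.findit_enrich_wilcox(set(ids[:6]), set(ids), peak_scores=scores)
        assert out.iloc[0]["p"] < 0.01


class TestTTPair:
    def _pairs(self, mapping):
        rows = [(tf, g) for tf, gs in mapping.items() for g in gs]
        df = pd.DataFrame(rows, columns=["tf_id", "target_gene_id"])
        df["confidence"] = np.nan
        return df

    def test_zero_overlap_gives_p_one(self):
        ids = [f"g{i}" for i in range(50)]
        pairs = self._pairs({"TF": ids[40:]})
        out = tfi.findit_tt_pair(set(ids[:10]), set(ids), pairs)
        assert out.iloc[0]["p"] == 1.0

    def test_matches_summation_oracle(self):
        ids = [f"g{i:04d}" for i in range(1000)]
        query = set(ids[:50])
        targets = set(ids[:20]) | set(ids[100:180])  # overlap 20, size 100
        out = tfi.findit_tt_pair(query, set(ids), self._pairs({"TF": sorted(targets)}))
        expected = hypergeom_tail_oracle(20, 1000, 100, 50)
        assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)
        assert out.iloc[0]["n_overlap"] == 20

    def test_exact_target_set_query_is_extremal(self):
        ids = [f"g{i:03d}" for i in range(200)]
        target_set = set(ids[:10])
        pairs = self._pairs({"TF_exact": sorted(target_set), "TF_other": ids[50:60]})
        out = tfi.findit_tt_pair(target_set, set(ids), pairs).set_index("tf_id")
        assert out.loc["TF_exact", "p"] < out.loc["TF_other", "p"]
        assert out.loc["TF_exact", "rank"] == 1

    def test_tf_without_universe_targets_dropped(self, caplog):
        ids = [f"g{i}" for i in range(20)]
        pairs = self._pairs({"TF_in": ids[:5], "TF_out": ["zzz"]})
        out = tfi.findit_tt_pair(set(ids[:5]), set(ids), pairs)
        assert list(out["tf_id"]) == ["TF_in"]


class TestTFHit:
    def test_background_only_binder_ranks_low(self, world):
        tf_world = world["tf_world"]
        hits = dict(tf_world.hits)
        query = set(tf_world.query_genes)
        scan = world["links"][world["links"]["mode"] == "scan"]
        bg_peaks = set(scan.loc[~scan["gene_id"].isin(query), "peak_id"])
        hits["TF_bgonly"] = set(sorted(bg_peaks)[: len(bg_peaks) // 2])
        out = tfi.findit_tfhit(query, set(world["genes"]["gene_id"]), hits, world["links"])
        out = out.set_index("tf_id")
        assert out.loc["TF_bgonly", "rank"] > len(out) / 2

    def test_tiny_counts_match_enumeration_oracle(self):
        # 3 query vs 2 background genes with counts {2,2,3} vs {0,1}
        genes = [f"g{i}" for i in range(5)]
        links = pd.DataFrame(
            [(f"p{i}", g, 0, "scan") for i, g in enumerate(
                ["g0", "g0", "g1", "g1", "g2", "g2", "g2", "g4"])],
            columns=["peak_id", "gene_id", "distance", "mode"],
        )
        hits = {"TF": {f"p{i}" for i in range(8)}}
        out = tfi.findit_tfhit({"g0", "g1", "g2"}, set(genes), hits, links)
        counts = np.array([2.0, 2, 3, 0, 1])
        ranks = stats.rankdata(counts)
        obs = ranks[:3].sum()
        hits_n = total = 0
        for idx in itertools.combinations(range(5), 3):
            total += 1
            hits_n += ranks[list(idx)].sum() >= obs - 1e-9
        assert out.iloc[0]["p"] == pytest.approx(hits_n / total)

    def test_weighted_counts_change_statistic_not_contract(self, world):
        tf_world = world["tf_world"]
        out = tfi.findit_tfhit(
            set(tf_world.query_genes), set(world["genes"]["gene_id"]),
            tf_world.hits, world["links"], weighted=True,
        )
        assert list(out["rank"]) == list(range(1, len(out) + 1))
        assert out.iloc[0]["tf_id"] == world["spec"].planted_tf_id


class TestRegionRP:
    def _tiny_profile(self):
        links = pd.DataFrame(
            [("p1", "gQ", 0, "scan"), ("p2", "gB", 0, "scan")],
            columns=["peak_id", "gene_id", "distance", "mode"],
        )
        sig = pd.DataFrame({"s1": [10.0, 10.0], "s2": [10.0, 10.0]}, index=["p1", "p2"])
        profile = calc_rp_region(links, sig, RPConfig())
        return profile, sig

    def test_unbound_tf_gets_p_one_everywhere(self):
        profile, sig = self._tiny_profile()
        summary, per_sample, _ = tfi.findit_region_rp({"gQ"}, profile, sig, {"TF": set()})
        assert (per_sample["p"] == 1.0).all()
        assert summary.iloc[0]["p"] == 1.0

    def test_single_bound_peak_gives_full_proportion(self):
        profile, sig = self._tiny_profile()
        _, _, detail = tfi.findit_region_rp({"gQ"}, profile, sig, {"TF": {"p1"}})
        assert (detail.loc[detail["tf_id"] == "TF", "proportion"] == 1.0).all()

    def test_sample_specific_signal_found_in_right_sample(self):
        """TF bound at query-linked peaks with signal only in s1 tops s1, not s2."""
        rng = np.random.default_rng(6)
        n_genes = 40
        genes = [f"g{i:02d}" for i in range(n_genes)]
        links = pd.DataFrame(
            [(f"p{i:02d}", genes[i], 0, "scan") for i in range(n_genes)],
            columns=["peak_id", "gene_id", "distance", "mode"],
        )
        sig = pd.DataFrame(
            {"s1": rng.uniform(1, 5, n_genes), "s2": rng.uniform(1, 5, n_genes)},
            index=links["peak_id"],
        )
        query = set(genes[:10])
        # TF binds exactly the query genes' peaks; decoys bind random peaks
        hits = {"TF_planted": {f"p{i:02d}" for i in range(10)}}
        for d in range(8):
            hits[f"TF_d{d}"] = set(rng.choice(links["peak_id"], 10, replace=False))
        sig.loc[[f"p{i:02d}" for i in range(10)], "s1"] *= 50
        profile = calc_rp_region(links, sig, RPConfig())
        _, per_sample, _ = tfi.findit_region_rp(query, profile, sig, hits)
        s1 = per_sample[per_sample["sample"] == "s1"].sort_values("p")
        assert s1.iloc[0]["tf_id"] == "TF_planted"

    def test_foreign_hit_peaks_ignored_with_warning(self, caplog):
        profile, sig = self._tiny_profile()
        summary, _, _ = tfi.findit_region_rp({"gQ"}, profile, sig, {"TF": {"p1", "alien"}})
        assert "ignored" in caplog.text
        assert len(summary) == 1


class TestMARA:
    def test_noiseless_recovery(self):
        fx = make_mara_fixture(seed=1, noise_frac=0.0)
        res = tfi.findit_mara(fx["signal"], fx["site_counts"], (1e-8,))
        for m in fx["activity"].index:
            np.testing.assert_allclose(
                res.activity.loc[m], fx["activity"].loc[m], atol=1e-6
            )

    def test_zero_signal_gives_zero_activity(self):
        signal = pd.DataFrame(0.0, index=[f"p{i}" for i in range(20)], columns=["a", "b", "c"])
        counts = pd.DataFrame(
            np.random.default_rng(0).poisson(2, (20, 4)).astype(float),
            index=signal.index, columns=list("wxyz"),
        )
        res = tfi.findit_mara(signal, counts)
        np.testing.assert_allclose(res.activity.to_numpy(), 0.0, atol=1e-12)

    def test_activity_rows_centered(self):
        fx = make_mara_fixture(seed=2)
        res = tfi.findit_mara(fx["signal"], fx["site_counts"])
        np.testing.assert_allclose(res.activity.mean(axis=1), 0.0, atol=1e-10)

    def test_parameter_recovery_with_noise(self):
        fx = make_mara_fixture(seed=0, n_peaks=200, n_motifs=10, n_samples=7, noise_frac=0.1)
        res = tfi.findit_mara(fx["signal"], fx["site_counts"])
        cors = [
            np.corrcoef(res.activity.loc[m], fx["activity"].loc[m])[0, 1]
            for m in fx["activity"].index
        ]
        assert sum(c >= 0.9 for c in cors) >= 9

    def test_top_variable_returns_most_variable_first(self):
        fx = make_mara_fixture(seed=3, planted_motif_scale=5.0)
        res = tfi.findit_mara(fx["signal"], fx["site_counts"])
        top = res.top_variable(3)
        assert top.index[0] == "m00"


class TestIntegrateReplicates:
    def _table(self, ps):
        df = pd.DataFrame({"tf_id": [f"T{i}" for i in range(len(ps))], "statistic": 0.0, "p": ps})
        return tfi._finalize_ranking(df)

    def test_identical_tables_idempotent(self):
        t = self._table([0.001, 0.01, 0.5, 0.9])
        out = tfi.integrate_replicates([t, t, t])
        assert list(out["tf_id"]) == list(t["tf_id"])

    def test_geometric_mean_arithmetic(self):
        t1 = self._table([1e-2, 0.5])
        t2 = self._table([1e-4, 0.5])
        out = tfi.integrate_replicates([t1, t2]).set_index("tf_id")
        assert out.loc["T0", "p"] == pytest.approx(1e-3)

    def test_noisy_replicates_promote_consistent_tf(self):
        # TF_A 2nd in both tables behind different one-off decoys
        t1 = tfi._finalize_ranking(pd.DataFrame(
            {"tf_id": ["dec1", "TF_A", "x", "y"], "statistic": 0.0, "p": [1e-6, 1e-4, 0.2, 0.9]}))
        t2 = tfi._finalize_ranking(pd.DataFrame(
            {"tf_id": ["dec2", "TF_A", "x", "y"], "statistic": 0.0, "p": [1e-6, 1e-4, 0.3, 0.8]}))
        t1 = pd.concat([t1, tfi._finalize_ranking(pd.DataFrame(
            {"tf_id": ["dec2"], "statistic": [0.0], "p": [0.5]}))], ignore_index=True)
        t2 = pd.concat([t2, tfi._finalize_ranking(pd.DataFrame(
            {"tf_id": ["dec1"], "statistic": [0.0], "p": [0.6]}))], ignore_index=True)
        out = tfi.integrate_replicates([t1, t2])
        assert out.iloc[0]["tf_id"] == "TF_A"

    def test_missing_tf_dropped_with_warning(self, caplog):
        t1 = self._table([0.1, 0.2])
        t2 = self._table([0.1, 0.2]).iloc[:1]
        out = tfi.integrate_replicates([t1, t2])
        assert len(out) == 1 and "dropped" in caplog.text

    def test_stouffer_and_mean_rank_modes(self):
        t1, t2 = self._table([0.01, 0.5, 0.9]), self._table([0.02, 0.4, 0.95])
        st = tfi.integrate_replicates([t1, t2], method="stouffer")
        mr = tfi.integrate_replicates([t1, t2], method="mean_rank")
        assert st.iloc[0]["tf_id"] == "T0" and mr.iloc[0]["tf_id"] == "T0"


class TestJaccard:
    def test_identity_and_disjoint(self):
        mat = tfi.jaccard_tf({"a": {1, 2}, "b": {1, 2}, "c": {9}})
        assert mat.loc["a", "b"] == 1.0
        assert mat.loc["a", "c"] == 0.0
        assert (np.diag(mat) == 1.0).all()

    def test_partial_overlap_arithmetic(self):
        mat = tfi.jaccard_tf({"a": {1, 2, 3, 4}, "b": {3, 4, 5, 6}})
        assert mat.loc["a", "b"] == pytest.approx(2 / 6)

    def test_restriction_to_query_set(self):
        mat = tfi.jaccard_tf({"a": {1, 2, 9}, "b": {2, 3, 9}}, restrict_to={1, 2, 3})
        assert mat.loc["a", "b"] == pytest.approx(1 / 3)

    def test_both_empty_defined_zero(self):
        mat = tfi.jaccard_tf({"a": set(), "b": set()})
        assert mat.loc["a", "b"] == 0.0


def test_ranking_contract_holds_for_every_statistic(world):
    """p_adj >= p, ranks are 1..n, z strictly decreasing in rank."""
    tf_world = world["tf_world"]
    uni_p = set(world["peaks"]["peak_id"])
    uni_g = set(world["genes"]["gene_id"])
    tables = [
        tfi.findit_enrich_fisher(set(tf_world.query_peaks), uni_p, tf_world.hits),
        tfi.findit_enrich_wilcox(set(tf_world.query_peaks), uni_p, tf_world.hits),
        tfi.findit_tt_pair(set(tf_world.query_genes), uni_g, tf_world.tt_pairs),
        tfi.findit_tfhit(set(tf_world.query_genes), uni_g, tf_world.hits, world["links"]),
        tfi.findit_region_rp(set(tf_world.query_genes), world["profile"],
                             world["peak_signal"], tf_world.hits)[0],
    ]
    for table in tables:
        assert (table["p_adj"] >= table["p"] - 1e-15).all()
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))
        z_sorted = table.sort_values("rank")["z"].to_numpy()
        assert (np.diff(z_sorted) < 0).all()
        # BH preserves the p ordering
        by_p = table.sort_values("p")["p_adj"].to_numpy()
        assert (np.diff(by_p) >= -1e-15).all()
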