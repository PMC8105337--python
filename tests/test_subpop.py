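"""Normalization, DEGs, enrichment, correlation grouping, tracking, QC."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from myelotrace import subpop, syndata
from myelotrace.subpop import SubpopulationProfile
from myelotrace.syndata import ClusterSpec, Program


@pytest.fixture(scope="module")
def planted_adata():
    spec = [ClusterSpec("hot", 0.5), ClusterSpec("cold", 0.5)]
    prog = Program("AP1", 50, 3.0, ("hot",))
    return syndata.gen_expression(spec, 500, 400, [prog], seed=42)


@pytest.fixture(scope="module")
def planted_norm(planted_adata):
    return subpop.normalize_log(planted_adata)


class TestNormalizeLog:
    def test_zero_count_cell_dropped(self):
        import anndata as ad

        x = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 0.0]])
        adata = ad.AnnData(X=x)
        with pytest.warns(UserWarning, match="zero-count"):
            out = subpop.normalize_log(adata)
        assert out.n_obs == 2

    def test_scale_invariance(self):
        import anndata as ad

        x = np.array([[1.0, 3.0, 6.0], [2.0, 6.0, 12.0]])
        out = subpop.normalize_log(ad.AnnData(X=x))
        assert np.allclose(out.X[0], out.X[1])

    def test_entry_matches_closed_form(self):
        import anndata as ad

        x = np.array([[5.0, 15.0]])
        out = subpop.normalize_log(ad.AnnData(X=x))
        assert out.X[0, 0] == pytest.approx(math.log1p(5 * 10_000 / 20))


class TestSelectDegs:
    def test_null_data_yields_no_degs(self):
        """Without a planted program the subcluster criterion returns a
        median of zero DEGs over seeded replicates."""
        counts = []
        for rep in range(10):
            spec = [ClusterSpec("a", 0.5), ClusterSpec("b", 0.5)]
            adata = syndata.gen_expression(spec, 200, 300, [], seed=rep)
            degs = subpop.select_degs(subpop.normalize_log(adata), "cluster")
            counts.append(sum(len(v) for v in degs.values()))
        assert np.median(counts) == 0

    def test_planted_program_sensitivity_and_fdr(self, planted_adata,
                                                 planted_norm):
        degs = subpop.select_degs(planted_norm, "cluster")
        planted = set(
            planted_adata.var_names[planted_adata.var["program"] == "AP1"]
        )
        found = set(degs["hot"]["gene"])
        sensitivity = len(found & planted) / len(planted)
        fdr = len(found - planted) / max(1, len(found))
        assert sensitivity >= 0.9
        assert fdr <= 0.1

    def test_cell_order_invariance(self, planted_norm):
        a = subpop.select_degs(planted_norm, "cluster")
        shuffled = planted_norm[np.random.default_rng(0).permutation(
            planted_norm.n_obs)]
        b = subpop.select_degs(shuffled, "cluster")
        for k in a:
            assert set(a[k]["gene"]) == set(b[k]["gene"])

    def test_small_cluster_raises_with_name(self, planted_norm):
        bad = planted_norm.copy()
        bad.obs["cluster"] = bad.obs["cluster"].astype(str)
        bad.obs.iloc[0, bad.obs.columns.get_loc("cluster")] = "tiny"
        with pytest.raises(ValueError, match="tiny"):
            subpop.select_degs(bad, "cluster")

    def test_marker_mode_keeps_positive_significant(self, planted_adata,
                                                    planted_norm):
        degs = subpop.select_degs(planted_norm, "cluster", mode="marker")
        assert (degs["hot"]["log2fc"] > 0).all()
        assert (degs["hot"]["qval"] < 0.05).all()


class TestEnrichPathways:
    def test_identical_pathway_attains_minimum_p(self):
        universe = {f"g{i}" for i in range(50)}
        degs = {f"g{i}" for i in range(10)}
        paths = {"exact": set(degs), "other": {f"g{i}" for i in range(40, 50)}}
        out = subpop.enrich_pathways(degs, universe, paths).set_index("pathway")
        # p of the complete overlap equals the minimum attainable value
        from scipy import stats

        pmin = stats.hypergeom.pmf(10, 50, 10, 10)
        assert out.loc["exact", "pval"] == pytest.approx(pmin)
        assert out.loc["exact", "pval"] < out.loc["other", "pval"]

    def test_p_equals_combinatorial_enumeration(self):
        """Upper-tail hypergeometric p for overlap 5 of 10 DEGs with a
        10-gene pathway in a 100-gene universe equals the explicit
        combinatorial sum."""
        universe = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(10)}
        degs = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        out = subpop.enrich_pathways(degs, universe, {"p": pathway})
        total = math.comb(100, 10)
        p_expected = sum(
            math.comb(10, k) * math.comb(90, 10 - k) for k in range(5, 11)
        ) / total
        assert out.iloc[0]["pval"] == pytest.approx(p_expected, rel=1e-12)

    def test_empty_deg_set_all_q_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = subpop.enrich_pathways(set(), universe,
                                     {"a": {"g1"}, "b": {"g2"}})
        assert (out["qval"] == 1.0).all()

    def test_zero_overlap_never_significant(self):
        universe = {f"g{i}" for i in range(100)}
        degs = {f"g{i}" for i in range(5)}
        paths = {f"p{j}": {f"g{i}" for i in range(50 + 5 * j, 55 + 5 * j)}
                 for j in range(5)}
        out = subpop.enrich_pathways(degs, universe, paths)
        assert (out["qval"] > 0.05).all()

    def test_bh_preserves_order_and_dominates_p(self):
        universe = {f"g{i}" for i in range(200)}
        rng = np.random.default_rng(0)
        degs = set(rng.choice(sorted(universe), 30, replace=False))
        paths = {
            f"p{j}": set(rng.choice(sorted(universe), 15, replace=False))
            for j in range(12)
        }
        out = subpop.enrich_pathways(degs, universe, paths)
        assert (out["qval"] >= out["pval"] - 1e-15).all()
        by_p = out.sort_values("pval")
        assert by_p["qval"].is_monotonic_increasing


class TestEnrichmentCorrelationClusters:
    def _planted_enrichment(self, seed=0, n_path=60):
        """Three archetypes, three subpopulations each, plus noise."""
        rng = np.random.default_rng(seed)
        rows, truth = {}, {}
        for arch_i in range(3):
            sig = slice(arch_i * 20, arch_i * 20 + 20)
            for rep in range(3):
                q = rng.uniform(0.2, 1.0, n_path)
                q[sig] = rng.uniform(1e-8, 0.01, 20)
                name = f"a{arch_i}_s{rep}"
                rows[name] = q
                truth[name] = arch_i
        return pd.DataFrame(rows).T, pd.Series(truth)

    def test_identical_profiles_grouped_with_r_one(self):
        q = np.array([1e-6, 0.5, 0.9, 1e-4])
        enr = pd.DataFrame([q, q, q * 0 + [0.9, 1e-5, 1e-3, 0.8]],
                           index=["s1", "s2", "s3"])
        corr, groups = subpop.enrichment_correlation_clusters(enr, n_groups=2)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert groups["s1"] == groups["s2"] != groups["s3"]

    def test_planted_archetypes_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        enr, truth = self._planted_enrichment()
        _, groups = subpop.enrichment_correlation_clusters(enr, n_groups=3)
        assert adjusted_rand_score(truth[groups.index], groups) >= 0.9

    def test_pathway_permutation_invariance(self):
        enr, _ = self._planted_enrichment(seed=3)
        perm = np.random.default_rng(1).permutation(enr.shape[1])
        _, g1 = subpop.enrichment_correlation_clusters(enr, n_groups=3)
        _, g2 = subpop.enrichment_correlation_clusters(
            enr.iloc[:, perm], n_groups=3
        )
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(g1, g2) == 1.0

    def test_no_significant_pathways_raises(self):
        enr = pd.DataFrame(np.full((3, 5), 0.5))
        with pytest.raises(ValueError, match="no significant"):
            subpop.enrichment_correlation_clusters(enr)

    def test_constant_profile_excluded_with_warning(self):
        enr = pd.DataFrame(
            [[1e-6, 0.5, 0.9], [1e-3, 0.7, 0.2], [0.04, 0.04, 0.04]],
            index=["s1", "s2", "flat"],
        )
        with pytest.warns(UserWarning, match="constant"):
            corr, groups = subpop.enrichment_correlation_clusters(
                enr, n_groups=2
            )
        assert "flat" not in groups.index


class TestCelltypeSampleCorrelation:
    def test_duplicated_sample_correlates_perfectly(self):
        spec = [
            ClusterSpec("p1", 0.25, sample="S1", cell_type="Plasma"),
            ClusterSpec("p2", 0.25, sample="S2", cell_type="Plasma"),
            ClusterSpec("b1", 0.25, sample="S1", cell_type="B"),
            ClusterSpec("b2", 0.25, sample="S2", cell_type="B"),
        ]
        prog = Program("M", 40, 5.0, ("p1", "p2"))
        adata = syndata.gen_expression(spec, 400, 300, [prog], seed=6)
        # duplicate S1 plasma cells under a new sample name
        dup = adata[(adata.obs["sample"] == "S1")].copy()
        dup.obs["sample"] = "S1copy"
        dup.obs_names = [f"{n}_dup" for n in dup.obs_names]
        import anndata as ad

        combined = ad.concat([adata, dup])
        combined.obs["cell_type"] = list(adata.obs["cell_type"]) + list(
            dup.obs["cell_type"]
        )
        norm = subpop.normalize_log(combined)
        out = subpop.celltype_sample_correlation(norm)
        assert out["Plasma"].loc["S1", "S1copy"] == pytest.approx(1.0)

    def test_archetype_structure_recovered(self):
        """Samples sharing an expression archetype correlate more with
        each other than with the other archetype."""
        specs, progs = [], []
        for arch_i, fold_clusters in enumerate([("S1", "S2"), ("S3", "S4")]):
            for s in fold_clusters:
                specs.append(ClusterSpec(f"c{s}", 0.25, sample=s,
                                         cell_type="Plasma"))
            progs.append(Program(f"P{arch_i}", 50, 6.0,
                                 tuple(f"c{s}" for s in fold_clusters)))
        adata = syndata.gen_expression(specs, 600, 400, progs, seed=8)
        norm = subpop.normalize_log(adata)
        # correlate samples over per-sample mean expression of the two
        # planted programs
        prog_genes = adata.var_names[adata.var["program"] != ""]
        profiles = {
            s: np.asarray(
                norm[norm.obs["sample"] == s][:, prog_genes].X.mean(axis=0)
            ).ravel()
            for s in ("S1", "S2", "S3", "S4")
        }
        r = pd.DataFrame(profiles).corr()
        assert r.loc["S1", "S2"] > r.loc["S1", "S3"]
        assert r.loc["S3", "S4"] > r.loc["S2", "S4"]

    def test_single_sample_raises(self, planted_norm):
        with pytest.raises(ValueError, match="two samples"):
            subpop.celltype_sample_correlation(planted_norm)


def make_profile(name, centroid, cnv, sample="S", n=10):
    return SubpopulationProfile(
        sample=sample, subcluster=name, n_cells=n,
        centroid=pd.Series(centroid, dtype=float), cnv_categories=cnv,
    )


class TestMatchSubpopulations:
    cnv_a = {"chr1": 2, "chr13": 1}
    cnv_b = {"chr1": 2, "chr13": 2}

    def test_identical_sets_all_stable_similarity_one(self):
        rng = np.random.default_rng(0)
        profs = [
            make_profile("a", rng.random(20), self.cnv_a),
            make_profile("b", rng.random(20), self.cnv_b),
        ]
        res = subpop.match_subpopulations(profs, profs)
        assert (res.patterns["pattern"] == "stable").all()
        assert np.allclose(res.matches["similarity"], 1.0)

    def test_novel_profile_gained(self):
        rng = np.random.default_rng(1)
        t1 = [make_profile("a", rng.random(20), self.cnv_a)]
        novel = make_profile("new", -t1[0].centroid.to_numpy(),
                             {"chr1": 4, "chr13": 4})
        res = subpop.match_subpopulations(t1, t1 + [novel])
        assert res.pattern_of("t2", novel.id) == "gained"
        assert res.pattern_of("t1", t1[0].id) == "stable"

    def test_swap_symmetry_maps_gained_to_lost(self):
        rng = np.random.default_rng(2)
        t1 = [make_profile("a", rng.random(20), self.cnv_a)]
        t2 = t1 + [make_profile("new", rng.random(20) * -1,
                                {"chr1": 0, "chr13": 4})]
        fwd = subpop.match_subpopulations(t1, t2)
        rev = subpop.match_subpopulations(t2, t1)
        assert fwd.pattern_of("t2", "S/new") == "gained"
        assert rev.pattern_of("t1", "S/new") == "lost"
        assert fwd.pattern_of("t1", "S/a") == rev.pattern_of("t2", "S/a") \
            == "stable"

    def test_empty_side_all_gained_or_lost(self):
        rng = np.random.default_rng(3)
        t2 = [make_profile("a", rng.random(10), self.cnv_a)]
        res = subpop.match_subpopulations([], t2)
        assert (res.patterns["pattern"] == "gained").all()
        res2 = subpop.match_subpopulations(t2, [])
        assert (res2.patterns["pattern"] == "lost").all()

    def test_planted_scenario_recovered(self):
        adata, cnv, expected = syndata.gen_tracking_scenario(seed=5)
        norm = subpop.normalize_log(adata)
        panel = list(adata.var_names[adata.var["program"] != ""])
        profiles = {}
        for tp, sample in ((0, "T1"), (1, "T2")):
            sub = norm[norm.obs["timepoint"] == tp]
            profiles[sample] = subpop.profiles_from_anndata(
                sub, "cluster", panel, cnv, sample=sample
            )
        res = subpop.match_subpopulations(profiles["T1"], profiles["T2"])
        for (tp, pid), pattern in expected.items():
            assert res.pattern_of(tp, pid) == pattern


class TestQcStratifiedCheck:
    def test_absent_gene_set_all_zero(self, planted_norm):
        means, _ = subpop.qc_stratified_check(
            planted_norm, {"NOT_A_GENE"}, ngene_thresh=100,
            cell_type_col="cluster",
        )
        assert (means["mean_expression"] == 0).all()

    def test_program_elevated_only_in_planted_type_both_strata(self):
        """The planted program is elevated in the plasma cluster in both
        gene-count strata, and in neither stratum elsewhere."""
        spec = [ClusterSpec("plasma", 0.5, cell_type="Plasma"),
                ClusterSpec("tcell", 0.5, cell_type="T")]
        prog = Program("AP1", 40, 5.0, ("plasma",))
        adata = syndata.gen_expression(spec, 500, 300, [prog], seed=12)
        norm = subpop.normalize_log(adata)
        gene_set = set(adata.var_names[adata.var["program"] == "AP1"])
        thresh = int(adata.obs["n_genes"].median())
        means, _ = subpop.qc_stratified_check(
            norm, gene_set, ngene_thresh=thresh
        )
        table = means.pivot(index="cell_type", columns="stratum",
                            values="mean_expression")
        for stratum in table.columns:
            assert table.loc["Plasma", stratum] > 1.5 * table.loc["T", stratum]

    def test_single_stratum_missing_no_crash(self, planted_norm):
        with pytest.warns(UserWarning, match="empty stratum"):
            means, stats_df = subpop.qc_stratified_check(
                planted_norm, set(planted_norm.var_names[:5]),
                ngene_thresh=10_000, cell_type_col="cluster",
            )
        assert stats_df["pval"].isna().all()

    def test_empty_gene_set_raises(self, planted_norm):
        with pytest.raises(ValueError):
            subpop.qc_stratified_check(planted_norm, set())
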