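import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from phenoscreen import profiles as prof
from phenoscreen.calls import StrainSummary
from phenoscreen.core_data import default_taxonomy
from phenoscreen.errors import InsufficientDataError
from tests._oracles import fisher_greater, hypergeom_upper_tail


def make_summary(gene, marker, fractions, taxonomy):
    wt = taxonomy.wild_type_class[marker]
    all_fracs = dict(fractions)
    all_fracs[wt] = 1.0 - sum(fractions.values())
    return StrainSummary(
        strain_id=gene, allele_id="a1", marker=marker, condition="30C",
        screen_type="combined", n_good_cells=100,
        class_fractions=all_fracs,
        class_counts={c: int(100 * f) for c, f in all_fracs.items()},
        penetrance=100.0 * (1 - all_fracs[wt]),
    )


class TestBuildProfiles:
    def full_gene(self, gene, taxonomy, level=0.1):
        return [
            make_summary(gene, m, {taxonomy.classes_of(m)[1]: level}, taxonomy)
            for m in taxonomy.markers
        ]

    def test_allele_averaging(self, taxonomy):
        summaries = self.full_gene("g1", taxonomy, 0.2)
        # second allele of g1 with a different vacuole fraction
        extra = [make_summary("g1", "vacuole", {"vac_enlarged": 0.4}, taxonomy)]
        profs, _ = prof.build_profiles(summaries + extra, taxonomy=taxonomy)
        assert profs.loc["g1", "vac_enlarged"] == pytest.approx(0.3)  # mean(0.2, 0.4)

    def test_incomplete_gene_excluded(self, taxonomy):
        summaries = self.full_gene("g1", taxonomy) + self.full_gene("g2", taxonomy)[:3]
        profs, incomplete = prof.build_profiles(summaries, taxonomy=taxonomy)
        assert list(profs.index) == ["g1"]
        assert incomplete == ["g2"]

    def test_single_allele_identity_and_shape(self, taxonomy):
        profs, _ = prof.build_profiles(self.full_gene("g1", taxonomy, 0.25), taxonomy=taxonomy)
        assert profs.shape == (1, 17)
        assert list(profs.columns) == list(taxonomy.aberrant_classes)
        assert profs.loc["g1", "vac_enlarged"] == pytest.approx(0.25)
        assert ((profs >= 0) & (profs <= 1)).all().all()


class TestProfileCorrelations:
    def test_identical_profiles_correlate_perfectly(self):
        base = np.linspace(0.0, 0.5, 17)
        profs = pd.DataFrame([base, base], index=["g1", "g2"])
        pcc = prof.profile_correlations(profs)
        assert pcc.loc["g1", "g2"] == pytest.approx(1.0)

    def test_anti_ranked_profiles_anticorrelate(self):
        profs = pd.DataFrame(
            [np.arange(1.0, 18.0), np.arange(17.0, 0.0, -1.0)], index=["g1", "g2"]
        )
        assert prof.profile_correlations(profs).loc["g1", "g2"] == pytest.approx(-1.0)

    def test_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        profs = pd.DataFrame(rng.random((6, 17)), index=[f"g{i}" for i in range(6)])
        pcc = prof.profile_correlations(profs)
        np.testing.assert_allclose(pcc, pcc.T)
        np.testing.assert_allclose(np.diag(pcc), 1.0)

    def test_zero_variance_profile_missing_with_warning(self):
        rng = np.random.default_rng(1)
        profs = pd.DataFrame(
            np.vstack([np.full(17, 0.2), rng.random((2, 17))]),
            index=["flat", "g1", "g2"],
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            pcc = prof.profile_correlations(profs)
        assert pcc.loc["flat", "g1"] != pcc.loc["flat", "g1"]  # NaN
        assert np.isfinite(pcc.loc["g1", "g2"])

    def test_single_profile_rejected(self):
        with pytest.raises(InsufficientDataError):
            prof.profile_correlations(pd.DataFrame([np.arange(17.0)]))


def planted_block_profiles(seed=2, n_per_block=6, noise=0.02):
    rng = np.random.default_rng(seed)
    shape_a = np.concatenate([np.full(8, 0.4), np.full(9, 0.05)])
    shape_b = np.concatenate([np.full(8, 0.05), np.full(9, 0.4)])
    rows, names, blocks = [], [], []
    for i in range(n_per_block):
        rows.append(shape_a + rng.normal(0, noise, 17))
        names.append(f"a{i}")
        blocks.append("A")
    for i in range(n_per_block):
        rows.append(shape_b + rng.normal(0, noise, 17))
        names.append(f"b{i}")
        blocks.append("B")
    return pd.DataFrame(rows, index=names), np.array(blocks)


class TestClusterProfiles:
    def test_top_split_separates_planted_blocks(self):
        profs, blocks = planted_block_profiles()
        pcc = prof.profile_correlations(profs)
        _, labels = prof.cluster_profiles(pcc, n_clusters=2)
        # same planted block <=> same cluster label
        a_labels = set(labels[blocks == "A"])
        b_labels = set(labels[blocks == "B"])
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels

    def test_input_order_invariance(self):
        profs, _ = planted_block_profiles()
        pcc = prof.profile_correlations(profs)
        perm = np.random.default_rng(3).permutation(len(pcc))
        pcc_perm = pcc.iloc[perm, perm]
        _, labels = prof.cluster_profiles(pcc, n_clusters=2)
        _, labels_perm = prof.cluster_profiles(pcc_perm, n_clusters=2)
        memb = {g: l for g, l in zip(pcc.index, labels)}
        memb_perm = {g: l for g, l in zip(pcc_perm.index, labels_perm)}
        same = {(a, b): memb[a] == memb[b] for a in memb for b in memb}
        same_perm = {(a, b): memb_perm[a] == memb_perm[b] for a in memb for b in memb}
        assert same == same_perm

    def test_single_profile_trivial_tree(self):
        Z, labels = prof.cluster_profiles(pd.DataFrame([[1.0]], index=["g"], columns=["g"]))
        assert Z.shape == (0, 4)
        assert list(labels) == [1]

    def test_newick_export_parses(self):
        from Bio import Phylo

        profs, _ = planted_block_profiles()
        pcc = prof.profile_correlations(profs)
        Z, _ = prof.cluster_profiles(pcc)
        nwk = prof.linkage_to_newick(Z, list(pcc.index))
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == set(pcc.index)


class TestPhenotypePairOverlap:
    def test_identical_sets_highly_significant(self):
        universe = {f"g{i}" for i in range(300)}
        shared = {f"g{i}" for i in range(15)}
        out = prof.phenotype_pair_overlap({"p1": shared, "p2": set(shared)}, universe)
        row = out.iloc[0]
        assert row["p"] < 1e-6
        assert row["significant"]

    def test_disjoint_sets_not_significant(self):
        universe = {f"g{i}" for i in range(40)}
        out = prof.phenotype_pair_overlap(
            {"p1": {f"g{i}" for i in range(20)}, "p2": {f"g{i}" for i in range(20, 40)}},
            universe,
        )
        row = out.iloc[0]
        assert row["p"] >= 0.5
        assert not row["significant"]

    def test_specific_table_matches_enumeration_oracle(self):
        # [[5, 2], [3, 90]]: 5 shared, 2 only in A, 3 only in B, 90 in neither
        universe = {f"g{i}" for i in range(100)}
        set_a = {f"g{i}" for i in range(7)}               # 5 shared + 2
        set_b = {f"g{i}" for i in range(5)} | {"g7", "g8", "g9"}
        out = prof.phenotype_pair_overlap({"a": set_a, "b": set_b}, universe)
        assert out.iloc[0]["p"] == pytest.approx(float(fisher_greater(5, 2, 3, 90)), rel=1e-9)

    def test_empty_set_skipped(self):
        universe = {"g1", "g2"}
        out = prof.phenotype_pair_overlap({"a": {"g1"}, "b": set()}, universe)
        assert len(out) == 0

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=3, max_size=30))
    @settings(deadline=None, max_examples=30)
    def test_bh_qvalues_monotone_in_sorted_p_order(self, pvals):
        q = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRandomizedEnrichment:
    def setup_standard(self, n_universe=400, seed=4):
        universe = {f"g{i}" for i in range(n_universe)}
        planted = {f"g{i}" for i in range(8)}
        standard = {"planted": set(planted)}
        rng = np.random.default_rng(seed)
        pool = sorted(universe - planted)
        for j in range(10):
            standard[f"decoy_{j}"] = set(rng.choice(pool, size=8, replace=False))
        return universe, planted, standard

    def test_planted_complex_detected_decoys_not(self):
        universe, planted, standard = self.setup_standard()
        hits = set(planted)
        out = prof.randomized_enrichment({"phen": hits}, standard, universe, n_rand=300, seed=5)
        by_term = out.set_index("term")
        assert by_term.loc["planted", "significant"]
        assert by_term.loc["planted", "P1"] == 8
        decoys = by_term[by_term.index.str.startswith("decoy")]
        assert not decoys["significant"].any()

    def test_null_hit_set_calibrated(self):
        universe, _, standard = self.setup_standard(seed=6)
        rng = np.random.default_rng(7)
        random_hits = set(rng.choice(sorted(universe), size=20, replace=False))
        out = prof.randomized_enrichment({"phen": random_hits}, standard, universe, n_rand=300, seed=8)
        assert out["significant"].mean() <= 0.1

    def test_pair_mode_requires_two_shared_components(self):
        universe = {f"g{i}" for i in range(50)}
        standard = {"c1": {"g0", "g1", "g2"}}
        hits = {"g0"}  # only 1 shared member
        out = prof.randomized_enrichment(
            {"pair": hits}, standard, universe, n_rand=100, seed=9, pair_mode=True
        )
        assert not out["significant"].any()

    def test_degree_preserving_scheme_mixes_across_phenotypes(self):
        # with >= 2 phenotypes the degree-preserving swap redistributes genes
        # between hit sets, so a planted complex concentrated in one
        # phenotype stands out against the null
        universe, planted, standard = self.setup_standard()
        rng = np.random.default_rng(10)
        other = set(rng.choice(sorted(universe - planted), size=12, replace=False))
        out = prof.randomized_enrichment(
            {"phen": set(planted), "other": other}, standard, universe,
            n_rand=200, seed=10, scheme="degree_preserving",
        )
        by = out.set_index(["phenotype", "term"])
        assert by.loc[("phen", "planted"), "significant"]
        # hit-set sizes are preserved by the scheme: observed overlap of the
        # full planted set can never be exceeded in the null
        assert by.loc[("phen", "planted"), "P1"] == 8
        assert by.loc[("phen", "planted"), "rnd_p95"] < 8


class TestGoEnrichment:
    def test_fold_formula(self):
        universe = {f"g{i}" for i in range(1000)}
        hits = {f"g{i}" for i in range(100)}
        term = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(500, 510)}
        out = prof.go_enrichment(hits, {"t": term}, universe)
        # 10 hits in a 20-gene term: (10/100)/(20/1000) = 5
        assert out.iloc[0]["fold"] == pytest.approx(5.0)

    def test_saturated_hits_fold_one(self):
        universe = {f"g{i}" for i in range(50)}
        standard = {"t1": {f"g{i}" for i in range(10)}, "t2": {f"g{i}" for i in range(20, 30)}}
        out = prof.go_enrichment(set(universe), standard, universe)
        np.testing.assert_allclose(out["fold"], 1.0)

    def test_p_matches_exhaustive_tail(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(6)}
        term = {f"g{i}" for i in range(4)} | {"g10"}
        out = prof.go_enrichment(hits, {"t": term}, universe)
        oracle = float(hypergeom_upper_tail(4, 20, 5, 6))
        assert out.iloc[0]["p"] == pytest.approx(oracle, rel=1e-10)

    def test_term_outside_universe_skipped(self):
        out = prof.go_enrichment({"g1"}, {"t": {"x1", "x2"}}, {"g1", "g2"})
        assert len(out) == 0


class TestGeneFeatureTests:
    def test_shifted_numeric_feature_detected(self):
        rng = np.random.default_rng(11)
        hits = [f"h{i}" for i in range(100)]
        nonhits = [f"n{i}" for i in range(100)]
        panel = {g: rng.normal(2.0, 1.0) for g in hits}
        panel.update({g: rng.normal(0.0, 1.0) for g in nonhits})
        out = prof.gene_feature_tests(hits, nonhits, numeric_panels={"abundance": panel})
        row = out.iloc[0]
        assert row["p"] < 0.001
        assert row["statistic"] == pytest.approx(2.0, abs=0.5)

    def test_identical_distributions_near_zero_z(self):
        rng = np.random.default_rng(12)
        hits = [f"h{i}" for i in range(150)]
        nonhits = [f"n{i}" for i in range(150)]
        panel = {g: rng.normal() for g in hits + nonhits}
        out = prof.gene_feature_tests(hits, nonhits, numeric_panels={"f": panel})
        assert abs(out.iloc[0]["statistic"]) < 0.3
        assert out.iloc[0]["p"] > 0.01

    def test_binary_equal_fractions_zero_log_fold(self):
        hits = [f"h{i}" for i in range(40)]
        nonhits = [f"n{i}" for i in range(40)]
        panel = {g: (int(g[1:]) % 2 == 0) for g in hits + nonhits}
        out = prof.gene_feature_tests(hits, nonhits, binary_panels={"dup": panel})
        assert out.iloc[0]["statistic"] == pytest.approx(0.0)
        assert out.iloc[0]["p"] > 0.5

    def test_missing_panel_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="no data"):
            out = prof.gene_feature_tests(["h"], ["n"], numeric_panels={"f": {}})
        assert len(out) == 0


class TestCategoryPccComparison:
    def test_planted_within_vs_cross_blocks(self):
        profs, blocks = planted_block_profiles(n_per_block=8)
        pcc = prof.profile_correlations(profs)
        names = list(profs.index)
        within, cross = [], []
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                (within if a[0] == b[0] else cross).append((a, b))
        values, tests = prof.category_pcc_comparison(
            pcc, {"within": within, "cross": cross}
        )
        assert np.median(values["within"]) > np.median(values["cross"])
        assert tests.iloc[0]["p"] < 0.01

    def test_identical_categories_null(self):
        rng = np.random.default_rng(13)
        profs = pd.DataFrame(rng.random((10, 17)), index=[f"g{i}" for i in range(10)])
        pcc = prof.profile_correlations(profs)
        pairs = [(f"g{i}", f"g{j}") for i in range(10) for j in range(i + 1, 10)]
        values, tests = prof.category_pcc_comparison(
            pcc, {"a": pairs, "b": list(pairs)}, alternative="two-sided"
        )
        assert tests.iloc[0]["p"] == pytest.approx(1.0, abs=0.5)

    def test_sparse_category_skipped(self):
        profs = pd.DataFrame(
            np.random.default_rng(14).random((4, 17)), index=list("wxyz")
        )
        pcc = prof.profile_correlations(profs)
        with pytest.warns(UserWarning, match="skipped"):
            values, _ = prof.category_pcc_comparison(
                pcc, {"ok": [("w", "x"), ("y", "z")], "empty": []}
            )
        assert "empty" not in values


class TestStandardsIO:
    def test_term_standard_round_trip(self, tmp_path):
        path = tmp_path / "complexes.tsv"
        path.write_text("c1\tg1\nc1\tg2\nc2\tg3\n")
        std = prof.load_term_standard(path)
        assert std == {"c1": {"g1", "g2"}, "c2": {"g3"}}

    def test_value_standard_round_trip(self, tmp_path):
        path = tmp_path / "smf.tsv"
        path.write_text("g1\t0.95\ng2\t0.4\n")
        vals = prof.load_value_standard(path)
        assert vals == {"g1": 0.95, "g2": 0.4}
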