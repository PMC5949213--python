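import numpy as np
import pandas as pd
import pytest

from oracles import bf_auc
from phenorank.evaluation import (
    bias_correlations,
    bias_features,
    loo_cross_validation,
    roc_auc,
    stratified_cv,
    tune_restart_probability,
)
from phenorank.prioritize import RunConfig


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_identical_scores_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_six_point_example_matches_pairwise_oracle(self):
        labels = [1, 0, 1, 0, 1, 0]
        scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.2]
        assert roc_auc(labels, scores) == pytest.approx(bf_auc(labels, scores))

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(10):
            labels = rng.integers(0, 2, size=20)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(20), 1)
            assert roc_auc(labels, scores) == pytest.approx(bf_auc(labels, scores))


class TestLooCrossValidation:
    def test_planted_gene_recovered_above_median(self, default_dataset):
        ds = default_dataset
        trials = ds.ground_truth[:3]
        cfg = RunConfig(n_sets=100, rng_seed=2)
        outcomes, auc = loo_cross_validation(
            ds.db, ds.network, ds.ontology, cfg, trials
        )
        for trial in outcomes:
            assert trial.masked_gene_rank < trial.n_eligible / 2
        assert auc > 0.5

    def test_eligible_excludes_coassociated_genes(self, default_dataset):
        ds = default_dataset
        # give the first planted disease a second associated gene
        disease, gene = ds.ground_truth[0]
        other = next(
            g for g in ds.network.gene_ids
            if g != gene and disease not in ds.db.gene_to_diseases.get(g, set())
        )
        had_key = other in ds.db.gene_to_diseases
        ds.db.gene_to_diseases.setdefault(other, set()).add(disease)
        try:
            outcomes, _ = loo_cross_validation(
                ds.db, ds.network, ds.ontology,
                RunConfig(mode="no_simulation"), [(disease, gene)],
            )
            assert outcomes[0].n_eligible == ds.network.n - 1
        finally:
            # restore the shared session fixture exactly
            if had_key:
                ds.db.gene_to_diseases[other].discard(disease)
            else:
                del ds.db.gene_to_diseases[other]

    def test_missing_trial_association_errors(self, default_dataset):
        ds = default_dataset
        with pytest.raises(KeyError):
            loo_cross_validation(
                ds.db, ds.network, ds.ontology, RunConfig(mode="no_simulation"),
                [("not_a_disease", ds.network.gene_ids[0])],
            )


class TestBiasFeatures:
    def test_sourceless_gene_has_nan_features_but_degree(self, default_dataset):
        ds = default_dataset
        table = bias_features(ds.db, ds.network, ds.ontology, {"PT:0000005"})
        sourceless = [
            g for g in ds.network.gene_ids
            if not ds.db.gene_to_diseases.get(g) and not ds.db.gene_to_mutants.get(g)
        ]
        assert sourceless, "fixture should contain unannotated genes"
        row = table.loc[sourceless[0]]
        assert np.isfinite(row["degree"])
        assert np.isnan(row["n_phenotype_sources"])
        assert np.isnan(row["median_max_depth"])

    def test_hand_medians(self, diamond_ontology):
        # gene with sources of sizes 3 and 4, query of size 4
        from phenorank.annotations import AssociationDB, PhenotypeSource
        from phenorank.network import PPINetwork

        db = AssociationDB()
        db.diseases["dx"] = PhenotypeSource(
            "dx", "human_disease", frozenset({"T:a", "T:b", "T:c"})
        )
        db.diseases["dy"] = PhenotypeSource(
            "dy", "human_disease", frozenset({"T:a", "T:b", "T:c", "T:root"})
        )
        db.gene_to_diseases["gm"] = {"dx", "dy"}
        net = PPINetwork(["gm", "g_other"], [("gm", "g_other")])
        w_q = {"T:a", "T:b", "T:c", "T:root"}
        table = bias_features(db, net, diamond_ontology, w_q)
        row = table.loc["gm"]
        assert row["degree"] == 1.0
        assert row["n_phenotype_sources"] == 2.0
        assert row["median_n_terms"] == 3.5
        assert row["median_abs_term_diff"] == 0.5
        # depths in the diamond: root 0, b/c 1, a 2 -> max depth 2 per source
        assert row["median_max_depth"] == 2.0

    def test_degree_column_matches_edge_incidence(self, default_dataset):
        ds = default_dataset
        table = bias_features(ds.db, ds.network, ds.ontology, set())
        degrees = dict(zip(ds.network.gene_ids, ds.network.degrees()))
        for g in ds.network.gene_ids[:20]:
            assert table.loc[g, "degree"] == degrees[g]


class TestBiasCorrelations:
    def test_scores_equal_to_degree_correlate_perfectly(self, default_dataset):
        ds = default_dataset
        table = bias_features(ds.db, ds.network, ds.ontology, set())
        rho = bias_correlations(table["degree"].to_numpy(), table)
        assert rho["degree"] == pytest.approx(1.0)

    def test_permuted_feature_uncorrelated(self, default_dataset):
        ds = default_dataset
        table = bias_features(ds.db, ds.network, ds.ontology, set()).copy()
        rng = np.random.default_rng(67)
        scores = rng.permutation(table["degree"].to_numpy())
        rho = bias_correlations(scores, table[["degree"]])
        assert abs(rho["degree"]) < 0.2

    def test_hand_table_matches_rank_formula(self):
        scores = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        feats = pd.DataFrame({"f": [30.0, 10.0, 40.0, 15.0, 50.0]})
        rho = bias_correlations(scores, feats)
        assert rho["f"] == pytest.approx(1.0)  # identical orderings

    def test_constant_feature_flagged_nan(self):
        scores = np.array([1.0, 2.0, 3.0])
        feats = pd.DataFrame({"f": [7.0, 7.0, 7.0]})
        assert np.isnan(bias_correlations(scores, feats)["f"])

    def test_pvalue_scores_sign_flipped(self):
        # smaller p on high-feature genes must give POSITIVE rho after the flip
        p = np.array([0.001, 0.01, 0.1, 0.5, 1.0])
        feats = pd.DataFrame({"f": [50.0, 40.0, 30.0, 20.0, 10.0]})
        rho = bias_correlations(p, feats, scores_are_pvalues=True)
        assert rho["f"] == pytest.approx(1.0)


class TestStratifiedCv:
    def test_strata_sizes_near_equal_and_partition(self, default_dataset):
        ds = default_dataset
        trials = ds.ground_truth  # 10 trials -> strata of 2
        df = stratified_cv(
            ds.db, ds.network, ds.ontology, RunConfig(mode="no_simulation"),
            trials, "degree", 5,
        )
        assert df["n_trials"].tolist() == [2, 2, 2, 2, 2]
        assert df["n_trials"].sum() == len(trials)
        # quantile boundaries: key ranges are non-decreasing across strata
        assert list(df["key_min"]) == sorted(df["key_min"])
        assert all(df["key_min"] <= df["key_max"])

    def test_too_few_trials_errors(self, default_dataset):
        ds = default_dataset
        with pytest.raises(ValueError):
            stratified_cv(
                ds.db, ds.network, ds.ontology, RunConfig(mode="no_simulation"),
                ds.ground_truth[:3], "degree", 5,
            )


class TestTuneRestartProbability:
    def test_overlapping_splits_rejected(self, default_dataset):
        ds = default_dataset
        trials = ds.ground_truth[:4]
        with pytest.raises(ValueError, match="disjoint"):
            tune_restart_probability(
                ds.db, ds.network, ds.ontology, RunConfig(mode="no_simulation"),
                [0.1, 0.5], trials[:2], trials[1:],
            )

    def test_grid_search_returns_best_r(self, default_dataset):
        ds = default_dataset
        best_r, grid = tune_restart_probability(
            ds.db, ds.network, ds.ontology, RunConfig(mode="no_simulation"),
            [0.1, 0.9], ds.ground_truth[:4], ds.ground_truth[4:],
        )
        assert set(grid["r"]) == {0.1, 0.9}
        assert best_r == grid.loc[grid["auc"].idxmax(), "r"]
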