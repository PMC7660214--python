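"""Population-graph construction: kernel, phenotype matching, baselines."""

import numpy as np
import pytest
from scipy import stats

import popgse as pg
from popgse.graphs import GraphConfigError, load_graph, save_graph, export_edge_list


class TestRsfcSimilarity:
    def test_identical_vectors_have_similarity_one(self, rng):
        x = rng.normal(size=20)
        assert pg.rsfc_similarity(x, x.copy(), sigma=1.0) == pytest.approx(1.0)

    def test_perfect_anticorrelation_matches_kernel_formula(self, rng):
        x = rng.normal(size=30)
        y = -x + 3.0
        # rho = 1 - (-1) = 2, independently confirmed via scipy
        rho = 1.0 - stats.pearsonr(x, y).statistic
        assert rho == pytest.approx(2.0)
        assert pg.rsfc_similarity(x, y, sigma=1.0) == pytest.approx(np.exp(-2.0))

    def test_constant_vector_convention_is_zero(self, rng):
        x = np.full(10, 0.3)
        y = rng.normal(size=10)
        assert pg.rsfc_similarity(x, y, sigma=1.0) == 0.0

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert pg.rsfc_similarity(x, y, 0.7) == pytest.approx(pg.rsfc_similarity(y, x, 0.7))

    def test_pairwise_matrix_matches_pairwise_calls(self, rng):
        X = rng.normal(size=(6, 12))
        S = pg.pairwise_rsfc_similarity(X, sigma=0.9)
        for i in range(6):
            for j in range(6):
                assert S[i, j] == pytest.approx(
                    pg.rsfc_similarity(X[i], X[j], 0.9), abs=1e-12
                )


class TestPhenotypeMatch:
    def test_counts_agreeing_features(self):
        vi = {"site": 3, "sex": 1, "age": 7.0}
        vj = {"site": 3, "sex": 1, "age": 40.0}
        assert pg.phenotype_match_count(vi, vj, ("site", "sex")) == 2
        edges = tuple(np.arange(5.0, 60.0, 5.0))
        assert pg.phenotype_match_count(vi, vj, ("site", "sex", "age"), edges) == 2
        assert pg.phenotype_match_count({"site": 1, "sex": 0, "age": 7.0},
                                        {"site": 2, "sex": 1, "age": 40.0},
                                        ("site", "sex", "age"), edges) == 0

    def test_age_binning_groups_nearby_ages(self):
        edges = tuple(np.arange(5.0, 60.0, 5.0))  # [5,10), [10,15), ...
        assert pg.phenotype_match_count(
            {"age": 7.0}, {"age": 9.0}, ("age",), edges
        ) == 1
        assert pg.phenotype_match_count(
            {"age": 9.0}, {"age": 11.0}, ("age",), edges
        ) == 0

    def test_missing_value_matches_nothing(self):
        assert pg.phenotype_match_count({"site": None}, {"site": None}, ("site",)) == 0


class TestBuildPopulationGraph:
    def test_cross_site_weight_vanishes_despite_similarity(self, small_cohort, small_features):
        config = pg.GraphConfig(use_rsfc=True, phenotype_features=("site",))
        graph = pg.build_population_graph(small_features, small_cohort, config)
        sites = small_cohort.phenotypes["site"].to_numpy()
        differ = sites[:, None] != sites[None, :]
        assert np.all(graph.weights[differ] == 0.0)

    def test_rsfc_weights_match_bruteforce_kernel(self, rng):
        X = rng.normal(size=(3, 10))
        cohort = pg.generate_cohort(pg.SimulationParams(n_patients=2, n_controls=1, r=5, seed=0))
        graph = pg.build_population_graph(X, cohort, pg.GraphConfig(use_rsfc=True), sigma=0.8)
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else pg.rsfc_similarity(X[i], X[j], 0.8)
                assert graph.weights[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetry_for_every_config(self, small_cohort, small_features):
        for config in pg.enumerate_graph_configs(include_baselines=True):
            graph = pg.build_population_graph(small_features, small_cohort, config)
            assert np.abs(graph.weights - graph.weights.T).max() < 1e-10
            assert np.all(np.diagonal(graph.weights) == 0.0)

    def test_product_factorization(self, small_cohort, small_features):
        """Combined graphs equal the elementwise product of their factors."""
        sigma = 1.0
        rsfc = pg.build_population_graph(
            small_features, small_cohort, pg.GraphConfig(use_rsfc=True), sigma=sigma
        )
        for subset in [("site",), ("sex", "age"), ("site", "sex", "age")]:
            pheno = pg.build_population_graph(
                small_features, small_cohort, pg.GraphConfig(phenotype_features=subset)
            )
            both = pg.build_population_graph(
                small_features,
                small_cohort,
                pg.GraphConfig(use_rsfc=True, phenotype_features=subset),
                sigma=sigma,
            )
            assert np.abs(both.weights - rsfc.weights * pheno.weights).max() < 1e-12

    def test_match_counts_monotone_in_feature_set(self, small_cohort, small_features):
        smaller = pg.build_population_graph(
            small_features, small_cohort, pg.GraphConfig(phenotype_features=("site",))
        )
        larger = pg.build_population_graph(
            small_features, small_cohort, pg.GraphConfig(phenotype_features=("site", "sex"))
        )
        assert np.all(larger.weights >= smaller.weights)
        # phenotype-only weights are integer match counts in [0, H]
        assert np.all(larger.weights == np.round(larger.weights))
        assert larger.weights.max() <= 2

    def test_subject_permutation_equivariance(self, small_cohort, small_features):
        config = pg.GraphConfig(use_rsfc=True, phenotype_features=("sex",))
        graph = pg.build_population_graph(small_features, small_cohort, config, sigma=1.0)
        perm = np.random.default_rng(0).permutation(small_cohort.n)
        shuffled = pg.Cohort(
            subject_ids=[small_cohort.subject_ids[i] for i in perm],
            rsfc=small_cohort.rsfc[perm],
            phenotypes=small_cohort.phenotypes.iloc[perm],
            labels=small_cohort.labels[perm],
        )
        graph_p = pg.build_population_graph(
            pg.vectorize_rsfc(shuffled), shuffled, config, sigma=1.0
        )
        assert np.allclose(graph_p.weights, graph.weights[np.ix_(perm, perm)], atol=1e-12)

    def test_invalid_configs_rejected(self, small_cohort, small_features):
        with pytest.raises(GraphConfigError):
            pg.GraphConfig().validate()
        with pytest.raises(GraphConfigError):
            pg.GraphConfig(baseline_kind="fc", use_rsfc=True).validate()
        with pytest.raises(GraphConfigError):
            pg.build_population_graph(small_features, small_cohort, pg.GraphConfig())


class TestBaselines:
    def test_fully_connected_unit_edges(self):
        graph = pg.build_baseline_graph("fc", 4)
        assert int(graph.weights.sum() / 2) == 6
        assert set(np.unique(graph.weights)) == {0.0, 1.0}

    def test_density_one_equals_fully_connected(self):
        random = pg.build_baseline_graph("random", 7, density=1.0, seed=5)
        fc = pg.build_baseline_graph("fc", 7)
        assert np.array_equal(random.weights, fc.weights)

    def test_random_edge_count_in_binomial_band(self):
        graph = pg.build_baseline_graph("random", 100, density=0.1, seed=11)
        edges = int(graph.weights.sum() / 2)
        n_pairs = 100 * 99 // 2
        lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, 0.1)
        assert lo <= edges <= hi

    def test_identity_graph_is_edgeless(self):
        graph = pg.build_baseline_graph("identity", 5)
        assert np.all(graph.weights == 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(GraphConfigError):
            pg.build_baseline_graph("mesh", 5)


class TestEnumerateConfigs:
    def test_fifteen_similarity_configs(self):
        configs = pg.enumerate_graph_configs(include_baselines=False)
        assert len(configs) == 15
        phenotype_only = [c for c in configs if not c.use_rsfc]
        assert len(phenotype_only) == 7
        assert len([c for c in configs if c.use_rsfc and c.phenotype_features]) == 7

    def test_eighteen_with_baselines_and_unique_names(self):
        configs = pg.enumerate_graph_configs(include_baselines=True)
        assert len(configs) == 18
        names = [c.name for c in configs]
        assert len(set(names)) == 18
        assert names[0] == "sim_RSFC"
        assert {"fc", "identity", "random"} <= set(names)


class TestGraphIO:
    @pytest.mark.parametrize("suffix,fmt", [(".csv", "csv"), (".h5", "hdf5")])
    def test_round_trip_with_sidecar(self, tmp_path, small_cohort, small_features, suffix, fmt):
        config = pg.GraphConfig(use_rsfc=True, phenotype_features=("sex",))
        graph = pg.build_population_graph(small_features, small_cohort, config)
        path = save_graph(graph, tmp_path / f"g{suffix}", fmt=fmt)
        loaded = load_graph(path)
        assert np.allclose(loaded.weights, graph.weights)
        assert loaded.config == config
        assert loaded.subject_ids == graph.subject_ids

    def test_edge_list_export(self, tmp_path):
        import pandas as pd

        graph = pg.build_baseline_graph("random", 10, density=0.3, seed=1)
        path = export_edge_list(graph, tmp_path / "edges.tsv")
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == int(graph.weights.sum() / 2)
        assert set(frame.columns) == {"subject_i", "subject_j", "weight"}
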