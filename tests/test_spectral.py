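"""Laplacian, graph Fourier transform, filtering and regime diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse.csgraph import connected_components
import scipy.sparse

import popgse as pg
from popgse.spectral import HIGH_FREQUENCY, LOW_FREQUENCY, LowPassFilter


def random_graph_adjacency(rng, n, density=0.3, weighted=True):
    upper = rng.random((n, n)) < density
    W = np.triu(upper, k=1).astype(float)
    if weighted:
        W *= rng.uniform(0.1, 2.0, size=W.shape)
    return W + W.T


class TestLaplacian:
    def test_path_graph_textbook_matrix(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        L = pg.combinatorial_laplacian(A)
        assert np.array_equal(L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_weighted_two_node_graph(self):
        A = np.array([[0, 0.5], [0.5, 0]])
        assert np.array_equal(
            pg.combinatorial_laplacian(A), [[0.5, -0.5], [-0.5, 0.5]]
        )

    def test_identity_baseline_gives_zero_laplacian(self):
        graph = pg.build_baseline_graph("identity", 6)
        assert np.all(pg.combinatorial_laplacian(graph) == 0.0)

    def test_rows_sum_to_zero_and_psd(self, rsfc_graph):
        L = pg.combinatorial_laplacian(rsfc_graph)
        assert np.abs(L.sum(axis=1)).max() < 1e-10
        assert np.linalg.eigvalsh(L).min() > -1e-8


class TestEigendecompose:
    def test_two_node_unit_edge_spectrum(self):
        basis = pg.eigendecompose(pg.combinatorial_laplacian(np.array([[0.0, 1], [1, 0]])))
        assert np.allclose(basis.eigenvalues, [0.0, 2.0])

    def test_complete_graph_spectrum(self):
        A = np.ones((3, 3)) - np.eye(3)
        basis = pg.eigendecompose(pg.combinatorial_laplacian(A))
        assert np.allclose(basis.eigenvalues, [0.0, 3.0, 3.0])

    def test_disconnected_barbell_has_two_zero_modes(self):
        A, _ = pg.generate_barbell_fixture(5, 0)
        basis = pg.eigendecompose(pg.combinatorial_laplacian(A))
        assert np.sum(np.abs(basis.eigenvalues) < 1e-8) == 2

    def test_reconstructs_laplacian(self, rsfc_basis, rsfc_graph):
        L = pg.combinatorial_laplacian(rsfc_graph)
        rebuilt = rsfc_basis.eigenvectors @ np.diag(rsfc_basis.eigenvalues) @ rsfc_basis.eigenvectors.T
        assert np.linalg.norm(rebuilt - L) / np.linalg.norm(L) < 1e-6

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValueError):
            pg.eigendecompose(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_zero_multiplicity_counts_components(self, rng):
        """Zero-eigenvalue multiplicity equals component count (union-find oracle)."""
        for trial in range(100):
            n = int(rng.integers(3, 25))
            A = random_graph_adjacency(rng, n, density=rng.uniform(0.05, 0.5))
            n_components, _ = connected_components(scipy.sparse.csr_matrix(A), directed=False)
            basis = pg.eigendecompose(pg.combinatorial_laplacian(A))
            assert np.sum(basis.eigenvalues < 1e-8) == n_components


class TestTransforms:
    def test_gft_of_basis_is_identity(self, rsfc_basis):
        out = pg.gft(rsfc_basis, rsfc_basis.eigenvectors)
        assert np.abs(out - np.eye(rsfc_basis.n)).max() < 1e-8

    def test_constant_signal_lives_on_zero_mode(self, rsfc_basis):
        xhat = pg.gft(rsfc_basis, np.ones((rsfc_basis.n, 1)))
        energy = xhat[:, 0] ** 2 / np.sum(xhat[:, 0] ** 2)
        assert energy[0] == pytest.approx(1.0, abs=1e-10)

    def test_round_trip_and_parseval(self, rsfc_basis, rng):
        X = rng.normal(size=(rsfc_basis.n, 7))
        Xhat = pg.gft(rsfc_basis, X)
        assert np.abs(pg.igft(rsfc_basis, Xhat) - X).max() < 1e-8
        assert np.allclose(
            np.linalg.norm(Xhat, axis=0), np.linalg.norm(X, axis=0), rtol=1e-8
        )

    def test_igft_of_unit_coefficient_returns_eigenvector(self, rsfc_basis):
        e1 = np.zeros((rsfc_basis.n, 1))
        e1[0, 0] = 1.0
        assert np.allclose(pg.igft(rsfc_basis, e1)[:, 0], rsfc_basis.eigenvectors[:, 0])

    def test_shape_mismatch_rejected(self, rsfc_basis, rng):
        with pytest.raises(ValueError):
            pg.gft(rsfc_basis, rng.normal(size=(rsfc_basis.n + 1, 2)))


def bruteforce_lowpass(basis, X, k):
    """Independent oracle: explicit sum of per-mode projections."""
    out = np.zeros_like(X, dtype=float)
    for i in range(k):
        u = basis.eigenvectors[:, i]
        out += np.outer(u, u @ X)
    return out


class TestLowpassFilter:
    def test_full_spectrum_is_identity(self, rsfc_basis, rng):
        X = rng.normal(size=(rsfc_basis.n, 4))
        assert np.abs(pg.lowpass_filter(rsfc_basis, X, rsfc_basis.n) - X).max() < 1e-8

    def test_constant_signal_survives_k1_on_connected_graph(self, rsfc_basis):
        X = np.full((rsfc_basis.n, 2), 3.0)
        assert np.abs(pg.lowpass_filter(rsfc_basis, X, 1) - X).max() < 1e-8

    def test_matches_bruteforce_oracle(self, rsfc_basis, rng):
        X = rng.normal(size=(rsfc_basis.n, 5))
        assert np.abs(
            pg.lowpass_filter(rsfc_basis, X, 3) - bruteforce_lowpass(rsfc_basis, X, 3)
        ).max() < 1e-10

    def test_idempotent_and_contractive(self, rsfc_basis, rng):
        X = rng.normal(size=(rsfc_basis.n, 3))
        once = pg.lowpass_filter(rsfc_basis, X, 10)
        twice = pg.lowpass_filter(rsfc_basis, once, 10)
        assert np.abs(twice - once).max() < 1e-8
        assert np.all(
            np.linalg.norm(once, axis=0) <= np.linalg.norm(X, axis=0) + 1e-12
        )

    @pytest.mark.parametrize("k", [0, -3, 1000])
    def test_out_of_range_k_rejected(self, rsfc_basis, k):
        with pytest.raises(ValueError):
            pg.lowpass_filter(rsfc_basis, np.zeros((rsfc_basis.n, 1)), k)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 50),
        k_frac=st.floats(0.05, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_property_matches_oracle_on_random_graphs(self, n, k_frac, seed):
        rng = np.random.default_rng(seed)
        A = random_graph_adjacency(rng, n, density=0.4)
        basis = pg.eigendecompose(pg.combinatorial_laplacian(A))
        X = rng.normal(size=(n, 3))
        k = max(1, int(np.ceil(k_frac * n)))
        assert np.abs(
            pg.lowpass_filter(basis, X, k) - bruteforce_lowpass(basis, X, k)
        ).max() < 1e-8


class TestSpectralProfile:
    def test_zero_signal_flagged_undefined(self, rsfc_basis):
        profile = pg.spectral_profile(rsfc_basis, np.zeros((rsfc_basis.n, 2)), 0)
        assert not profile.defined
        assert np.all(profile.coefficient_magnitudes == 0.0)

    def test_barbell_indicator_energy_concentrates_in_two_modes(self):
        A, signal = pg.generate_barbell_fixture(6, 0)
        basis = pg.eigendecompose(pg.combinatorial_laplacian(A))
        profile = pg.spectral_profile(basis, signal[:, None], 0)
        assert profile.energy_fraction[1] == pytest.approx(1.0, abs=1e-10)

    def test_energy_fraction_monotone_to_one(self, rsfc_basis, rng):
        profile = pg.spectral_profile(rsfc_basis, rng.normal(size=(rsfc_basis.n, 3)), 1)
        assert np.all(np.diff(profile.energy_fraction) >= -1e-12)
        assert profile.energy_fraction[-1] == pytest.approx(1.0, abs=1e-10)

    def test_csv_export_columns(self, tmp_path, rsfc_basis, rng):
        import pandas as pd

        profile = pg.spectral_profile(rsfc_basis, rng.normal(size=(rsfc_basis.n, 2)), 0)
        path = profile.to_csv(tmp_path / "profile.csv")
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "eigenvalue_rank", "eigenvalue", "coefficient_magnitude", "cumulative_energy",
        ]
        assert len(frame) == rsfc_basis.n


class TestRegimeCategorization:
    def test_peak_only_at_full_spectrum_is_high_frequency(self):
        k = np.array([10, 20, 100])
        assert pg.categorize_frequency_regime(k, [0.5, 0.6, 0.9], 100) == HIGH_FREQUENCY

    def test_flat_after_low_k_is_low_frequency(self):
        k = np.array([10, 20, 100])
        assert pg.categorize_frequency_regime(k, [0.88, 0.9, 0.9], 100) == LOW_FREQUENCY

    def test_requires_grid_ending_at_n(self):
        with pytest.raises(ValueError):
            pg.categorize_frequency_regime(np.array([10, 20]), [0.5, 0.6], 100)
        with pytest.raises(ValueError):
            pg.categorize_frequency_regime(np.array([]), [], 100)

    def test_smooth_graph_low_and_random_high_on_synthetic_cohorts(self):
        """Connectivity graphs read low-frequency, random baselines high."""
        hits = 0
        for seed in range(10):
            cohort = pg.generate_cohort(
                pg.smooth_cohort_params(n_patients=30, n_controls=30, seed=seed)
            )
            feats = pg.vectorize_rsfc(cohort)
            n = cohort.n
            k_grid = np.array([max(1, int(0.1 * n)), int(0.2 * n), n])
            plan = pg.stratified_kfold(cohort.labels, 2, seed=seed)
            regimes = {}
            for config in [pg.GraphConfig(use_rsfc=True), pg.GraphConfig(baseline_kind="random", seed=seed)]:
                graph = pg.build_population_graph(feats, cohort, config)
                accs = pg.block_accuracy_curve(
                    graph, feats, cohort.labels, k_grid, plan.assignments,
                    random_state=seed, epochs=20,
                )
                regimes[config.name] = pg.categorize_frequency_regime(k_grid, accs, n)
            hits += regimes["sim_RSFC"] == LOW_FREQUENCY and regimes["random"] == HIGH_FREQUENCY
        assert hits >= 8


class TestLowPassFilterTransformer:
    def test_transform_matches_function_and_clamps_k(self, rsfc_basis, rng):
        X = rng.normal(size=(rsfc_basis.n, 4))
        filt = LowPassFilter(basis=rsfc_basis, k=10_000).fit(X)
        assert filt.k_effective_ == rsfc_basis.n
        assert np.allclose(filt.transform(X), X)
        filt.set_params(k=5)
        out = filt.fit(X).transform(X)
        assert np.allclose(out, pg.lowpass_filter(rsfc_basis, X, 5))
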