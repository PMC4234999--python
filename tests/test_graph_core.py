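"""Graph construction, Laplacian assembly and spectral decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochshield.graph_core import (
    Edge,
    MeasurementVector,
    ReactionGraph,
    ReducibleGraphError,
    build_laplacian,
    connected_components,
    spectral_decomposition,
    stationary_distribution,
    stoichiometry,
    stoichiometry_matrix,
)
from stochshield.hh_channels import k_channel_rates


class TestReactionGraph:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError, match="self-loop"):
            ReactionGraph(2, (Edge(0, 0, 1.0),))

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError, match="rate"):
            ReactionGraph(2, (Edge(0, 1, 0.0),))

    def test_rejects_out_of_range_index(self):
        with pytest.raises(ValueError, match="out of range"):
            ReactionGraph(2, (Edge(0, 5, 1.0),))


class TestBuildLaplacian:
    def test_threestate_matrix(self, threestate):
        graph, _ = threestate
        lap = build_laplacian(graph)
        expected = np.array([[-1, 1, 0], [1, -2, 1], [0, 1, -1]], dtype=float)
        np.testing.assert_array_equal(lap.matrix, expected)
        assert lap.symmetric

    def test_two_node_reversible(self, two_state):
        lap = build_laplacian(two_state)
        np.testing.assert_array_equal(lap.matrix, [[-1.0, 1.0], [1.0, -1.0]])

    def test_hh_potassium_laplacian_at_rest(self):
        # assemble the 5-state K+ chain by hand from the subunit rates at
        # V = -65 mV and compare with the package's construction
        a, b = k_channel_rates(-65.0)
        A = np.zeros((5, 5))
        for i, mult in enumerate((4, 3, 2, 1)):
            A[i, i + 1] = mult * a
            A[i + 1, i] = (i + 1) * b
        expected = (A - np.diag(A.sum(axis=1))).T
        edges = tuple(
            Edge(i, j, A[i, j]) for i in range(5) for j in range(5) if A[i, j]
        )
        lap = build_laplacian(ReactionGraph(5, edges))
        np.testing.assert_allclose(lap.matrix, expected, rtol=1e-15)
        assert not lap.symmetric

    def test_duplicate_edge_rejected_then_merged(self):
        g = ReactionGraph(2, (Edge(0, 1, 1.0), Edge(0, 1, 2.0), Edge(1, 0, 1.0)))
        with pytest.raises(ValueError, match="duplicate"):
            build_laplacian(g)
        lap = build_laplacian(g, merge_parallel=True)
        assert lap.adjacency[0, 1] == 3.0

    def test_column_sums_zero_on_random_graphs(self):
        from conftest import random_connected_er

        rng = np.random.default_rng(0)
        for _ in range(25):
            g = random_connected_er(rng)
            L = build_laplacian(g).matrix
            np.testing.assert_allclose(
                L.sum(axis=0), 0.0, atol=1e-12 * max(np.abs(L).max(), 1.0)
            )
            assert np.all(L[~np.eye(g.n_nodes, dtype=bool)] >= 0)


class TestStoichiometry:
    def test_threestate_measurement_projections(self, threestate):
        graph, M = threestate
        # reaction 3 (2->3) raises the readout, reaction 1 (1->2) leaves it
        assert M.values @ stoichiometry(graph, 2) == +1
        assert M.values @ stoichiometry(graph, 0) == 0
        assert M.values @ stoichiometry(graph, 3) == -1

    def test_out_of_range(self, threestate):
        graph, _ = threestate
        with pytest.raises(IndexError):
            stoichiometry(graph, 4)

    @given(st.integers(0, 3))
    @settings(deadline=None)
    def test_constant_measurement_annihilates(self, k):
        graph = ReactionGraph(
            3, (Edge(0, 1, 1.0), Edge(1, 0, 1.0), Edge(1, 2, 1.0), Edge(2, 1, 1.0))
        )
        z = stoichiometry(graph, k)
        assert z.sum() == 0.0
        assert np.count_nonzero(z) == 2
        assert set(z[z != 0]) == {-1.0, 1.0}

    def test_matrix_matches_columns(self, threestate):
        graph, _ = threestate
        Z = stoichiometry_matrix(graph)
        for k in range(graph.n_edges):
            np.testing.assert_array_equal(Z[:, k], stoichiometry(graph, k))


class TestSpectralDecomposition:
    def test_two_node_closed_form(self, two_state):
        dec = spectral_decomposition(build_laplacian(two_state))
        np.testing.assert_allclose(dec.eigenvalues, [0.0, -2.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(dec.right[:, 0]), [1, 1] / np.sqrt(2))
        np.testing.assert_allclose(np.abs(dec.right[:, 1]), [1, 1] / np.sqrt(2))
        assert dec.right[0, 1] * dec.right[1, 1] < 0

    def test_threestate_eigenvalues(self, threestate):
        graph, _ = threestate
        dec = spectral_decomposition(build_laplacian(graph))
        np.testing.assert_allclose(dec.eigenvalues, [0.0, -1.0, -3.0], atol=1e-12)

    def test_hh_sodium_reconstruction(self):
        from stochshield.hh_channels import build_channel_graph, sodium_channel

        graph, _ = build_channel_graph(sodium_channel(), -60.0)
        lap = build_laplacian(graph)
        dec = spectral_decomposition(lap)
        err = np.abs(dec.reconstruct() - lap.matrix).max()
        assert err <= 1e-8 * np.abs(lap.matrix).max()

    def test_reconstruction_on_random_er_ensemble(self):
        # round-trip L -> eigenpairs -> sum lambda_i v_i w_i^T across many
        # random graphs (scaled-down sweep of the ensemble regime)
        from stochshield.ensemble import er_laplacian

        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(3, 31))
            L = er_laplacian(n, 0.5, rng)
            try:
                dec = spectral_decomposition(L)
            except ReducibleGraphError:
                continue
            except ValueError:
                continue  # disconnected sample: repeated zero eigenvalue
            rel = np.abs(dec.reconstruct() - L).max() / max(np.abs(L).max(), 1.0)
            assert rel < 1e-8

    def test_symmetric_left_equals_right(self, threestate):
        graph, _ = threestate
        dec = spectral_decomposition(build_laplacian(graph))
        assert dec.symmetric
        np.testing.assert_allclose(dec.left, dec.right.T)
        np.testing.assert_allclose(dec.left @ dec.right, np.eye(3), atol=1e-12)

    def test_biorthogonality_nonsymmetric(self):
        from stochshield.hh_channels import build_channel_graph, potassium_channel

        graph, _ = build_channel_graph(potassium_channel(), -30.0)
        dec = spectral_decomposition(build_laplacian(graph))
        np.testing.assert_allclose(dec.left @ dec.right, np.eye(5), atol=1e-9)

    def test_constant_left_null_vector(self):
        from stochshield.hh_channels import build_channel_graph, sodium_channel

        graph, _ = build_channel_graph(sodium_channel(), 0.0)
        dec = spectral_decomposition(build_laplacian(graph))
        w0 = np.real(dec.left[0, :])
        assert np.ptp(w0 / w0.mean()) < 1e-9

    def test_rejects_non_laplacian(self):
        with pytest.raises(ValueError, match="positive real part"):
            spectral_decomposition(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestStationaryDistribution:
    def test_threestate_uniform(self, threestate):
        graph, _ = threestate
        dec = spectral_decomposition(build_laplacian(graph))
        np.testing.assert_allclose(stationary_distribution(dec), np.full(3, 1 / 3), atol=1e-12)

    def test_two_state_balance(self):
        g = ReactionGraph(2, (Edge(0, 1, 2.0), Edge(1, 0, 3.0)))
        dec = spectral_decomposition(build_laplacian(g))
        np.testing.assert_allclose(stationary_distribution(dec), [0.6, 0.4], atol=1e-12)

    def test_hh_potassium_binomial(self):
        from stochshield.hh_channels import (
            build_channel_graph,
            k_stationary_binomial,
            potassium_channel,
        )

        for V in (-80.0, -65.0, -20.0, 40.0):
            graph, pi = build_channel_graph(potassium_channel(), V)
            np.testing.assert_allclose(pi, k_stationary_binomial(V), atol=1e-10)
            L = build_laplacian(graph).matrix
            assert abs(pi.sum() - 1) < 1e-10
            np.testing.assert_allclose(L @ pi, 0.0, atol=1e-10)

    def test_reducible_graph_signals(self):
        g = ReactionGraph(
            4, (Edge(0, 1, 1.0), Edge(1, 0, 1.0), Edge(2, 3, 1.0), Edge(3, 2, 1.0))
        )
        dec = spectral_decomposition(build_laplacian(g))
        with pytest.raises(ReducibleGraphError):
            stationary_distribution(dec)

    def test_stationarity_on_fixtures(self):
        from stochshield.io import load_fixture

        for name in ("threestate", "hhk", "hhna"):
            graph, _ = load_fixture(name)
            lap = build_laplacian(graph)
            pi = stationary_distribution(spectral_decomposition(lap))
            assert abs(pi.sum() - 1.0) < 1e-10
            np.testing.assert_allclose(lap.matrix @ pi, 0.0, atol=1e-10)


class TestConnectedComponents:
    def test_chain_single_component(self, threestate):
        graph, _ = threestate
        assert connected_components(graph) == [[0, 1, 2]]

    def test_two_disjoint_cycles(self):
        g = ReactionGraph(
            4, (Edge(0, 1, 1.0), Edge(1, 0, 1.0), Edge(2, 3, 1.0), Edge(3, 2, 1.0))
        )
        assert connected_components(g) == [[0, 1], [2, 3]]

    def test_er_sample_connected(self):
        from stochshield.ensemble import sample_er_graph

        rng = np.random.default_rng(2)
        g = sample_er_graph(50, 0.5, rng, require_connected=False)
        assert len(connected_components(g)) == 1  # P[disconnected] ~ 2e-12


class TestMeasurementVector:
    def test_binary_validation(self):
        with pytest.raises(ValueError):
            MeasurementVector(np.array([0.0, 0.5]), mode="binary")

    def test_graded_range(self):
        with pytest.raises(ValueError):
            MeasurementVector(np.array([0.0, 1.5]), mode="graded")

    def test_mode_inference(self):
        assert MeasurementVector.from_values([0, 1, 1]).mode == "binary"
        assert MeasurementVector.from_values([0.2, 0.9, 0]).mode == "graded"
        np.testing.assert_array_equal(
            MeasurementVector.from_values([0, 1, 1]).support, [1, 2]
        )
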