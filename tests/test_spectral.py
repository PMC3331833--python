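"""Laplacian eigenbases, graph-Fourier transform and attenuation series."""

import math

import networkx as nx
import numpy as np
import pytest

from polyq_netscreen.spectral import (
    AttenuationSeries,
    ConfigurationError,
    NetworkInputError,
    SpectralBasis,
    attenuation_series,
    confidence_core,
    dirichlet_energy,
    graph_fourier,
    inverse_graph_fourier,
    laplacian,
    normalize_weights,
    restrict_to_scored,
)
from polyq_netscreen.synthetic import (
    SyntheticTruth,
    simulate_network,
    simulate_smooth_signal,
)


class TestLaplacian:
    def test_single_edge(self):
        g = nx.Graph([("a", "b", {"weight": 1.0})])
        _, L = laplacian(g)
        assert np.linalg.eigvalsh(L) == pytest.approx([0.0, 2.0], abs=1e-12)

    def test_triangle(self, triangle):
        _, L = laplacian(triangle)
        assert np.linalg.eigvalsh(L) == pytest.approx([0.0, 3.0, 3.0], abs=1e-12)

    def test_singleton(self):
        g = nx.Graph()
        g.add_node("a")
        _, L = laplacian(g)
        assert L.shape == (1, 1) and L[0, 0] == 0.0

    def test_negative_weight_rejected(self):
        g = nx.Graph([("a", "b", {"weight": -0.5})])
        with pytest.raises(NetworkInputError, match="weight"):
            laplacian(g)

    def test_unweighted_option_ignores_weights(self):
        g = nx.Graph([("a", "b", {"weight": 7.0})])
        _, L = laplacian(g, use_weights=False)
        assert np.linalg.eigvalsh(L) == pytest.approx([0.0, 2.0], abs=1e-12)


class TestBasis:
    def test_orthonormal_and_one_zero_per_component(self, small_network):
        basis = SpectralBasis.from_network(small_network)
        for comp in basis.components:
            V = comp.eigenvectors
            assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
            assert comp.eigenvalues[0] == 0.0
            if len(comp.nodes) > 1:
                assert comp.eigenvalues[1] > 1e-12  # connected: single zero
            assert np.all(np.diff(comp.eigenvalues) >= -1e-12)

    def test_normalize_weights_degenerate_all_equal(self):
        g = nx.Graph([("a", "b", {"weight": 3.0}), ("b", "c", {"weight": 3.0})])
        out = normalize_weights(g)
        assert all(d["weight"] == 1.0 for _, _, d in out.edges(data=True))

    def test_confidence_core_drops_weak_edges(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 0.9), ("b", "c", 0.1), ("c", "d", 0.8)])
        core = confidence_core(g, 0.5)
        assert set(core.nodes) == {"a", "b", "c", "d"}
        assert not core.has_edge("b", "c")
        assert core.has_edge("a", "b")


class TestFourier:
    def test_constant_signal_all_energy_at_zero_frequency(self, triangle):
        basis = SpectralBasis.from_network(triangle)
        coeffs = graph_fourier({n: 2.5 for n in triangle}, basis)
        (c,) = coeffs
        assert c[0] == pytest.approx(2.5 * math.sqrt(3), abs=1e-10)
        assert np.allclose(c[1:], 0.0, atol=1e-10)

    def test_eigenvector_signal_single_coefficient(self, triangle):
        basis = SpectralBasis.from_network(triangle)
        comp = basis.components[0]
        signal = dict(zip(comp.nodes, comp.eigenvectors[:, 1]))
        (c,) = graph_fourier(signal, basis)
        expected = np.zeros(3)
        expected[1] = 1.0
        assert np.allclose(c, expected, atol=1e-10)

    def test_round_trip(self, triangle):
        rng = np.random.default_rng(7)
        signal = {n: float(rng.normal()) for n in triangle}
        basis = SpectralBasis.from_network(triangle)
        back = inverse_graph_fourier(graph_fourier(signal, basis), basis)
        assert all(abs(back[n] - signal[n]) < 1e-10 for n in signal)

    def test_missing_gene_rejected(self, triangle):
        basis = SpectralBasis.from_network(triangle)
        with pytest.raises(NetworkInputError, match="missing"):
            graph_fourier({"a": 1.0, "b": 2.0}, basis)


class TestRestrictToScored:
    def test_identity_when_all_scored(self, triangle):
        out = restrict_to_scored(triangle, {n: 0.0 for n in triangle})
        assert set(out.nodes) == set(triangle.nodes)
        assert out.number_of_edges() == 3

    def test_unscored_middle_node_splits_path(self):
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        out = restrict_to_scored(g, {n: 0.0 for n in "abde"})
        comps = sorted(sorted(c) for c in nx.connected_components(out))
        assert comps == [["a", "b"], ["d", "e"]]

    def test_scored_gene_missing_from_network_kept_as_singleton(self, triangle):
        out = restrict_to_scored(triangle, {"a": 1.0, "b": 1.0, "c": 1.0, "z": 5.0})
        assert "z" in out.nodes and out.degree("z") == 0

    def test_empty_intersection_rejected(self, triangle):
        with pytest.raises(ConfigurationError):
            restrict_to_scored(triangle, {"x": 1.0, "y": 2.0})


class TestAttenuation:
    def test_default_produces_40_smoothed_levels(self, small_network, small_signal):
        basis = SpectralBasis.from_network(small_network)
        series = attenuation_series(small_signal, basis)
        assert series.n_steps == 40
        assert list(series.signal.columns) == [f"level_{k}" for k in range(41)]
        assert series.kept_fraction[0] == 1.0
        assert series.kept_fraction[-1] == 0.0  # removal exhausted

    def test_level_zero_reconstructs_input(self, small_network, small_signal):
        basis = SpectralBasis.from_network(small_network)
        series = attenuation_series(small_signal, basis)
        for gene, value in small_signal.items():
            assert abs(series.level(0)[gene] - value) < 1e-8

    def test_final_level_is_component_means(self, small_network, small_signal):
        basis = SpectralBasis.from_network(small_network)
        series = attenuation_series(small_signal, basis)
        last = series.level(40)
        for comp in basis.components:
            mean = np.mean([small_signal[n] for n in comp.nodes])
            assert last[list(comp.nodes)].to_numpy() == pytest.approx(
                np.full(len(comp.nodes), mean), abs=1e-8
            )

    def test_component_mean_preserved_every_level(self, small_network, small_signal):
        basis = SpectralBasis.from_network(small_network)
        series = attenuation_series(small_signal, basis)
        for comp in basis.components:
            mean0 = np.mean([small_signal[n] for n in comp.nodes])
            for k in series.levels:
                level_mean = series.level(k)[list(comp.nodes)].mean()
                assert level_mean == pytest.approx(mean0, abs=1e-8)

    def test_dirichlet_energy_non_increasing(self, small_network, small_signal):
        basis = SpectralBasis.from_network(small_network)
        series = attenuation_series(small_signal, basis)
        energies = [
            dirichlet_energy(series.level(k).to_dict(), basis) for k in series.levels
        ]
        assert all(e1 <= e0 + 1e-9 for e0, e1 in zip(energies, energies[1:]))

    def test_zero_step_returns_input_at_every_level(self, triangle):
        signal = {"a": 1.0, "b": -2.0, "c": 0.5}
        basis = SpectralBasis.from_network(triangle)
        series = attenuation_series(signal, basis, step=0.0, n_steps=5)
        for k in series.levels:
            for gene, value in signal.items():
                assert abs(series.level(k)[gene] - value) < 1e-10

    def test_constant_input_invariant(self, triangle):
        basis = SpectralBasis.from_network(triangle)
        series = attenuation_series({n: 1.5 for n in triangle}, basis)
        assert np.allclose(series.signal.to_numpy(), 1.5, atol=1e-10)

    def test_infeasible_step_config_rejected(self, triangle):
        basis = SpectralBasis.from_network(triangle)
        with pytest.raises(ConfigurationError):
            attenuation_series({n: 1.0 for n in triangle}, basis, step=0.1, n_steps=11)

    def test_smoothing_improves_signal_recovery(self):
        """On planted smooth modules + noise, correlation with the clean
        signal is non-decreasing over the first attenuation levels."""
        truth = SyntheticTruth(
            n_genes=120, module_sizes=(8, 8), module_effects_sd=(2.0, -2.0),
            p_in=0.8, p_out=0.02, seed=3,
        )
        network = simulate_network(truth)
        noisy, clean = simulate_smooth_signal(truth)
        basis = SpectralBasis.from_network(restrict_to_scored(network, noisy))
        series = attenuation_series(noisy, basis)
        genes = sorted(noisy)
        clean_vec = np.array([clean[g] for g in genes])
        cors = [
            np.corrcoef(series.level(k).reindex(genes), clean_vec)[0, 1]
            for k in range(0, 9, 2)
        ]
        assert all(c1 >= c0 - 1e-6 for c0, c1 in zip(cors, cors[1:]))
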