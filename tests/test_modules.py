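"""Module extraction: thresholding, stability, redundancy, annotation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from polyq_netscreen.enrichment import GeneSetCollection
from polyq_netscreen.modules import (
    Module,
    annotate_modules,
    connected_modules,
    deduplicate,
    detect_modules,
    export_module_graph,
    modules_frame,
    signal_statistics,
    threshold_genes,
    track_stability,
)
from polyq_netscreen.spectral import (
    AttenuationSeries,
    SpectralBasis,
    attenuation_series,
    restrict_to_scored,
)
from polyq_netscreen.synthetic import (
    SyntheticTruth,
    simulate_network,
    simulate_smooth_signal,
)
from tests.test_enrichment import enumeration_upper_tail


def _series_from_frame(frame: pd.DataFrame) -> AttenuationSeries:
    g = nx.empty_graph(list(frame.index))
    basis = SpectralBasis.from_network(g)
    n_levels = len(frame.columns)
    return AttenuationSeries(
        signal=frame,
        kept_fraction=tuple([1.0] * n_levels),
        step=1.0 / max(n_levels - 1, 1),
        n_steps=n_levels - 1,
        basis=basis,
    )


class TestThreshold:
    def test_strict_inequality_empty_at_sigma_zero(self):
        frame = pd.DataFrame({"level_0": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        series = _series_from_frame(frame)
        assert threshold_genes(series, 0, mu=1.0, sigma=0.0, sign="positive") == frozenset()

    def test_sign_selects_direction(self):
        frame = pd.DataFrame({"level_0": [2.0, -2.0, 0.0]}, index=["g1", "g2", "g3"])
        series = _series_from_frame(frame)
        assert threshold_genes(series, 0, 0.0, 1.0, "positive") == {"g1"}
        assert threshold_genes(series, 0, 0.0, 1.0, "negative") == {"g2"}

    def test_planted_module_recovered_at_level_4(self):
        truth = SyntheticTruth(
            n_genes=200, module_sizes=(10,), module_effects_sd=(2.0,),
            p_in=0.8, p_out=0.01, seed=21,
        )
        network = simulate_network(truth)
        noisy, _ = simulate_smooth_signal(truth)
        basis = SpectralBasis.from_network(restrict_to_scored(network, noisy))
        series = attenuation_series(noisy, basis)
        mu, sigma = signal_statistics(series)
        hit = threshold_genes(series, 4, mu, sigma, "positive")
        planted = set(truth.planted_modules[0].genes)
        assert len(hit & planted) >= 0.8 * len(planted)


class TestConnectedModules:
    def test_empty_input(self, triangle):
        assert connected_modules(frozenset(), triangle) == []

    def test_disconnected_endpoints_form_no_module(self):
        g = nx.path_graph(["a", "b", "c"])
        assert connected_modules(frozenset({"a", "c"}), g) == []

    def test_two_cliques_two_modules(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        g.add_edges_from([("x", "y"), ("y", "z"), ("x", "z")])
        mods = connected_modules(frozenset("abcxyz"), g)
        assert sorted(sorted(m) for m in mods) == [["a", "b", "c"], ["x", "y", "z"]]


class TestStability:
    def _levels(self, sets_by_level):
        thresholds = {k: frozenset(v) for k, v in sets_by_level.items()}
        g = nx.complete_graph(
            sorted(set().union(*[set(v) for v in sets_by_level.values()]))
        )
        per_level = {k: connected_modules(t, g) for k, t in thresholds.items()}
        return per_level, thresholds

    def test_identical_across_levels_retained(self):
        genes = {"a", "b", "c"}
        per_level, thresholds = self._levels({k: genes for k in range(0, 8)})
        mods = track_stability(per_level, thresholds, "positive")
        assert mods and all(m.stability_run >= 2 for m in mods)
        assert min(m.birth_level for m in mods) == 4

    def test_module_before_start_level_rejected(self):
        sets = {k: set() for k in range(0, 8)}
        sets[3] = {"a", "b"}
        per_level, thresholds = self._levels(sets)
        assert track_stability(per_level, thresholds, "positive") == []

    def test_exactly_forty_percent_retained(self):
        ten = {f"g{i}" for i in range(10)}
        four = {f"g{i}" for i in range(4)}
        sets = {k: set() for k in range(0, 8)}
        sets[4] = ten
        sets[5] = four
        sets[6] = four
        per_level, thresholds = self._levels(sets)
        mods = track_stability(per_level, thresholds, "positive")
        assert any(m.genes == frozenset(ten) and m.stability_run == 2 for m in mods)

    def test_below_forty_percent_rejected(self):
        ten = {f"g{i}" for i in range(10)}
        three = {f"g{i}" for i in range(3)}
        sets = {k: set() for k in range(0, 8)}
        sets[4] = ten
        sets[5] = three
        sets[6] = three
        per_level, thresholds = self._levels(sets)
        mods = track_stability(per_level, thresholds, "positive")
        assert not any(m.genes == frozenset(ten) for m in mods)


class TestDeduplicate:
    def _mod(self, genes, run=3, birth=4, sign="positive"):
        return Module(frozenset(genes), sign, birth, run)

    def test_identical_duplicates_collapse(self):
        mods = [self._mod("abc", birth=4), self._mod("abc", birth=5)]
        out = deduplicate(mods)
        assert len(out) == 1 and out[0].birth_level == 4

    def test_disjoint_all_retained(self):
        mods = [self._mod("abc"), self._mod("xyz")]
        assert len(deduplicate(mods)) == 2

    def test_nested_pair_superset_kept(self):
        sub = [f"g{i}" for i in range(10)]
        sup = sub + ["g10", "g11"]  # Jaccard 10/12 ~ 0.83
        mods = [self._mod(sub), self._mod(sup)]
        out = deduplicate(mods, jaccard_threshold=0.8)
        assert len(out) == 1 and out[0].genes == frozenset(sup)

    def test_longer_run_preferred(self):
        a = self._mod("abcd", run=2)
        b = self._mod("abce", run=5)
        out = deduplicate([a, b], jaccard_threshold=0.5)
        assert out == [b]


class TestAnnotate:
    def test_whole_set_smallest_p(self):
        universe = frozenset(f"g{i}" for i in range(50))
        coll = GeneSetCollection(
            "sets",
            {"T1": frozenset({"g1", "g2", "g3"}), "T2": frozenset({"g1", "g9"})},
            universe,
        )
        m = Module(frozenset({"g1", "g2", "g3"}), "positive", 4, 2)
        (annotated,) = annotate_modules([m], [coll])
        assert annotated.annotations[0][0] == "sets:T1"

    def test_disjoint_module_no_annotations(self):
        universe = frozenset(f"g{i}" for i in range(50))
        coll = GeneSetCollection("sets", {"T1": frozenset({"g1", "g2"})}, universe)
        m = Module(frozenset({"g40", "g41"}), "positive", 4, 2)
        (annotated,) = annotate_modules([m], [coll])
        assert annotated.annotations == ()

    def test_p_matches_enumeration(self):
        universe = frozenset(f"g{i}" for i in range(200))
        big_set = frozenset(f"g{i}" for i in range(10))
        coll = GeneSetCollection("sets", {"T": big_set}, universe)
        module_genes = frozenset({"g0", "g1", "g2", "g3", "g100", "g101"})
        m = Module(module_genes, "positive", 4, 2)
        (annotated,) = annotate_modules([m], [coll])
        label, p, k = annotated.annotations[0]
        assert k == 4
        # hypergeometric tail via the closed-form sum (enumeration over
        # overlap counts), independent of scipy
        from fractions import Fraction
        from math import comb

        expected = sum(
            Fraction(comb(10, i) * comb(190, 6 - i), comb(200, 6)) for i in range(4, 7)
        )
        assert p == pytest.approx(float(expected), rel=1e-10)


class TestExportGraph:
    def test_uniform_weights_all_one(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 2.0), ("b", "c", 2.0)])
        m = Module(frozenset("abc"), "positive", 4, 2)
        out = export_module_graph(m, g)
        assert list(out["weight"]) == [1.0, 1.0]

    def test_min_max_scaling(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 2.0), ("b", "c", 4.0), ("c", "d", 6.0)])
        m = Module(frozenset("abcd"), "positive", 4, 2)
        out = export_module_graph(m, g)
        assert list(out["weight"]) == [0.0, 0.5, 1.0]

    def test_single_edge(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 0.3)])
        m = Module(frozenset("ab"), "positive", 4, 2)
        out = export_module_graph(m, g)
        assert list(out["weight"]) == [1.0]


@pytest.fixture(scope="module")
def chain():
    truth = SyntheticTruth(
        n_genes=150, module_sizes=(8, 8), module_effects_sd=(2.0, -2.0),
        p_in=0.8, p_out=0.02, seed=9,
    )
    network = simulate_network(truth)
    noisy, _ = simulate_smooth_signal(truth)
    restricted = restrict_to_scored(network, noisy)
    basis = SpectralBasis.from_network(restricted)
    series = attenuation_series(noisy, basis)
    return truth, restricted, series


class TestDetectModules:
    def test_no_mixed_signs(self, chain):
        truth, restricted, series = chain
        for m in detect_modules(series, restricted):
            assert m.sign in ("positive", "negative")

    def test_filters_hold_as_configured(self, chain):
        truth, restricted, series = chain
        for m in detect_modules(series, restricted):
            assert m.birth_level >= 4
            assert m.stability_run >= 2
            assert len(m.genes) >= 2

    def test_deterministic_output(self, chain):
        truth, restricted, series = chain
        first = modules_frame(detect_modules(series, restricted)).to_csv()
        second = modules_frame(detect_modules(series, restricted)).to_csv()
        assert first == second
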