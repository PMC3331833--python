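"""Graph-Fourier smoothing of the S-score signal on a gene network.

The S scores of scored genes are treated as a signal on the functional
gene network.  The combinatorial Laplacian L = D - W of each connected
component is eigendecomposed; eigenvalues play the role of frequencies
(lambda = 0 is the constant, per-component-mean component).  Low-pass
filtering iteratively zeroes the globally highest-frequency 2.5% of the
nonzero-frequency coefficients per step, producing 40 increasingly
smoothed versions of the data.  The zero-frequency coefficient of every
component is never removed, so full attenuation flattens each component
to its mean rather than to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_STEP = 0.025
DEFAULT_N_STEPS = 40

#: Components larger than this trigger a dense-eigendecomposition warning.
LARGE_COMPONENT_WARNING = 3000


class NetworkInputError(ValueError):
    """Raised on malformed networks or signals."""


class ConfigurationError(ValueError):
    """Raised on infeasible smoothing parameters or empty inputs."""


def validate_network(network: nx.Graph) -> None:
    """Check the no-self-loop / non-negative-finite-weight invariants."""
    for u, v, data in network.edges(data=True):
        if u == v:
            raise NetworkInputError(f"self-loop on node {u!r}")
        w = data.get("weight", 1.0)
        if not math.isfinite(w) or w < 0:
            raise NetworkInputError(f"edge ({u!r}, {v!r}) has invalid weight {w}")


def normalize_weights(network: nx.Graph) -> nx.Graph:
    """Min-max normalize edge confidence weights to [0, 1].

    With all weights equal (including a single edge) every normalized
    weight is defined as 1.0.
    """
    g = network.copy()
    weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
    if not weights:
        return g
    lo, hi = min(weights), max(weights)
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        d["weight"] = 1.0 if hi == lo else (w - lo) / (hi - lo)
    return g


def scale_weights(network: nx.Graph) -> nx.Graph:
    """Scale confidence weights by the maximum to (0, 1].

    Used before Laplacian construction: unlike min-max normalization it
    cannot send a positive-confidence edge to weight zero, which would
    silently disconnect a component inside the spectral basis.
    """
    g = network.copy()
    weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
    if not weights:
        return g
    hi = max(weights)
    if hi <= 0:
        return g
    for _, _, d in g.edges(data=True):
        d["weight"] = d.get("weight", 1.0) / hi
    return g


def confidence_core(network: nx.Graph, min_confidence: float = 0.5) -> nx.Graph:
    """High-confidence core of a network: keep edges whose min-max
    normalized confidence weight is >= ``min_confidence``.

    The analogue of restricting to a core functional network: low-
    confidence links add bridges between unrelated genes and dilute
    module connectivity.  All nodes are retained.
    """
    if not 0 <= min_confidence <= 1:
        raise ConfigurationError(
            f"min_confidence must be in [0, 1], got {min_confidence}"
        )
    normed = normalize_weights(network)
    core = nx.Graph()
    core.add_nodes_from(normed.nodes)
    core.add_edges_from(
        (u, v, d)
        for u, v, d in normed.edges(data=True)
        if d.get("weight", 1.0) >= min_confidence
    )
    return core


def restrict_to_scored(
    network: nx.Graph, scores: Mapping[str, float]
) -> nx.Graph:
    """Induced subgraph on scored genes, keeping unmatched genes as singletons.

    Scored genes absent from the network become isolated nodes so the
    downstream gene lists stay complete (a singleton's value is its own
    component mean and is unchanged by smoothing).
    """
    if not scores:
        raise ConfigurationError("no scored genes supplied")
    scored = set(scores)
    common = scored & set(network.nodes)
    if not common:
        raise ConfigurationError(
            "no scored gene appears in the network; check identifier conventions"
        )
    sub = network.subgraph(common).copy()
    missing = scored - common
    if missing:
        logger.info(
            "%d scored genes absent from the network kept as singletons",
            len(missing),
        )
    sub.add_nodes_from(missing)
    return sub


def laplacian(
    network: nx.Graph, use_weights: bool = True, normalized: bool = False
) -> tuple[list, np.ndarray]:
    """Combinatorial (or symmetric normalized) graph Laplacian.

    Returns ``(nodes, L)`` with nodes in sorted order and L = D - W
    (W = confidence weights, or 0/1 adjacency when ``use_weights`` is
    off).  L is symmetric positive semidefinite with one zero eigenvalue
    per connected component.
    """
    validate_network(network)
    if network.number_of_nodes() == 0:
        raise NetworkInputError("empty network")
    nodes = sorted(network.nodes)
    weight_key = "weight" if use_weights else None
    if normalized:
        L = nx.normalized_laplacian_matrix(
            network, nodelist=nodes, weight=weight_key
        ).toarray()
    else:
        L = nx.laplacian_matrix(network, nodelist=nodes, weight=weight_key).toarray()
    return nodes, np.asarray(L, dtype=float)


@dataclass(frozen=True)
class _Component:
    nodes: tuple
    eigenvalues: np.ndarray  # ascending, eigenvalues[0] ~ 0
    eigenvectors: np.ndarray  # columns orthonormal


@dataclass(frozen=True)
class SpectralBasis:
    """Per-component Laplacian eigenbases of a gene network.

    Components are ordered by their lexicographically smallest node for
    determinism; within each component nodes are sorted.  Eigenvalues are
    ascending, the first being the (exactly one) zero frequency of the
    connected component.
    """

    components: tuple[_Component, ...]

    @classmethod
    def from_network(
        cls,
        network: nx.Graph,
        use_weights: bool = True,
        normalized: bool = False,
        normalize_edge_weights: bool = True,
    ) -> "SpectralBasis":
        validate_network(network)
        if network.number_of_nodes() == 0:
            raise NetworkInputError("empty network")
        if use_weights and normalize_edge_weights:
            network = scale_weights(network)
        comps = []
        for comp_nodes in sorted(
            (sorted(c) for c in nx.connected_components(network)),
            key=lambda ns: ns[0],
        ):
            if len(comp_nodes) > LARGE_COMPONENT_WARNING:
                logger.warning(
                    "dense eigendecomposition of a %d-node component; "
                    "expect O(n^3) cost",
                    len(comp_nodes),
                )
            sub = network.subgraph(comp_nodes)
            if len(comp_nodes) == 1:
                vals = np.zeros(1)
                vecs = np.ones((1, 1))
            else:
                _, L = laplacian(sub, use_weights=use_weights, normalized=normalized)
                vals, vecs = np.linalg.eigh(L)
                vals = np.clip(vals, 0.0, None)
                vals[0] = 0.0  # connected component: exactly one zero eigenvalue
            comps.append(
                _Component(tuple(comp_nodes), vals, vecs)
            )
        return cls(tuple(comps))

    @property
    def nodes(self) -> list:
        return [n for c in self.components for n in c.nodes]

    @property
    def n_nodes(self) -> int:
        return sum(len(c.nodes) for c in self.components)

    @property
    def n_components(self) -> int:
        return len(self.components)


def _signal_vectors(
    signal: Mapping[str, float], basis: SpectralBasis
) -> list[np.ndarray]:
    vectors = []
    for comp in basis.components:
        try:
            vectors.append(np.array([float(signal[n]) for n in comp.nodes]))
        except KeyError as e:
            raise NetworkInputError(f"signal missing value for gene {e.args[0]!r}")
    return vectors


def graph_fourier(
    signal: Mapping[str, float], basis: SpectralBasis
) -> list[np.ndarray]:
    """Project the signal onto each component's Laplacian eigenbasis."""
    return [
        comp.eigenvectors.T @ x
        for comp, x in zip(basis.components, _signal_vectors(signal, basis))
    ]


def inverse_graph_fourier(
    coefficients: Sequence[np.ndarray], basis: SpectralBasis
) -> dict[str, float]:
    """Reconstruct a gene->value signal from spectral coefficients."""
    out: dict[str, float] = {}
    for comp, coef in zip(basis.components, coefficients):
        x = comp.eigenvectors @ coef
        out.update(zip(comp.nodes, x.tolist()))
    return out


def dirichlet_energy(
    signal: Mapping[str, float], basis: SpectralBasis
) -> float:
    """Graph smoothness functional x'Lx (0 for constant-per-component)."""
    total = 0.0
    for comp, coef in zip(basis.components, graph_fourier(signal, basis)):
        total += float(np.sum(comp.eigenvalues * coef**2))
    return total


@dataclass(frozen=True)
class AttenuationSeries:
    """Smoothed S signals at attenuation levels 0..n_steps.

    ``signal`` holds one column per level (``level_0`` is the input
    reconstructed through the basis); ``kept_fraction[k]`` is the
    fraction of nonzero-frequency coefficients retained at level k.
    """

    signal: pd.DataFrame  # index: gene, columns: level_0..level_n
    kept_fraction: tuple[float, ...]
    step: float
    n_steps: int
    basis: SpectralBasis

    def level(self, k: int) -> pd.Series:
        return self.signal[f"level_{k}"]

    @property
    def levels(self) -> range:
        return range(self.n_steps + 1)


def attenuation_series(
    signal: Mapping[str, float],
    basis: SpectralBasis,
    step: float = DEFAULT_STEP,
    n_steps: int = DEFAULT_N_STEPS,
) -> AttenuationSeries:
    """Low-pass filter the signal in ``n_steps`` frequency-removal steps.

    At level k the globally highest ``floor(k * step * (m - c))``
    nonzero-frequency components are zeroed, where m is the number of
    scored genes and c the number of connected components.  Ranking is by
    eigenvalue pooled across components, ties broken by (component index,
    within-component index).  Zero-frequency coefficients are never
    removed, so per-component means are preserved at every level and
    level ``1/step`` flattens each component to its mean.
    """
    if not 0 <= step <= 1:
        raise ConfigurationError(f"step must be in [0, 1], got {step}")
    if n_steps < 1 or n_steps * step > 1 + 1e-12:
        raise ConfigurationError(
            f"n_steps * step must be <= 1, got {n_steps} * {step}"
        )
    coeffs = graph_fourier(signal, basis)
    # Pool nonzero-frequency indices; highest frequency first.
    pooled = [
        (comp.eigenvalues[i], ci, i)
        for ci, comp in enumerate(basis.components)
        for i in range(1, len(comp.nodes))
    ]
    pooled.sort(key=lambda t: (-t[0], t[1], t[2]))
    n_removable = len(pooled)  # = m - c
    columns: dict[str, pd.Series] = {}
    kept = []
    for k in range(n_steps + 1):
        n_zero = min(int(math.floor(k * step * n_removable)), n_removable)
        level_coeffs = [c.copy() for c in coeffs]
        for _, ci, i in pooled[:n_zero]:
            level_coeffs[ci][i] = 0.0
        values = inverse_graph_fourier(level_coeffs, basis)
        columns[f"level_{k}"] = pd.Series(values)
        kept.append(1.0 if n_removable == 0 else 1.0 - n_zero / n_removable)
    frame = pd.DataFrame(columns).reindex(sorted(signal))
    return AttenuationSeries(
        signal=frame,
        kept_fraction=tuple(kept),
        step=step,
        n_steps=n_steps,
        basis=basis,
    )
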