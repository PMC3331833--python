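"""Signed gene-module extraction from the attenuation series.

A module is a connected set of >= 2 genes whose smoothed S signal lies
above mean + SD (positive, suppressor-like) or below mean - SD (negative,
enhancer-like) of the raw signal.  Candidate modules observed at or after
the 4th attenuation are kept when at least 40% of their genes stay above
threshold for at least 2 successive further attenuations; survivors are
pruned for redundant gene content (Jaccard similarity) and annotated by
hypergeometric enrichment against gene-set collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from polyq_netscreen.enrichment import GeneSetCollection, enrich
from polyq_netscreen.spectral import AttenuationSeries, confidence_core

logger = logging.getLogger(__name__)

DEFAULT_START_LEVEL = 4
DEFAULT_STABILITY_FRACTION = 0.40
DEFAULT_MIN_RUN = 2
DEFAULT_JACCARD = 0.8
DEFAULT_MIN_CONFIDENCE = 0.5

#: Module size range reported by the analysis on real screens; sizes
#: outside it are allowed but logged.
TYPICAL_SIZE_RANGE = (2, 50)

SIGNS = ("positive", "negative")


@dataclass(frozen=True)
class Module:
    """A signed connected gene set surviving the stability filters.

    ``sign`` is "positive" for suppressor-like (pathogenic-process-
    associated) modules and "negative" for enhancer-like (protection-
    associated) modules.  ``birth_level`` is the attenuation level at
    which the module was extracted; ``stability_run`` the number of
    successive later levels at which it kept enough genes above
    threshold.
    """

    genes: frozenset[str]
    sign: str
    birth_level: int
    stability_run: int
    annotations: tuple[tuple[str, float, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")

    @property
    def sorted_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))

    def jaccard(self, other: "Module") -> float:
        inter = len(self.genes & other.genes)
        union = len(self.genes | other.genes)
        return inter / union if union else 0.0


def signal_statistics(series: AttenuationSeries) -> tuple[float, float]:
    """Mean and sample SD of the raw (level-0) S signal.

    These define the module threshold mu +/- sigma and are held fixed
    across attenuation levels.
    """
    raw = series.level(0).to_numpy()
    return float(np.mean(raw)), float(np.std(raw, ddof=1))


def threshold_genes(
    series: AttenuationSeries,
    level: int,
    mu: float,
    sigma: float,
    sign: str,
) -> frozenset[str]:
    """Genes whose smoothed value at a level clears mu +/- sigma (strict)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}, got {sign!r}")
    values = series.level(level)
    if sign == "positive":
        mask = values > mu + sigma
    else:
        mask = values < mu - sigma
    return frozenset(values.index[mask])


def connected_modules(
    genes: frozenset[str] | set[str], network: nx.Graph
) -> list[frozenset[str]]:
    """Connected components (size >= 2) of the induced subgraph.

    Singletons are discarded: an isolated above-threshold gene is not a
    module.  Output order is deterministic (lexicographic by sorted gene
    tuple).
    """
    sub = network.subgraph(genes)
    comps = [frozenset(c) for c in nx.connected_components(sub) if len(c) >= 2]
    return sorted(comps, key=lambda c: tuple(sorted(c)))


def track_stability(
    per_level_modules: dict[int, list[frozenset[str]]],
    per_level_threshold: dict[int, frozenset[str]],
    sign: str,
    start_level: int = DEFAULT_START_LEVEL,
    stability_fraction: float = DEFAULT_STABILITY_FRACTION,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[Module]:
    """Retain modules with stable gene content across attenuations.

    A candidate module at level k >= ``start_level`` is retained when,
    for each of at least ``min_run`` successive later levels, at least
    ``stability_fraction`` of its genes are still above threshold (the
    boundary is inclusive: exactly 40% qualifies).  ``stability_run`` is
    the length of that streak.  Duplicated lineages across levels are
    collapsed later by :func:`deduplicate`.
    """
    levels = sorted(per_level_modules)
    if levels != list(range(levels[0], levels[0] + len(levels))):
        raise ValueError("attenuation levels must be contiguous")
    max_level = levels[-1]
    retained: list[Module] = []
    for k in levels:
        if k < start_level:
            continue
        for genes in per_level_modules[k]:
            size = len(genes)
            run = 0
            j = k + 1
            while j <= max_level:
                frac = len(genes & per_level_threshold[j]) / size
                if frac >= stability_fraction - 1e-12:
                    run += 1
                    j += 1
                else:
                    break
            if run >= min_run:
                if not TYPICAL_SIZE_RANGE[0] <= size <= TYPICAL_SIZE_RANGE[1]:
                    logger.info(
                        "module of size %d outside the typical %s range",
                        size,
                        TYPICAL_SIZE_RANGE,
                    )
                retained.append(
                    Module(genes=genes, sign=sign, birth_level=k, stability_run=run)
                )
    return retained


def _preference_key(m: Module) -> tuple:
    # longer stability run, then earlier birth, then larger size, then
    # lexicographically smallest gene set
    return (-m.stability_run, m.birth_level, -len(m.genes), m.sorted_genes)


def deduplicate(
    modules: list[Module], jaccard_threshold: float = DEFAULT_JACCARD
) -> list[Module]:
    """Drop modules with redundant gene content.

    Among any pair with Jaccard similarity >= ``jaccard_threshold`` the
    preferred one survives: longer stability run, ties broken by lower
    birth level, then larger size, then lexicographically smallest gene
    set.  Output is sorted by the same preference for determinism.
    """
    kept: list[Module] = []
    for m in sorted(modules, key=_preference_key):
        if all(m.jaccard(other) < jaccard_threshold for other in kept):
            kept.append(m)
    return kept


def annotate_modules(
    modules: list[Module],
    collections: list[GeneSetCollection],
    max_terms: int = 5,
) -> list[Module]:
    """Attach hypergeometric enrichment annotations to each module.

    Each annotation is ``("collection:term", p_value, overlap_count)``;
    the ``max_terms`` best terms per collection are kept, ordered by
    (p, label).
    """
    annotated = []
    for m in modules:
        ann: list[tuple[str, float, int]] = []
        for coll in collections:
            for r in enrich(set(m.genes), coll)[:max_terms]:
                ann.append((f"{coll.name}:{r.term}", r.p_value, r.k))
        ann.sort(key=lambda t: (t[1], t[0]))
        annotated.append(replace(m, annotations=tuple(ann)))
    return annotated


def export_module_graph(
    module: Module, network: nx.Graph
) -> pd.DataFrame:
    """Induced module edges with confidence weights min-max scaled to [0,1].

    A confidence graph for display: the weakest induced edge maps to 0.0
    and the strongest to 1.0; if all weights are equal (including a
    single edge) every edge gets 1.0.  Edges are sorted by (gene_a,
    gene_b) with each pair in sorted order.
    """
    edges = []
    for u, v, data in network.subgraph(module.genes).edges(data=True):
        a, b = sorted((u, v))
        edges.append((a, b, float(data.get("weight", 1.0))))
    edges.sort()
    if edges:
        ws = [w for _, _, w in edges]
        lo, hi = min(ws), max(ws)
        edges = [
            (a, b, 1.0 if hi == lo else (w - lo) / (hi - lo)) for a, b, w in edges
        ]
    return pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"])


def detect_modules(
    series: AttenuationSeries,
    network: nx.Graph,
    start_level: int = DEFAULT_START_LEVEL,
    stability_fraction: float = DEFAULT_STABILITY_FRACTION,
    min_run: int = DEFAULT_MIN_RUN,
    jaccard_threshold: float = DEFAULT_JACCARD,
    threshold_per_level: bool = False,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[Module]:
    """Full module-detection chain on a smoothed attenuation series.

    Thresholds each level at mu +/- sigma (statistics of the raw signal
    by default; per-level statistics with ``threshold_per_level``), takes
    connected components of the high-confidence core of the scored-gene
    network (edges with min-max-normalized confidence >=
    ``min_confidence``; 0 disables the restriction), applies the
    birth-level and stability filters for each sign, and removes
    redundant modules.  Returns positive (suppressor-like) then negative
    (enhancer-like) modules.

    Connectivity is restricted to confident links because low-confidence
    edges act as bridges between unrelated above-threshold genes and
    merge distinct modules; the same motivation leads screen analyses to
    work on a core, high-confidence functional network.
    """
    if min_confidence > 0:
        network = confidence_core(network, min_confidence)
    mu0, sigma0 = signal_statistics(series)
    out: list[Module] = []
    for sign in SIGNS:
        thresholds: dict[int, frozenset[str]] = {}
        per_level: dict[int, list[frozenset[str]]] = {}
        for k in series.levels:
            if threshold_per_level:
                vals = series.level(k).to_numpy()
                mu, sigma = float(np.mean(vals)), float(np.std(vals, ddof=1))
            else:
                mu, sigma = mu0, sigma0
            t = threshold_genes(series, k, mu, sigma, sign)
            thresholds[k] = t
            per_level[k] = connected_modules(t, network)
        candidates = track_stability(
            per_level,
            thresholds,
            sign,
            start_level=start_level,
            stability_fraction=stability_fraction,
            min_run=min_run,
        )
        out.extend(deduplicate(candidates, jaccard_threshold))
    return out


def modules_frame(modules: list[Module]) -> pd.DataFrame:
    """Tabulate modules for TSV export."""
    return pd.DataFrame(
        [
            {
                "module_id": f"{m.sign[:3]}_{i:03d}",
                "sign": m.sign,
                "birth_level": m.birth_level,
                "stability_run": m.stability_run,
                "n_genes": len(m.genes),
                "genes": ";".join(m.sorted_genes),
            }
            for i, m in enumerate(modules, start=1)
        ],
        columns=["module_id", "sign", "birth_level", "stability_run", "n_genes", "genes"],
    )
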