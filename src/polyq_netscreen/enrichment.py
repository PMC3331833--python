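"""Hypergeometric gene-set enrichment and GO-style annotation handling.

Enrichment of suppressor/enhancer gene lists against pathway gene sets
uses the upper-tail hypergeometric probability P[X >= k] for an overlap
of k between a query of size n and a set of size K drawn from a universe
of N genes.  Raw p-values are reported by default (Benjamini-Hochberg
q-values optional).  Ontology annotations can be closed under the
true-path rule: a gene annotated to a term is annotated to all its
ancestors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentInputError(ValueError):
    """Raised on infeasible counts or malformed collections."""


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # overlap size
    n: int  # query size (restricted to universe)
    K: int  # gene-set size
    N: int  # universe size
    p_value: float
    overlap_genes: tuple[str, ...]
    q_value: float | None = None


@dataclass
class GeneSetCollection:
    """A named collection of gene sets over a common universe.

    Sets are restricted to the universe on construction; empty sets are
    dropped.
    """

    name: str
    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise EnrichmentInputError(f"collection {self.name!r}: empty universe")
        self.universe = frozenset(self.universe)
        restricted = {}
        for term, genes in self.sets.items():
            g = frozenset(genes) & self.universe
            if g:
                restricted[term] = g
        self.sets = restricted


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    ``k`` successes in a size-``n`` draw without replacement from a
    universe of ``N`` genes of which ``K`` belong to the set.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise EnrichmentInputError(
            f"infeasible hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    # sf(k-1) = P[X > k-1] = P[X >= k]
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str] | frozenset[str],
    collection: GeneSetCollection,
    min_overlap: int = 1,
    compute_q: bool = False,
) -> list[EnrichmentResult]:
    """Test a query gene list against every set in the collection.

    Query genes outside the universe are dropped (their count is logged).
    Returns one result per term with overlap >= ``min_overlap``, sorted
    by (p-value, term label) for determinism.  With ``compute_q``,
    Benjamini-Hochberg q-values are attached (computed over the returned
    terms).
    """
    query = frozenset(query)
    inside = query & collection.universe
    dropped = len(query) - len(inside)
    if dropped:
        logger.info(
            "enrich(%s): dropped %d query genes outside the universe",
            collection.name,
            dropped,
        )
    n, N = len(inside), len(collection.universe)
    results = []
    for term, genes in collection.sets.items():
        overlap = inside & genes
        k = len(overlap)
        if k < min_overlap:
            continue
        p = hypergeom_upper_tail(k, n, len(genes), N)
        results.append(
            EnrichmentResult(
                term=term,
                k=k,
                n=n,
                K=len(genes),
                N=N,
                p_value=p,
                overlap_genes=tuple(sorted(overlap)),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if compute_q and results:
        _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        results = [
            EnrichmentResult(
                r.term, r.k, r.n, r.K, r.N, r.p_value, r.overlap_genes, float(qi)
            )
            for r, qi in zip(results, q)
        ]
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p_value,
                "q": r.q_value if r.q_value is not None else "",
                "genes": ";".join(r.overlap_genes),
            }
            for r in results
        ],
        columns=["term", "k", "n", "K", "N", "p", "q", "genes"],
    )


def propagate_ontology(
    direct_annotations: dict[str, set[str]],
    ontology: nx.DiGraph,
) -> dict[str, set[str]]:
    """Close gene->terms annotations under the true-path rule.

    ``ontology`` is a DAG with edges pointing child -> parent (the
    orientation obonet produces for ``is_a``).  Each gene gains every
    ancestor of each directly annotated term.  Idempotent; annotations
    only grow.
    """
    if not nx.is_directed_acyclic_graph(ontology):
        cycle = nx.find_cycle(ontology)
        raise EnrichmentInputError(f"ontology contains a cycle: {cycle}")
    # ancestors along child->parent edges = nx.descendants
    closure_cache: dict[str, set[str]] = {}

    def closure(term: str) -> set[str]:
        if term not in closure_cache:
            anc = nx.descendants(ontology, term) if term in ontology else set()
            closure_cache[term] = {term} | anc
        return closure_cache[term]

    return {
        gene: set().union(*(closure(t) for t in terms)) if terms else set()
        for gene, terms in direct_annotations.items()
    }


def category_counts(
    genes: set[str],
    annotations: dict[str, set[str]],
    min_genes: int = 18,
) -> pd.DataFrame:
    """Count query genes per annotation term, keeping frequent terms.

    Mirrors the functional-classification bar chart convention: only
    categories with at least ``min_genes`` query genes are reported,
    sorted by descending count then term label.
    """
    counts: dict[str, int] = {}
    for g in genes:
        for t in annotations.get(g, ()):
            counts[t] = counts.get(t, 0) + 1
    rows = [
        {"term": t, "count": c} for t, c in counts.items() if c >= min_genes
    ]
    df = pd.DataFrame(rows, columns=["term", "count"])
    if not df.empty:
        df = df.sort_values(
            ["count", "term"], ascending=[False, True], ignore_index=True
        )
    return df
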