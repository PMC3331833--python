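"""Cross-species intersection of worm modifiers with mouse dysregulation.

Worm modifier genes (suppressors/enhancers of 128Q-neuron dysfunction)
are mapped to mouse genes through an ortholog-cluster table, then
intersected with striatal dysregulation tables from two Huntington's
disease mouse models.  Counting is done at the mouse-gene level; a mouse
gene present in both tables with different directions is flagged as
oppositely dysregulated.  The default prioritization flags genes whose
RNAi knockdown suppresses worm neuron dysfunction and that are
up-regulated in at least one mouse model — candidate targets for
inhibition.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down")

PRIORITIZE_RULES = ("suppressor_up",)


class CrossSpeciesInputError(ValueError):
    """Raised on malformed ortholog or dysregulation tables."""


def _check_dysregulation(table: pd.DataFrame, label: str) -> pd.DataFrame:
    required = {"mouse_gene", "direction"}
    if not required <= set(table.columns):
        raise CrossSpeciesInputError(
            f"dysregulation table {label!r} must have columns {sorted(required)}"
        )
    bad = set(table["direction"]) - set(DIRECTIONS)
    if bad:
        raise CrossSpeciesInputError(
            f"table {label!r}: invalid directions {sorted(bad)}; allowed {DIRECTIONS}"
        )
    per_gene = table.groupby("mouse_gene")["direction"].nunique()
    conflicted = per_gene[per_gene > 1]
    if not conflicted.empty:
        raise CrossSpeciesInputError(
            f"table {label!r}: conflicting directions for genes "
            f"{sorted(conflicted.index)[:5]}"
        )
    return table.drop_duplicates(subset=["mouse_gene"])


def conserved_modifiers(
    modifiers: Mapping[str, str],
    orthologs: pd.DataFrame,
) -> pd.DataFrame:
    """Expand worm modifiers to their mouse orthologs.

    Parameters
    ----------
    modifiers
        ``worm_gene -> hit_class`` for modifier genes
        (suppressor/enhancer).
    orthologs
        Columns ``worm_gene, mouse_gene, cluster_id``; many-to-many
        mappings allowed.

    Returns
    -------
    pandas.DataFrame
        Columns ``mouse_gene, worm_gene, hit_class``, one row per
        (worm, mouse) pair.  Worm modifiers without any ortholog are
        counted and logged.
    """
    if not modifiers or orthologs.empty:
        return pd.DataFrame(columns=["mouse_gene", "worm_gene", "hit_class"])
    mod = pd.DataFrame(
        {"worm_gene": list(modifiers), "hit_class": list(modifiers.values())}
    )
    merged = mod.merge(orthologs[["worm_gene", "mouse_gene"]], on="worm_gene")
    n_orphan = len(set(mod["worm_gene"]) - set(merged["worm_gene"]))
    if n_orphan:
        logger.info("%d worm modifiers have no mouse ortholog", n_orphan)
    return (
        merged[["mouse_gene", "worm_gene", "hit_class"]]
        .drop_duplicates()
        .sort_values(["mouse_gene", "worm_gene"], ignore_index=True)
    )


def intersect_dysregulation(
    conserved: pd.DataFrame,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Intersect conserved modifier genes with two dysregulation tables.

    Each conserved mouse gene is counted once however many worm genes map
    to it.  Returns a per-gene report and summary counts
    ``in_A_only, in_B_only, in_both_concordant, in_both_opposite, total``
    (the four categories partition the dysregulated conserved genes).
    """
    ta = _check_dysregulation(table_a, label_a).set_index("mouse_gene")["direction"]
    tb = _check_dysregulation(table_b, label_b).set_index("mouse_gene")["direction"]
    hit_by_gene = (
        conserved.groupby("mouse_gene")["hit_class"]
        .agg(lambda s: ";".join(sorted(set(s))))
        if not conserved.empty
        else pd.Series(dtype=object)
    )
    rows = []
    for gene in sorted(hit_by_gene.index):
        da = ta.get(gene)
        db = tb.get(gene)
        if da is None and db is None:
            continue
        rows.append(
            {
                "mouse_gene": gene,
                "hit_class": hit_by_gene[gene],
                f"direction_{label_a}": da or "",
                f"direction_{label_b}": db or "",
                "in_both": da is not None and db is not None,
                "opposite": da is not None and db is not None and da != db,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "mouse_gene",
            "hit_class",
            f"direction_{label_a}",
            f"direction_{label_b}",
            "in_both",
            "opposite",
        ],
    )
    if report.empty:
        summary = {
            f"in_{label_a}_only": 0,
            f"in_{label_b}_only": 0,
            "in_both_concordant": 0,
            "in_both_opposite": 0,
            "total": 0,
        }
    else:
        only_a = ((report[f"direction_{label_a}"] != "") & ~report["in_both"]).sum()
        only_b = ((report[f"direction_{label_b}"] != "") & ~report["in_both"]).sum()
        opp = report["opposite"].sum()
        conc = (report["in_both"] & ~report["opposite"]).sum()
        summary = {
            f"in_{label_a}_only": int(only_a),
            f"in_{label_b}_only": int(only_b),
            "in_both_concordant": int(conc),
            "in_both_opposite": int(opp),
            "total": len(report),
        }
    return report, summary


def prioritize(report: pd.DataFrame, rule: str = "suppressor_up") -> list[str]:
    """Rank candidate therapeutic targets from an intersection report.

    The default ``suppressor_up`` rule selects genes whose worm RNAi
    knockdown suppresses neuron dysfunction and that are up-regulated in
    at least one mouse model: their overexpression correlates with
    disease and their inhibition is protective in the worm.
    """
    if rule not in PRIORITIZE_RULES:
        raise CrossSpeciesInputError(
            f"unknown prioritization rule {rule!r}; available: {PRIORITIZE_RULES}"
        )
    if report.empty:
        return []
    dir_cols = [c for c in report.columns if c.startswith("direction_")]
    is_suppressor = report["hit_class"].str.contains("suppressor")
    any_up = report[dir_cols].eq("up").any(axis=1)
    return sorted(report.loc[is_suppressor & any_up, "mouse_gene"])
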