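"""TSV readers and writers for all pipeline file formats.

All files are UTF-8 TSV with '#' comment lines and no quoting, matching
the conventions of functional-network edge lists and gene-annotation
dumps.  Gene identifiers are opaque case-sensitive strings; dual
"SEQID/name" identifiers (e.g. ``B0478.1/jnk-1``) are canonicalized to
the first token.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from polyq_netscreen.screen import Baseline, ScreenRecord
from polyq_netscreen.spectral import AttenuationSeries

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class FileFormatError(ValueError):
    """Raised on malformed input files; message carries the line number."""


def canonical_gene_id(identifier: str) -> str:
    """First token of a 'SEQID/name' dual identifier."""
    return identifier.split("/", 1)[0]


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# -- screen records -----------------------------------------------------

RECORD_HEADER = ["clone_id", "gene_id", "batch", "touches", "responses", "flags"]


def read_screen_records(path: str | Path) -> list[ScreenRecord]:
    """Read touch-test records (responses ';'-joined, flags ','-joined)."""
    records = []
    rows = list(_data_lines(path))
    if not rows:
        return records
    header_no, header = rows[0]
    cols = header.split("\t")
    if cols != RECORD_HEADER:
        raise FileFormatError(
            f"{path}:{header_no}: expected header {RECORD_HEADER}, got {cols}"
        )
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != len(RECORD_HEADER):
            raise FileFormatError(
                f"{path}:{lineno}: expected {len(RECORD_HEADER)} columns, "
                f"got {len(parts)}"
            )
        clone_id, gene_id, batch, touches, responses, flags = parts
        try:
            records.append(
                ScreenRecord(
                    clone_id=clone_id,
                    gene_id=canonical_gene_id(gene_id),
                    batch=batch,
                    animal_responses=tuple(
                        int(r) for r in responses.split(";") if r != ""
                    ),
                    touches=int(touches),
                    phenotype_flags=frozenset(
                        f for f in flags.split(",") if f
                    ),
                )
            )
        except ValueError as e:
            raise FileFormatError(f"{path}:{lineno}: {e}") from e
    return records


def write_screen_records(records: list[ScreenRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(RECORD_HEADER) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.clone_id,
                        r.gene_id,
                        r.batch,
                        str(r.touches),
                        ";".join(str(x) for x in r.animal_responses),
                        ",".join(sorted(r.phenotype_flags)),
                    ]
                )
                + "\n"
            )


# -- baselines ----------------------------------------------------------


def read_baselines(path: str | Path) -> dict[str, Baseline]:
    """Read per-batch baselines (batch, mean_percent, sd_percent)."""
    out: dict[str, Baseline] = {}
    rows = list(_data_lines(path))
    for lineno, line in rows:
        parts = line.split("\t")
        if parts[0] == "batch":
            continue
        if len(parts) != 3:
            raise FileFormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            out[parts[0]] = Baseline(
                mean_percent=float(parts[1]),
                sd_percent=float(parts[2]),
                batch=parts[0],
            )
        except ValueError as e:
            raise FileFormatError(f"{path}:{lineno}: {e}") from e
    return out


def write_baselines(baselines: dict[str, Baseline], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("batch\tmean_percent\tsd_percent\n")
        for batch in sorted(baselines):
            b = baselines[batch]
            fh.write(
                f"{batch}\t{FLOAT_FORMAT % b.mean_percent}\t"
                f"{FLOAT_FORMAT % b.sd_percent}\n"
            )


# -- generic frames -----------------------------------------------------


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with 6-significant-digit floats."""
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- network ------------------------------------------------------------


def read_network(path: str | Path) -> nx.Graph:
    """Read a weighted edge list (gene_a, gene_b, weight)."""
    g = nx.Graph()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] in ("gene_a", "gene1"):
            continue
        if len(parts) < 2:
            raise FileFormatError(f"{path}:{lineno}: expected >= 2 columns")
        a, b = canonical_gene_id(parts[0]), canonical_gene_id(parts[1])
        try:
            w = float(parts[2]) if len(parts) > 2 else 1.0
        except ValueError as e:
            raise FileFormatError(f"{path}:{lineno}: bad weight {parts[2]!r}") from e
        if w < 0:
            raise FileFormatError(f"{path}:{lineno}: negative weight {w}")
        if a == b:
            raise FileFormatError(f"{path}:{lineno}: self-loop on {a!r}")
        g.add_edge(a, b, weight=w)
    return g


def write_network(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in network.edges(data=True))
        ):
            fh.write(f"{u}\t{v}\t{FLOAT_FORMAT % data.get('weight', 1.0)}\n")


# -- signals and attenuation series ------------------------------------


def read_signal(path: str | Path) -> dict[str, float]:
    """Read a 2-column (gene, S) signal."""
    out: dict[str, float] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if parts[0] in ("gene", "gene_id"):
            continue
        if len(parts) != 2:
            raise FileFormatError(f"{path}:{lineno}: expected 2 columns")
        try:
            out[canonical_gene_id(parts[0])] = float(parts[1])
        except ValueError as e:
            raise FileFormatError(f"{path}:{lineno}: bad value {parts[1]!r}") from e
    return out


def write_signal(signal: dict[str, float], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\ts\n")
        for gene in sorted(signal):
            fh.write(f"{gene}\t{FLOAT_FORMAT % signal[gene]}\n")


def write_attenuation_series(series: AttenuationSeries, path: str | Path) -> None:
    frame = series.signal.copy()
    frame.insert(0, "gene", frame.index)
    write_table(frame, path)


# -- gene sets ----------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene sets from GMT (term, description, genes...) or
    two-column (gene, term) TSV; the format is auto-detected per file."""
    sets: dict[str, set[str]] = {}
    lines = list(_data_lines(path))
    if not lines:
        return {}
    is_gmt = all(len(line.split("\t")) >= 3 for _, line in lines)
    for lineno, line in lines:
        parts = line.split("\t")
        if is_gmt:
            term = parts[0]
            genes = {canonical_gene_id(g) for g in parts[2:] if g}
            sets.setdefault(term, set()).update(genes)
        else:
            if len(parts) != 2:
                raise FileFormatError(
                    f"{path}:{lineno}: expected 2 columns (gene, term)"
                )
            gene, term = parts
            if gene in ("gene", "gene_id"):
                continue
            sets.setdefault(term, set()).add(canonical_gene_id(gene))
    return {t: frozenset(g) for t, g in sets.items()}


def write_gene_sets(sets: dict[str, frozenset[str]], path: str | Path) -> None:
    """Write sets in GMT form (term, description, genes...)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(sets):
            fh.write("\t".join([term, "na", *sorted(sets[term])]) + "\n")


def read_ontology(path: str | Path) -> nx.DiGraph:
    """Read an OBO subset (is_a edges only) as a child->parent DiGraph."""
    import obonet

    graph = obonet.read_obo(path)
    dag = nx.DiGraph()
    dag.add_nodes_from(graph.nodes)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


# -- cross-species tables -----------------------------------------------


def read_orthologs(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"worm_gene", "mouse_gene"}
    if not required <= set(df.columns):
        raise FileFormatError(f"{path}: needs columns {sorted(required)}")
    if "cluster_id" not in df.columns:
        df["cluster_id"] = ""
    if df[["worm_gene", "mouse_gene"]].isna().any().any():
        raise FileFormatError(f"{path}: empty ortholog identifiers")
    df["worm_gene"] = df["worm_gene"].map(canonical_gene_id)
    return df[["worm_gene", "mouse_gene", "cluster_id"]]


def read_dysregulation(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"mouse_gene", "direction"}
    if not required <= set(df.columns):
        raise FileFormatError(f"{path}: needs columns {sorted(required)}")
    if "model_label" not in df.columns:
        df["model_label"] = ""
    return df[["mouse_gene", "direction", "model_label"]]
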