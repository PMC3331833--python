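"""End-to-end orchestration: score -> smooth -> modules -> enrich -> crossmap.

A :class:`PipelineConfig` carries every input path and stage parameter
(the defaults are the screen's published constants: 2.6 SD hit band,
2.5% attenuation over 40 steps, birth level 4, 40% stability over 2
levels).  :func:`run_pipeline` executes all stages in order, writes every
intermediate artifact under the output directory, and emits a manifest
with content hashes so identical config + inputs reproduce identical
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from polyq_netscreen import io as pio
from polyq_netscreen.cross_species import (
    conserved_modifiers,
    intersect_dysregulation,
    prioritize,
)
from polyq_netscreen.enrichment import GeneSetCollection, enrich, results_frame
from polyq_netscreen.modules import detect_modules, export_module_graph, modules_frame
from polyq_netscreen.screen import (
    modifier_gene_scores,
    score_screen,
    screen_summary,
)
from polyq_netscreen.spectral import (
    SpectralBasis,
    attenuation_series,
    restrict_to_scored,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and stage parameters for one pipeline run."""

    records: str = "records.tsv"
    baselines: str = "baselines.tsv"
    network: str = "network.tsv"
    gene_sets: str = "gene_sets.gmt"
    orthologs: str = "orthologs.tsv"
    dysregulation_a: str = "dysregulation_chl2.tsv"
    dysregulation_b: str = "dysregulation_r62.tsv"
    out_dir: str = "out"

    multiplier: float = 2.6
    step: float = 0.025
    n_steps: int = 40
    start_level: int = 4
    stability_fraction: float = 0.40
    min_run: int = 2
    jaccard: float = 0.8
    min_confidence: float = 0.5
    use_weights: bool = True
    normalized_laplacian: bool = False
    threshold_per_level: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, base_dir: str | Path = ".") -> dict:
    """Run every stage in order and return the manifest.

    Stage failures abort with :class:`PipelineError` naming the stage.
    The manifest records parameters, per-stage timings, and SHA-256
    hashes of every written artifact.
    """
    base = Path(base_dir)
    out = base / config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def _write(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        manifest["outputs"][name] = _sha256(path)

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                manifest["stages"][name] = round(
                    time.perf_counter() - self_inner.t0, 3
                )
                return False

        return _Timer()

    with _stage("score"):
        records = pio.read_screen_records(base / config.records)
        baselines = pio.read_baselines(base / config.baselines)
        table = score_screen(records, baselines, multiplier=config.multiplier)
        summary = screen_summary(table)
        _write("sscores.tsv", pio.write_table, table)
        (out / "screen_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        manifest["outputs"]["screen_summary.json"] = _sha256(
            out / "screen_summary.json"
        )
        scores = modifier_gene_scores(table)
        _write("signal.tsv", pio.write_signal, scores)

    with _stage("smooth"):
        network = pio.read_network(base / config.network)
        restricted = restrict_to_scored(network, scores)
        basis = SpectralBasis.from_network(
            restricted,
            use_weights=config.use_weights,
            normalized=config.normalized_laplacian,
        )
        series = attenuation_series(
            scores, basis, step=config.step, n_steps=config.n_steps
        )
        _write("attenuation.tsv", pio.write_attenuation_series, series)

    with _stage("modules"):
        mods = detect_modules(
            series,
            restricted,
            start_level=config.start_level,
            stability_fraction=config.stability_fraction,
            min_run=config.min_run,
            jaccard_threshold=config.jaccard,
            threshold_per_level=config.threshold_per_level,
            min_confidence=config.min_confidence,
        )
        _write("modules.tsv", pio.write_table, modules_frame(mods))
        edges = []
        for i, m in enumerate(mods, start=1):
            g = export_module_graph(m, restricted)
            g.insert(0, "module_id", f"{m.sign[:3]}_{i:03d}")
            edges.append(g)
        edge_frame = (
            pd.concat(edges, ignore_index=True)
            if edges
            else pd.DataFrame(columns=["module_id", "gene_a", "gene_b", "weight"])
        )
        _write("module_edges.tsv", pio.write_table, edge_frame)

    with _stage("enrich"):
        sets = pio.read_gene_sets(base / config.gene_sets)
        universe = frozenset(scores)
        collection = GeneSetCollection("pathways", dict(sets), universe)
        scored = table[~table["excluded"]]
        for hit_class in ("suppressor", "enhancer"):
            genes = set(scored.loc[scored["hit_class"] == hit_class, "gene_id"])
            res = enrich(genes, collection, compute_q=True)
            _write(f"enrichment_{hit_class}.tsv", pio.write_table, results_frame(res))

    with _stage("crossmap"):
        orthologs = pio.read_orthologs(base / config.orthologs)
        dys_a = pio.read_dysregulation(base / config.dysregulation_a)
        dys_b = pio.read_dysregulation(base / config.dysregulation_b)
        modifiers = {
            row.gene_id: row.hit_class
            for row in scored.itertuples(index=False)
            if row.hit_class in ("suppressor", "enhancer")
        }
        conserved = conserved_modifiers(modifiers, orthologs)
        report, cross_summary = intersect_dysregulation(conserved, dys_a, dys_b)
        cross_summary["prioritized"] = prioritize(report)
        _write("crossmap_report.tsv", pio.write_table, report)
        (out / "crossmap_summary.json").write_text(
            json.dumps(cross_summary, indent=2, sort_keys=True) + "\n"
        )
        manifest["outputs"]["crossmap_summary.json"] = _sha256(
            out / "crossmap_summary.json"
        )

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def validate_inputs(paths: dict[str, str | Path]) -> list[str]:
    """Per-file format checks; returns a list of failure messages.

    Accepts any subset of the keys ``records, baselines, network,
    gene_sets, orthologs, dysregulation_a, dysregulation_b``.
    """
    readers = {
        "records": pio.read_screen_records,
        "baselines": pio.read_baselines,
        "network": pio.read_network,
        "gene_sets": pio.read_gene_sets,
        "orthologs": pio.read_orthologs,
        "dysregulation_a": pio.read_dysregulation,
        "dysregulation_b": pio.read_dysregulation,
    }
    failures: list[str] = []
    for key, path in paths.items():
        reader = readers.get(key)
        if reader is None:
            failures.append(f"{key}: unknown input kind")
            continue
        path = Path(path)
        if not path.exists():
            failures.append(f"{key}: file not found: {path}")
            continue
        try:
            result = reader(path)
        except Exception as e:  # report, don't raise
            failures.append(f"{key}: {e}")
            continue
        if key == "records":
            seen: set[str] = set()
            for rec in result:
                if rec.clone_id in seen:
                    failures.append(f"records: duplicate clone_id {rec.clone_id!r}")
                seen.add(rec.clone_id)
    return failures
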