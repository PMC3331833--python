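"""Seeded generators for every pipeline input.

The raw screen data and the reference networks behind the original
analysis are not deposited, so the package ships generators that emulate
their statistical structure: per-animal Bernoulli touch responses (5
touches, 70-90 animals per clone) around a 20.6% baseline with ~3%
between-well SD, a planted-partition gene network with confidence
weights, planted suppressor/enhancer modules shifted by a configurable
number of baseline SDs, and mock annotation / ortholog / mouse
dysregulation tables with controllable overlap structure.

All generators are pure functions of (parameters, seed): the same truth
object always yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from polyq_netscreen.enrichment import GeneSetCollection
from polyq_netscreen.screen import PHENOTYPE_FLAGS, Baseline, ScreenRecord


class SyntheticConfigError(ValueError):
    """Raised on infeasible generator parameters."""


@dataclass(frozen=True)
class PlantedModule:
    genes: tuple[str, ...]
    sign: str  # "positive" (suppressor-like) or "negative"
    effect_sd: float  # shift of true responsiveness, in baseline-SD units


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth and parameters for one synthetic study.

    Defaults reproduce the screen geometry the analysis assumes: 5
    touches per animal, 70-90 animals per clone, a 20.6% baseline
    responsiveness with 3% SD (binomial sampling plus ~2.2% between-well
    variation), and three planted 10-gene network modules whose true
    responsiveness is shifted by +/- 2 baseline SDs.
    """

    n_genes: int = 500
    module_sizes: tuple[int, ...] = (10, 10, 10)
    module_effects_sd: tuple[float, ...] = (2.0, -2.0, 2.0)
    p_in: float = 0.6
    p_out: float = 0.01
    baseline_mean: float = 20.6
    baseline_sd: float = 3.0
    well_sd_percent: float = 2.2
    animals_range: tuple[int, int] = (70, 90)
    touches: int = 5
    n_batches: int = 2
    n_control_wells: int = 24
    toxic_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise SyntheticConfigError(
                f"planted modules need {sum(self.module_sizes)} genes but "
                f"n_genes = {self.n_genes}"
            )
        if len(self.module_sizes) != len(self.module_effects_sd):
            raise SyntheticConfigError("one effect size per planted module required")
        for p in (self.p_in, self.p_out):
            if not 0 <= p <= 1:
                raise SyntheticConfigError(f"edge probability {p} outside [0, 1]")

    @property
    def genes(self) -> tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"g{i:0{width}d}" for i in range(1, self.n_genes + 1))

    @property
    def batches(self) -> tuple[str, ...]:
        return tuple(f"month_{i + 1}" for i in range(self.n_batches))

    @property
    def planted_modules(self) -> tuple[PlantedModule, ...]:
        genes = self.genes
        mods = []
        start = 0
        for size, eff in zip(self.module_sizes, self.module_effects_sd):
            mods.append(
                PlantedModule(
                    genes=genes[start : start + size],
                    sign="positive" if eff > 0 else "negative",
                    effect_sd=eff,
                )
            )
            start += size
        return tuple(mods)

    @property
    def planted_genes(self) -> frozenset[str]:
        return frozenset(g for m in self.planted_modules for g in m.genes)

    def true_effects(self) -> dict[str, float]:
        """Gene -> true responsiveness percent.

        Background genes sit at the baseline mean; planted genes are
        shifted by ``effect_sd`` baseline SDs.
        """
        effects = {g: self.baseline_mean for g in self.genes}
        for mod in self.planted_modules:
            shift = mod.effect_sd * self.baseline_sd
            for g in mod.genes:
                effects[g] = float(np.clip(self.baseline_mean + shift, 0.0, 100.0))
        return effects

    def noise_sd_s(self) -> float:
        """Background S-score noise SD implied by the screen geometry."""
        return self.baseline_sd / self.baseline_mean

    def _rng(self, stream: str) -> np.random.Generator:
        streams = {
            "network": 1,
            "screen": 2,
            "signal": 3,
            "annotations": 4,
            "mouse": 5,
            "mouse_truth": 6,
        }
        return np.random.default_rng([streams[stream], self.seed])


def simulate_network(truth: SyntheticTruth) -> nx.Graph:
    """Planted-partition functional gene network with confidence weights.

    Within-module pairs are connected with probability ``p_in`` and
    carry high confidence (Uniform(0.5, 1]); background pairs with
    ``p_out`` and low confidence (Uniform(0, 0.5]).  Each planted module
    is guaranteed connected by a spanning path.
    """
    rng = truth._rng("network")
    g = nx.Graph()
    g.add_nodes_from(truth.genes)
    genes = truth.genes
    module_of: dict[str, int] = {}
    for mi, mod in enumerate(truth.planted_modules):
        for gene in mod.genes:
            module_of[gene] = mi
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genes[i], genes[j]
            same = module_of.get(a) is not None and module_of.get(a) == module_of.get(b)
            p = truth.p_in if same else truth.p_out
            if rng.random() < p:
                lo, hi = (0.5, 1.0) if same else (0.0, 0.5)
                w = lo + (hi - lo) * (1.0 - rng.random())  # (lo, hi]
                g.add_edge(a, b, weight=float(w))
    for mod in truth.planted_modules:  # spanning path keeps modules connected
        for a, b in zip(mod.genes, mod.genes[1:]):
            if not g.has_edge(a, b):
                w = 0.5 + 0.5 * (1.0 - rng.random())
                g.add_edge(a, b, weight=float(w))
    return g


def simulate_screen(
    truth: SyntheticTruth,
    estimate_baseline: bool = False,
) -> tuple[list[ScreenRecord], dict[str, Baseline]]:
    """Per-clone touch-test records plus per-batch baselines.

    One clone per gene; animals per clone ~ Uniform{70..90}; each
    animal's response count ~ Binomial(5, p) with p the gene's true
    responsiveness plus a per-well Gaussian jitter
    (``well_sd_percent``).  A ``toxic_fraction`` of background clones
    carries a random toxicity phenotype flag (planted genes are never
    toxic so the network signal stays intact).

    With ``estimate_baseline`` the per-batch baselines are estimated
    from simulated empty-vector control wells at p = 0.206; otherwise
    the nominal (20.6, 3.0) baseline is attached to every batch.
    """
    rng = truth._rng("screen")
    effects = truth.true_effects()
    lo, hi = truth.animals_range
    records = []
    for gi, gene in enumerate(truth.genes):
        batch = truth.batches[gi % truth.n_batches]
        toxic = (
            gene not in truth.planted_genes
            and rng.random() < truth.toxic_fraction
        )
        flags = frozenset()
        if toxic:
            flags = frozenset({PHENOTYPE_FLAGS[rng.integers(len(PHENOTYPE_FLAGS))]})
        n_animals = int(rng.integers(lo, hi + 1))
        p_well = effects[gene] + rng.normal(0.0, truth.well_sd_percent)
        p_well = float(np.clip(p_well, 0.0, 100.0)) / 100.0
        responses = rng.binomial(truth.touches, p_well, size=n_animals)
        records.append(
            ScreenRecord(
                clone_id=f"clone_{gene}",
                gene_id=gene,
                batch=batch,
                animal_responses=tuple(int(r) for r in responses),
                touches=truth.touches,
                phenotype_flags=flags,
            )
        )
    baselines: dict[str, Baseline] = {}
    if estimate_baseline:
        for batch in truth.batches:
            means = []
            for _ in range(truth.n_control_wells):
                n_animals = int(rng.integers(lo, hi + 1))
                p_well = truth.baseline_mean + rng.normal(0.0, truth.well_sd_percent)
                p_well = float(np.clip(p_well, 0.0, 100.0)) / 100.0
                resp = rng.binomial(truth.touches, p_well, size=n_animals)
                means.append(100.0 * float(np.mean(resp)) / truth.touches)
            baselines[batch] = Baseline(
                mean_percent=float(np.mean(means)),
                sd_percent=float(np.std(means, ddof=1)),
                batch=batch,
            )
        baselines["cumulated"] = Baseline(
            mean_percent=float(np.mean([b.mean_percent for b in baselines.values()])),
            sd_percent=float(np.mean([b.sd_percent for b in baselines.values()])),
            batch="cumulated",
        )
    else:
        for batch in (*truth.batches, "cumulated"):
            baselines[batch] = Baseline(
                truth.baseline_mean, truth.baseline_sd, batch=batch
            )
    return records, baselines


def simulate_smooth_signal(truth: SyntheticTruth) -> tuple[dict[str, float], dict[str, float]]:
    """Direct S-scale signal: planted shifts plus i.i.d. Gaussian noise.

    Returns ``(noisy, clean)`` gene->S maps; the clean signal is the
    planted module shift in S units (effect_sd * baseline_sd /
    baseline_mean), zero elsewhere.  Used to exercise the spectral stage
    in isolation from the screen-simulation stage.
    """
    rng = truth._rng("signal")
    sigma = truth.noise_sd_s()
    clean = {g: 0.0 for g in truth.genes}
    for mod in truth.planted_modules:
        for g in mod.genes:
            clean[g] = mod.effect_sd * sigma
    noisy = {g: clean[g] + float(rng.normal(0.0, sigma)) for g in truth.genes}
    return noisy, clean


def simulate_annotations(
    truth: SyntheticTruth,
    n_random_terms: int = 10,
    genes_per_term: int = 15,
    name: str = "synthetic_pathways",
) -> GeneSetCollection:
    """Mock pathway collection: one exact term per planted module plus
    random terms drawn from the whole gene universe."""
    rng = truth._rng("annotations")
    sets: dict[str, frozenset[str]] = {}
    for i, mod in enumerate(truth.planted_modules, start=1):
        sets[f"planted_module_{i}"] = frozenset(mod.genes)
    genes = list(truth.genes)
    for i in range(1, n_random_terms + 1):
        chosen = rng.choice(len(genes), size=min(genes_per_term, len(genes)), replace=False)
        sets[f"random_term_{i:02d}"] = frozenset(genes[j] for j in chosen)
    return GeneSetCollection(name=name, sets=sets, universe=frozenset(truth.genes))


def simulate_truth_orthologs(
    truth: SyntheticTruth,
    conserved_background_fraction: float = 0.2,
    label_a: str = "CHL2",
    label_b: str = "R6/2",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ortholog and dysregulation tables tied to the truth's own genes.

    Every planted gene is conserved (mouse ortholog ``Mm_<gene>``), as is
    a random fraction of background genes.  Positive-module (suppressor-
    like) genes are up-regulated in model A and, for every second gene,
    also in model B — except the last, which is flipped to exercise the
    oppositely-dysregulated path; negative-module genes are down-
    regulated in one model.  Conserved background genes are dysregulated
    at random in one model.  Together with :func:`simulate_screen` this
    yields a coherent input set for the full pipeline.
    """
    rng = truth._rng("mouse_truth")
    ortho_rows = []
    a_rows, b_rows = [], []
    for gene in truth.genes:
        planted = gene in truth.planted_genes
        if not planted and rng.random() >= conserved_background_fraction:
            continue
        mouse = f"Mm_{gene}"
        ortho_rows.append((gene, mouse, f"cluster_{gene}"))
        if not planted:
            if rng.random() < 0.3:  # some conserved background dysregulated
                direction = "up" if rng.random() < 0.5 else "down"
                if rng.random() < 0.5:
                    a_rows.append((mouse, direction, label_a))
                else:
                    b_rows.append((mouse, direction, label_b))
            continue
        mod = next(m for m in truth.planted_modules if gene in m.genes)
        if mod.sign == "positive":
            a_rows.append((mouse, "up", label_a))
            idx = mod.genes.index(gene)
            if idx == len(mod.genes) - 1:
                b_rows.append((mouse, "down", label_b))  # opposite direction
            elif idx % 2 == 0:
                b_rows.append((mouse, "up", label_b))
        else:
            if rng.random() < 0.5:
                a_rows.append((mouse, "down", label_a))
            else:
                b_rows.append((mouse, "down", label_b))
    orthologs = pd.DataFrame(
        ortho_rows, columns=["worm_gene", "mouse_gene", "cluster_id"]
    )
    table_a = pd.DataFrame(a_rows, columns=["mouse_gene", "direction", "model_label"])
    table_b = pd.DataFrame(b_rows, columns=["mouse_gene", "direction", "model_label"])
    return orthologs, table_a, table_b


@dataclass(frozen=True)
class MouseOverlapSpec:
    """Target structure for the synthetic cross-species fixture.

    Defaults mirror a screen with 662 modifiers (399 suppressors, 263
    enhancers) of which 239 are conserved in the mouse; of the conserved
    genes 49 are dysregulated in at least one mouse model, 6 of those
    oppositely between the two models, and 12 are
    suppressor-and-up-regulated candidates.
    """

    n_suppressors: int = 399
    n_enhancers: int = 263
    n_conserved: int = 239
    in_a_only: int = 20
    in_b_only: int = 14
    in_both_concordant: int = 9
    in_both_opposite: int = 6
    n_suppressor_up: int = 12
    n_background_dysregulated: int = 50

    @property
    def n_modifiers(self) -> int:
        return self.n_suppressors + self.n_enhancers

    @property
    def n_dysregulated(self) -> int:
        return (
            self.in_a_only
            + self.in_b_only
            + self.in_both_concordant
            + self.in_both_opposite
        )

    def validate(self) -> None:
        if self.n_conserved > self.n_modifiers:
            raise SyntheticConfigError("more conserved genes than modifiers")
        if self.n_dysregulated > self.n_conserved:
            raise SyntheticConfigError("more dysregulated genes than conserved genes")
        if self.n_suppressor_up > self.n_dysregulated:
            raise SyntheticConfigError(
                "n_suppressor_up exceeds the number of dysregulated genes"
            )


@dataclass(frozen=True)
class MouseFixture:
    modifiers: dict[str, str]  # worm_gene -> hit_class
    orthologs: pd.DataFrame  # worm_gene, mouse_gene, cluster_id
    table_a: pd.DataFrame  # CHL2-style dysregulation
    table_b: pd.DataFrame  # R6/2-style dysregulation
    expected_summary: dict[str, int]


def simulate_mouse_tables(
    truth: SyntheticTruth,
    overlap: MouseOverlapSpec | None = None,
    label_a: str = "CHL2",
    label_b: str = "R6/2",
) -> MouseFixture:
    """Ortholog map plus two mouse dysregulation tables by construction.

    The tables are assembled so that the cross-species intersection
    reproduces the counts in ``overlap`` exactly, including the number
    of suppressor-and-upregulated priority candidates.  Background
    dysregulated mouse genes (no worm modifier ortholog) are added to
    both tables so the intersection is a real filter.
    """
    overlap = overlap or MouseOverlapSpec()
    overlap.validate()
    rng = truth._rng("mouse")

    supp = [f"w{i:04d}" for i in range(1, overlap.n_suppressors + 1)]
    enh = [
        f"w{i:04d}"
        for i in range(
            overlap.n_suppressors + 1, overlap.n_suppressors + overlap.n_enhancers + 1
        )
    ]
    modifiers = {g: "suppressor" for g in supp}
    modifiers.update({g: "enhancer" for g in enh})

    # slots: (category, direction_a, direction_b, hit_class)
    slots: list[tuple[str, str | None, str | None, str]] = []
    quota = overlap.n_suppressor_up
    categories = (
        [("a_only",)] * overlap.in_a_only
        + [("b_only",)] * overlap.in_b_only
        + [("both_conc",)] * overlap.in_both_concordant
        + [("both_opp",)] * overlap.in_both_opposite
    )
    for (cat,) in categories:
        take_quota = quota > 0
        if cat == "a_only":
            da, db = ("up", None) if take_quota else ("down", None)
        elif cat == "b_only":
            da, db = (None, "up") if take_quota else (None, "down")
        elif cat == "both_conc":
            da = db = "up" if take_quota else "down"
        else:  # both_opp always contains one 'up'
            da, db = "up", "down"
        if take_quota:
            cls = "suppressor"
            quota -= 1
        else:
            # avoid creating extra suppressor-up candidates
            cls = "enhancer" if "up" in (da, db) else "suppressor"
        slots.append((cat, da, db, cls))
    if quota > 0:
        raise SyntheticConfigError(
            "overlap spec cannot accommodate n_suppressor_up "
            "(not enough dysregulated slots)"
        )

    supp_pool = iter(supp)
    enh_pool = iter(enh)
    ortho_rows = []
    a_rows, b_rows = [], []
    mi = 0
    try:
        for cat, da, db, cls in slots:
            mi += 1
            mouse = f"Mm{mi:04d}"
            worm = next(supp_pool if cls == "suppressor" else enh_pool)
            ortho_rows.append((worm, mouse, f"cluster_{mi:04d}"))
            if da:
                a_rows.append((mouse, da, label_a))
            if db:
                b_rows.append((mouse, db, label_b))
        # conserved but not dysregulated
        for _ in range(overlap.n_conserved - overlap.n_dysregulated):
            mi += 1
            mouse = f"Mm{mi:04d}"
            worm = next(supp_pool) if mi % 2 else next(enh_pool)
            ortho_rows.append((worm, mouse, f"cluster_{mi:04d}"))
    except StopIteration:
        raise SyntheticConfigError(
            "overlap spec requires more suppressor or enhancer genes than available"
        )

    # background mouse genes dysregulated without a worm-modifier ortholog
    for j in range(overlap.n_background_dysregulated):
        mouse = f"MmBG{j + 1:04d}"
        direction = "up" if rng.random() < 0.5 else "down"
        if rng.random() < 0.5:
            a_rows.append((mouse, direction, label_a))
        else:
            b_rows.append((mouse, direction, label_b))

    orthologs = pd.DataFrame(
        ortho_rows, columns=["worm_gene", "mouse_gene", "cluster_id"]
    )
    table_a = pd.DataFrame(a_rows, columns=["mouse_gene", "direction", "model_label"])
    table_b = pd.DataFrame(b_rows, columns=["mouse_gene", "direction", "model_label"])
    expected = {
        f"in_{label_a}_only": overlap.in_a_only,
        f"in_{label_b}_only": overlap.in_b_only,
        "in_both_concordant": overlap.in_both_concordant,
        "in_both_opposite": overlap.in_both_opposite,
        "total": overlap.n_dysregulated,
    }
    return MouseFixture(
        modifiers=modifiers,
        orthologs=orthologs,
        table_a=table_a,
        table_b=table_b,
        expected_summary=expected,
    )
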