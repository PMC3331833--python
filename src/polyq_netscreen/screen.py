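"""Touch-response scoring and hit calling for the RNAi screen.

Each RNAi clone is assayed by scoring 5 light touches at the tail on
70-90 F1 young adults.  Per-animal responsiveness (percent of touches
answered) is averaged per clone and converted to an S-score, the relative
change versus the empty-vector baseline:

    S = (percent_response - baseline_mean) / baseline_mean

S = -1 means complete loss of touch response, S = 0 means the clone sits
exactly at baseline.  A clone is a hit (suppressor of neuron dysfunction
for S > 0, enhancer for S < 0) when the whole interval S +/- SD clears a
band of 2.6 baseline standard deviations around 0.  Clones showing
toxicity phenotypes (lethality, larval arrest, ...) are excluded before
scoring and never reach the network analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical ordering of toxicity phenotypes; the first flag present on a
#: record becomes the recorded exclusion reason.
PHENOTYPE_FLAGS: tuple[str, ...] = (
    "lethality",
    "larval_arrest",
    "egg_laying_defect",
    "developmental_delay",
    "morphological_abnormality",
    "other_abnormality",
)

HIT_CLASSES = ("suppressor", "enhancer", "no_effect")

#: Band width multiplier for hit calling, in units of baseline SD.
DEFAULT_MULTIPLIER = 2.6

#: Columns of the S-score table, in stable output order.
SSCORE_COLUMNS = (
    "clone_id",
    "gene_id",
    "batch",
    "n_animals",
    "percent_response",
    "sd_percent",
    "s",
    "s_sd",
    "hit_class",
    "excluded",
    "exclusion_reason",
)


class ScreenInputError(ValueError):
    """Raised when a screen record or baseline violates its domain."""


@dataclass(frozen=True)
class Baseline:
    """Empty-vector control responsiveness for one batch (month).

    Parameters
    ----------
    mean_percent
        Mean responsiveness of control animals, in percent (0, 100].
    sd_percent
        Standard deviation of control responsiveness, in percent.
    batch
        Month label, or ``"cumulated"`` for the whole-screen baseline.
    """

    mean_percent: float
    sd_percent: float
    batch: str = "cumulated"

    def __post_init__(self) -> None:
        if not 0 < self.mean_percent <= 100:
            raise ScreenInputError(
                f"baseline mean_percent must be in (0, 100], got {self.mean_percent}"
            )
        if self.sd_percent < 0:
            raise ScreenInputError(
                f"baseline sd_percent must be >= 0, got {self.sd_percent}"
            )

    @property
    def sd_s(self) -> float:
        """Baseline SD expressed on the S scale (sd_percent / mean_percent)."""
        return self.sd_percent / self.mean_percent


@dataclass(frozen=True)
class ScreenRecord:
    """Raw touch-test result for one RNAi clone.

    ``animal_responses`` holds, per assayed animal, the number of touches
    (out of ``touches``) the animal responded to.
    """

    clone_id: str
    gene_id: str
    batch: str
    animal_responses: tuple[int, ...]
    touches: int = 5
    phenotype_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "animal_responses", tuple(self.animal_responses))
        object.__setattr__(self, "phenotype_flags", frozenset(self.phenotype_flags))
        if self.touches < 1:
            raise ScreenInputError(f"touches must be >= 1, got {self.touches}")
        if len(self.animal_responses) < 1:
            raise ScreenInputError(f"clone {self.clone_id!r}: no animals recorded")
        for r in self.animal_responses:
            if not 0 <= r <= self.touches:
                raise ScreenInputError(
                    f"clone {self.clone_id!r}: response count {r} outside "
                    f"[0, {self.touches}]"
                )
        unknown = self.phenotype_flags - set(PHENOTYPE_FLAGS)
        if unknown:
            raise ScreenInputError(
                f"clone {self.clone_id!r}: unknown phenotype flags {sorted(unknown)}; "
                f"allowed: {list(PHENOTYPE_FLAGS)}"
            )


def percent_responsiveness(responses: int, touches: int = 5) -> float:
    """Percent of touches an animal responded to (4 of 5 -> 80.0).

    Raises
    ------
    ScreenInputError
        If ``responses`` is negative, exceeds ``touches``, or ``touches < 1``.
    """
    if touches < 1:
        raise ScreenInputError(f"touches must be >= 1, got {touches}")
    if not 0 <= responses <= touches:
        raise ScreenInputError(
            f"responses must be in [0, {touches}], got {responses}"
        )
    return 100.0 * responses / touches


def s_score(percent_response: float, baseline_mean: float) -> float:
    """Relative change in responsiveness versus the control baseline.

    ``(percent_response - baseline_mean) / baseline_mean``; equals -1
    exactly when responsiveness is 0 (complete loss of touch response)
    and 0 when the clone matches the baseline.
    """
    if baseline_mean <= 0:
        raise ScreenInputError(f"baseline_mean must be > 0, got {baseline_mean}")
    if not 0 <= percent_response <= 100:
        raise ScreenInputError(
            f"percent_response must be in [0, 100], got {percent_response}"
        )
    return (percent_response - baseline_mean) / baseline_mean


def call_hit(
    s_mean: float,
    s_sd: float,
    baseline_sd_s: float,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> str:
    """Classify a scored clone as suppressor, enhancer or no_effect.

    The interval ``[s_mean - s_sd, s_mean + s_sd]`` must lie strictly
    outside the band ``+/- multiplier * baseline_sd_s`` (the baseline is 0
    on the S scale).  The nearest interval edge must clear the band, so a
    clone exactly on the band edge is no_effect.
    """
    if s_sd < 0:
        raise ScreenInputError(f"s_sd must be >= 0, got {s_sd}")
    if baseline_sd_s < 0:
        raise ScreenInputError(f"baseline_sd_s must be >= 0, got {baseline_sd_s}")
    band = multiplier * baseline_sd_s
    if s_mean - s_sd > band:
        return "suppressor"
    if s_mean + s_sd < -band:
        return "enhancer"
    return "no_effect"


def classify_toxicity(record: ScreenRecord) -> tuple[bool, str | None]:
    """Return ``(excluded, reason)`` for a record.

    A clone is excluded iff it carries any toxicity phenotype flag; the
    reason is the first flag in the canonical ordering
    (lethality before larval arrest before egg-laying defect, ...).
    """
    for flag in PHENOTYPE_FLAGS:
        if flag in record.phenotype_flags:
            return True, flag
    return False, None


def _animal_std(percents: np.ndarray) -> float:
    """Sample SD across animals (ddof=1); 0 for a single animal."""
    if percents.size < 2:
        return 0.0
    return float(np.std(percents, ddof=1))


def score_screen(
    records: Iterable[ScreenRecord],
    baselines: Mapping[str, Baseline] | Baseline,
    multiplier: float = DEFAULT_MULTIPLIER,
) -> pd.DataFrame:
    """Score every clone, excluding toxic ones, into an S-score table.

    Parameters
    ----------
    records
        Raw per-clone touch-test records.
    baselines
        Either a single (cumulated) :class:`Baseline` or a mapping
        ``batch -> Baseline``.  A ``"cumulated"`` entry acts as fallback
        for batches without their own baseline.
    multiplier
        Hit-calling band width in baseline SD units (default 2.6).

    Returns
    -------
    pandas.DataFrame
        One row per clone, columns :data:`SSCORE_COLUMNS`.  Excluded
        clones carry ``excluded=True`` with a reason and an empty
        hit_class; per-clone ``s_sd`` is the SD of per-animal S values
        (equivalently the SD of per-animal percents divided by the
        baseline mean).
    """
    if isinstance(baselines, Baseline):
        baselines = {"cumulated": baselines}
    rows = []
    for rec in records:
        excluded, reason = classify_toxicity(rec)
        base = baselines.get(rec.batch, baselines.get("cumulated"))
        if base is None:
            raise ScreenInputError(
                f"no baseline for batch {rec.batch!r} and no 'cumulated' fallback"
            )
        percents = np.array(
            [percent_responsiveness(r, rec.touches) for r in rec.animal_responses]
        )
        if excluded:
            rows.append(
                {
                    "clone_id": rec.clone_id,
                    "gene_id": rec.gene_id,
                    "batch": rec.batch,
                    "n_animals": len(percents),
                    "percent_response": math.nan,
                    "sd_percent": math.nan,
                    "s": math.nan,
                    "s_sd": math.nan,
                    "hit_class": "",
                    "excluded": True,
                    "exclusion_reason": reason,
                }
            )
            continue
        pr = float(np.mean(percents))
        sd_pct = _animal_std(percents)
        s = s_score(pr, base.mean_percent)
        s_sd = sd_pct / base.mean_percent
        rows.append(
            {
                "clone_id": rec.clone_id,
                "gene_id": rec.gene_id,
                "batch": rec.batch,
                "n_animals": len(percents),
                "percent_response": pr,
                "sd_percent": sd_pct,
                "s": s,
                "s_sd": s_sd,
                "hit_class": call_hit(s, s_sd, base.sd_s, multiplier),
                "excluded": False,
                "exclusion_reason": None,
            }
        )
    return pd.DataFrame(rows, columns=list(SSCORE_COLUMNS))


def screen_summary(table: pd.DataFrame) -> dict[str, dict[str, int]]:
    """Clone- and gene-level bookkeeping of an S-score table.

    Gene-level counts deduplicate clones targeting the same gene: a gene
    is a modifier if any of its clones is a hit; a gene whose clones are
    all toxic counts as toxic.  When a gene has clones of both hit signs
    it is assigned the class of the clone with the largest absolute S.
    ``total_modifiers = suppressor + enhancer`` at each level.
    """
    counts = {"clone": {}, "gene": {}}
    if table.empty:
        zero = {
            "toxic": 0,
            "no_effect": 0,
            "suppressor": 0,
            "enhancer": 0,
            "total_modifiers": 0,
            "total": 0,
        }
        return {"clone": dict(zero), "gene": dict(zero)}

    cl = counts["clone"]
    cl["toxic"] = int(table["excluded"].sum())
    for cls in HIT_CLASSES:
        cl[cls] = int((table["hit_class"] == cls).sum())
    cl["total_modifiers"] = cl["suppressor"] + cl["enhancer"]
    cl["total"] = len(table)

    gene_class: dict[str, str] = {}
    gene_best: dict[str, float] = {}
    for row in table.itertuples(index=False):
        g = row.gene_id
        if row.excluded:
            gene_class.setdefault(g, "toxic")
            continue
        cur = gene_class.get(g)
        if row.hit_class in ("suppressor", "enhancer"):
            mag = abs(row.s)
            if cur not in ("suppressor", "enhancer") or mag > gene_best.get(g, -1.0):
                gene_class[g] = row.hit_class
                gene_best[g] = mag
        elif cur in (None, "toxic"):
            gene_class[g] = "no_effect"
    gl = counts["gene"]
    for label in ("toxic", "no_effect", "suppressor", "enhancer"):
        gl[label] = sum(1 for c in gene_class.values() if c == label)
    gl["total_modifiers"] = gl["suppressor"] + gl["enhancer"]
    gl["total"] = len(gene_class)
    return counts


def confirm_hits(primary: pd.DataFrame, secondary: pd.DataFrame) -> pd.DataFrame:
    """Intersect hit calls from two screen passes.

    A clone is confirmed iff it is a hit of the same sign in both passes;
    returns the primary rows of confirmed clones with an added
    ``confirmed`` column (the full primary table is returned, non-hits
    and unconfirmed hits carry ``confirmed=False``).
    """
    sec = secondary.set_index("clone_id")["hit_class"]
    confirmed = []
    for row in primary.itertuples(index=False):
        ok = (
            row.hit_class in ("suppressor", "enhancer")
            and sec.get(row.clone_id, "") == row.hit_class
        )
        confirmed.append(bool(ok))
    out = primary.copy()
    out["confirmed"] = confirmed
    return out


def modifier_gene_scores(table: pd.DataFrame) -> dict[str, float]:
    """Gene -> mean S over that gene's scored (non-excluded) clones.

    This is the 'signal' handed to the network smoothing stage: every
    gene with an S score participates, hits and no-effect genes alike.
    """
    scored = table[~table["excluded"]]
    return scored.groupby("gene_id")["s"].mean().to_dict()
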