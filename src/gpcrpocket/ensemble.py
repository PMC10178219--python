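"""Model-ensemble post-processing.

After a modeling run produces an ensemble of receptor models, the
pocket volume of every model is measured, the per-receptor median
volume is taken, and models outside a ±200 Å³ band around that median
are discarded; the surviving models are ranked by total score and the
best k (default 5) are selected.  A pocket-volume difference against a
reference structure is classified as within natural variation
(|Δ| ≤ 200 Å³), deviating (shrunken/enlarged), or — at three times the
band — a failed pocket construction.  Docking post-processing counts
interface scores at or below −6 REU as successful poses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, ResolutionError
from .geometry import LabeledPointSet, pocket_volume
from .numbering import PocketDefinition, ResidueMap, resolve
from .structure_io import StructureModel

__all__ = [
    "ModelRecord",
    "FilterOutcome",
    "VolumeDifference",
    "median_volume",
    "filter_by_volume",
    "select_best",
    "classify_volume_difference",
    "trajectory_volumes",
    "count_docking_successes",
    "VOLUME_BAND",
    "TOP_K",
    "DOCKING_CUTOFF",
]

#: natural pocket-size variation band, Å³
VOLUME_BAND = 200.0
#: number of best-scoring models kept after filtering
TOP_K = 5
#: interface-score success cutoff, REU ("−6 REU or lower")
DOCKING_CUTOFF = -6.0


@dataclass
class ModelRecord:
    label: str
    volume: float
    total_score: float | None = None
    interface_score: float | None = None

    def __post_init__(self) -> None:
        if self.volume is not None and self.volume <= 0:
            raise FormatError(f"model {self.label!r} has non-positive volume")


@dataclass
class FilterOutcome:
    median_volume: float
    band: float
    passing: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)


def median_volume(volumes: Sequence[float]) -> float:
    """Median of a volume list; even counts average the two middle values."""
    if len(volumes) == 0:
        raise FormatError("cannot take the median of an empty volume list")
    return float(np.median(np.asarray(volumes, dtype=float)))


def filter_by_volume(
    records: Sequence[ModelRecord], band: float = VOLUME_BAND
) -> FilterOutcome:
    """Keep models within ±``band`` Å³ of the ensemble median volume.

    The median is taken over *all* input records and the band is a
    closed interval (|V − median| == band passes).
    """
    if not records:
        raise FormatError("empty ensemble")
    med = median_volume([r.volume for r in records])
    passing = [r.label for r in records if abs(r.volume - med) <= band]
    return FilterOutcome(median_volume=med, band=band, passing=passing)


def select_best(
    outcome: FilterOutcome,
    scores: dict[str, float],
    k: int = TOP_K,
) -> list[str]:
    """The k best-scoring (lowest total score) labels among the passing set.

    Ties break lexicographically by label for determinism.  The result
    is also recorded on ``outcome.selected``.
    """
    missing = [lab for lab in outcome.passing if lab not in scores]
    if missing:
        raise FormatError(f"no score for passing model(s): {missing[:3]}")
    ranked = sorted(outcome.passing, key=lambda lab: (scores[lab], lab))
    outcome.selected = ranked[:k]
    return outcome.selected


@dataclass(frozen=True)
class VolumeDifference:
    """Classification of a model-vs-reference pocket volume difference."""

    delta: float
    category: str   # within_natural_variation | deviating | failed
    direction: str  # shrunken | enlarged | none


def classify_volume_difference(
    delta: float, band: float = VOLUME_BAND
) -> VolumeDifference:
    """Classify a pocket-volume difference against the natural-variation band.

    |Δ| ≤ band: within natural variation; band < |Δ| ≤ 3·band: a
    deviating (shrunken or enlarged) pocket; |Δ| > 3·band: a failed
    pocket construction.  Boundaries are inclusive on the benign side.
    """
    if band <= 0:
        raise FormatError("band must be positive")
    mag = abs(delta)
    if mag <= band:
        return VolumeDifference(delta, "within_natural_variation", "none")
    direction = "shrunken" if delta < 0 else "enlarged"
    if mag <= 3 * band:
        return VolumeDifference(delta, "deviating", direction)
    return VolumeDifference(delta, "failed", direction)


def trajectory_volumes(
    series: Sequence[tuple[str, StructureModel]],
    rmap: ResidueMap,
    pocket: PocketDefinition,
) -> list[tuple[str, float]]:
    """Pocket volume along an ordered structure series (e.g. relax steps)."""
    out = []
    for label, model in series:
        try:
            resolved = resolve(rmap, model, pocket.surrogate_ids)
        except ResolutionError as exc:
            raise ResolutionError(f"structure {label!r}: {exc}") from exc
        out.append((label, pocket_volume(LabeledPointSet.from_resolved(resolved))))
    return out


def count_docking_successes(
    scores: Iterable[float], cutoff: float = DOCKING_CUTOFF
) -> int:
    """Number of interface scores at or below the success cutoff."""
    return sum(1 for s in scores if s <= cutoff)


def ensemble_report_tsv(
    records: Sequence[ModelRecord],
    outcome: FilterOutcome,
    reference_volume: float | None = None,
) -> str:
    """Tabular per-model report: volume, score, filter and selection flags,
    and (if a reference volume is given) the classified volume difference."""
    passing = set(outcome.passing)
    selected = set(outcome.selected)
    lines = ["label\tvolume\ttotal_score\tpass_flag\tselected_flag"
             "\tdelta_vs_reference\tcategory"]
    for r in records:
        if reference_volume is not None:
            diff = classify_volume_difference(r.volume - reference_volume,
                                              outcome.band)
            delta_txt, cat = f"{diff.delta:.1f}", diff.category
        else:
            delta_txt, cat = "", ""
        score_txt = "" if r.total_score is None else f"{r.total_score:.3f}"
        lines.append(
            f"{r.label}\t{r.volume:.1f}\t{score_txt}"
            f"\t{int(r.label in passing)}\t{int(r.label in selected)}"
            f"\t{delta_txt}\t{cat}"
        )
    return "\n".join(lines) + "\n"
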