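"""Image-level toxicity scoring and group statistics.

The core statistic is the *toxicity probability* of a sample image: the
percentage of its tiles the classifier calls positive. For the soma
compartment the statistical sample unit is one quadrant segment of a
local image (four segments per captured image, 36 tiles each); for the
axon compartment it is the whole local image (16 tiles).

From per-sample percentages the module builds per-condition summaries
(mean +/- SEM), the negative-control decision line (pooled mean of the
vehicle and negative compound samples plus twice their sample SD), and
one-way ANOVA followed by Dunnett's many-to-one comparison against the
vehicle group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classifier import TilePrediction, TrainedTileModel, predict_tiles
from .errors import InsufficientDataError, UsageError
from .images import AreaImage
from .phenotypes import AreaKind
from .tiling import split_soma_local_image


@dataclass(frozen=True)
class ToxicityProbability:
    """Percent of positive tiles in one sample image."""

    image_id: str
    area_kind: AreaKind
    n_tiles: int
    n_positive: int
    compound: str = ""
    concentration: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        if self.n_tiles < 1:
            raise UsageError("n_tiles must be >= 1")
        if not 0 <= self.n_positive <= self.n_tiles:
            raise UsageError("n_positive must be within [0, n_tiles]")

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_tiles


@dataclass(frozen=True)
class CompoundSummary:
    """Mean +/- SEM toxicity probability for one compound x concentration."""

    compound: str
    concentration: str
    area_kind: AreaKind
    mean_percent: float
    sem_percent: float
    n_images: int


@dataclass(frozen=True)
class ToxicityLine:
    """Negative-control decision threshold: mean + 2 * sample SD."""

    area_kind: AreaKind
    threshold_percent: float
    negative_mean: float
    negative_sd: float
    source_image_ids: tuple[str, ...]


@dataclass(frozen=True)
class StatTestResult:
    comparison: str
    statistic: float
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def toxicity_probability(predictions: Sequence[TilePrediction],
                         area_kind: AreaKind = "soma") -> ToxicityProbability:
    """Aggregate one sample image's tile calls into its percent positive."""
    if not predictions:
        raise UsageError("empty prediction list")
    parents = {p.parent_id for p in predictions}
    if len(parents) != 1:
        raise UsageError(f"predictions span multiple images: {sorted(parents)}")
    n_pos = sum(bool(p.positive_call) for p in predictions)
    return ToxicityProbability(image_id=predictions[0].parent_id,
                               area_kind=area_kind, n_tiles=len(predictions),
                               n_positive=n_pos)


def score_image(model: TrainedTileModel, image: AreaImage) -> list[ToxicityProbability]:
    """Score one local image into its per-sample toxicity probabilities.

    Returns four results for a soma image (one per quadrant segment) and
    one for an axon image.
    """
    samples = (split_soma_local_image(image) if image.area_kind == "soma"
               else [image])
    out = []
    for s in samples:
        preds = predict_tiles(model, s)
        n_pos = sum(p.positive_call for p in preds)
        out.append(ToxicityProbability(
            image_id=s.image_id, area_kind=image.area_kind,
            n_tiles=len(preds), n_positive=n_pos,
            compound=image.compound,
            concentration=image.concentration.label if image.concentration else "",
            split=image.split or ""))
    return out


def score_images(model: TrainedTileModel,
                 images: Iterable[AreaImage]) -> list[ToxicityProbability]:
    out: list[ToxicityProbability] = []
    for img in images:
        out.extend(score_image(model, img))
    return out


def summarize(probs: Sequence[ToxicityProbability]) -> list[CompoundSummary]:
    """Per-condition mean +/- SEM of per-sample percentages."""
    groups: dict[tuple, list[float]] = {}
    kinds: dict[tuple, str] = {}
    for p in probs:
        key = (p.compound, p.concentration)
        groups.setdefault(key, []).append(p.percent_positive)
        kinds[key] = p.area_kind
    out = []
    for key in sorted(groups):
        vals = np.asarray(groups[key])
        n = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(CompoundSummary(compound=key[0], concentration=key[1],
                                   area_kind=kinds[key],
                                   mean_percent=float(vals.mean()),
                                   sem_percent=sem, n_images=n))
    return out


def toxicity_line(negatives: Sequence[ToxicityProbability]) -> ToxicityLine:
    """Decision line from pooled vehicle + negative-compound samples."""
    if len(negatives) < 2:
        raise InsufficientDataError(
            "need at least 2 negative-control samples for the line")
    kinds = {p.area_kind for p in negatives}
    if len(kinds) != 1:
        raise UsageError(f"negatives mix area kinds: {sorted(kinds)}")
    vals = np.asarray([p.percent_positive for p in negatives], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    return ToxicityLine(area_kind=kinds.pop(),
                        threshold_percent=mean + 2.0 * sd,
                        negative_mean=mean, negative_sd=sd,
                        source_image_ids=tuple(p.image_id for p in negatives))


def exceeds_line(value: ToxicityProbability | CompoundSummary | float,
                 line: ToxicityLine) -> bool:
    """Strict exceedance; a value exactly on the line does not exceed it."""
    if isinstance(value, ToxicityProbability):
        if value.area_kind != line.area_kind:
            raise UsageError("area kind mismatch between value and line")
        v = value.percent_positive
    elif isinstance(value, CompoundSummary):
        if value.area_kind != line.area_kind:
            raise UsageError("area kind mismatch between summary and line")
        v = value.mean_percent
    else:
        v = float(value)
    return v > line.threshold_percent


def anova_dunnett(groups: Mapping[str, Sequence[float]], control: str,
                  alpha: float = 0.05) -> list[StatTestResult]:
    """Omnibus one-way ANOVA plus Dunnett many-to-one vs the control group."""
    from .stats import dunnett_from_samples

    if control not in groups:
        raise UsageError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise UsageError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientDataError(f"group {name!r} has n < 2")
    names = [n for n in groups if n != control]
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    ctrl = np.asarray(groups[control], dtype=float)

    all_arrays = [ctrl] + arrays
    if all(np.ptp(a) == 0 for a in all_arrays) and len(
            {a.mean() for a in all_arrays}) == 1:
        f_stat, f_p = 0.0, 1.0  # all observations identical: no evidence
    else:
        f_stat, f_p = sps.f_oneway(*all_arrays)
    results = [StatTestResult(comparison="ANOVA", statistic=float(f_stat),
                              p_value=float(f_p), alpha=alpha)]
    tstats, pvals = dunnett_from_samples(arrays, ctrl)
    for name, t, p in zip(names, tstats, pvals):
        results.append(StatTestResult(comparison=f"{name} vs {control}",
                                      statistic=float(t), p_value=float(p),
                                      alpha=alpha))
    return results


# ---------------------------------------------------------------------------
# Tabular export helpers
# ---------------------------------------------------------------------------

def probabilities_frame(probs: Sequence[ToxicityProbability]) -> pd.DataFrame:
    return pd.DataFrame([{
        "image_id": p.image_id, "compound": p.compound,
        "concentration": p.concentration, "area_kind": p.area_kind,
        "n_tiles": p.n_tiles, "n_positive": p.n_positive,
        "percent_positive": p.percent_positive,
    } for p in probs])


def summaries_frame(summaries: Sequence[CompoundSummary],
                    line: ToxicityLine | None = None) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "compound": s.compound, "concentration": s.concentration,
            "area_kind": s.area_kind, "mean_percent": s.mean_percent,
            "sem_percent": s.sem_percent, "n_images": s.n_images,
        }
        if line is not None:
            row["exceeds_line"] = exceeds_line(s, line)
        rows.append(row)
    return pd.DataFrame(rows)
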