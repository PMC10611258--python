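"""2D mechanism-of-action integration of the two compartment scores.

Each compound x concentration condition becomes a point in the plane
(axon toxicity % on x, soma toxicity % on y). Crossing the two
negative-control decision lines partitions the plane into four readings:

* ``none`` - neither compartment exceeds its line;
* ``soma-dominant`` - only the soma score exceeds its line;
* ``axon-dominant`` - only the axon score exceeds its line;
* ``mixed`` - both exceed.

Pairwise separation between conditions is tested with a two-group
one-way MANOVA (Wilks' Lambda) on replicate-level points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import PairingError, UsageError
from .scoring import (CompoundSummary, StatTestResult, ToxicityLine,
                      ToxicityProbability, exceeds_line)
from .stats import wilks_manova

Category = Literal["none", "soma-dominant", "axon-dominant", "mixed"]


@dataclass(frozen=True)
class MoAPoint:
    """One (axon %, soma %) coordinate; per condition mean or per replicate."""

    compound: str
    concentration: str
    axon_percent: float
    soma_percent: float
    mode: Literal["mean", "replicate"] = "mean"
    replicate: int | None = None

    def __post_init__(self) -> None:
        for v in (self.axon_percent, self.soma_percent):
            if not 0.0 <= v <= 100.0:
                raise UsageError(f"coordinate {v} outside [0, 100]")

    @property
    def condition(self) -> str:
        return f"{self.compound} {self.concentration}".strip()


@dataclass(frozen=True)
class MoACall:
    compound: str
    concentration: str
    category: Category


def make_moa_points(soma_summaries: Sequence[CompoundSummary],
                    axon_summaries: Sequence[CompoundSummary]) -> list[MoAPoint]:
    """One mean-mode point per condition present in both compartments."""
    axon = {(s.compound, s.concentration): s for s in axon_summaries}
    points = []
    seen = set()
    for s in soma_summaries:
        key = (s.compound, s.concentration)
        if key not in axon:
            raise PairingError(f"no axon summary for {key}")
        seen.add(key)
        points.append(MoAPoint(compound=s.compound, concentration=s.concentration,
                               axon_percent=axon[key].mean_percent,
                               soma_percent=s.mean_percent, mode="mean"))
    missing = set(axon) - seen
    if missing:
        raise PairingError(f"no soma summary for {sorted(missing)}")
    return points


def make_replicate_points(soma_probs: Sequence[ToxicityProbability],
                          axon_probs: Sequence[ToxicityProbability]) -> list[MoAPoint]:
    """Replicate-mode points, paired by sample index within each condition.

    The two compartments have different replicate counts per condition;
    pairing truncates to the smaller count.
    """
    def grouped(probs):
        g: dict[tuple, list[ToxicityProbability]] = {}
        for p in probs:
            g.setdefault((p.compound, p.concentration), []).append(p)
        return g

    soma_g, axon_g = grouped(soma_probs), grouped(axon_probs)
    if set(soma_g) != set(axon_g):
        raise PairingError(
            f"conditions differ between compartments: "
            f"{sorted(set(soma_g) ^ set(axon_g))}")
    points = []
    for key in sorted(soma_g):
        s_list = sorted(soma_g[key], key=lambda p: p.image_id)
        a_list = sorted(axon_g[key], key=lambda p: p.image_id)
        for i, (s, a) in enumerate(zip(s_list, a_list)):
            points.append(MoAPoint(
                compound=key[0], concentration=key[1],
                axon_percent=a.percent_positive, soma_percent=s.percent_positive,
                mode="replicate", replicate=i))
    return points


def classify_moa(point: MoAPoint, soma_line: ToxicityLine,
                 axon_line: ToxicityLine) -> MoACall:
    """Quadrant reading of a point against the two decision lines."""
    if soma_line.area_kind != "soma" or axon_line.area_kind != "axon":
        raise UsageError("lines must be (soma, axon) in that order")
    soma_hit = exceeds_line(point.soma_percent, soma_line)
    axon_hit = exceeds_line(point.axon_percent, axon_line)
    category: Category
    if soma_hit and axon_hit:
        category = "mixed"
    elif soma_hit:
        category = "soma-dominant"
    elif axon_hit:
        category = "axon-dominant"
    else:
        category = "none"
    return MoACall(point.compound, point.concentration, category)


def manova_pairwise(points: Sequence[MoAPoint],
                    alpha: float = 0.05) -> tuple[list[str], pd.DataFrame,
                                                  list[StatTestResult]]:
    """Two-group Wilks' Lambda MANOVA for every unordered pair of conditions.

    Returns the retained condition labels, the symmetric p-value matrix
    (NaN diagonal) and the flat list of test results. Conditions with
    fewer than 3 replicate points are excluded with a warning (their 2x2
    within-group covariance would be rank deficient).
    """
    groups: dict[str, list[list[float]]] = {}
    for p in points:
        if p.mode != "replicate":
            raise UsageError("pairwise MANOVA requires replicate-mode points")
        groups.setdefault(p.condition, []).append(
            [p.axon_percent, p.soma_percent])
    labels = []
    for name in groups:
        if len(groups[name]) < 3:
            warnings.warn(f"excluding {name!r} from MANOVA (n < 3)")
        else:
            labels.append(name)
    mat = pd.DataFrame(np.full((len(labels), len(labels)), np.nan),
                       index=labels, columns=labels)
    results = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            res = wilks_manova([np.asarray(groups[a]), np.asarray(groups[b])])
            mat.loc[a, b] = mat.loc[b, a] = res.p_value
            results.append(StatTestResult(
                comparison=f"{a} vs {b}", statistic=res.wilks_lambda,
                p_value=res.p_value, alpha=alpha))
    return labels, mat, results


def plot_moa(points: Sequence[MoAPoint], soma_line: ToxicityLine,
             axon_line: ToxicityLine, path) -> None:
    """Scatter plot of the 2D integration with both decision lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    conditions = sorted({p.condition for p in points})
    cmap = plt.get_cmap("tab20")
    for k, cond in enumerate(conditions):
        xs = [p.axon_percent for p in points if p.condition == cond]
        ys = [p.soma_percent for p in points if p.condition == cond]
        ax.scatter(xs, ys, s=22, color=cmap(k % 20), label=cond, alpha=0.8)
    ax.axhline(soma_line.threshold_percent, ls="--", lw=1, color="gray")
    ax.axvline(axon_line.threshold_percent, ls="--", lw=1, color="gray")
    ax.set_xlabel("axon-area toxicity probability (%)")
    ax.set_ylabel("soma-area toxicity probability (%)")
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax.legend(fontsize=6, loc="upper right", ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
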