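"""Classifier and ranking assessment: ROC, cost curves, top-n accuracy, MCC.

Cost curves are computed under equal misclassification costs, so the
x-axis is the probability cost PC = fraction of positive instances and
every ROC point (fpr, tpr) maps to the line

    NE(PC) = (1 - tpr) * PC + fpr * (1 - PC)

whose values at PC = 0 and PC = 1 are exactly (fpr, 1 - tpr).  The cost
curve proper is the exact lower envelope of those lines over PC in [0, 1];
the always-negative / always-positive trivial classifiers give the
reference envelope min(PC, 1 - PC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float


def roc(scores: Sequence[float], labels: Sequence[bool]) -> list[RocPoint]:
    """ROC points for a higher-is-more-positive score.

    One point per distinct threshold (ties grouped) plus the (0, 0) and
    (1, 1) endpoints; sorted by decreasing threshold so fpr and tpr are
    nondecreasing.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    points = [RocPoint(threshold=math.inf, fpr=0.0, tpr=0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        threshold = scores[i]
        while i < n and scores[i] == threshold:
            if labels[i]:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append(RocPoint(threshold=float(threshold), fpr=fp / n_neg, tpr=tp / n_pos))
    return points


# ---------------------------------------------------------------------------
# Cost curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostLine:
    """NE(PC) = intercept + slope * PC for one ROC operating point."""

    fpr: float
    tpr: float
    cost_ratio: float = 1.0  # optional unequal-cost scale on the PC axis

    @property
    def intercept(self) -> float:
        return self.fpr

    @property
    def slope(self) -> float:
        return (1.0 - self.tpr) - self.fpr

    def value_at(self, pc: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * pc


def cost_lines(points: Iterable[RocPoint], cost_ratio: float = 1.0) -> list[CostLine]:
    """One cost line per ROC point."""
    return [CostLine(fpr=p.fpr, tpr=p.tpr, cost_ratio=cost_ratio) for p in points]


def trivial_lines() -> list[CostLine]:
    """The always-negative (NE = PC) and always-positive (NE = 1 - PC) lines."""
    return [CostLine(fpr=0.0, tpr=0.0), CostLine(fpr=1.0, tpr=1.0)]


@dataclass
class CostCurve:
    """Lower envelope of a set of cost lines over PC in [0, 1].

    ``vertices`` is the ordered breakpoint list [(pc, ne), ...] with
    pc running from 0 to 1; the curve is piecewise linear and concave.
    """

    vertices: list[tuple[float, float]]

    def value_at(self, pc: float | np.ndarray) -> float | np.ndarray:
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return np.interp(pc, xs, ys)


def lower_envelope(lines: Sequence[CostLine]) -> CostCurve:
    """Exact pointwise minimum of the lines over PC in [0, 1].

    Monotone-chain construction on lines sorted by slope; dominated lines
    never contribute a segment.
    """
    if not lines:
        raise ValueError("need at least one line")
    # per slope keep only the lowest intercept
    best: dict[float, CostLine] = {}
    for line in lines:
        kept = best.get(line.slope)
        if kept is None or line.intercept < kept.intercept:
            best[line.slope] = line
    # active lines of a lower envelope run left-to-right in decreasing slope
    candidates = sorted(best.values(), key=lambda l: -l.slope)

    def intersection(p: CostLine, q: CostLine) -> float:
        return (q.intercept - p.intercept) / (p.slope - q.slope)

    hull: list[CostLine] = []
    for line in candidates:
        while len(hull) >= 2 and intersection(hull[-2], line) <= intersection(
            hull[-2], hull[-1]
        ):
            hull.pop()
        hull.append(line)
    # clip the chain to [0, 1]
    breaks = [intersection(hull[i], hull[i + 1]) for i in range(len(hull) - 1)]
    vertices: list[tuple[float, float]] = []
    xs = [0.0] + [x for x in breaks if 0.0 < x < 1.0] + [1.0]
    for x in xs:
        y = min(line.value_at(x) for line in hull)
        vertices.append((float(x), float(y)))
    return CostCurve(vertices=vertices)


@dataclass
class EnvelopeDifference:
    """Signed vertical comparison of two cost curves (A minus B)."""

    max_abs: float
    mean: float  # exact integral mean of A - B over [0, 1]
    a_below_fraction: float  # measure of {pc : A(pc) < B(pc)}


def envelope_difference(curve_a: CostCurve, curve_b: CostCurve) -> EnvelopeDifference:
    """Exact difference statistics on the merged breakpoint grid.

    The difference of two piecewise-linear curves is piecewise linear, so
    its extrema sit on the union of their vertices and its integral is the
    trapezoid sum there.
    """
    xs = sorted({v[0] for v in curve_a.vertices} | {v[0] for v in curve_b.vertices})
    diff = np.array([float(curve_a.value_at(x)) - float(curve_b.value_at(x)) for x in xs])
    xs_arr = np.array(xs)
    widths = np.diff(xs_arr)
    mean = float(np.sum((diff[:-1] + diff[1:]) / 2.0 * widths))
    below = 0.0
    for i in range(len(xs) - 1):
        d0, d1 = diff[i], diff[i + 1]
        w = widths[i]
        if d0 < 0 and d1 < 0:
            below += w
        elif (d0 < 0) != (d1 < 0) and d0 != d1:
            x_zero = d0 / (d0 - d1)
            below += w * (x_zero if d0 < 0 else 1.0 - x_zero)
    return EnvelopeDifference(
        max_abs=float(np.max(np.abs(diff))),
        mean=mean,
        a_below_fraction=float(below),
    )


# ---------------------------------------------------------------------------
# Top-n accuracy and MCC
# ---------------------------------------------------------------------------

def topn_accuracy(
    ranked_pairs: Sequence[tuple[str, str]],
    gold_positives: Iterable[tuple[str, str]],
    ns: Iterable[int],
) -> list[tuple[int, float]]:
    """Accuracy (confirmed positives / n) at each list depth n.

    ``ranked_pairs`` must already be sorted strongest-first.  Depths
    beyond the list length are dropped (logged).
    """
    positives = set(gold_positives)
    hits = np.cumsum([pair in positives for pair in ranked_pairs])
    curve = []
    for n in ns:
        if n < 1:
            raise ValueError("n must be >= 1")
        if n > len(ranked_pairs):
            log.info("top-n curve truncated: n=%d exceeds list length %d", n, len(ranked_pairs))
            continue
        curve.append((n, float(hits[n - 1] / n)))
    return curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any root factor is zero."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denominator = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denominator == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denominator)


def confusion_counts(
    predicted_positive: Sequence[bool], actual_positive: Sequence[bool]
) -> ConfusionCounts:
    predicted = np.asarray(predicted_positive, dtype=bool)
    actual = np.asarray(actual_positive, dtype=bool)
    return ConfusionCounts(
        tp=int((predicted & actual).sum()),
        tn=int((~predicted & ~actual).sum()),
        fp=int((predicted & ~actual).sum()),
        fn=int((~predicted & actual).sum()),
    )


# ---------------------------------------------------------------------------
# Ranking external pair lists
# ---------------------------------------------------------------------------

def rank_external(
    pairs: Sequence[tuple[str, str]],
    probabilities: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Order an external pair list by descending positive-class probability.

    ``probabilities`` holds the classifier score for every pair whose
    features were computable; listed pairs without one are placed last and
    flagged.  Ties are broken deterministically by pair id.
    """
    rows = []
    for pair in pairs:
        probability = probabilities.get(pair)
        rows.append(
            {
                "protein_a": pair[0],
                "protein_b": pair[1],
                "score": probability if probability is not None else np.nan,
                "has_features": probability is not None,
            }
        )
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "score", "has_features"])
    if df.empty:
        return df
    return df.sort_values(
        by=["has_features", "score", "protein_a", "protein_b"],
        ascending=[False, False, True, True],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Curve file output
# ---------------------------------------------------------------------------

def write_roc(points: Sequence[RocPoint], path) -> None:
    pd.DataFrame(
        {"threshold": [p.threshold for p in points],
         "fpr": [p.fpr for p in points],
         "tpr": [p.tpr for p in points]}
    ).to_csv(path, sep="\t", index=False)


def write_cost_curve(curve: CostCurve, path) -> None:
    pd.DataFrame(curve.vertices, columns=["pc", "ne"]).to_csv(path, sep="\t", index=False)


def write_topn(curve: Sequence[tuple[int, float]], path) -> None:
    pd.DataFrame(curve, columns=["n", "accuracy"]).to_csv(path, sep="\t", index=False)
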