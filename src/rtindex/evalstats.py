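"""Evaluation statistics for detector validation and score analysis.

Covers the standard retrieval metrics (precision, recall, F1) computed from
per-type confusion counts, curator-vs-classifier agreement rates on paired
presence/absence labels, Spearman rank-order correlation, and the first-order
partial correlation

    y_abc = (r_ab − r_ac·r_bc) / sqrt((1 − r_ac²)(1 − r_bc²))

used to adjust a pairwise correlation for a third variable. Disagreements
between curator and classifier are split into false positives/negatives under
the convention that the curator is always correct.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "precision_recall_f1",
    "agreement_rate",
    "spearman",
    "partial_correlation",
    "agreement_to_csv",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator vanished; the value is undefined, not zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-entity-type confusion counts against a curated gold standard."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); raises when a denominator is zero.

    F1 is the harmonic mean 2PR/(P+R), taken as 0 when P = R = 0.
    """
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: tp + fp = 0")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn = 0")
    p = counts.tp / (counts.tp + counts.fp)
    r = counts.tp / (counts.tp + counts.fn)
    f1 = 0.0 if (p + r) == 0 else 2 * p * r / (p + r)
    return p, r, f1


def agreement_rate(
    curated_labels: Mapping[str, Mapping[str, bool]],
    tool_labels: Mapping[str, Mapping[str, bool]],
) -> dict[str, dict[str, float]]:
    """Per-type curator-vs-classifier agreement on presence/absence labels.

    Both arguments map paper id → {entity type → present?}. Papers present in
    one set but not the other raise. For each entity type the result carries
    the agreement rate plus false-positive / false-negative counts and rates
    (curator taken as ground truth).
    """
    missing = sorted(set(curated_labels) ^ set(tool_labels))
    if missing:
        raise ValueError(f"unpaired papers: {missing}")
    if not curated_labels:
        raise ValueError("no papers to compare")
    types = sorted({t for labels in curated_labels.values() for t in labels})
    n = len(curated_labels)
    out: dict[str, dict[str, float]] = {}
    for t in types:
        fp = fn = agree = 0
        for paper, curated in curated_labels.items():
            truth = bool(curated.get(t, False))
            pred = bool(tool_labels[paper].get(t, False))
            if pred == truth:
                agree += 1
            elif pred and not truth:
                fp += 1
            else:
                fn += 1
        out[t] = {
            "n": n,
            "agreement": agree / n,
            "false_positives": fp,
            "false_negatives": fn,
            "fp_rate": fp / n,
            "fn_rate": fn / n,
        }
    return out


def spearman(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Spearman rank-order correlation: Pearson correlation of the ranks.

    Ties receive average ranks. Constant input is undefined and raises.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-D and of equal length")
    if xs.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise UndefinedMetricError("spearman undefined for a constant vector")
    rx = rankdata(xs)  # average ranks for ties
    ry = rankdata(ys)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def partial_correlation(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation of A and B adjusting for C.

    All three inputs are pairwise correlation coefficients in [−1, 1];
    |r_ac| = 1 or |r_bc| = 1 leaves the adjustment undefined and raises.
    """
    for name, r in (("r_ab", r_ab), ("r_ac", r_ac), ("r_bc", r_bc)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} = {r} outside [-1, 1]")
    if abs(r_ac) >= 1.0 or abs(r_bc) >= 1.0:
        raise UndefinedMetricError("partial correlation undefined: |r| = 1 with the adjusting variable")
    return (r_ab - r_ac * r_bc) / math.sqrt((1.0 - r_ac**2) * (1.0 - r_bc**2))


def agreement_to_csv(agreement: Mapping[str, Mapping[str, float]], path) -> None:
    """Write per-type agreement metrics as CSV (type, n, fp, fn, agreement)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["entity_type", "n", "false_positives", "fp_rate",
             "false_negatives", "fn_rate", "agreement"]
        )
        for t, m in agreement.items():
            writer.writerow(
                [t, m["n"], m["false_positives"], f"{m['fp_rate']:.4f}",
                 m["false_negatives"], f"{m['fn_rate']:.4f}", f"{m['agreement']:.4f}"]
            )
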