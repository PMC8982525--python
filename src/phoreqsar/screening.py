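"""Classification-style validation and virtual-screening hit handling.

Covers the activity-threshold labeling (active <= 400 nM, inactive
> 3000 nM, intermediate excluded), confusion-matrix statistics, exact
pairwise ROC AUC, the Guner-Henry composite score and predicted-activity
hit filtering (predicted IC50 <= 0.5 uM by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ScreeningThresholds",
    "classify_by_thresholds",
    "confusion",
    "gh_score",
    "roc_auc",
    "rank_and_filter_hits",
    "dedupe_hits",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    active_ic50_max: float = 400e-9  # molar
    inactive_ic50_min: float = 3000e-9  # molar, exclusive
    hit_predicted_ic50_max: float = 0.5e-6  # molar
    primary_inhibition_min: float = 75.0  # percent at 10 uM

    def __post_init__(self) -> None:
        if self.active_ic50_max >= self.inactive_ic50_min:
            raise ValueError("active cutoff must lie below the inactive cutoff")

    @property
    def hit_activity_min(self) -> float:
        """Hit-retention cutoff on the log(1/IC50) scale."""
        return -math.log10(self.hit_predicted_ic50_max)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.TP + self.FN
        return self.TP / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.TN + self.FP
        return self.TN / d if d else None

    @property
    def accuracy(self) -> Optional[float]:
        return (self.TP + self.TN) / self.total if self.total else None

    @property
    def yield_of_actives(self) -> Optional[float]:
        d = self.TP + self.FP
        return self.TP / d if d else None


def classify_by_thresholds(
    ic50_values: Mapping[str, float],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> dict:
    """Label each compound active / inactive / intermediate by IC50 (molar).

    Boundary handling: active is inclusive (<= cutoff), inactive strict
    (> cutoff); everything between is intermediate and excluded from ROC
    tallies.
    """
    labels = {}
    for cid, ic50 in ic50_values.items():
        if ic50 <= 0:
            raise ValueError(f"{cid}: IC50 must be positive, got {ic50}")
        if ic50 <= thresholds.active_ic50_max:
            labels[cid] = "active"
        elif ic50 > thresholds.inactive_ic50_min:
            labels[cid] = "inactive"
        else:
            labels[cid] = "intermediate"
    return labels


def confusion(
    predicted_hit_flags: Sequence[bool], true_labels: Sequence[bool]
) -> ConfusionCounts:
    """Standard 2x2 tally; True in ``true_labels`` means active."""
    if len(predicted_hit_flags) != len(true_labels):
        raise ValueError(
            f"{len(predicted_hit_flags)} predictions vs {len(true_labels)} labels"
        )
    tp = fp = tn = fn = 0
    for pred, truth in zip(predicted_hit_flags, true_labels):
        if truth:
            tp += bool(pred)
            fn += not pred
        else:
            fp += bool(pred)
            tn += not pred
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def gh_score(counts: ConfusionCounts) -> float:
    """Guner-Henry score (0.75*Ya + 0.25*SEN) * SPC, all as fractions."""
    for name, value in (
        ("Ya", counts.yield_of_actives),
        ("SEN", counts.sensitivity),
        ("SPC", counts.specificity),
    ):
        if value is None:
            raise ValueError(f"GH score undefined: {name} has a zero denominator")
    return (0.75 * counts.yield_of_actives + 0.25 * counts.sensitivity) * counts.specificity


def roc_auc(scores: Sequence[float], true_labels: Sequence[bool]) -> float:
    """Exact ROC AUC via the Mann-Whitney pair statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(true_labels, dtype=bool)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels differ in length")
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC AUC needs at least one active and one inactive")
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels.astype(int), scores))


def rank_and_filter_hits(
    predictions: Mapping[str, float],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> List[Tuple[str, float]]:
    """Keep compounds whose predicted log(1/IC50) clears the retention
    cutoff; descending by prediction, ties by compound id."""
    cutoff = thresholds.hit_activity_min
    kept = [
        (cid, pred)
        for cid, pred in predictions.items()
        if pred >= cutoff - 1e-12
    ]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return kept


def dedupe_hits(hit_lists: Iterable[Sequence[str]]) -> List[str]:
    """Union of per-model hit lists preserving first-seen order."""
    seen = set()
    out: List[str] = []
    for hits in hit_lists:
        for cid in hits:
            if cid not in seen:
                seen.add(cid)
                out.append(cid)
    return out
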