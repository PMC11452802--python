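"""Hybrid human/machine diagnostic decisions with a confidence reject option.

Cross-validated logistic predictions carry a graded confidence
``max(p_gts, 1 - p_gts)``. High-confidence predictions (confidence strictly
above a threshold, 0.9 by default) are accepted automatically; the
remainder are routed to an expert reviewer of assumed accuracy (95% by
default). The report gives subgroup accuracies, the review burden (fraction
of videos an expert must watch), the analytic combined accuracy — the
n-weighted mean of the automated high-confidence accuracy and the expert
accuracy — and the empirically realized plain and balanced accuracies of
the simulated hybrid decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .classify import CVPrediction
from .simulate import GTS, HC, simulate_expert

DEFAULT_CONFIDENCE_THRESHOLD = 0.9
DEFAULT_EXPERT_ACCURACY_PCT = 95.0


@dataclass(frozen=True)
class HybridReport:
    confidence_threshold: float
    n_total: int
    n_high: int
    n_low: int
    review_fraction: float  # percent
    acc_high: Optional[float]  # percent, None if no high-confidence videos
    acc_low: Optional[float]  # percent, None if no low-confidence videos
    expert_accuracy: float  # percent (assumed)
    combined_accuracy: float  # percent, analytic n-weighted mean
    realized_accuracy: float  # percent, simulated hybrid decisions
    realized_balanced_accuracy: float  # percent, simulated hybrid decisions

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def stratify_by_confidence(
    predictions: list[CVPrediction],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> tuple[list[CVPrediction], list[CVPrediction]]:
    """Partition predictions into (high, low) confidence subsets.

    A video is high-confidence iff max(p_gts, 1 - p_gts) > threshold
    (strict), i.e. p_gts > threshold or p_gts < 1 - threshold; a prediction
    exactly at the threshold is low-confidence.
    """
    # 0.5 itself is allowed as a degenerate threshold: only predictions at
    # exactly 0.5 (no confident direction) are then routed to review.
    if not (0.5 <= confidence_threshold < 1.0):
        raise ValueError(f"confidence_threshold must be in [0.5, 1), got {confidence_threshold}")
    high = [p for p in predictions if max(p.p_gts, 1.0 - p.p_gts) > confidence_threshold]
    low = [p for p in predictions if max(p.p_gts, 1.0 - p.p_gts) <= confidence_threshold]
    return high, low


def _decisions(predictions: list[CVPrediction], decision_threshold: float) -> list[str]:
    return [GTS if p.p_gts >= decision_threshold else HC for p in predictions]


def _plain_accuracy(true: list[str], decided: list[str]) -> float:
    return 100.0 * float(np.mean([t == d for t, d in zip(true, decided)]))


def _balanced_accuracy(true: list[str], decided: list[str]) -> float:
    per_class = []
    for g in (GTS, HC):
        idx = [i for i, t in enumerate(true) if t == g]
        if not idx:
            raise ValueError(f"class {g} absent; balanced accuracy undefined")
        per_class.append(float(np.mean([decided[i] == g for i in idx])))
    return 100.0 * float(np.mean(per_class))


def subgroup_accuracy(
    subset: list[CVPrediction],
    decision_threshold: float = 0.5,
    balanced: bool = False,
) -> float:
    """Percent of correct automated decisions within a confidence subgroup.

    Plain fraction-correct by default; ``balanced=True`` gives the mean of
    per-class accuracies (requires both classes present in the subset).
    """
    if not subset:
        raise ValueError("subgroup_accuracy requires a nonempty subset")
    true = [p.true_group for p in subset]
    decided = _decisions(subset, decision_threshold)
    return _balanced_accuracy(true, decided) if balanced else _plain_accuracy(true, decided)


def review_burden(n_low: int, n_total: int) -> float:
    """Percent of videos routed to expert review: 100 * n_low / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_low <= n_total):
        raise ValueError(f"n_low must be in [0, n_total], got {n_low}/{n_total}")
    return 100.0 * n_low / n_total


def combined_accuracy(
    n_high: int, acc_high: float, n_low: int, expert_accuracy: float
) -> float:
    """Analytic hybrid accuracy: n-weighted mean of machine and expert accuracy.

    ``acc_high`` and ``expert_accuracy`` are percentages in [0, 100].
    """
    if n_high < 0 or n_low < 0 or n_high + n_low == 0:
        raise ValueError("subgroup counts must be >= 0 and not both zero")
    for name, a in (("acc_high", acc_high), ("expert_accuracy", expert_accuracy)):
        if not (0.0 <= a <= 100.0):
            raise ValueError(f"{name} must be in [0, 100], got {a}")
    return (n_high * acc_high + n_low * expert_accuracy) / (n_high + n_low)


def run_hybrid(
    predictions: list[CVPrediction],
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    expert_accuracy: float = DEFAULT_EXPERT_ACCURACY_PCT,
    seed: int = 0,
    decision_threshold: float = 0.5,
) -> HybridReport:
    """Evaluate the full hybrid scheme on a set of cross-validated predictions.

    High-confidence videos keep their automated decision; low-confidence
    videos receive a simulated expert call (label-flip noise at
    ``expert_accuracy`` percent, independent across videos). Reports both
    the analytic combined accuracy and the realized plain/balanced
    accuracies of the hybrid decisions.
    """
    if not predictions:
        raise ValueError("run_hybrid requires at least one prediction")
    high, low = stratify_by_confidence(predictions, confidence_threshold)
    n_total, n_high, n_low = len(predictions), len(high), len(low)

    acc_high = subgroup_accuracy(high, decision_threshold) if high else None
    acc_low = subgroup_accuracy(low, decision_threshold) if low else None

    true = [p.true_group for p in high] + [p.true_group for p in low]
    decided = _decisions(high, decision_threshold) + simulate_expert(
        [p.true_group for p in low], expert_accuracy / 100.0, seed
    )

    if n_low == 0:
        analytic = acc_high
    elif n_high == 0:
        analytic = expert_accuracy
    else:
        analytic = combined_accuracy(n_high, acc_high, n_low, expert_accuracy)

    return HybridReport(
        confidence_threshold=confidence_threshold,
        n_total=n_total,
        n_high=n_high,
        n_low=n_low,
        review_fraction=review_burden(n_low, n_total),
        acc_high=acc_high,
        acc_low=acc_low,
        expert_accuracy=expert_accuracy,
        combined_accuracy=float(analytic),
        realized_accuracy=_plain_accuracy(true, decided),
        realized_balanced_accuracy=_balanced_accuracy(true, decided),
    )


def threshold_sweep(
    predictions: list[CVPrediction],
    thresholds,
    expert_accuracy: float = DEFAULT_EXPERT_ACCURACY_PCT,
    seed: int = 0,
) -> pd.DataFrame:
    """Hybrid report across a grid of confidence thresholds, as a table."""
    rows = []
    for i, t in enumerate(thresholds):
        r = run_hybrid(predictions, float(t), expert_accuracy, seed=seed + i)
        rows.append(asdict(r))
    # empty subgroups have no accuracy; keep the columns numeric (NaN)
    return pd.DataFrame(rows).astype({"acc_high": float, "acc_low": float})
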