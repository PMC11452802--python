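"""The five per-video tic summary scores.

A video arrives as one tic probability per 1-second interval (output of an
upstream per-second tic detector). Intervals are binarized at a 0.5
threshold ("tic interval" iff probability >= 0.5) and summarized as:

1. ``proportion_tic_intervals`` — percentage of tic intervals;
2. ``mean_tic_probability`` — mean of the raw (un-binarized) probabilities;
3. ``max_tic_segment_s`` — longest run of consecutive tic intervals (s);
4. ``max_ticfree_segment_s`` — longest run of tic-free intervals (s);
5. ``clusters_per_minute`` — maximal runs of >= 3 consecutive tic
   intervals ("tic clusters"), per minute of video.

Rates are normalized by the actual video length, so videos need not be
exactly 150 s. A probability exactly at the threshold counts as a tic
(inclusive threshold), clusters touching the video boundary count, and two
tic runs separated by a single tic-free second are two distinct clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .simulate import TicProbabilitySeries

#: Canonical score column order used in tables and as default predictors.
SCORE_NAMES = (
    "proportion_tic_intervals",
    "mean_tic_probability",
    "max_tic_segment_s",
    "max_ticfree_segment_s",
    "clusters_per_minute",
)

DEFAULT_THRESHOLD = 0.5
DEFAULT_CLUSTER_MIN_S = 3


@dataclass(frozen=True)
class BinaryTicSeries:
    """Binarized per-second tic indicators for one video."""

    video_id: str
    intervals: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        x = np.asarray(self.intervals, dtype=np.int8)
        object.__setattr__(self, "intervals", x)
        if x.size == 0:
            raise ValueError(f"video {self.video_id!r}: empty binary series")
        if not np.isin(x, (0, 1)).all():
            raise ValueError(f"video {self.video_id!r}: binary series must contain only 0/1")


@dataclass(frozen=True)
class TicSummaryScores:
    proportion_tic_intervals: float  # percent, [0, 100]
    mean_tic_probability: float  # [0, 1]
    max_tic_segment_s: int
    max_ticfree_segment_s: int
    clusters_per_minute: float  # min^-1

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def binarize(
    series: TicProbabilitySeries, threshold: float = DEFAULT_THRESHOLD
) -> BinaryTicSeries:
    """Threshold per-second probabilities into tic / tic-free intervals.

    Interval i is a tic interval iff probability_i >= threshold; a
    probability exactly at the threshold counts as a tic.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    p = series.probabilities  # validated to [0, 1] on construction
    return BinaryTicSeries(
        video_id=series.video_id,
        intervals=(p >= threshold).astype(np.int8),
        threshold_used=threshold,
    )


def run_lengths(values) -> list[tuple[int, int]]:
    """Maximal-run encoding of a 0/1 sequence: [(value, length), ...].

    Lengths sum to the sequence length and adjacent runs alternate in value.
    """
    a = np.asarray(getattr(values, "intervals", values)).ravel()
    if a.size == 0:
        raise ValueError("run_lengths requires a nonempty sequence")
    change = np.flatnonzero(np.diff(a)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [a.size]))
    return [(int(a[s]), int(e - s)) for s, e in zip(starts, ends)]


def compute_scores(
    series: TicProbabilitySeries,
    threshold: float = DEFAULT_THRESHOLD,
    cluster_min_s: int = DEFAULT_CLUSTER_MIN_S,
) -> TicSummaryScores:
    """Compute the five tic summary scores for one video."""
    if cluster_min_s < 1:
        raise ValueError(f"cluster_min_s must be >= 1, got {cluster_min_s}")
    binary = binarize(series, threshold)
    runs = run_lengths(binary.intervals)
    L = binary.intervals.size
    tic_runs = [length for value, length in runs if value == 1]
    free_runs = [length for value, length in runs if value == 0]
    n_clusters = sum(1 for length in tic_runs if length >= cluster_min_s)
    return TicSummaryScores(
        proportion_tic_intervals=100.0 * float(binary.intervals.mean()),
        mean_tic_probability=float(series.probabilities.mean()),
        max_tic_segment_s=max(tic_runs, default=0),
        max_ticfree_segment_s=max(free_runs, default=0),
        clusters_per_minute=n_clusters / (L / 60.0),
    )


def scores_table(
    videos: list[TicProbabilitySeries],
    threshold: float = DEFAULT_THRESHOLD,
    cluster_min_s: int = DEFAULT_CLUSTER_MIN_S,
) -> pd.DataFrame:
    """Per-video scores table: identity columns followed by the five scores."""
    rows = []
    for v in videos:
        s = compute_scores(v, threshold=threshold, cluster_min_s=cluster_min_s)
        rows.append(
            {"video_id": v.video_id, "participant_id": v.participant_id, "group": v.group}
            | s.as_dict()
        )
    return pd.DataFrame(rows, columns=["video_id", "participant_id", "group", *SCORE_NAMES])
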