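"""Readers and writers for the pipeline's tabular exchange formats.

The canonical probability exchange format is a long CSV with one row per
video-second — ``video_id, second_index, probability[, hidden_state]`` with
``second_index`` contiguous from 0 within each video — so that any upstream
per-second tic detector can feed the pipeline. Cohort structure travels in
a manifest CSV (``video_id, participant_id, group, matched_partner_id``).
Schema violations are reported with the offending row number (1-based,
counting the header as row 1).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GROUPS, TicProbabilitySeries


class FormatError(ValueError):
    """A pipeline input file violates its schema."""


MANIFEST_COLUMNS = ("video_id", "participant_id", "group", "matched_partner_id")
PROBABILITY_COLUMNS = ("video_id", "second_index", "probability")


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest[list(MANIFEST_COLUMNS)].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in MANIFEST_COLUMNS if c != "group"})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest is missing columns {missing}")
    bad = ~df["group"].isin(GROUPS)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}: row {row}: group must be one of {GROUPS}")
    return df


def write_probability_table(videos: list[TicProbabilitySeries], path) -> None:
    """Write videos as the long-format probabilities CSV.

    The hidden_state column is included only when every video carries
    simulated ground truth.
    """
    frames = []
    with_hidden = all(v.hidden_states is not None for v in videos)
    for v in videos:
        f = pd.DataFrame(
            {
                "video_id": v.video_id,
                "second_index": np.arange(v.duration_s),
                "probability": v.probabilities,
            }
        )
        if with_hidden:
            f["hidden_state"] = v.hidden_states
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_probability_table(path, manifest: pd.DataFrame | None = None) -> list[TicProbabilitySeries]:
    """Read per-second tic probabilities, one series per video.

    Validates the schema: required columns present, probabilities in
    [0, 1], and ``second_index`` contiguous from 0 within each video (rows
    may appear in any order). If a manifest is given, participant and group
    metadata are attached; otherwise they are left empty.
    """
    df = pd.read_csv(path)
    missing = [c for c in PROBABILITY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    probs = df["probability"].to_numpy(dtype=float)
    bad = ~np.isfinite(probs) | (probs < 0) | (probs > 1)
    if bad.any():
        row = int(df.index[bad.nonzero()[0][0]]) + 2
        raise FormatError(f"{path}: row {row}: probability outside [0, 1]")

    meta: dict[str, tuple[str, str]] = {}
    if manifest is not None:
        meta = {
            r["video_id"]: (r["participant_id"], r["group"]) for _, r in manifest.iterrows()
        }

    series: list[TicProbabilitySeries] = []
    for vid, g in df.groupby("video_id", sort=True):
        g = g.sort_values("second_index")
        idx = g["second_index"].to_numpy(dtype=int)
        expected = np.arange(len(idx))
        if not np.array_equal(idx, expected):
            first_bad = int(np.flatnonzero(idx != expected)[0])
            row = int(g.index[first_bad]) + 2
            raise FormatError(
                f"{path}: video {vid}: second_index not contiguous from 0 (row {row})"
            )
        participant_id, group = meta.get(str(vid), ("", ""))
        hidden = (
            g["hidden_state"].to_numpy(dtype=np.int8) if "hidden_state" in g.columns else None
        )
        series.append(
            TicProbabilitySeries(
                video_id=str(vid),
                participant_id=participant_id,
                group=group,
                probabilities=g["probability"].to_numpy(dtype=float),
                hidden_states=hidden,
            )
        )
    if not series:
        raise FormatError(f"{path}: no videos found")
    return series


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"video_id": str, "participant_id": str})


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"video_id": str, "fold_id": str})
    required = ("video_id", "true_group", "p_gts", "fold_id")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: predictions file missing columns {missing}")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
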