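"""Synthetic matched-pair cohorts of per-second tic-probability time series.

Real tic videos cannot be shared, so every downstream stage (scoring,
classification, hybrid review) is exercised on simulated cohorts that
reproduce the structural features the analysis relies on:

* matched GTS/HC participant pairs, each pair contributing the same number
  of ~150-second videos;
* temporally clustered tic events — a hidden two-state Markov chain
  (quiescent / tic) per second, so tic seconds arrive in bursts whose mean
  length is ``1 / (1 - p_stay_tic)``;
* noisy per-second detector probabilities — each second's emitted
  probability is Beta-distributed around a state-dependent mean, so traces
  cross the 0.5 detection threshold the way real detector output does;
* participant-level heterogeneity — the per-second tic entry rate is
  jittered on the log-odds scale per participant, producing "few tics" and
  "many tics" individuals within the GTS group.

Healthy controls use the same generative mechanism with lower rates:
spontaneous extra movements are frequent in controls too, so an all-zero
control signal would be unrealistically easy to classify.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

GTS = "GTS"
HC = "HC"
GROUPS = (GTS, HC)


class ConfigError(ValueError):
    """A simulation or pipeline configuration field is out of range."""


@dataclass(frozen=True)
class MarkovEmissionParams:
    """Per-group parameters of the hidden tic chain and its emissions.

    Parameters
    ----------
    p_enter_tic
        Per-second probability of transitioning quiescent -> tic state.
    p_stay_tic
        Per-second probability of remaining in the tic state; controls
        burstiness (mean tic run length is ``1 / (1 - p_stay_tic)``).
    emission_concentration
        Beta concentration of the emitted probability around the
        state-dependent mean; larger values give cleaner traces.
    tic_emission_mean, quiescent_emission_mean
        Mean emitted probability in tic / quiescent seconds.
    """

    p_enter_tic: float
    p_stay_tic: float
    emission_concentration: float = 10.0
    tic_emission_mean: float = 0.8
    quiescent_emission_mean: float = 0.2

    def validate(self) -> None:
        for name in ("p_enter_tic", "p_stay_tic", "tic_emission_mean", "quiescent_emission_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not self.emission_concentration > 0:
            raise ConfigError(
                f"emission_concentration must be > 0, got {self.emission_concentration}"
            )
        denom = self.p_enter_tic + 1.0 - self.p_stay_tic
        if denom <= 0 and self.p_enter_tic > 0:
            raise ConfigError("degenerate chain: p_enter_tic > 0 with p_stay_tic = 1")

    @property
    def stationary_tic_fraction(self) -> float:
        """Long-run fraction of seconds spent in the tic state."""
        denom = self.p_enter_tic + 1.0 - self.p_stay_tic
        if denom == 0.0:
            return 0.0
        return self.p_enter_tic / denom


# Default group parameters: well separated, matching the regime in which the
# analysis operates (GTS ~20% tic seconds in bursts of mean length 5 s; HC
# ~0.7% tic seconds in short isolated bursts).
GTS_DEFAULT_PARAMS = MarkovEmissionParams(p_enter_tic=0.05, p_stay_tic=0.8)
HC_DEFAULT_PARAMS = MarkovEmissionParams(p_enter_tic=0.005, p_stay_tic=0.3)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults mirror the study layout: 42 matched pairs, 1–4 videos per
    participant (~107 videos per group), 150-second videos, and a 95%
    accurate expert for the hybrid-review simulation.
    """

    n_pairs: int = 42
    videos_per_participant: tuple[int, int] = (1, 4)
    video_duration_s: int = 150
    gts_params: MarkovEmissionParams = GTS_DEFAULT_PARAMS
    hc_params: MarkovEmissionParams = HC_DEFAULT_PARAMS
    participant_logodds_jitter_sd: float = 0.5
    expert_accuracy: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ConfigError(f"n_pairs must be >= 1, got {self.n_pairs}")
        if self.video_duration_s < 1:
            raise ConfigError(f"video_duration_s must be >= 1, got {self.video_duration_s}")
        lo, hi = self.videos_per_participant
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"videos_per_participant must satisfy 1 <= min <= max, got {self.videos_per_participant}"
            )
        if not (0.0 <= self.expert_accuracy <= 1.0):
            raise ConfigError(f"expert_accuracy must be in [0, 1], got {self.expert_accuracy}")
        if self.participant_logodds_jitter_sd < 0:
            raise ConfigError("participant_logodds_jitter_sd must be >= 0")
        self.gts_params.validate()
        self.hc_params.validate()

    def group_params(self, group: str) -> MarkovEmissionParams:
        if group == GTS:
            return self.gts_params
        if group == HC:
            return self.hc_params
        raise ConfigError(f"unknown group {group!r}")


@dataclass(frozen=True)
class TicProbabilitySeries:
    """One video's per-second tic probabilities plus identity metadata.

    ``hidden_states`` carries the simulated ground-truth tic/quiescent state
    per second; it is None for data read from an external detector.
    """

    video_id: str
    participant_id: str
    group: str
    probabilities: np.ndarray
    hidden_states: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 1 or p.size == 0:
            raise ValueError(f"video {self.video_id!r}: probabilities must be a nonempty 1-d sequence")
        if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
            raise ValueError(f"video {self.video_id!r}: probabilities must lie in [0, 1]")
        if self.hidden_states is not None:
            h = np.asarray(self.hidden_states, dtype=np.int8)
            object.__setattr__(self, "hidden_states", h)
            if h.shape != p.shape:
                raise ValueError(f"video {self.video_id!r}: hidden_states length mismatch")

    @property
    def duration_s(self) -> int:
        return int(self.probabilities.size)


@dataclass
class CohortDataset:
    """Matched-pair cohort: participant table plus one series per video.

    ``participants`` rows are (participant_id, group, matched_partner_id);
    matching is a bijection between the GTS and HC groups and matched
    partners contribute equal numbers of videos.
    """

    participants: "pd.DataFrame"  # noqa: F821 - imported lazily below
    videos: list[TicProbabilitySeries]

    def validate(self) -> None:
        part = self.participants.set_index("participant_id")
        for pid, row in part.iterrows():
            partner = row["matched_partner_id"]
            if partner not in part.index:
                raise ValueError(f"participant {pid}: partner {partner} missing")
            if part.loc[partner, "matched_partner_id"] != pid:
                raise ValueError(f"matching is not symmetric for {pid}/{partner}")
            if part.loc[partner, "group"] == row["group"]:
                raise ValueError(f"partners {pid}/{partner} are in the same group")
        counts: dict[str, int] = {pid: 0 for pid in part.index}
        for v in self.videos:
            if v.participant_id not in counts:
                raise ValueError(f"video {v.video_id} references unknown participant {v.participant_id}")
            counts[v.participant_id] += 1
        for pid, row in part.iterrows():
            if counts[pid] != counts[row["matched_partner_id"]]:
                raise ValueError(f"pair {pid}/{row['matched_partner_id']}: unequal video counts")

    @property
    def n_pairs(self) -> int:
        return len(self.participants) // 2

    def manifest(self) -> "pd.DataFrame":
        """Per-video manifest (video_id, participant_id, group, matched_partner_id)."""
        import pandas as pd

        part = self.participants.set_index("participant_id")
        rows = [
            {
                "video_id": v.video_id,
                "participant_id": v.participant_id,
                "group": v.group,
                "matched_partner_id": part.loc[v.participant_id, "matched_partner_id"],
            }
            for v in self.videos
        ]
        return pd.DataFrame(rows)


def _simulate_hidden_chain(
    rng: np.random.Generator, n_seconds: int, p_enter: float, p_stay: float
) -> np.ndarray:
    """Simulate the two-state (0=quiescent, 1=tic) chain for one video.

    The initial state is drawn from the stationary distribution so the
    chain is stationary from the first second.
    """
    denom = p_enter + 1.0 - p_stay
    pi_tic = p_enter / denom if denom > 0 else 0.0
    u = rng.random(n_seconds)
    states = np.empty(n_seconds, dtype=np.int8)
    state = 1 if u[0] < pi_tic else 0
    states[0] = state
    for t in range(1, n_seconds):
        p_tic = p_stay if state == 1 else p_enter
        state = 1 if u[t] < p_tic else 0
        states[t] = state
    return states


def _emit_probabilities(
    rng: np.random.Generator, states: np.ndarray, params: MarkovEmissionParams
) -> np.ndarray:
    means = np.where(states == 1, params.tic_emission_mean, params.quiescent_emission_mean)
    c = params.emission_concentration
    return rng.beta(means * c, (1.0 - means) * c)


def _jitter_entry_rate(rng: np.random.Generator, p_enter: float, sd: float) -> float:
    """Per-participant entry rate: normal jitter on the log-odds scale."""
    if sd == 0.0 or p_enter <= 0.0 or p_enter >= 1.0:
        return p_enter
    return float(expit(logit(p_enter) + rng.normal(0.0, sd)))


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a matched-pair cohort of synthetic tic-probability videos.

    Deterministic given ``config.seed``: a master ``SeedSequence`` is
    spawned into per-pair, per-participant and per-video substreams, so the
    same seed always yields the same cohort and individual videos are
    stable under partial regeneration.
    """
    import pandas as pd

    config.validate()
    master = np.random.SeedSequence(config.seed)
    pair_seeds = master.spawn(config.n_pairs)

    lo, hi = config.videos_per_participant
    part_rows = []
    videos: list[TicProbabilitySeries] = []
    for i, pair_seed in enumerate(pair_seeds, start=1):
        pair_rng = np.random.default_rng(pair_seed)
        n_videos = int(pair_rng.integers(lo, hi + 1))
        gts_id, hc_id = f"G{i:03d}", f"H{i:03d}"
        part_rows.append({"participant_id": gts_id, "group": GTS, "matched_partner_id": hc_id})
        part_rows.append({"participant_id": hc_id, "group": HC, "matched_partner_id": gts_id})
        for pid, group, part_seed in zip((gts_id, hc_id), GROUPS, pair_seed.spawn(2)):
            params = config.group_params(group)
            part_rng = np.random.default_rng(part_seed)
            p_enter_i = _jitter_entry_rate(
                part_rng, params.p_enter_tic, config.participant_logodds_jitter_sd
            )
            for v, video_seed in enumerate(part_seed.spawn(n_videos), start=1):
                vid_rng = np.random.default_rng(video_seed)
                states = _simulate_hidden_chain(
                    vid_rng, config.video_duration_s, p_enter_i, params.p_stay_tic
                )
                probs = _emit_probabilities(vid_rng, states, params)
                videos.append(
                    TicProbabilitySeries(
                        video_id=f"{pid}_v{v}",
                        participant_id=pid,
                        group=group,
                        probabilities=probs,
                        hidden_states=states,
                    )
                )
    cohort = CohortDataset(participants=pd.DataFrame(part_rows), videos=videos)
    cohort.validate()
    return cohort


def simulate_expert(
    labels: Sequence[str], expert_accuracy: float, seed: int
) -> list[str]:
    """Simulate an expert reviewer's group calls.

    Each true label is reproduced independently with probability
    ``expert_accuracy`` and flipped to the other group otherwise.
    """
    if not (0.0 <= expert_accuracy <= 1.0):
        raise ConfigError(f"expert_accuracy must be in [0, 1], got {expert_accuracy}")
    flip = {GTS: HC, HC: GTS}
    rng = np.random.default_rng(seed)
    correct = rng.random(len(labels)) < expert_accuracy
    return [lab if ok else flip[lab] for lab, ok in zip(labels, correct)]
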