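"""Randomized truth-list generation for simulated auditory point-count surveys.

A survey is a 180-s timeline divided into 3-s recording intervals. Each
species' 4-s vocalization clip occurs a discrete-uniform random number of
times (1-4 by default); clips are placed in uniformly random order with the
remaining "white noise" time distributed across the gaps by uniform
stick-breaking, so clips may be back-to-back but never overlap. The resulting
ordered clip list is the ground truth ("truth list") against which observer
reports are scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .roster import DEFAULT_ROSTER, SpeciesRoster


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of the truth-list generator.

    duration_s
        Survey length in seconds (default 180, i.e. three minutes).
    interval_s
        Width of the recording grid in seconds (default 3).
    clip_s
        Length of every vocalization clip in seconds (default 4).
    count_low, count_high
        Bounds of the discrete-uniform per-species occurrence count
        (default 1..4).
    """

    duration_s: float = 180.0
    interval_s: float = 3.0
    clip_s: float = 4.0
    roster: SpeciesRoster = field(default_factory=lambda: DEFAULT_ROSTER)
    count_low: int = 1
    count_high: int = 4

    def __post_init__(self) -> None:
        if self.interval_s <= 0 or self.duration_s <= 0 or self.clip_s <= 0:
            raise ValueError("durations must be positive")
        if abs(self.duration_s / self.interval_s - round(self.duration_s / self.interval_s)) > 1e-9:
            raise ValueError("duration_s must be divisible by interval_s")
        if not (0 <= self.count_low <= self.count_high):
            raise ValueError("need 0 <= count_low <= count_high")
        worst = len(self.roster) * self.count_high * self.clip_s
        if worst > self.duration_s:
            raise ValueError(
                f"worst-case clip time {worst:.0f}s exceeds survey duration "
                f"{self.duration_s:.0f}s; reduce count_high or clip_s"
            )

    @property
    def n_intervals(self) -> int:
        return int(round(self.duration_s / self.interval_s))


@dataclass(frozen=True)
class TruthClip:
    """One played vocalization: what, when (seconds and grid interval)."""

    clip_id: int
    species: str
    onset_s: float
    onset_interval: int


@dataclass(frozen=True)
class SurveySchedule:
    """A truth list: ordered non-overlapping clips on the survey timeline."""

    survey_id: str
    config: ScheduleConfig
    clips: tuple[TruthClip, ...]

    def __post_init__(self) -> None:
        cfg = self.config
        prev_end = -math.inf
        for c in self.clips:
            if not (0.0 <= c.onset_s <= cfg.duration_s - cfg.clip_s + 1e-9):
                raise ValueError(f"clip {c.clip_id} onset {c.onset_s} outside timeline")
            if c.onset_interval != int(c.onset_s // cfg.interval_s):
                raise ValueError(f"clip {c.clip_id} interval index inconsistent with onset")
            if c.onset_s < prev_end - 1e-9:
                raise ValueError(f"clip {c.clip_id} overlaps the previous clip")
            prev_end = c.onset_s + cfg.clip_s

    @property
    def n_clips(self) -> int:
        return len(self.clips)

    def species_counts(self) -> dict[str, int]:
        counts = {code: 0 for code in self.config.roster.codes}
        for c in self.clips:
            counts[c.species] += 1
        return counts


@dataclass(frozen=True)
class BatchSummary:
    n_surveys: int
    total_clips: int
    mean: float
    sd: float
    min: int
    max: int


def draw_species_counts(config: ScheduleConfig, rng: np.random.Generator) -> dict[str, int]:
    """Draw each species' occurrence count, discrete-uniform on [low, high]."""
    draws = rng.integers(config.count_low, config.count_high + 1, size=len(config.roster))
    return dict(zip(config.roster.codes, (int(d) for d in draws)))


def generate_schedule(
    config: ScheduleConfig,
    rng: np.random.Generator,
    survey_id: str = "S0000",
) -> SurveySchedule:
    """Generate one truth list.

    Construction: draw per-species counts, shuffle the resulting clip
    multiset uniformly, split the white-noise slack over the n+1 gaps by
    uniform stick-breaking (Dirichlet(1,..,1)), then lay clips down
    cumulatively. Clips may be consecutive (zero gap) but never overlap.
    """
    counts = draw_species_counts(config, rng)
    species = [code for code, k in counts.items() for _ in range(k)]
    n = len(species)
    slack = config.duration_s - n * config.clip_s
    if slack < 0:
        raise ValueError(
            f"infeasible draw for survey {survey_id}: {n} clips x {config.clip_s}s "
            f"= {n * config.clip_s}s exceeds {config.duration_s}s"
        )
    order = rng.permutation(n)
    species = [species[i] for i in order]
    # n+1 gap widths summing to the slack: order statistics of n uniforms.
    if n > 0:
        cuts = np.sort(rng.uniform(0.0, slack, size=n))
        gaps = np.diff(np.concatenate(([0.0], cuts, [slack])))
    else:
        gaps = np.array([slack])
    clips = []
    t = 0.0
    for k in range(n):
        t += gaps[k]
        onset = float(t)
        clips.append(
            TruthClip(
                clip_id=k,
                species=species[k],
                onset_s=onset,
                onset_interval=int(onset // config.interval_s),
            )
        )
        t += config.clip_s
    return SurveySchedule(survey_id=survey_id, config=config, clips=tuple(clips))


def _survey_rng(seed: int, index: int) -> np.random.Generator:
    # Per-survey sub-stream keyed by index: reproducible and order-independent.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_batch(
    config: ScheduleConfig,
    n_surveys: int,
    seed: int,
    id_prefix: str = "S",
) -> tuple[list[SurveySchedule], BatchSummary]:
    """Generate ``n_surveys`` independent truth lists from one root seed."""
    if n_surveys < 1:
        raise ValueError("n_surveys must be >= 1")
    schedules = [
        generate_schedule(config, _survey_rng(seed, i), survey_id=f"{id_prefix}{i:04d}")
        for i in range(n_surveys)
    ]
    per_survey = np.array([s.n_clips for s in schedules])
    summary = BatchSummary(
        n_surveys=n_surveys,
        total_clips=int(per_survey.sum()),
        mean=float(per_survey.mean()),
        sd=float(per_survey.std(ddof=1)) if n_surveys > 1 else 0.0,
        min=int(per_survey.min()),
        max=int(per_survey.max()),
    )
    return schedules, summary
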