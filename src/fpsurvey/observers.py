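"""Stochastic observer models for simulated auditory surveys.

The human observers of the original experiment are replaced by a minimal
generative model that produces every error category the scoring rule must
classify:

* per-species detection probability (misses -> false negatives),
* a row-stochastic confusion matrix (misidentifications -> false positives),
* timing jitter of +/-1 recording interval (mistimed reports),
* for dependent double-observer (DDO) surveys, a removal protocol with a
  collaboration probability kappa: a primary misidentification is replaced
  by the correct identification when the secondary observer independently
  detected and correctly identified the same clip.

ISO = independent single observer; DDO = dependent double observer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .roster import SpeciesRoster
from .schedule import ScheduleConfig, SurveySchedule, generate_schedule

_ROLES = ("single", "primary", "secondary")


@dataclass(frozen=True)
class ObserverProfile:
    """One observer's error model over a species roster.

    species
        Roster codes, fixing row/column order of ``confusion``.
    p_detect
        Per-species probability of detecting a played clip (length n).
    confusion
        Row-stochastic n x n matrix: given a detected clip of true species i,
        probability of reporting species j. The diagonal is the correct-ID
        probability.
    jitter
        Probability mass over interval offsets {-1, 0, +1} applied to the
        reported interval (clamped at the grid edges).
    spurious_rate
        Per-interval probability of a clip-less (hallucinated) detection of a
        uniformly random species. Defaults to 0: the study's false-positive
        definition covers only misidentified or mistimed real clips.
    """

    label: str
    species: tuple[str, ...]
    p_detect: np.ndarray
    confusion: np.ndarray
    jitter: Mapping[int, float] = field(default_factory=lambda: {-1: 0.0, 0: 1.0, 1: 0.0})
    spurious_rate: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.p_detect, dtype=float)
        c = np.asarray(self.confusion, dtype=float)
        object.__setattr__(self, "p_detect", p)
        object.__setattr__(self, "confusion", c)
        n = len(self.species)
        if p.shape != (n,) or c.shape != (n, n):
            raise ValueError("p_detect/confusion shapes must match the species list")
        if np.any(p < 0) or np.any(p > 1) or np.any(c < 0) or np.any(c > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(c.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")
        if set(self.jitter) - {-1, 0, 1}:
            raise ValueError("jitter offsets must be in {-1, 0, +1}")
        if abs(sum(self.jitter.values()) - 1.0) > 1e-9:
            raise ValueError("jitter mass must sum to 1")
        if not (0.0 <= self.spurious_rate <= 1.0):
            raise ValueError("spurious_rate must lie in [0, 1]")

    @classmethod
    def from_mappings(
        cls,
        label: str,
        roster: SpeciesRoster,
        p_detect: Mapping[str, float] | float,
        confusion: Mapping[str, Mapping[str, float]],
        jitter: Mapping[int, float] | None = None,
        spurious_rate: float = 0.0,
    ) -> "ObserverProfile":
        codes = roster.codes
        if isinstance(p_detect, (int, float)):
            p = np.full(len(codes), float(p_detect))
        else:
            missing = [c for c in codes if c not in p_detect]
            if missing:
                raise KeyError(f"p_detect missing species {missing}")
            p = np.array([p_detect[c] for c in codes], dtype=float)
        conf = np.zeros((len(codes), len(codes)))
        for i, ci in enumerate(codes):
            row = confusion.get(ci)
            if row is None:
                raise KeyError(f"confusion missing row for {ci}")
            for j, cj in enumerate(codes):
                conf[i, j] = float(row.get(cj, 0.0))
        return cls(
            label=label,
            species=codes,
            p_detect=p,
            confusion=conf,
            jitter=dict(jitter) if jitter is not None else {-1: 0.0, 0: 1.0, 1: 0.0},
            spurious_rate=spurious_rate,
        )

    def index(self, code: str) -> int:
        return self.species.index(code)


@dataclass(frozen=True)
class DDOConfig:
    """Collaboration probability kappa of the removal protocol.

    With probability ``collaboration`` a primary misidentification is replaced
    by the correct species when the secondary observer independently detected
    and correctly identified the same clip; attribution stays with the primary
    observer, as the protocol requires.
    """

    collaboration: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.collaboration <= 1.0):
            raise ValueError("collaboration must lie in [0, 1]")


@dataclass(frozen=True)
class DetectionRecord:
    """One reported vocalization on the 3-s recording grid."""

    survey_id: str
    detection_id: int
    interval_index: int
    reported_species: str
    role: str  # single | primary | secondary

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}")


def _check_profile_covers(schedule: SurveySchedule, profile: ObserverProfile) -> None:
    missing = [c for c in schedule.config.roster.codes if c not in profile.species]
    if missing:
        raise KeyError(f"profile {profile.label!r} missing species {missing}")


def _jitter_offsets(profile: ObserverProfile, rng: np.random.Generator, size: int) -> np.ndarray:
    offsets = np.array(sorted(profile.jitter))
    probs = np.array([profile.jitter[o] for o in offsets])
    return rng.choice(offsets, size=size, p=probs)


def _draw_reported(profile: ObserverProfile, true_idx: int, rng: np.random.Generator) -> int:
    return int(rng.choice(len(profile.species), p=profile.confusion[true_idx]))


def _spurious(
    schedule: SurveySchedule,
    profile: ObserverProfile,
    role: str,
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    if profile.spurious_rate == 0.0:
        return []
    out = []
    for interval in range(schedule.config.n_intervals):
        if rng.random() < profile.spurious_rate:
            sp = profile.species[int(rng.integers(len(profile.species)))]
            out.append((interval, sp, role))
    return out


def _finalize(schedule: SurveySchedule, raw: list[tuple[int, str, str]]) -> list[DetectionRecord]:
    # Records are listed in recording order (interval, then emission order).
    raw.sort(key=lambda t: t[0])
    return [
        DetectionRecord(
            survey_id=schedule.survey_id,
            detection_id=k,
            interval_index=interval,
            reported_species=sp,
            role=role,
        )
        for k, (interval, sp, role) in enumerate(raw)
    ]


def simulate_iso(
    schedule: SurveySchedule,
    profile: ObserverProfile,
    rng: np.random.Generator,
) -> list[DetectionRecord]:
    """Simulate one independent single-observer survey of a truth list.

    Each clip is independently detected with probability p_detect[species];
    a detected clip is reported as a species drawn from its confusion row, in
    the clip's interval shifted by a jitter offset (clamped to the grid).
    """
    _check_profile_covers(schedule, profile)
    n_int = schedule.config.n_intervals
    raw: list[tuple[int, str, str]] = []
    for clip in schedule.clips:
        i = profile.index(clip.species)
        if rng.random() < profile.p_detect[i]:
            j = _draw_reported(profile, i, rng)
            off = int(_jitter_offsets(profile, rng, 1)[0])
            interval = int(np.clip(clip.onset_interval + off, 0, n_int - 1))
            raw.append((interval, profile.species[j], "single"))
    raw.extend(_spurious(schedule, profile, "single", rng))
    return _finalize(schedule, raw)


def simulate_ddo(
    schedule: SurveySchedule,
    primary: ObserverProfile,
    secondary: ObserverProfile,
    ddo: DDOConfig,
    rng: np.random.Generator,
) -> list[DetectionRecord]:
    """Simulate one dependent double-observer survey (removal design).

    Per clip: the primary observer's detection is drawn first. If the primary
    detects, exactly one primary-role record is emitted; a misidentification
    is corrected to the true species with probability kappa when the secondary
    independently detected and correctly identified the clip. If the primary
    misses and the secondary detects, one secondary-role record is emitted.
    At most one record per clip.
    """
    _check_profile_covers(schedule, primary)
    _check_profile_covers(schedule, secondary)
    n_int = schedule.config.n_intervals
    raw: list[tuple[int, str, str]] = []
    for clip in schedule.clips:
        i1 = primary.index(clip.species)
        i2 = secondary.index(clip.species)
        if rng.random() < primary.p_detect[i1]:
            j = _draw_reported(primary, i1, rng)
            if j != i1:
                sec_detects = rng.random() < secondary.p_detect[i2]
                sec_correct = sec_detects and (_draw_reported(secondary, i2, rng) == i2)
                if sec_correct and rng.random() < ddo.collaboration:
                    j = i1
            off = int(_jitter_offsets(primary, rng, 1)[0])
            interval = int(np.clip(clip.onset_interval + off, 0, n_int - 1))
            raw.append((interval, primary.species[j], "primary"))
        elif rng.random() < secondary.p_detect[i2]:
            j = _draw_reported(secondary, i2, rng)
            off = int(_jitter_offsets(secondary, rng, 1)[0])
            interval = int(np.clip(clip.onset_interval + off, 0, n_int - 1))
            raw.append((interval, secondary.species[j], "secondary"))
    raw.extend(_spurious(schedule, primary, "primary", rng))
    return _finalize(schedule, raw)


@dataclass(frozen=True)
class ScenarioSpec:
    """One (experience x method) arm of a simulated survey campaign."""

    experience: str  # e.g. "expert" / "naive"
    method: str  # "ISO" | "DDO"
    n_surveys: int
    profiles: tuple[ObserverProfile, ...]
    ddo: DDOConfig | None = None

    def __post_init__(self) -> None:
        if self.method not in ("ISO", "DDO"):
            raise ValueError(f"unknown method label {self.method!r}")
        if self.n_surveys < 1:
            raise ValueError("n_surveys must be >= 1")
        if self.method == "DDO":
            if len(self.profiles) != 2:
                raise ValueError("DDO scenarios need exactly two profiles")
            if self.ddo is None:
                raise ValueError("DDO scenarios need a DDOConfig")
        elif not self.profiles:
            raise ValueError("ISO scenarios need at least one profile")

    @property
    def label(self) -> str:
        return f"{self.experience}-{self.method}"


@dataclass(frozen=True)
class SurveyAssignment:
    survey_id: str
    experience: str
    method: str
    observer: str  # ISO observer or DDO primary for this survey
    partner: str | None  # DDO secondary, if any


@dataclass
class CampaignResult:
    schedules: dict[str, SurveySchedule]
    detections: list[DetectionRecord]
    assignments: list[SurveyAssignment]

    def detections_by_survey(self) -> dict[str, list[DetectionRecord]]:
        out: dict[str, list[DetectionRecord]] = {sid: [] for sid in self.schedules}
        for d in self.detections:
            out[d.survey_id].append(d)
        return out


def simulate_campaign(
    scenarios: Sequence[ScenarioSpec],
    schedule_config: ScheduleConfig,
    seed: int,
) -> CampaignResult:
    """Run a multi-scenario campaign with deterministic per-survey streams.

    Every survey gets a fresh truth list. Within a DDO scenario the two
    profiles swap primary/secondary roles on alternating surveys, as in the
    field protocol; ISO scenarios cycle through their profiles.
    """
    labels = [s.label for s in scenarios]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    schedules: dict[str, SurveySchedule] = {}
    detections: list[DetectionRecord] = []
    assignments: list[SurveyAssignment] = []
    for si, sc in enumerate(scenarios):
        for k in range(sc.n_surveys):
            sid = f"{sc.label}-{k:03d}"
            rng_sched = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(si, k, 0))
            )
            rng_obs = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(si, k, 1))
            )
            sched = generate_schedule(schedule_config, rng_sched, survey_id=sid)
            schedules[sid] = sched
            if sc.method == "ISO":
                prof = sc.profiles[k % len(sc.profiles)]
                detections.extend(simulate_iso(sched, prof, rng_obs))
                assignments.append(
                    SurveyAssignment(sid, sc.experience, sc.method, prof.label, None)
                )
            else:
                primary = sc.profiles[k % 2]
                secondary = sc.profiles[(k + 1) % 2]
                detections.extend(simulate_ddo(sched, primary, secondary, sc.ddo, rng_obs))
                assignments.append(
                    SurveyAssignment(sid, sc.experience, sc.method, primary.label, secondary.label)
                )
    return CampaignResult(schedules=schedules, detections=detections, assignments=assignments)
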