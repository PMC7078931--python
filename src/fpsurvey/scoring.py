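"""Detection scoring against the truth list.

A detection is correct when a clip of the reported species was played in the
reported 3-s interval or the interval on either side (the 9-s allowable
window), and that clip is assigned to it one-to-one; every other detection is
a false positive, caused either by misidentification (an unmatched clip of a
different species lies in the window) or by reporting outside the allowable
window.

Matching rule. Detections are processed in time order and each is matched to
the earliest unmatched same-species clip inside its +/-1-interval window.
Because a clip at interval i is eligible only for detections at intervals
i-1..i+1, this earliest-deadline-first greedy attains the maximum number of
correct matches achievable by any one-to-one assignment (the per-species
eligibility sets are intervals, so the standard exchange argument applies;
the test suite verifies optimality against a maximum-bipartite-matching
oracle). A naive "same-interval-first" preference is not optimal and is not
used.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .observers import DetectionRecord
from .roster import SpeciesRoster
from .schedule import SurveySchedule

CORRECT = "correct"
FALSE_POSITIVE = "false_positive"
CAUSE_MISID = "misidentification"
CAUSE_WINDOW = "out_of_window"
CAUSE_NONE = "none"


@dataclass(frozen=True)
class ScoredDetection:
    detection: DetectionRecord
    classification: str  # correct | false_positive
    fp_cause: str  # misidentification | out_of_window | none
    matched_clip_id: int | None = None
    inferred_true_species: str | None = None

    def __post_init__(self) -> None:
        correct = self.classification == CORRECT
        if correct != (self.fp_cause == CAUSE_NONE) or correct != (self.matched_clip_id is not None):
            raise ValueError("inconsistent classification/cause/match fields")


@dataclass
class SurveyScore:
    """Classification of every detection in one survey, plus clip accounting.

    Unmatched clips partition into misidentification sources (clips inferred
    to have been reported as another species) and pure nondetections;
    ``n_unmatched`` = clips without a correct match = their union.
    """

    survey_id: str
    n_clips: int
    scored: list[ScoredDetection]
    nondetection_clip_ids: list[int]
    misid_source_clip_ids: list[int]
    confusion_counts: Counter  # (true_species, reported_species) -> count

    @property
    def n_detections(self) -> int:
        return len(self.scored)

    @property
    def n_correct(self) -> int:
        return sum(1 for s in self.scored if s.classification == CORRECT)

    @property
    def n_fp(self) -> int:
        return sum(1 for s in self.scored if s.classification == FALSE_POSITIVE)

    @property
    def n_unmatched(self) -> int:
        return len(self.nondetection_clip_ids) + len(self.misid_source_clip_ids)


def match_survey(schedule: SurveySchedule, detections: Sequence[DetectionRecord]) -> SurveyScore:
    """Score one survey's detections against its truth list."""
    for d in detections:
        if d.survey_id != schedule.survey_id:
            raise ValueError(
                f"detection {d.detection_id} belongs to survey {d.survey_id!r}, "
                f"not {schedule.survey_id!r}"
            )
    clips = sorted(schedule.clips, key=lambda c: (c.onset_interval, c.clip_id))
    by_species: dict[str, list] = defaultdict(list)
    for c in clips:
        by_species[c.species].append(c)
    matched: dict[int, int] = {}  # clip_id -> detection_id
    ordered = sorted(detections, key=lambda d: (d.interval_index, d.detection_id))

    scored_map: dict[int, ScoredDetection] = {}
    unmatched_dets = []
    for d in ordered:
        candidates = [
            c
            for c in by_species.get(d.reported_species, [])
            if c.clip_id not in matched and abs(c.onset_interval - d.interval_index) <= 1
        ]
        if candidates:
            clip = candidates[0]  # earliest unmatched: earliest-deadline-first
            matched[clip.clip_id] = d.detection_id
            scored_map[d.detection_id] = ScoredDetection(
                detection=d,
                classification=CORRECT,
                fp_cause=CAUSE_NONE,
                matched_clip_id=clip.clip_id,
            )
        else:
            unmatched_dets.append(d)

    # False-positive cause attribution: nearest unmatched different-species
    # clip in the window, preferring clips not already blamed for another
    # false positive; ties by smaller |offset|, then earlier clip.
    confusion: Counter = Counter()
    attributed: set[int] = set()
    for d in unmatched_dets:
        cands = [
            c
            for c in clips
            if c.clip_id not in matched
            and c.species != d.reported_species
            and abs(c.onset_interval - d.interval_index) <= 1
        ]
        if cands:
            cands.sort(
                key=lambda c: (
                    c.clip_id in attributed,
                    abs(c.onset_interval - d.interval_index),
                    c.clip_id,
                )
            )
            src = cands[0]
            attributed.add(src.clip_id)
            confusion[(src.species, d.reported_species)] += 1
            scored_map[d.detection_id] = ScoredDetection(
                detection=d,
                classification=FALSE_POSITIVE,
                fp_cause=CAUSE_MISID,
                inferred_true_species=src.species,
            )
        else:
            scored_map[d.detection_id] = ScoredDetection(
                detection=d, classification=FALSE_POSITIVE, fp_cause=CAUSE_WINDOW
            )

    scored = [scored_map[d.detection_id] for d in ordered]
    unmatched_clips = [c.clip_id for c in clips if c.clip_id not in matched]
    score = SurveyScore(
        survey_id=schedule.survey_id,
        n_clips=schedule.n_clips,
        scored=scored,
        nondetection_clip_ids=[cid for cid in unmatched_clips if cid not in attributed],
        misid_source_clip_ids=[cid for cid in unmatched_clips if cid in attributed],
        confusion_counts=confusion,
    )
    assert score.n_correct + score.n_fp == score.n_detections
    assert len(matched) + score.n_unmatched == schedule.n_clips
    return score


def confusion_counts(scores: Iterable[SurveyScore], roster: SpeciesRoster) -> pd.DataFrame:
    """Aggregate (true -> reported) misidentification counts, roster-ordered.

    Rows are inferred true species, columns reported species; asymmetric by
    construction. The diagonal is zero (correct detections are not confusions).
    """
    codes = roster.codes
    mat = pd.DataFrame(0, index=list(codes), columns=list(codes), dtype=int)
    for s in scores:
        for (true_sp, rep_sp), k in s.confusion_counts.items():
            mat.loc[true_sp, rep_sp] += k
    return mat


def species_totals(
    schedules: Iterable[SurveySchedule], scores: Iterable[SurveyScore]
) -> pd.DataFrame:
    """Per-species truth vs observed totals and the bias decomposition.

    bias = observed - truth = (false positives credited to the species)
    - (false negatives of the species), where a species' false negatives are
    its unmatched clips (nondetections plus clips reported as another
    species). The identity holds exactly by construction.
    """
    schedules = list(schedules)
    scores = list(scores)
    sched_map = {s.survey_id: s for s in schedules}
    roster = schedules[0].config.roster
    rows = []
    truth = Counter()
    observed = Counter()
    fp = Counter()
    fn = Counter()
    for sc in scores:
        sched = sched_map[sc.survey_id]
        clip_species = {c.clip_id: c.species for c in sched.clips}
        for c in sched.clips:
            truth[c.species] += 1
        for sd in sc.scored:
            observed[sd.detection.reported_species] += 1
            if sd.classification == FALSE_POSITIVE:
                fp[sd.detection.reported_species] += 1
        for cid in sc.nondetection_clip_ids + sc.misid_source_clip_ids:
            fn[clip_species[cid]] += 1
    for code in roster.codes:
        rows.append(
            {
                "species": code,
                "truth_total": truth[code],
                "observed_total": observed[code],
                "bias": observed[code] - truth[code],
                "n_fp": fp[code],
                "n_fn": fn[code],
            }
        )
    df = pd.DataFrame(rows).set_index("species")
    if not (df["bias"] == df["n_fp"] - df["n_fn"]).all():
        raise AssertionError("species bias identity violated")
    return df
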