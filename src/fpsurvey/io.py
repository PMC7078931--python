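"""Tab/comma-separated on-disk formats for schedules, detections and scores.

All files are UTF-8 with header rows. Schedules and detections are TSV (one
clip / one detection per row); aggregate outputs are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .observers import DDOConfig, DetectionRecord, ObserverProfile
from .roster import SpeciesRoster
from .schedule import ScheduleConfig, SurveySchedule, TruthClip
from .scoring import SurveyScore

SCHEDULE_COLUMNS = ["survey_id", "clip_id", "species", "onset_s", "onset_interval"]
DETECTION_COLUMNS = ["survey_id", "detection_id", "interval_index", "reported_species", "role"]


def schedules_to_frame(schedules: Iterable[SurveySchedule]) -> pd.DataFrame:
    rows = [
        {
            "survey_id": s.survey_id,
            "clip_id": c.clip_id,
            "species": c.species,
            "onset_s": round(c.onset_s, 6),
            "onset_interval": c.onset_interval,
        }
        for s in schedules
        for c in s.clips
    ]
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def write_schedules(schedules: Iterable[SurveySchedule], path: str | Path) -> None:
    schedules_to_frame(schedules).to_csv(path, sep="\t", index=False)


def read_schedules(path: str | Path, config: ScheduleConfig) -> list[SurveySchedule]:
    """Rebuild SurveySchedule objects from a schedule TSV.

    The config is supplied by the caller (a TSV row carries no grid/roster
    metadata); schedule invariants are re-validated on construction.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("survey_id", sort=True):
        grp = grp.sort_values(["onset_s", "clip_id"])
        clips = tuple(
            TruthClip(
                clip_id=int(r.clip_id),
                species=str(r.species),
                onset_s=float(r.onset_s),
                onset_interval=int(r.onset_interval),
            )
            for r in grp.itertuples()
        )
        out.append(SurveySchedule(survey_id=str(sid), config=config, clips=clips))
    return out


def detections_to_frame(detections: Iterable[DetectionRecord]) -> pd.DataFrame:
    rows = [
        {
            "survey_id": d.survey_id,
            "detection_id": d.detection_id,
            "interval_index": d.interval_index,
            "reported_species": d.reported_species,
            "role": d.role,
        }
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections(detections: Iterable[DetectionRecord], path: str | Path) -> None:
    detections_to_frame(detections).to_csv(path, sep="\t", index=False)


def read_detections(path: str | Path) -> list[DetectionRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections file missing columns {sorted(missing)}")
    return [
        DetectionRecord(
            survey_id=str(r.survey_id),
            detection_id=int(r.detection_id),
            interval_index=int(r.interval_index),
            reported_species=str(r.reported_species),
            role=str(r.role),
        )
        for r in df.itertuples()
    ]


def scored_detections_to_frame(scores: Iterable[SurveyScore]) -> pd.DataFrame:
    rows = []
    for s in scores:
        for sd in s.scored:
            rows.append(
                {
                    "survey_id": sd.detection.survey_id,
                    "detection_id": sd.detection.detection_id,
                    "interval_index": sd.detection.interval_index,
                    "reported_species": sd.detection.reported_species,
                    "role": sd.detection.role,
                    "classification": sd.classification,
                    "fp_cause": sd.fp_cause,
                    "matched_clip_id": sd.matched_clip_id,
                    "inferred_true_species": sd.inferred_true_species,
                }
            )
    return pd.DataFrame(
        rows,
        columns=DETECTION_COLUMNS
        + ["classification", "fp_cause", "matched_clip_id", "inferred_true_species"],
    )


def survey_scores_to_frame(scores: Iterable[SurveyScore]) -> pd.DataFrame:
    rows = [
        {
            "survey_id": s.survey_id,
            "n_clips": s.n_clips,
            "n_detections": s.n_detections,
            "n_correct": s.n_correct,
            "n_fp": s.n_fp,
            "n_nondetections": len(s.nondetection_clip_ids),
            "n_misid_source_clips": len(s.misid_source_clip_ids),
        }
        for s in scores
    ]
    return pd.DataFrame(rows)


def load_profiles(path: str | Path, roster: SpeciesRoster) -> tuple[dict[str, ObserverProfile], DDOConfig]:
    """Read observer profiles (+ optional DDO collaboration) from YAML/JSON.

    Layout::

        profiles:
          expert:
            p_detect: 0.95            # scalar or {code: prob}
            confusion: {BHCO: {BHCO: 0.9, HOLA: 0.1}, ...}
            jitter: {-1: 0.08, 0: 0.84, 1: 0.08}
        ddo:
          collaboration: 0.8
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    profiles = {}
    for label, spec in data["profiles"].items():
        jitter = spec.get("jitter")
        if jitter is not None:
            jitter = {int(k): float(v) for k, v in jitter.items()}
        profiles[label] = ObserverProfile.from_mappings(
            label=label,
            roster=roster,
            p_detect=spec["p_detect"],
            confusion=spec["confusion"],
            jitter=jitter,
            spurious_rate=float(spec.get("spurious_rate", 0.0)),
        )
    ddo = DDOConfig(collaboration=float(data.get("ddo", {}).get("collaboration", 0.0)))
    return profiles, ddo


def profiles_to_dict(profiles: Mapping[str, ObserverProfile], ddo: DDOConfig) -> dict:
    out: dict = {"profiles": {}, "ddo": {"collaboration": ddo.collaboration}}
    for label, p in profiles.items():
        out["profiles"][label] = {
            "p_detect": {c: float(v) for c, v in zip(p.species, p.p_detect)},
            "confusion": {
                ci: {cj: float(p.confusion[i, j]) for j, cj in enumerate(p.species) if p.confusion[i, j] > 0}
                for i, ci in enumerate(p.species)
            },
            "jitter": {int(k): float(v) for k, v in p.jitter.items()},
            "spurious_rate": p.spurious_rate,
        }
    return out
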