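"""End-to-end experiment orchestration and printed-table reproduction.

``run_experiment`` chains simulate -> observe -> score -> analyze into a run
directory with a JSON manifest (config hash, seed, per-file content hashes),
so a rerun with the same config and seed is byte-identical.

``reproduce_tables`` recomputes every derivable quantity of the embedded
reference tables from their primitive counts and flags agreement at printed
precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import fixtures, io
from .observers import CampaignResult, ScenarioSpec, simulate_campaign
from .schedule import ScheduleConfig
from .scoring import SurveyScore, confusion_counts, match_survey, species_totals
from .stats import (
    ScenarioCounts,
    fit_saturated_logit,
    fp_rate,
    percent_reduction,
    rate_from_counts,
)

logger = logging.getLogger("fpsurvey")


@dataclass(frozen=True)
class ExperimentConfig:
    schedule: ScheduleConfig
    scenarios: tuple[ScenarioSpec, ...]
    seed: int
    out_dir: Path
    write_scored_detections: bool = True

    def __post_init__(self) -> None:
        labels = [s.label for s in self.scenarios]
        if len(set(labels)) != len(labels):
            raise ValueError("scenario labels must be unique")


def _config_fingerprint(config: ExperimentConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "tolist"):
            return o.tolist()
        return str(o)

    payload = {
        "schedule": dataclasses.asdict(config.schedule),
        "scenarios": [dataclasses.asdict(s) for s in config.scenarios],
        "seed": config.seed,
    }
    blob = json.dumps(payload, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def score_campaign(result: CampaignResult) -> dict[str, SurveyScore]:
    by_survey = result.detections_by_survey()
    return {
        sid: match_survey(sched, by_survey.get(sid, []))
        for sid, sched in result.schedules.items()
    }


def campaign_scenario_counts(
    result: CampaignResult, scores: dict[str, SurveyScore]
) -> list[ScenarioCounts]:
    by_arm: dict[tuple[str, str], list[SurveyScore]] = {}
    for a in result.assignments:
        by_arm.setdefault((a.experience, a.method), []).append(scores[a.survey_id])
    return [
        ScenarioCounts(
            experience=exp,
            method=met,
            n_surveys=len(ss),
            n_detections=sum(s.n_detections for s in ss),
            n_fp=sum(s.n_fp for s in ss),
        )
        for (exp, met), ss in sorted(by_arm.items())
    ]


def scenario_counts_frame(cells: Sequence[ScenarioCounts]) -> pd.DataFrame:
    rows = []
    for c in cells:
        est = rate_from_counts(c)
        rows.append(
            {
                "experience": c.experience,
                "method": c.method,
                "n_surveys": c.n_surveys,
                "n_detections": c.n_detections,
                "n_fp": c.n_fp,
                "fp_rate": est.rate,
                "se": est.se,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> Path:
    """Run all stages; returns the run directory.

    Fails loudly with the failing stage named. All randomness descends from
    config.seed, so reruns are byte-identical apart from nothing: timestamps
    are deliberately excluded from every output.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        result = simulate_campaign(list(config.scenarios), config.schedule, config.seed)
        io.write_schedules(result.schedules.values(), out / "schedules.tsv")
        io.write_detections(result.detections, out / "detections.tsv")
        pd.DataFrame([dataclasses.asdict(a) for a in result.assignments]).to_csv(
            out / "assignments.csv", index=False
        )
        logger.info("simulate: %d surveys, %d detections", len(result.schedules), len(result.detections))

        stage = "score"
        scores = score_campaign(result)
        if config.write_scored_detections:
            io.scored_detections_to_frame(scores.values()).to_csv(
                out / "scored_detections.tsv", sep="\t", index=False
            )
        io.survey_scores_to_frame(scores.values()).to_csv(out / "survey_scores.csv", index=False)
        roster = config.schedule.roster
        confusion_counts(scores.values(), roster).to_csv(out / "confusion_matrix.csv")
        species_totals(result.schedules.values(), scores.values()).to_csv(out / "species_totals.csv")
        logger.info("score: %d surveys scored", len(scores))

        stage = "analyze"
        cells = campaign_scenario_counts(result, scores)
        scen = scenario_counts_frame(cells)
        scen.to_csv(out / "scenario_rates.csv", index=False)
        if len(cells) == 4 and all(0 < c.n_fp < c.n_detections for c in cells):
            fit = fit_saturated_logit(cells)
            logit_frame(fit).to_csv(out / "logit_odds_ratios.csv", index=False)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_sha256": _config_fingerprint(config),
        "files": {p.name: _sha256(p) for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def logit_frame(fit) -> pd.DataFrame:
    rows = []
    for name, t in fit.terms().items():
        rows.append(
            {
                "term": name,
                "estimate": t.estimate,
                "exp_se": t.exp_se,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "p_value": t.p_value,
            }
        )
    return pd.DataFrame(rows)


def reproduce_tables(decimals: int = 3) -> dict[str, pd.DataFrame]:
    """Recompute the reference tables from their primitive counts.

    Returns frames with computed vs printed values and a ``match`` flag at
    ``decimals`` places (reductions compared at 1 d.p.).
    """
    cells = fixtures.SCENARIO_CELLS
    rows = []
    for c in cells:
        est = rate_from_counts(c)
        pr_rate, pr_sd = fixtures.SCENARIO_PRINTED[(c.experience, c.method)]
        rows.append(
            {
                "scenario": f"{c.experience} {c.method}",
                "n_surveys": c.n_surveys,
                "n_detections": c.n_detections,
                "n_fp": c.n_fp,
                "rate": est.rate,
                "printed_rate": pr_rate,
                "sd": est.se,
                "printed_sd": pr_sd,
            }
        )
    tot_fp = sum(c.n_fp for c in cells)
    tot_det = sum(c.n_detections for c in cells)
    est = fp_rate(tot_fp, tot_det)
    pr_rate, pr_sd = fixtures.SCENARIO_PRINTED["total"]
    rows.append(
        {
            "scenario": "total",
            "n_surveys": sum(c.n_surveys for c in cells),
            "n_detections": tot_det,
            "n_fp": tot_fp,
            "rate": est.rate,
            "printed_rate": pr_rate,
            "sd": est.se,
            "printed_sd": pr_sd,
        }
    )
    t1 = pd.DataFrame(rows)
    t1["match"] = (t1["rate"].round(decimals) == t1["printed_rate"]) & (
        t1["sd"].round(decimals) == t1["printed_sd"]
    )

    fit = fit_saturated_logit(list(cells))
    t2rows = []
    for name, printed_key in [
        ("intercept", "intercept"),
        ("naive", "naive"),
        ("ISO", "ISO"),
        ("naive x ISO", "naive x ISO"),
    ]:
        t = fit.terms()[name]
        pr_est, pr_se = fixtures.LOGIT_PRINTED[printed_key]
        t2rows.append(
            {
                "term": name,
                "estimate": t.estimate,
                "printed_estimate": pr_est,
                "exp_se": t.exp_se,
                "printed_se": pr_se,
                "p_value": t.p_value,
            }
        )
    t2 = pd.DataFrame(t2rows)
    t2["match"] = (t2["estimate"].round(decimals) == t2["printed_estimate"]) & (
        t2["exp_se"].round(decimals) == t2["printed_se"]
    )

    by_arm = {(c.experience, c.method): rate_from_counts(c).rate for c in cells}
    red_rows = []
    for exp in ("expert", "naive"):
        red = percent_reduction(by_arm[(exp, "ISO")], by_arm[(exp, "DDO")], rounding=3)
        red_rows.append(
            {
                "experience": exp,
                "percent_reduction": red,
                "printed": fixtures.PRINTED_REDUCTIONS[exp],
                "match": round(red, 1) == fixtures.PRINTED_REDUCTIONS[exp],
            }
        )
    reductions = pd.DataFrame(red_rows)
    return {"scenario_rates": t1, "logit": t2, "reductions": reductions}
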