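"""Observer models: ISO/DDO branch logic, removal design, campaign plumbing."""

import dataclasses

import numpy as np
import pytest

from fpsurvey.observers import (
    DDOConfig,
    ObserverProfile,
    ScenarioSpec,
    simulate_campaign,
    simulate_ddo,
    simulate_iso,
)
from fpsurvey.roster import DEFAULT_ROSTER
from fpsurvey.schedule import ScheduleConfig, generate_batch, generate_schedule

from conftest import NO_JITTER, make_schedule, perfect_profile


def tiny_profile(roster, p, confusion, label="obs", jitter=None):
    return ObserverProfile(
        label=label,
        species=roster.codes,
        p_detect=np.asarray(p, float),
        confusion=np.asarray(confusion, float),
        jitter=jitter or dict(NO_JITTER),
    )


class TestProfileValidation:
    def test_rejects_non_stochastic_rows(self, tiny_roster):
        bad = np.full((3, 3), 0.4)
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_profile(tiny_roster, [1, 1, 1], bad)

    def test_rejects_bad_jitter(self, tiny_roster):
        with pytest.raises(ValueError, match="jitter"):
            tiny_profile(tiny_roster, [1, 1, 1], np.eye(3), jitter={-2: 0.5, 0: 0.5})

    def test_missing_species_raises(self, tiny_config, tiny_roster):
        sched = generate_schedule(tiny_config, np.random.default_rng(0))
        small = ObserverProfile(
            label="partial",
            species=("AAAA",),
            p_detect=np.array([1.0]),
            confusion=np.eye(1),
        )
        with pytest.raises(KeyError, match="missing species"):
            simulate_iso(sched, small, np.random.default_rng(0))


class TestISO:
    def test_perfect_observer_reproduces_truth(self, default_config, perfect_default_profile):
        sched = generate_schedule(default_config, np.random.default_rng(1))
        recs = simulate_iso(sched, perfect_default_profile, np.random.default_rng(2))
        assert len(recs) == sched.n_clips
        got = sorted((r.interval_index, r.reported_species) for r in recs)
        want = sorted((c.onset_interval, c.species) for c in sched.clips)
        assert got == want
        assert all(r.role == "single" for r in recs)

    def test_blind_observer_detects_nothing(self, tiny_config, tiny_roster):
        sched = generate_schedule(tiny_config, np.random.default_rng(3))
        prof = tiny_profile(tiny_roster, [0, 0, 0], np.eye(3))
        assert simulate_iso(sched, prof, np.random.default_rng(4)) == []

    def test_confusion_sampling_fraction(self, tiny_config, tiny_roster):
        # species AAAA reported as BBBB with probability q: empirical fraction
        # over >=10^4 detections sits within 3 binomial SEs of q
        q = 0.3
        conf = np.array([[0.7, q, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        prof = tiny_profile(tiny_roster, [1, 1, 1], conf)
        cfg = dataclasses.replace(tiny_config, count_low=4, count_high=4)
        rng = np.random.default_rng(5)
        n_a = n_ab = 0
        schedules, _ = generate_batch(cfg, 900, seed=6)
        for sched in schedules:
            recs = simulate_iso(sched, prof, rng)
            # p=1 and zero jitter: records align one-to-one with clips in time order
            for clip, rec in zip(sched.clips, recs):
                if clip.species == "AAAA":
                    n_a += 1
                    n_ab += rec.reported_species == "BBBB"
        assert n_a >= 3_000
        se = np.sqrt(q * (1 - q) / n_a)
        assert abs(n_ab / n_a - q) < 3 * se

    def test_jitter_clamped_to_grid(self, tiny_config, tiny_roster):
        sched = make_schedule(tiny_config, [("AAAA", 0.0), ("BBBB", 176.0)])
        prof_left = tiny_profile(tiny_roster, [1, 1, 1], np.eye(3), jitter={-1: 1.0, 0: 0.0, 1: 0.0})
        prof_right = tiny_profile(tiny_roster, [1, 1, 1], np.eye(3), jitter={-1: 0.0, 0: 0.0, 1: 1.0})
        lo = simulate_iso(sched, prof_left, np.random.default_rng(7))
        hi = simulate_iso(sched, prof_right, np.random.default_rng(8))
        n_int = tiny_config.n_intervals
        assert min(r.interval_index for r in lo) == 0
        assert max(r.interval_index for r in hi) == n_int - 1


class TestDDO:
    def test_both_perfect_all_primary(self, tiny_config, tiny_roster):
        sched = generate_schedule(tiny_config, np.random.default_rng(9))
        p = perfect_profile(tiny_roster)
        recs = simulate_ddo(sched, p, p, DDOConfig(0.5), np.random.default_rng(10))
        assert len(recs) == sched.n_clips
        assert all(r.role == "primary" for r in recs)
        got = sorted((r.interval_index, r.reported_species) for r in recs)
        want = sorted((c.onset_interval, c.species) for c in sched.clips)
        assert got == want

    def test_blind_primary_perfect_secondary(self, tiny_config, tiny_roster):
        sched = generate_schedule(tiny_config, np.random.default_rng(11))
        blind = tiny_profile(tiny_roster, [0, 0, 0], np.eye(3))
        recs = simulate_ddo(
            sched, blind, perfect_profile(tiny_roster), DDOConfig(0.0), np.random.default_rng(12)
        )
        assert len(recs) == sched.n_clips
        assert all(r.role == "secondary" for r in recs)

    def test_full_collaboration_eliminates_misids(self, tiny_config, tiny_roster):
        # kappa=1 with a perfect secondary: every primary misidentification is
        # corrected, so all reports carry the true species
        conf = np.array([[0.5, 0.25, 0.25], [0.25, 0.5, 0.25], [0.25, 0.25, 0.5]])
        primary = tiny_profile(tiny_roster, [1, 1, 1], conf)
        rng = np.random.default_rng(13)
        for seed in range(30):
            sched = generate_schedule(tiny_config, np.random.default_rng(100 + seed))
            recs = simulate_ddo(sched, primary, perfect_profile(tiny_roster), DDOConfig(1.0), rng)
            assert [r.reported_species for r in sorted(recs, key=lambda r: r.interval_index)] == [
                c.species for c in sched.clips
            ]

    def test_removal_design_at_most_one_record_per_clip(self, tiny_config, tiny_roster):
        conf = np.array([[0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
        a = tiny_profile(tiny_roster, [0.7, 0.8, 0.9], conf, "a")
        b = tiny_profile(tiny_roster, [0.5, 0.6, 0.7], conf, "b")
        rng = np.random.default_rng(14)
        for seed in range(50):
            sched = generate_schedule(tiny_config, np.random.default_rng(200 + seed))
            recs = simulate_ddo(sched, a, b, DDOConfig(0.5), rng)
            assert len(recs) <= sched.n_clips

    def test_per_clip_outcome_probabilities_match_enumeration(self, tiny_config, tiny_roster):
        # brute-force enumeration of the per-clip branch tree vs Monte Carlo
        p1 = tiny_profile(
            tiny_roster, [0.8, 0.8, 0.8],
            np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.15, 0.15, 0.7]]), "p1",
        )
        p2 = tiny_profile(
            tiny_roster, [0.6, 0.6, 0.6],
            np.array([[0.75, 0.15, 0.1], [0.05, 0.9, 0.05], [0.1, 0.1, 0.8]]), "p2",
        )
        kappa = 0.7
        i = 0  # true species AAAA
        pa, pb = 0.8, 0.6
        corr = pb * p2.confusion[i, i] * kappa
        expected = {
            ("primary", "AAAA"): pa * (p1.confusion[i, i] + (1 - p1.confusion[i, i]) * corr),
            ("primary", "BBBB"): pa * p1.confusion[i, 1] * (1 - corr),
            ("primary", "CCCC"): pa * p1.confusion[i, 2] * (1 - corr),
            ("secondary", "AAAA"): (1 - pa) * pb * p2.confusion[i, 0],
            ("secondary", "BBBB"): (1 - pa) * pb * p2.confusion[i, 1],
            ("secondary", "CCCC"): (1 - pa) * pb * p2.confusion[i, 2],
            "nondetection": (1 - pa) * (1 - pb),
        }
        assert sum(expected.values()) == pytest.approx(1.0)
        sched = make_schedule(tiny_config, [("AAAA", 10.0)])
        rng = np.random.default_rng(15)
        n = 30_000
        observed = {k: 0 for k in expected}
        for _ in range(n):
            recs = simulate_ddo(sched, p1, p2, DDOConfig(kappa), rng)
            key = (recs[0].role, recs[0].reported_species) if recs else "nondetection"
            observed[key] += 1
        for key, p in expected.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(observed[key] / n - p) < 3.5 * se, key


class TestCampaign:
    @staticmethod
    def scenarios(n_ddo=2, n_iso=2):
        a = perfect_profile(DEFAULT_ROSTER, "A")
        b = perfect_profile(DEFAULT_ROSTER, "B")
        return [
            ScenarioSpec("expert", "DDO", n_ddo, (a, b), DDOConfig(0.5)),
            ScenarioSpec("expert", "ISO", n_iso, (a,)),
        ]

    def test_roles_alternate_between_surveys(self):
        res = simulate_campaign(self.scenarios(), ScheduleConfig(), seed=16)
        ddo = [x for x in res.assignments if x.method == "DDO"]
        assert (ddo[0].observer, ddo[0].partner) == ("A", "B")
        assert (ddo[1].observer, ddo[1].partner) == ("B", "A")

    def test_dataset_partitions_by_scenario(self):
        res = simulate_campaign(self.scenarios(3, 4), ScheduleConfig(), seed=17)
        assert len(res.schedules) == 7
        by_survey = res.detections_by_survey()
        assert sum(len(v) for v in by_survey.values()) == len(res.detections)
        for sid, sched in res.schedules.items():
            assert len(by_survey[sid]) == sched.n_clips  # perfect observers

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            ScenarioSpec("expert", "XXX", 1, (perfect_profile(DEFAULT_ROSTER),))

    def test_higher_diagonal_means_fewer_misids(self, tiny_roster):
        cfg = ScheduleConfig(roster=tiny_roster)
        sharp = tiny_profile(tiny_roster, [1, 1, 1], np.full((3, 3), 0.05) + np.eye(3) * 0.85, "sharp")
        dull = tiny_profile(tiny_roster, [1, 1, 1], np.full((3, 3), 0.3) + np.eye(3) * 0.1, "dull")
        res = simulate_campaign(
            [
                ScenarioSpec("expert", "ISO", 60, (sharp,)),
                ScenarioSpec("naive", "ISO", 60, (dull,)),
            ],
            cfg,
            seed=18,
        )
        frac = {}
        for arm in ("expert", "naive"):
            wrong = tot = 0
            for x in res.assignments:
                if x.experience != arm:
                    continue
                sched = res.schedules[x.survey_id]
                truth = [c.species for c in sched.clips]
                recs = res.detections_by_survey()[x.survey_id]
                for clip, rec in zip(sched.clips, recs):  # p=1, zero jitter
                    tot += 1
                    wrong += rec.reported_species != clip.species
            frac[arm] = wrong / tot
        assert frac["expert"] < frac["naive"]
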