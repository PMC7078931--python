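import numpy as np
import pytest

from fpsurvey.observers import ObserverProfile
from fpsurvey.roster import DEFAULT_ROSTER, SpeciesEntry, SpeciesRoster
from fpsurvey.schedule import ScheduleConfig, SurveySchedule, TruthClip

NO_JITTER = {-1: 0.0, 0: 1.0, 1: 0.0}


@pytest.fixture
def default_config() -> ScheduleConfig:
    return ScheduleConfig()


@pytest.fixture
def tiny_roster() -> SpeciesRoster:
    return SpeciesRoster(
        (
            SpeciesEntry("AAAA", "species a", "Aus aus"),
            SpeciesEntry("BBBB", "species b", "Bus bus"),
            SpeciesEntry("CCCC", "species c", "Cus cus"),
        )
    )


@pytest.fixture
def tiny_config(tiny_roster) -> ScheduleConfig:
    return ScheduleConfig(roster=tiny_roster, count_low=1, count_high=4)


def perfect_profile(roster: SpeciesRoster, label: str = "perfect") -> ObserverProfile:
    n = len(roster)
    return ObserverProfile(
        label=label,
        species=roster.codes,
        p_detect=np.ones(n),
        confusion=np.eye(n),
        jitter=dict(NO_JITTER),
    )


def make_schedule(config: ScheduleConfig, species_onsets, survey_id: str = "T0") -> SurveySchedule:
    """Handcraft a schedule from (species, onset_s) pairs (sorted by onset)."""
    pairs = sorted(species_onsets, key=lambda t: t[1])
    clips = tuple(
        TruthClip(
            clip_id=k,
            species=sp,
            onset_s=float(t),
            onset_interval=int(t // config.interval_s),
        )
        for k, (sp, t) in enumerate(pairs)
    )
    return SurveySchedule(survey_id=survey_id, config=config, clips=clips)


@pytest.fixture
def perfect_default_profile() -> ObserverProfile:
    return perfect_profile(DEFAULT_ROSTER)
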