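import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from fhrtrend.cleaning import CleanedEpisode, clean_episode
from fhrtrend.episode import Episode, correct_clock_drift
from fhrtrend.pipeline import RunConfig, prepare_episodes
from fhrtrend.simulate import GeneratorConfig, generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_episode(
    values,
    start_s: float = -9000.0,
    episode_id: str = "ep0",
    outcome: str = "normal",
    mhr_t=(),
    mhr_bpm=(),
) -> Episode:
    """Episode from a literal FHR list (None/NaN = missing)."""
    fhr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    return Episode(
        episode_id=episode_id,
        fhr=fhr,
        fhr_start_s=start_s,
        mhr_t=np.asarray(mhr_t, dtype=float),
        mhr_bpm=np.asarray(mhr_bpm, dtype=float),
        outcome=outcome,
    )


def as_cleaned(episode: Episode) -> CleanedEpisode:
    """Wrap an episode as if cleaning removed nothing (pass-through)."""
    return CleanedEpisode(
        episode=episode,
        filled_mask=~episode.measured_mask(),
        removed_mask=np.zeros(episode.n_ticks, dtype=bool),
        cleaned_fhr=episode.fhr.copy(),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 230 episodes, fixed seed."""
    return generate_cohort(GeneratorConfig(), seed=123)


@pytest.fixture(scope="session")
def default_cleaned(default_cohort):
    episodes = [ep for ep, _ in default_cohort]
    return prepare_episodes(episodes, RunConfig())


@pytest.fixture(scope="session")
def normal_cleaned(default_cleaned):
    return [c for c in default_cleaned if c.outcome == "normal"]


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort for I/O and pipeline smoke tests."""
    cfg = GeneratorConfig(
        n_normal=8,
        n_ncu=3,
        n_vend=2,
        n_fsb=2,
        n_unlabeled=1,
        span_start_min_s=-12600.0,
        span_start_max_s=-10800.0,
    )
    return cfg, generate_cohort(cfg, seed=7)
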