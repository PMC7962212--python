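"""Shared setup for the numbered analysis drivers.

Every driver regenerates the default synthetic cohort deterministically
from (config, seed) rather than reading hundreds of megabytes of episode
CSVs from disk; `01_simulate_cohort.py --write-episodes DIR` exists for
anyone who wants the on-disk layout.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from fhrtrend.cohort import assign_groups
from fhrtrend.pipeline import RunConfig, prepare_episodes
from fhrtrend.simulate import GeneratorConfig, generate_cohort


def make_parser(description: str) -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    return parser


def default_cohort(seed: int):
    """(cohort, episodes, cleaned episodes, partition) for the default
    study conditions."""
    cfg = GeneratorConfig()
    cohort = generate_cohort(cfg, seed=seed)
    episodes = [ep for ep, _ in cohort]
    cleaneds = prepare_episodes(episodes, RunConfig())
    partition = assign_groups(episodes)
    return cfg, cohort, cleaneds, partition


def group_members(cleaneds, partition, key: str):
    ids = partition.groups[key]
    return [c for c in cleaneds if c.episode_id in ids]
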