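"""Outcome-group assignment and the cohort summary table.

Episodes are grouped by the neonatal outcome recorded 24 h after birth:
normal (s1), still admitted to the neonatal care unit (s2), very early
neonatal death (s4) and fresh stillbirth (s5). The perinatal-mortality
group s3 is the union of s4 and s5, and s0 is all labeled episodes;
unlabeled episodes are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cleaning import CleanedEpisode, removed_fraction
from .episode import Episode, Window, missing_fraction
from .errors import CohortValidationError, UndefinedResultError

GROUP_LABELS = (
    "s0_all_labeled",
    "s1_normal",
    "s2_ncu",
    "s3_perinatal",
    "s4_vend",
    "s5_fsb",
)

_OUTCOME_TO_BASE = {"normal": "s1_normal", "ncu": "s2_ncu",
                    "vend": "s4_vend", "fsb": "s5_fsb"}


@dataclass
class GroupPartition:
    """Episode-id sets per outcome group plus the excluded (unlabeled) set."""

    groups: dict[str, set[str]]
    excluded: set[str]

    def __post_init__(self) -> None:
        g = self.groups
        for label in GROUP_LABELS:
            g.setdefault(label, set())
        base = [g["s1_normal"], g["s2_ncu"], g["s4_vend"], g["s5_fsb"]]
        for i in range(len(base)):
            for j in range(i + 1, len(base)):
                if base[i] & base[j]:
                    raise CohortValidationError("outcome groups overlap")
        if g["s3_perinatal"] != g["s4_vend"] | g["s5_fsb"]:
            raise CohortValidationError("s3 must equal s4 ∪ s5")
        if g["s0_all_labeled"] != set().union(*base):
            raise CohortValidationError("s0 must be the union of s1, s2, s4, s5")
        if g["s0_all_labeled"] & self.excluded:
            raise CohortValidationError("excluded ids overlap labeled ids")

    @property
    def n_total(self) -> int:
        return len(self.groups["s0_all_labeled"]) + len(self.excluded)

    def size(self, label: str) -> int:
        return len(self.groups[label])


def assign_groups(
    cohort: Union[Mapping[str, str], Iterable[Episode]],
) -> GroupPartition:
    """Partition a cohort by outcome.

    ``cohort`` is either episodes or a mapping ``episode_id -> outcome``.
    Unlabeled episodes go to ``excluded``.
    """
    if isinstance(cohort, Mapping):
        outcomes = dict(cohort)
    else:
        outcomes = {}
        for ep in cohort:
            if ep.episode_id in outcomes:
                raise CohortValidationError(
                    f"duplicate episode_id {ep.episode_id!r}"
                )
            outcomes[ep.episode_id] = ep.outcome
    groups: dict[str, set[str]] = {label: set() for label in GROUP_LABELS}
    excluded: set[str] = set()
    for eid, outcome in outcomes.items():
        base = _OUTCOME_TO_BASE.get(outcome)
        if base is None:
            excluded.add(eid)
            continue
        groups[base].add(eid)
    groups["s3_perinatal"] = groups["s4_vend"] | groups["s5_fsb"]
    groups["s0_all_labeled"] = (
        groups["s1_normal"] | groups["s2_ncu"] | groups["s3_perinatal"]
    )
    return GroupPartition(groups=groups, excluded=excluded)


def _per_episode_pct(
    cleaneds: Sequence[CleanedEpisode],
    ids: set[str],
    window: Optional[Window],
    kind: str,
) -> np.ndarray:
    vals = []
    for c in cleaneds:
        if c.episode_id not in ids:
            continue
        ep = c.episode
        if window is None:
            first, last = ep.recorded_span()
            w = Window(start_s=first, duration_s=(last - first) + 0.5)
        else:
            w = window
        try:
            frac = (
                missing_fraction(ep, w) if kind == "missing"
                else removed_fraction(c, w)
            )
        except UndefinedResultError:
            continue
        vals.append(100.0 * frac)
    return np.asarray(vals)


def summary_table(
    cleaneds: Sequence[CleanedEpisode],
    partition: GroupPartition,
    window: Optional[Window] = None,
) -> pd.DataFrame:
    """Per-group episode counts and missing/removed data percentages.

    Statistics are the mean ± sample sd (ddof=1) over episodes of the
    per-episode missing-data and removed-data percentages, computed over
    each episode's recorded span unless an explicit ``window`` (e.g. the
    last 150 min) is given. The sd is left blank (NaN) for single-episode
    groups, where the sample sd is undefined.
    """
    display = [
        ("all", None),
        ("all_labeled", "s0_all_labeled"),
        ("normal", "s1_normal"),
        ("ncu", "s2_ncu"),
        ("vend", "s4_vend"),
        ("fsb", "s5_fsb"),
        ("perinatal", "s3_perinatal"),
        ("unlabeled", "excluded"),
    ]
    all_ids = partition.groups["s0_all_labeled"] | partition.excluded
    rows = []
    for name, key in display:
        if key is None:
            ids = all_ids
        elif key == "excluded":
            ids = partition.excluded
        else:
            ids = partition.groups[key]
        row: dict[str, object] = {"group": name, "n_episodes": len(ids)}
        for kind in ("missing", "removed"):
            vals = _per_episode_pct(cleaneds, ids, window, kind)
            if vals.size == 0:
                mean = sd = float("nan")
            else:
                mean = round(float(vals.mean()), 2)
                sd = (
                    round(float(vals.std(ddof=1)), 2)
                    if vals.size > 1
                    else float("nan")
                )
            row[f"{kind}_pct_mean"] = mean
            row[f"{kind}_pct_sd"] = sd
        rows.append(row)
    table = pd.DataFrame(rows)
    assert table.loc[0, "n_episodes"] == partition.n_total
    return table
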