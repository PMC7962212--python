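"""Windowed median-FHR trend and the associated statistical tests.

The trend for an outcome group is the median of *all* measured FHR samples
pooled across the group's episodes within each non-overlapping window
(mFHR(p)), with the 1st/3rd quartiles describing the spread. Windows
partition the last t0 seconds before birth into intervals of Δ seconds,
indexed p = (t + t0) / Δ.

Significance of the pre-birth shift is assessed with the Wilcoxon
signed-rank test on per-episode window medians (episodes present in both
windows), and between-group differences with the Kruskal–Wallis test on
per-episode window medians — heart-rate samples within an episode are
strongly autocorrelated, so the episode, not the sample, is the
independent observation unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import CleanedEpisode
from .episode import Window
from .errors import ConfigurationError, InsufficientDataError

#: Windows backed by fewer episodes than this are flagged low-support.
LOW_SUPPORT_EPISODES = 5


def window_partition(t0_s: float, delta_s: float) -> list[Window]:
    """Contiguous half-open windows covering [-t0, 0), indexed p = 0..t0/Δ-1."""
    if delta_s <= 0 or t0_s <= 0:
        raise ConfigurationError("t0_s and delta_s must be positive")
    n = t0_s / delta_s
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(
            f"delta_s={delta_s} does not divide t0_s={t0_s}"
        )
    n = int(round(n))
    return [
        Window(start_s=-t0_s + p * delta_s, duration_s=delta_s, index=p)
        for p in range(n)
    ]


@dataclass
class TrendResult:
    """Per-window pooled median/quartile trend for one group."""

    group: str
    delta_s: float
    t0_s: float
    table: pd.DataFrame
    # columns: p, start_s, mfhr, q1, q3, n_samples, n_episodes, low_support

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "group", self.group)
        return out


def _window_samples(cleaned: CleanedEpisode, window: Window) -> np.ndarray:
    t = cleaned.fhr_times()
    mask = window.contains(t) & cleaned.retained_mask()
    return cleaned.cleaned_fhr[mask]


def episode_window_median(cleaned: CleanedEpisode, window: Window) -> float:
    """Median of one episode's retained samples in a window (NaN if none)."""
    vals = _window_samples(cleaned, window)
    return float(np.median(vals)) if vals.size else float("nan")


def pooled_trend(
    cleaneds: Sequence[CleanedEpisode],
    windows: Sequence[Window],
    group: str = "all",
) -> TrendResult:
    """Median and quartiles of pooled measured samples per window.

    Samples from all episodes are concatenated before taking order
    statistics — episodes with more measured data weigh more, exactly as
    in the pooled-median definition of the trend. Windows with no measured
    samples are flagged absent (NaN), never zero.
    """
    if len(cleaneds) == 0:
        raise ConfigurationError("pooled_trend requires at least one episode")
    rows = []
    for w in windows:
        chunks = [
            v for c in cleaneds if (v := _window_samples(c, w)).size
        ]
        n_eps = len(chunks)
        if n_eps:
            vals = np.concatenate(chunks)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            n = vals.size
        else:
            q1 = med = q3 = float("nan")
            n = 0
        rows.append(
            {
                "p": w.index,
                "start_s": w.start_s,
                "mfhr": med,
                "q1": q1,
                "q3": q3,
                "n_samples": n,
                "n_episodes": n_eps,
                "low_support": n_eps < LOW_SUPPORT_EPISODES,
            }
        )
    table = pd.DataFrame(rows)
    present = table["n_samples"] > 0
    assert (
        (table.loc[present, "q1"] <= table.loc[present, "mfhr"])
        & (table.loc[present, "mfhr"] <= table.loc[present, "q3"])
    ).all(), "quartile ordering violated"
    delta = windows[0].duration_s if windows else float("nan")
    t0 = -windows[0].start_s if windows else float("nan")
    return TrendResult(group=group, delta_s=delta, t0_s=t0, table=table)


# -- statistical tests ------------------------------------------------------


@dataclass
class ShiftTestResult:
    statistic: float
    p_value: float
    n_pairs: int


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]


def shift_test_from_medians(
    medians_a: np.ndarray,
    medians_b: np.ndarray,
    method: str = "auto",
) -> ShiftTestResult:
    """Paired Wilcoxon signed-rank test on per-episode window medians.

    ``method`` is passed to scipy ("auto", "exact" or "approx" — the normal
    approximation to the signed-rank null).
    """
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired median arrays must have equal length")
    if a.size < 2:
        raise InsufficientDataError(
            f"signed-rank test needs >= 2 paired episodes, got {a.size}"
        )
    if np.allclose(a, b):
        # all differences zero: no detectable shift
        return ShiftTestResult(statistic=float("nan"), p_value=1.0, n_pairs=a.size)
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
    return ShiftTestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue), n_pairs=a.size
    )


def window_shift_test(
    cleaneds: Sequence[CleanedEpisode],
    window_a: Window,
    window_b: Window,
    method: str = "auto",
) -> ShiftTestResult:
    """Test whether the group's median FHR shifts between two windows.

    Each episode contributes its median FHR in each window; episodes
    lacking measured data in either window are excluded; the remaining
    per-episode pairs enter a Wilcoxon signed-rank test.
    """
    med_a = np.array([episode_window_median(c, window_a) for c in cleaneds])
    med_b = np.array([episode_window_median(c, window_b) for c in cleaneds])
    complete = np.isfinite(med_a) & np.isfinite(med_b)
    if complete.sum() < 2:
        raise InsufficientDataError(
            f"only {int(complete.sum())} episode(s) have data in both windows"
        )
    return shift_test_from_medians(med_a[complete], med_b[complete], method=method)


def between_group_test_from_medians(
    groups: Sequence[np.ndarray],
) -> GroupTestResult:
    """Kruskal–Wallis H test on per-episode window medians across groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InsufficientDataError("need at least two groups to compare")
    for g in arrays:
        if g.size < 2:
            raise InsufficientDataError(
                "each group needs >= 2 episodes with data in the window"
            )
    h, p = stats.kruskal(*arrays)
    return GroupTestResult(
        statistic=float(h),
        p_value=float(p),
        group_sizes=tuple(g.size for g in arrays),
    )


def between_group_test(
    groups: Mapping[str, Sequence[CleanedEpisode]],
    window: Window,
) -> GroupTestResult:
    """Compare outcome groups' per-episode window medians in one window."""
    arrays = []
    for label, cleaneds in groups.items():
        med = np.array([episode_window_median(c, window) for c in cleaneds])
        med = med[np.isfinite(med)]
        if med.size < 2:
            raise InsufficientDataError(
                f"group {label!r} has {med.size} episode(s) with data in the window"
            )
        arrays.append(med)
    return between_group_test_from_medians(arrays)
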