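"""Maternal/fetal heart-rate ambiguity.

A Doppler FHR sensor can lock onto the maternal pulse; when the measured
FHR lies within a small threshold of a simultaneously measured MHR the two
are *ambiguous* — indistinguishable without extra information. The
ambiguity statistic is the fraction of matched FHR/MHR sample pairs whose
absolute difference is at or below the threshold T_mhr (5 bpm by default,
following the clinical CTG literature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .cleaning import CleanedEpisode
from .episode import Episode, TICK_S
from .errors import UndefinedResultError

DEFAULT_T_MHR = 5.0
DEFAULT_MATCH_TOLERANCE_S = 0.25  # half a grid tick


@dataclass
class HeartRatePairSet:
    """Matched (t, fhr, mhr) sample pairs for one episode (or a pool)."""

    t: np.ndarray
    fhr: np.ndarray
    mhr: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.mhr = np.asarray(self.mhr, dtype=float)
        if not (self.t.shape == self.fhr.shape == self.mhr.shape):
            raise ValueError("pair arrays must have equal length")
        if self.fhr.size and not ((self.fhr > 0).all() and (self.mhr > 0).all()):
            raise ValueError("pairs require strictly positive measured rates")

    @property
    def n_pairs(self) -> int:
        return self.t.size

    def abs_diff(self) -> np.ndarray:
        return np.abs(self.fhr - self.mhr)


def match_pairs(
    episode: Union[Episode, CleanedEpisode],
    match_tolerance_s: float = DEFAULT_MATCH_TOLERANCE_S,
) -> HeartRatePairSet:
    """Pair each MHR point with the nearest measured FHR grid tick.

    The two channels are logged at different rates, so each intermittent
    MHR point is matched to the FHR tick closest in time, provided that
    tick is within ``match_tolerance_s``, carries a measured value and —
    when a cleaned episode is given — survived noise removal. Each FHR tick
    is used at most once (nearest MHR point wins); unmatched points are
    dropped.
    """
    if match_tolerance_s < 0:
        raise ValueError("match_tolerance_s must be non-negative")
    if isinstance(episode, CleanedEpisode):
        ep = episode.episode
        fhr = episode.cleaned_fhr
    else:
        ep = episode
        fhr = ep.fhr
    if ep.mhr_t.size == 0:
        return HeartRatePairSet(np.empty(0), np.empty(0), np.empty(0))
    ticks = np.round((ep.mhr_t - ep.fhr_start_s) / TICK_S).astype(int)
    tick_time = ep.fhr_start_s + ticks * TICK_S
    ok = (
        (ticks >= 0)
        & (ticks < fhr.size)
        & (np.abs(tick_time - ep.mhr_t) <= match_tolerance_s + 1e-9)
    )
    ok &= np.where(ok, np.isfinite(fhr[np.clip(ticks, 0, fhr.size - 1)]), False)
    # one pair per tick: keep the MHR point nearest its tick
    order = np.argsort(np.abs(tick_time - ep.mhr_t), kind="stable")
    chosen: dict[int, int] = {}
    for j in order:
        if ok[j] and ticks[j] not in chosen:
            chosen[ticks[j]] = j
    sel = np.array(sorted(chosen.values(), key=lambda j: ep.mhr_t[j]), dtype=int)
    if sel.size == 0:
        return HeartRatePairSet(np.empty(0), np.empty(0), np.empty(0))
    return HeartRatePairSet(
        t=ep.mhr_t[sel], fhr=fhr[ticks[sel]], mhr=ep.mhr_bpm[sel]
    )


def indicator(fhr_bpm: float, mhr_bpm: float, t_mhr: float = DEFAULT_T_MHR) -> int:
    """1 iff the pair is ambiguous: |fhr - mhr| <= T_mhr (boundary inclusive)."""
    if t_mhr < 0:
        raise ValueError("t_mhr must be non-negative")
    return int(abs(fhr_bpm - mhr_bpm) <= t_mhr)


def ambiguity_fraction(
    pairs: Union[HeartRatePairSet, Iterable[HeartRatePairSet]],
    t_mhr: float = DEFAULT_T_MHR,
) -> float:
    """Mean of the ambiguity indicator over a pair set (or a pool of sets).

    Pooling weights each episode by its pair count, matching a single
    cohort-wide rate. Raises :class:`UndefinedResultError` when no pairs
    exist — an empty pool has no defined ambiguity, which is not 0.
    """
    if t_mhr < 0:
        raise ValueError("t_mhr must be non-negative")
    if isinstance(pairs, HeartRatePairSet):
        pairs = [pairs]
    n = 0
    hits = 0
    for ps in pairs:
        n += ps.n_pairs
        hits += int((ps.abs_diff() <= t_mhr).sum())
    if n == 0:
        raise UndefinedResultError("ambiguity undefined: no matched pairs")
    return hits / n


def pooled_pair_set(pair_sets: Iterable[HeartRatePairSet]) -> HeartRatePairSet:
    """Concatenate per-episode pair sets (for histograms of |fhr - mhr|)."""
    sets = [p for p in pair_sets if p.n_pairs]
    if not sets:
        return HeartRatePairSet(np.empty(0), np.empty(0), np.empty(0))
    t = np.concatenate([p.t for p in sets])
    fhr = np.concatenate([p.fhr for p in sets])
    mhr = np.concatenate([p.mhr for p in sets])
    order = np.argsort(t, kind="stable")
    return HeartRatePairSet(t[order], fhr[order], mhr[order])
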