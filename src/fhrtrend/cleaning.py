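"""FhrClean-style preprocessing of Doppler FHR traces.

Doppler-derived FHR is noisy: short spikes far outside the physiological
range, longer stretches that are not plausibly fetal, and missing samples.
With no beat-level ground truth available, the cleaning step is deliberately
conservative: it removes only *short* (< 30 s) segments bounded by
physiologically impossible tick-to-tick changes, and leaves everything else
alone. Gap filling by replication exists solely to let the change detector
run over a gap-free signal; the filled values are never analysed — all
downstream statistics use measured samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .episode import Episode, TICK_S, Window
from .errors import EmptyEpisodeError, UndefinedResultError

#: Largest plausible change between adjacent 0.5 s ticks, in bpm. Real
#: beat-to-beat variation is an order of magnitude smaller; jumps beyond
#: this mark a sensor artefact (or a fetal->maternal lock change).
DEFAULT_JUMP_THRESHOLD_BPM = 25.0
DEFAULT_MAX_SEGMENT_S = 30.0


@dataclass
class CleaningParams:
    jump_threshold_bpm: float = DEFAULT_JUMP_THRESHOLD_BPM
    max_segment_s: float = DEFAULT_MAX_SEGMENT_S


@dataclass
class CleanedEpisode:
    """An episode plus the masks produced by cleaning.

    ``cleaned_fhr`` equals the original grid with removed samples set to
    missing; filled ticks are missing here too (fills only support
    detection). ``filled_mask`` marks ticks imputed during detection;
    ``removed_mask`` marks *measured* ticks removed as noise.
    """

    episode: Episode
    filled_mask: np.ndarray
    removed_mask: np.ndarray
    cleaned_fhr: np.ndarray

    @property
    def episode_id(self) -> str:
        return self.episode.episode_id

    @property
    def outcome(self) -> str:
        return self.episode.outcome

    def fhr_times(self) -> np.ndarray:
        return self.episode.fhr_times()

    def retained_mask(self) -> np.ndarray:
        """Measured samples that survived cleaning."""
        return np.isfinite(self.cleaned_fhr)


def fill_gaps(fhr_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing ticks by forward replication (backward at the head).

    Each missing tick takes the value of the nearest preceding measured
    sample; leading missing ticks take the first measured value. Returns
    the filled grid and a mask of imputed ticks.
    """
    x = np.asarray(fhr_grid, dtype=float)
    measured = np.isfinite(x)
    if not measured.any():
        raise EmptyEpisodeError("cannot fill a grid with no measured samples")
    filled_mask = ~measured
    # forward replication: index of most recent measured tick
    idx = np.where(measured, np.arange(x.size), -1)
    idx = np.maximum.accumulate(idx)
    first = np.flatnonzero(measured)[0]
    idx[idx < 0] = first  # backward replication at the head
    return x[idx], filled_mask


def detect_untrustworthy_segments(
    filled_grid: np.ndarray,
    jump_threshold_bpm: float = DEFAULT_JUMP_THRESHOLD_BPM,
    max_segment_s: float = DEFAULT_MAX_SEGMENT_S,
) -> list[tuple[int, int]]:
    """Find short excursions bounded by physiologically impossible jumps.

    A candidate segment starts at a tick whose absolute first difference
    exceeds ``jump_threshold_bpm``. It ends at the first later tick whose
    value returns to within the threshold of the pre-jump level, or at a
    second jump of opposite sign (the excursion snapping back). Candidates
    that never terminate within ``max_segment_s`` are *kept* as data — only
    temporary excursions are treated as noise. Overlapping or contiguous
    candidates are merged before the duration test.

    Returns disjoint half-open tick ranges ``(start, end)`` in increasing
    order, each strictly shorter than ``max_segment_s``.
    """
    x = np.asarray(filled_grid, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("filled grid must not contain missing ticks")
    if jump_threshold_bpm <= 0:
        raise ValueError("jump_threshold_bpm must be positive")
    thr = jump_threshold_bpm
    max_ticks = int(round(max_segment_s / TICK_S))
    d = np.diff(x)
    jump_at = np.flatnonzero(np.abs(d) > thr) + 1
    candidates: list[tuple[int, int]] = []
    pos = 0  # last tick known to be back at a trustworthy level
    for i in jump_at:
        if i <= pos:
            # inside a consumed excursion, or its own exit jump — the
            # signal at `pos` is already back at a trustworthy level
            continue
        pre = x[i - 1]  # last trusted level before the excursion
        chain_start = i
        cur = i
        while True:
            # one chain member: from `cur`, find a trusted return to the
            # pre-jump level, or the next opposite-signed jump (the
            # excursion snapping toward a new, still-untrusted level)
            sign = np.sign(x[cur] - pre)
            nxt = None
            returned = False
            stop = min(cur + max_ticks + 1, x.size)
            for k in range(cur + 1, stop):
                if abs(x[k] - pre) <= thr:
                    nxt, returned = k, True
                    break
                dk = x[k] - x[k - 1]
                if abs(dk) > thr and np.sign(dk) == -sign:
                    nxt, returned = k, False
                    break
            if nxt is None:
                # no boundary within the duration limit: the last member
                # never terminates, so it is retained; earlier members of
                # the chain (bounded by impossible jumps on both sides)
                # are removed
                if cur > chain_start:
                    candidates.append((chain_start, cur))
                pos = cur
                break
            if returned:
                if (nxt - chain_start) < max_ticks:
                    candidates.append((chain_start, nxt))
                pos = nxt
                break
            if (nxt - chain_start) >= max_ticks:
                # excursion lasted >= the duration limit before returning:
                # not "temporary", retain it wholesale
                pos = nxt - 1
                break
            cur = nxt  # chain on from the intermediate jump
    # candidates are disjoint and non-contiguous by construction (a
    # retained tick separates consecutive chains); merge defensively and
    # re-apply the duration rule
    merged: list[tuple[int, int]] = []
    for s, e in candidates:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if (e - s) < max_ticks]


def clean_episode(
    episode: Episode, params: CleaningParams | None = None
) -> CleanedEpisode:
    """Run gap filling + segment detection and mask out detected noise.

    Removal applies only to measured ticks — replicated fills inside a
    detected segment stay flagged as filled, never as removed — and the
    returned ``cleaned_fhr`` keeps every untouched measured sample
    bit-identical to the input.
    """
    params = params or CleaningParams()
    filled, filled_mask = fill_gaps(episode.fhr)
    segments = detect_untrustworthy_segments(
        filled, params.jump_threshold_bpm, params.max_segment_s
    )
    removed_mask = np.zeros(episode.n_ticks, dtype=bool)
    for s, e in segments:
        removed_mask[s:e] = True
    removed_mask &= episode.measured_mask()
    cleaned = episode.fhr.copy()
    cleaned[removed_mask] = np.nan
    out = CleanedEpisode(
        episode=episode,
        filled_mask=filled_mask,
        removed_mask=removed_mask,
        cleaned_fhr=cleaned,
    )
    _assert_removal_invariants(out, params)
    return out


def _assert_removal_invariants(c: CleanedEpisode, params: CleaningParams) -> None:
    max_ticks = int(round(params.max_segment_s / TICK_S))
    runs = _mask_runs(c.removed_mask)
    for s, e in runs:
        if (e - s) >= max_ticks:
            raise AssertionError(
                f"removed run of {(e - s) * TICK_S:.1f} s violates the "
                f"<{params.max_segment_s:.0f} s rule"
            )
    if (c.removed_mask & ~c.episode.measured_mask()).any():
        raise AssertionError("removed_mask set on an unmeasured tick")


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, end) ranges of True runs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def removed_fraction(cleaned: CleanedEpisode, window: Window) -> float:
    """Removed measured samples / all measured samples within ``window``."""
    t = cleaned.fhr_times()
    in_win = window.contains(t)
    measured = cleaned.episode.measured_mask() & in_win
    n = int(measured.sum())
    if n == 0:
        raise UndefinedResultError(
            f"no measured samples in window [{window.start_s}, {window.end_s}) "
            f"of episode {cleaned.episode_id!r}"
        )
    return int((cleaned.removed_mask & in_win).sum()) / n


def removed_fraction_profile(
    cleaneds: Iterable[CleanedEpisode], windows: Sequence[Window]
) -> np.ndarray:
    """Pooled removed fraction per window (NaN where nothing was measured).

    With 5-min windows over the last 150 min this reproduces the
    removed-noise-versus-time curve reported for the cleaning step.
    """
    removed = np.zeros(len(windows))
    measured = np.zeros(len(windows))
    for c in cleaneds:
        t = c.fhr_times()
        for j, w in enumerate(windows):
            in_win = w.contains(t)
            measured[j] += int((c.episode.measured_mask() & in_win).sum())
            removed[j] += int((c.removed_mask & in_win).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(measured > 0, removed / np.maximum(measured, 1), np.nan)
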