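"""Core data types and I/O for intrapartum heart-rate episodes.

An *episode* is one labour's recording session: a fetal heart rate (FHR)
series logged on a uniform 2 Hz grid, plus sparse intermittent maternal
heart rate (MHR) points, both time-referenced to the time of birth
(t = 0; negative seconds are before birth).

Conventions
-----------
* The FHR grid spacing is exactly 0.5 s; sample ``k`` of an episode lives
  at ``fhr_start_s + 0.5 * k``.
* Missing samples are ``NaN`` in memory and empty fields on disk; a logged
  value of 0 is treated as missing on read (presence is defined as a
  strictly positive rate).
* Analysis windows are half-open ``[start, start + duration)`` so that no
  grid tick belongs to two windows of a partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    CohortValidationError,
    EmptyEpisodeError,
    OutOfRangeError,
    UndefinedResultError,
)

TICK_S = 0.5
FS_HZ = 2.0

#: Recognised neonatal outcomes at 24 h after birth.
OUTCOMES = ("normal", "ncu", "vend", "fsb", "unlabeled")


@dataclass(frozen=True)
class Window:
    """Half-open time window ``[start_s, start_s + duration_s)``.

    ``index`` is the partition index p = (t + t0) / delta when the window
    comes from a regular partition of the last t0 seconds before birth.
    """

    start_s: float
    duration_s: float
    index: int = 0

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("window duration must be positive")

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask of times inside the half-open interval."""
        t = np.asarray(t)
        return (t >= self.start_s) & (t < self.end_s)


@dataclass
class Episode:
    """One labour's FHR/MHR recordings, time-referenced to birth.

    Attributes
    ----------
    episode_id : str
        Opaque identifier.
    fhr : ndarray of float
        FHR in bpm on the uniform 2 Hz grid; NaN marks missing samples.
    fhr_start_s : float
        Time of the first grid tick, in seconds relative to birth
        (negative = before birth).
    mhr_t, mhr_bpm : ndarray
        Sparse, strictly increasing MHR sample times (s relative to birth)
        and values (bpm). May be empty.
    outcome : str
        One of ``OUTCOMES``.
    drift_shift_s : float
        Total time-of-birth correction already applied (seconds); see
        :func:`correct_clock_drift`.
    """

    episode_id: str
    fhr: np.ndarray
    fhr_start_s: float
    mhr_t: np.ndarray = field(default_factory=lambda: np.empty(0))
    mhr_bpm: np.ndarray = field(default_factory=lambda: np.empty(0))
    outcome: str = "unlabeled"
    drift_shift_s: float = 0.0

    def __post_init__(self) -> None:
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.mhr_t = np.asarray(self.mhr_t, dtype=float)
        self.mhr_bpm = np.asarray(self.mhr_bpm, dtype=float)
        if self.outcome not in OUTCOMES:
            raise CohortValidationError(
                f"episode {self.episode_id!r}: unknown outcome {self.outcome!r}"
            )
        if self.mhr_t.shape != self.mhr_bpm.shape:
            raise CohortValidationError(
                f"episode {self.episode_id!r}: MHR time/value length mismatch"
            )
        finite = self.fhr[np.isfinite(self.fhr)]
        if finite.size and (finite <= 0).any():
            raise CohortValidationError(
                f"episode {self.episode_id!r}: non-positive FHR values"
            )
        if self.mhr_bpm.size and not (self.mhr_bpm > 0).all():
            raise CohortValidationError(
                f"episode {self.episode_id!r}: non-positive MHR values"
            )
        if self.mhr_t.size > 1 and not (np.diff(self.mhr_t) > 0).all():
            raise CohortValidationError(
                f"episode {self.episode_id!r}: MHR times not strictly increasing"
            )

    @property
    def n_ticks(self) -> int:
        return self.fhr.size

    def fhr_times(self) -> np.ndarray:
        """Grid tick times in seconds relative to birth."""
        return self.fhr_start_s + TICK_S * np.arange(self.n_ticks)

    def measured_mask(self) -> np.ndarray:
        return np.isfinite(self.fhr)

    def recorded_span(self) -> tuple[float, float]:
        """(first, last) measured sample times; raises if all missing."""
        idx = np.flatnonzero(self.measured_mask())
        if idx.size == 0:
            raise EmptyEpisodeError(
                f"episode {self.episode_id!r} has no measured FHR samples"
            )
        t = self.fhr_times()
        return float(t[idx[0]]), float(t[idx[-1]])


def sample_index(t: float, t0: float) -> int:
    """Map a time to its 0-based position on the 2 Hz grid.

    The grid origin is ``t0`` seconds before birth; ``n = 2 (t + t0)``.
    ``t`` must be grid-aligned (a multiple of 0.5 s from the origin).
    """
    if t < -t0:
        raise OutOfRangeError(f"t={t} precedes grid origin -t0={-t0}")
    n = FS_HZ * (t + t0)
    n_int = round(n)
    if not math.isclose(n, n_int, abs_tol=1e-6):
        raise ValueError(f"t={t} is not aligned to the 0.5 s grid")
    return int(n_int)


def index_time(n: int, t0: float) -> float:
    """Inverse of :func:`sample_index`: ``t = n/2 - t0``."""
    if n < 0:
        raise OutOfRangeError("sample index must be non-negative")
    return n / FS_HZ - t0


def correct_clock_drift(episode: Episode) -> Episode:
    """Correct clock drift by re-referencing birth to the last measured FHR.

    The monitor clock can drift by up to tens of minutes, so some episodes
    log FHR samples *after* the recorded time of birth. Those episodes are
    corrected by shifting all times so the last measured FHR sample sits at
    t = 0; the applied shift is recorded in ``drift_shift_s``. Episodes
    whose last measured sample is already at or before birth are returned
    unchanged. Idempotent.
    """
    _, last = episode.recorded_span()
    if last <= 0:
        return episode
    return replace(
        episode,
        fhr_start_s=episode.fhr_start_s - last,
        mhr_t=episode.mhr_t - last,
        drift_shift_s=episode.drift_shift_s + last,
    )


def missing_fraction(episode, window: Window) -> float:
    """Fraction of grid ticks that are missing within ``window``.

    The denominator is the number of grid ticks inside the intersection of
    the window with the episode's recorded span (first to last measured
    sample). Ticks imputed by gap filling count as missing (they were not
    measured); ticks removed as noise count as measured. Accepts an
    :class:`Episode` or a cleaned episode wrapper exposing ``.episode``.

    Raises :class:`UndefinedResultError` when the window does not overlap
    the recorded span.
    """
    ep: Episode = getattr(episode, "episode", episode)
    first, last = ep.recorded_span()
    lo = max(window.start_s, first)
    hi = min(window.end_s, last + TICK_S)  # span is inclusive of the last tick
    t = ep.fhr_times()
    in_win = (t >= lo) & (t < hi)
    n = int(in_win.sum())
    if n == 0:
        raise UndefinedResultError(
            f"window [{window.start_s}, {window.end_s}) does not overlap the "
            f"recorded span of episode {ep.episode_id!r}"
        )
    n_missing = int((~np.isfinite(ep.fhr[in_win])).sum())
    return n_missing / n


# ---------------------------------------------------------------------------
# Cohort I/O: plain CSV, UTF-8, '.' decimal separator.
#   FHR file:  time_s,fhr_bpm   (empty fhr_bpm = missing; 0 also = missing)
#   MHR file:  time_s,mhr_bpm   (sparse)
#   Manifest:  episode_id,outcome,fhr_file,mhr_file
# ---------------------------------------------------------------------------


def _read_fhr_file(path: Path, episode_id: str) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "fhr_bpm"]:
        raise CohortValidationError(
            f"episode {episode_id!r}: FHR file {path} has columns "
            f"{list(df.columns)}, expected ['time_s', 'fhr_bpm']"
        )
    t = df["time_s"].to_numpy(dtype=float)
    v = df["fhr_bpm"].to_numpy(dtype=float)
    if t.size == 0:
        raise CohortValidationError(f"episode {episode_id!r}: empty FHR file")
    dt = np.diff(t)
    if t.size > 1 and not np.allclose(dt, TICK_S, atol=1e-6):
        bad = int(np.argmax(~np.isclose(dt, TICK_S, atol=1e-6))) + 2
        raise CohortValidationError(
            f"episode {episode_id!r}: FHR times not on a 0.5 s grid "
            f"(row {bad} of {path})"
        )
    v = np.where(v == 0, np.nan, v)  # 0 = absent measurement
    return v, float(t[0])


def _read_mhr_file(path: Path, episode_id: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "mhr_bpm"]:
        raise CohortValidationError(
            f"episode {episode_id!r}: MHR file {path} has columns "
            f"{list(df.columns)}, expected ['time_s', 'mhr_bpm']"
        )
    df = df.dropna()
    return df["time_s"].to_numpy(dtype=float), df["mhr_bpm"].to_numpy(dtype=float)


def normalize_outcome(raw: object) -> str:
    """Case-insensitive outcome mapping; unrecognised strings -> unlabeled."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return "unlabeled"
    s = str(raw).strip().lower()
    return s if s in OUTCOMES else "unlabeled"


def read_cohort(manifest_path, data_dir=None) -> list[Episode]:
    """Read a cohort from a manifest CSV plus per-episode FHR/MHR CSVs.

    Relative file paths in the manifest are resolved against ``data_dir``
    (default: the manifest's directory). Unrecognised outcome strings map
    to ``unlabeled``; a missing data file raises ``FileNotFoundError``
    naming the episode; duplicate episode ids raise
    :class:`CohortValidationError`.
    """
    manifest_path = Path(manifest_path)
    base = Path(data_dir) if data_dir is not None else manifest_path.parent
    mf = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    required = ["episode_id", "outcome", "fhr_file", "mhr_file"]
    if list(mf.columns) != required:
        raise CohortValidationError(
            f"manifest columns {list(mf.columns)}, expected {required}"
        )
    dupes = mf["episode_id"][mf["episode_id"].duplicated()]
    if len(dupes):
        raise CohortValidationError(
            f"duplicate episode_id(s) in manifest: {sorted(set(dupes))}"
        )
    episodes = []
    for row in mf.itertuples(index=False):
        eid = row.episode_id
        fhr_path = base / row.fhr_file
        if not fhr_path.is_file():
            raise FileNotFoundError(
                f"episode {eid!r}: FHR file not found: {fhr_path}"
            )
        try:
            fhr, start = _read_fhr_file(fhr_path, eid)
        except ValueError as exc:  # malformed numerics from pandas
            raise CohortValidationError(f"episode {eid!r}: {exc}") from exc
        mhr_t = np.empty(0)
        mhr_v = np.empty(0)
        if row.mhr_file:
            mhr_path = base / row.mhr_file
            if not mhr_path.is_file():
                raise FileNotFoundError(
                    f"episode {eid!r}: MHR file not found: {mhr_path}"
                )
            mhr_t, mhr_v = _read_mhr_file(mhr_path, eid)
        episodes.append(
            Episode(
                episode_id=eid,
                fhr=fhr,
                fhr_start_s=start,
                mhr_t=mhr_t,
                mhr_bpm=mhr_v,
                outcome=normalize_outcome(row.outcome),
            )
        )
    return episodes


def write_cohort(episodes: Iterable[Episode], out_dir) -> Path:
    """Write episodes in the standard manifest/CSV layout; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ep in episodes:
        fhr_name = f"{ep.episode_id}_fhr.csv"
        pd.DataFrame(
            {"time_s": ep.fhr_times(), "fhr_bpm": ep.fhr}
        ).to_csv(out_dir / fhr_name, index=False)
        mhr_name = ""
        if ep.mhr_t.size:
            mhr_name = f"{ep.episode_id}_mhr.csv"
            pd.DataFrame(
                {"time_s": ep.mhr_t, "mhr_bpm": ep.mhr_bpm}
            ).to_csv(out_dir / mhr_name, index=False)
        rows.append((ep.episode_id, ep.outcome, fhr_name, mhr_name))
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(
        rows, columns=["episode_id", "outcome", "fhr_file", "mhr_file"]
    ).to_csv(manifest, index=False)
    return manifest
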