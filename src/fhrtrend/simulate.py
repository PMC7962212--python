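"""Seeded generator of Moyo-like intrapartum heart-rate episodes.

The real cohort this package was designed around is access-restricted, so
this module synthesises episodes with the same observable structure —
2 Hz FHR with heavy dropout, short impossible-spike noise, intermittent
maternal heart rate, occasional maternal pickup on the fetal channel, and
group-specific pre-birth baseline trends — together with full per-episode
ground truth, so that every pipeline stage can be tested against known
inputs.

What the generator emulates (defaults):

* group baseline profiles with a pre-birth drop: the pooled 10-min-window
  median falls from ~134 bpm at 150 min before birth to ~119 bpm in the
  last window, with the perinatal-mortality profile dropping earlier and
  deeper;
* within-episode variability: stationary AR(1) wander whose sd ramps up
  toward birth (labour intensifies), plus episode-level baseline offsets
  and smooth decelerations;
* ~30% missing data in dropout runs, ~1.8% removable spike noise outside
  the 110–160 bpm band in runs shorter than 30 s;
* intermittent MHR blocks covering ~0.4% of the episode in ~30% of
  episodes, with a configurable fraction of blocks where the fetal channel
  records the maternal series (ambiguity);
* optional clock drift up to ±30 min.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .episode import Episode, TICK_S, Window, write_cohort
from .errors import ConfigurationError

#: Default baseline profiles: knots of (minutes before birth, bpm),
#: linearly interpolated, clamped outside the knot span. The normal/NCU
#: shapes share a mild mid-labour hump (the pooled mode sits near 137 bpm
#: at 90–60 min) and a steep final drop; the perinatal profile starts its
#: large decline ~40 min before birth.
DEFAULT_PROFILES: dict[str, tuple[tuple[float, float], ...]] = {
    "normal": (
        (150.0, 134.0), (120.0, 136.0), (90.0, 137.0), (60.0, 136.5),
        (40.0, 135.0), (20.0, 131.0), (10.0, 126.0), (0.0, 112.0),
    ),
    "ncu": (
        (150.0, 133.0), (120.0, 135.0), (90.0, 136.0), (60.0, 135.5),
        (40.0, 134.0), (20.0, 129.0), (10.0, 124.0), (0.0, 110.0),
    ),
    "perinatal": (
        (150.0, 133.0), (120.0, 134.0), (90.0, 134.0), (60.0, 133.0),
        (40.0, 130.0), (20.0, 118.0), (10.0, 112.0), (0.0, 98.0),
    ),
}

_GROUP_PROFILE = {
    "normal": "normal",
    "ncu": "ncu",
    "vend": "perinatal",
    "fsb": "perinatal",
    "unlabeled": "normal",
}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort. All rates/fractions are
    per-episode means unless noted; the rng seed fully determines output."""

    # cohort composition
    n_normal: int = 200
    n_ncu: int = 20
    n_vend: int = 6
    n_fsb: int = 4
    n_unlabeled: int = 0

    # timing (seconds relative to birth)
    t0_s: float = 9000.0
    span_start_min_s: float = -36000.0   # earliest recording start (-10 h)
    span_start_max_s: float = -10800.0   # latest recording start (-3 h)
    end_before_birth_fraction: float = 0.3
    early_end_max_s: float = 1800.0      # early enders stop within 30 min of birth

    # baseline and variability
    profiles: dict[str, tuple[tuple[float, float], ...]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    episode_offset_sd_bpm: float = 8.0
    noise_sd_bpm: float = 6.0
    noise_ar1: float = 0.9
    variability_birth_factor: float = 2.0  # sd multiplier reached at t = 0

    # decelerations (smooth, physiological — must survive cleaning)
    decel_rate_per_hour: float = 2.0
    decel_depth_bpm: float = 15.0
    decel_duration_s: float = 60.0

    # dropout
    dropout_mean: float = 0.30
    dropout_sd: float = 0.15
    dropout_run_mean_s: float = 45.0

    # spike noise (removable: short, far outside the physiological band)
    spike_fraction: float = 0.018
    spike_amp_min_bpm: float = 50.0
    spike_amp_max_bpm: float = 80.0
    spike_run_mean_s: float = 5.0
    spike_run_max_s: float = 25.0

    # maternal heart rate
    mhr_episode_fraction: float = 0.305
    mhr_coverage_mean: float = 0.004
    mhr_coverage_sd: float = 0.0025
    mhr_block_s: float = 60.0
    mhr_rate_hz: float = 1.0
    mhr_baseline_mean_bpm: float = 85.0
    mhr_baseline_sd_bpm: float = 10.0
    mhr_wander_sd_bpm: float = 3.0
    #: fraction of MHR-covered time where the FHR channel records the MHR.
    #: Realised as whole blocks (>= 30 s) so noise removal keeps them.
    ambiguity_fraction: float = 0.045

    # clock drift
    drift_max_s: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "end_before_birth_fraction", "dropout_mean", "spike_fraction",
            "mhr_episode_fraction", "mhr_coverage_mean", "ambiguity_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must be in [0, 1]")
        if self.spike_run_max_s >= 30.0:
            raise ConfigurationError(
                "spike_run_max_s must stay below the 30 s removal rule"
            )
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ConfigurationError("noise_ar1 must be in [0, 1)")
        if self.drift_max_s > 1800.0:
            raise ConfigurationError("drift_max_s exceeds the 30 min bound")
        if self.span_start_min_s > self.span_start_max_s:
            raise ConfigurationError("span_start_min_s must be <= span_start_max_s")

    def group_sizes(self) -> dict[str, int]:
        return {
            "normal": self.n_normal,
            "ncu": self.n_ncu,
            "vend": self.n_vend,
            "fsb": self.n_fsb,
            "unlabeled": self.n_unlabeled,
        }


@dataclass
class GroundTruth:
    """Per-episode generator internals, for test oracles only."""

    episode_id: str
    baseline: np.ndarray          # profile + episode offset, per tick
    offset_bpm: float
    missing_mask: np.ndarray      # True where dropout removed the sample
    dropout_target: float
    spike_segments: list[tuple[int, int]]   # half-open tick ranges
    ambiguity_intervals: list[tuple[float, float]]  # seconds rel. to birth
    drift_s: float


def profile_value(
    knots: Sequence[tuple[float, float]], t_s: np.ndarray
) -> np.ndarray:
    """Evaluate a (minutes-before-birth, bpm) knot profile at times (s)."""
    pts = sorted(((-60.0 * m, bpm) for m, bpm in knots))
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return np.interp(np.asarray(t_s, dtype=float), xs, ys)


def profile_window_median(
    config: GeneratorConfig, group: str, window: Window
) -> float:
    """Median of the generating profile over a window's tick grid.

    Independent closed-form-ish oracle for trend-recovery tests: with
    mean-zero offsets and noise, the pooled window median should recover
    this value.
    """
    knots = config.profiles[_GROUP_PROFILE[group]]
    t = np.arange(window.start_s, window.end_s - 1e-9, TICK_S)
    return float(np.median(profile_value(knots, t)))


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance AR(1) series of length n."""
    burn = 200
    e = rng.standard_normal(n + burn) * np.sqrt(max(1.0 - rho**2, 1e-12))
    x = lfilter([1.0], [1.0, -rho], e)
    return x[burn:]


def _alternating_runs(
    n: int, p_missing: float, gap_mean_ticks: float, rng: np.random.Generator
) -> np.ndarray:
    """Missing mask from alternating exponential measured/gap runs."""
    meas_mean = gap_mean_ticks * (1.0 - p_missing) / max(p_missing, 1e-9)
    mask = np.zeros(n, dtype=bool)
    pos = 0
    state_missing = rng.random() < p_missing
    while pos < n:
        mean = gap_mean_ticks if state_missing else meas_mean
        run = max(1, int(round(rng.exponential(mean))))
        if state_missing:
            mask[pos : pos + run] = True
        pos += run
        state_missing = not state_missing
    return mask


def _tick_floor(x: float) -> float:
    return np.floor(x / TICK_S) * TICK_S


def generate_episode(
    config: GeneratorConfig,
    group: str,
    rng: np.random.Generator,
    episode_id: Optional[str] = None,
) -> tuple[Episode, GroundTruth]:
    """Generate one episode plus its ground truth.

    The signal is assembled in layers: baseline profile + episode offset,
    AR(1) wander with a variability ramp toward birth, smooth
    decelerations, optional maternal-pickup (ambiguity) blocks, dropout
    runs, and finally spike noise on measured ticks; clock drift shifts
    all logged times last.
    """
    if group not in _GROUP_PROFILE:
        raise ConfigurationError(f"unknown group {group!r}")
    episode_id = episode_id or f"{group}-ep"
    knots = config.profiles[_GROUP_PROFILE[group]]

    # --- recording span on the 0.5 s grid
    start_s = _tick_floor(
        rng.uniform(config.span_start_min_s, config.span_start_max_s)
    )
    end_s = 0.0
    if rng.random() < config.end_before_birth_fraction:
        end_s = _tick_floor(rng.uniform(-config.early_end_max_s, 0.0))
    n = int(round((end_s - start_s) / TICK_S))
    t = start_s + TICK_S * np.arange(n)

    # --- baseline + variability + decelerations
    offset = rng.normal(0.0, config.episode_offset_sd_bpm)
    baseline = profile_value(knots, t) + offset
    ramp = 1.0 + (config.variability_birth_factor - 1.0) * np.clip(
        (t + config.t0_s) / config.t0_s, 0.0, 1.0
    )
    noise = _ar1(n, config.noise_ar1, rng) * config.noise_sd_bpm * ramp
    fhr = baseline + noise
    dur_h = (end_s - start_s) / 3600.0
    for _ in range(rng.poisson(config.decel_rate_per_hour * dur_h)):
        center = rng.uniform(start_s, end_s)
        depth = config.decel_depth_bpm * rng.uniform(0.7, 1.3)
        dur = config.decel_duration_s * rng.uniform(0.7, 1.3)
        local = np.abs(t - center) < dur / 2
        fhr[local] -= depth * np.cos(np.pi * (t[local] - center) / dur) ** 2

    # --- maternal channel + ambiguity blocks
    mhr_t = np.empty(0)
    mhr_v = np.empty(0)
    amb_intervals: list[tuple[float, float]] = []
    block_ticks = int(round(config.mhr_block_s / TICK_S))
    if rng.random() < config.mhr_episode_fraction and n > 2 * block_ticks:
        coverage = np.clip(
            rng.normal(config.mhr_coverage_mean, config.mhr_coverage_sd),
            0.0005, 0.03,
        )
        n_blocks = max(1, int(round(coverage * n / block_ticks)))
        starts: list[int] = []
        for _ in range(20 * n_blocks):
            if len(starts) == n_blocks:
                break
            s = int(rng.integers(1, n - block_ticks - 1))
            if all(abs(s - s2) >= block_ticks + 4 for s2 in starts):
                starts.append(s)
        m_base = rng.normal(
            config.mhr_baseline_mean_bpm, config.mhr_baseline_sd_bpm
        )
        step = max(1, int(round(1.0 / (config.mhr_rate_hz * TICK_S))))
        mt_chunks, mv_chunks = [], []
        for s in sorted(starts):
            ticks = np.arange(s, s + block_ticks, step)
            wander = _ar1(ticks.size, 0.95, rng) * config.mhr_wander_sd_bpm
            vals = np.maximum(m_base + wander, 40.0)
            mt_chunks.append(t[ticks])
            mv_chunks.append(vals)
            if rng.random() < config.ambiguity_fraction:
                # the fetal channel locks onto the maternal pulse for the
                # whole block: FHR ticks take the interpolated MHR series
                seg = slice(s, s + block_ticks)
                fhr[seg] = np.interp(t[seg], t[ticks], vals)
                amb_intervals.append((float(t[s]), float(t[s + block_ticks - 1])))
        mhr_t = np.concatenate(mt_chunks)
        mhr_v = np.concatenate(mv_chunks)

    # --- dropout
    p_missing = float(
        np.clip(rng.normal(config.dropout_mean, config.dropout_sd), 0.02, 0.85)
    )
    gap_mean_ticks = config.dropout_run_mean_s / TICK_S
    missing = _alternating_runs(n, p_missing, gap_mean_ticks, rng)
    # keep at least one measured sample, with the last one at the very end
    # for episodes recorded through birth (anchors the episode span)
    if missing.all():
        missing[n - 1] = False

    # --- spike noise on measured ticks, clear of ambiguity blocks
    spike_segments: list[tuple[int, int]] = []
    if config.spike_fraction > 0:
        measured_idx = np.flatnonzero(~missing)
        target = int(round(config.spike_fraction * measured_idx.size))
        amb_ticks = np.zeros(n, dtype=bool)
        for a, b in amb_intervals:
            amb_ticks[int((a - start_s) / TICK_S) : int((b - start_s) / TICK_S) + 1] = True
        run_mean = config.spike_run_mean_s / TICK_S
        run_max = int(config.spike_run_max_s / TICK_S)
        injected = 0
        attempts = 0
        occupied = np.zeros(n, dtype=bool)
        while injected < target - 1 and attempts < 50 * max(target, 1):
            attempts += 1
            # clip the last run so realized spike load lands on the target
            L = int(np.clip(
                round(rng.exponential(run_mean)), 2, min(run_max, target - injected)
            ))
            if L < 2:
                break
            s = int(rng.integers(2, n - L - 2))
            span = slice(s - 2, s + L + 2)  # need clean measured margins
            if missing[span].any() or occupied[span].any() or amb_ticks[span].any():
                continue
            amp = rng.uniform(config.spike_amp_min_bpm, config.spike_amp_max_bpm)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            vals = fhr[s : s + L] + sign * amp + rng.normal(0.0, 1.0, L)
            fhr[s : s + L] = np.maximum(vals, 35.0)
            occupied[s : s + L] = True
            spike_segments.append((s, s + L))
            injected += L
        spike_segments.sort()

    fhr_out = fhr.copy()
    fhr_out[missing] = np.nan
    fhr_out = np.maximum(fhr_out, 35.0)

    # --- clock drift in the logged timestamps
    drift = 0.0
    if config.drift_max_s > 0:
        drift = _tick_floor(rng.uniform(-config.drift_max_s, config.drift_max_s))

    episode = Episode(
        episode_id=episode_id,
        fhr=fhr_out,
        fhr_start_s=start_s + drift,
        mhr_t=mhr_t + drift if mhr_t.size else mhr_t,
        mhr_bpm=mhr_v,
        outcome=group,
    )
    truth = GroundTruth(
        episode_id=episode_id,
        baseline=baseline,
        offset_bpm=float(offset),
        missing_mask=missing,
        dropout_target=p_missing,
        spike_segments=spike_segments,
        ambiguity_intervals=amb_intervals,
        drift_s=float(drift),
    )
    return episode, truth


def generate_cohort(
    config: GeneratorConfig,
    seed: int,
    out_dir=None,
    force: bool = False,
) -> list[tuple[Episode, GroundTruth]]:
    """Generate a full cohort; optionally write the on-disk layout.

    The cohort is a deterministic function of (config, seed): each episode
    draws from its own child of the seed sequence, in a fixed order. When
    ``out_dir`` is given, the standard manifest/CSV layout plus a
    ``truth.csv`` sidecar (never read by the pipeline) is written;
    a non-empty target directory is refused unless ``force``.
    """
    sizes = config.group_sizes()
    total = sum(sizes.values())
    children = np.random.SeedSequence(seed).spawn(total)
    out: list[tuple[Episode, GroundTruth]] = []
    i = 0
    for group in ("normal", "ncu", "vend", "fsb", "unlabeled"):
        for k in range(sizes[group]):
            rng = np.random.default_rng(children[i])
            out.append(
                generate_episode(config, group, rng, episode_id=f"{group}{k:04d}")
            )
            i += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not force:
            raise ConfigurationError(
                f"output directory {out_dir} is not empty (use force to overwrite)"
            )
        write_cohort([ep for ep, _ in out], out_dir)
        truth_rows = [
            {
                "episode_id": tr.episode_id,
                "offset_bpm": tr.offset_bpm,
                "dropout_target": tr.dropout_target,
                "realized_missing": float(tr.missing_mask.mean()),
                "n_spike_segments": len(tr.spike_segments),
                "spike_ticks": sum(e - s for s, e in tr.spike_segments),
                "n_ambiguity_intervals": len(tr.ambiguity_intervals),
                "drift_s": tr.drift_s,
            }
            for _, tr in out
        ]
        pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    return out
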