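"""Windowed probability-density estimation of the FHR by normalized histogram.

For each time window, measured FHR samples from all episodes of a group
are binned at 1 bpm resolution over the physiological support 50–200 bpm
(bin l covers [l-0.5, l+0.5)), histograms are summed across episodes and
normalized by the total count N. The variance of the implied heart-rate
distribution, sigma^2_PDF, summarises the spread; stacking the per-window
densities gives the pdf-over-time surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cleaning import CleanedEpisode
from .episode import Window
from .errors import UndefinedResultError

BIN_MIN_BPM = 50
BIN_MAX_BPM = 200
#: Integer bin centers, 50..200 bpm inclusive.
BIN_CENTERS = np.arange(BIN_MIN_BPM, BIN_MAX_BPM + 1)


def episode_histogram(
    cleaned: CleanedEpisode, window: Window
) -> tuple[np.ndarray, int]:
    """Counts of one episode's measured samples per 1-bpm bin in a window.

    Returns ``(counts, overflow)`` where ``overflow`` tallies samples
    outside [49.5, 200.5) bpm, which are excluded from the bins.
    """
    t = cleaned.fhr_times()
    vals = cleaned.cleaned_fhr[window.contains(t) & cleaned.retained_mask()]
    bins = np.floor(vals + 0.5).astype(int)  # bin l covers [l-0.5, l+0.5)
    in_range = (bins >= BIN_MIN_BPM) & (bins <= BIN_MAX_BPM)
    counts = np.bincount(
        bins[in_range] - BIN_MIN_BPM, minlength=BIN_CENTERS.size
    )
    return counts, int((~in_range).sum())


@dataclass
class WindowedPdf:
    """Normalized FHR histogram for one group and one window."""

    group: str
    window: Window
    counts: np.ndarray
    density: np.ndarray
    n_total: int
    overflow: int
    variance: float
    n_episodes: int

    def __post_init__(self) -> None:
        if self.n_total > 0:
            s = float(self.density.sum())
            assert abs(s - 1.0) < 1e-9, f"density sums to {s}"
        assert self.variance >= 0

    def peak_bin(self) -> int:
        """Bin center (bpm) of the density mode."""
        return int(BIN_CENTERS[int(np.argmax(self.density))])

    def mean(self) -> float:
        return float(np.dot(self.density, BIN_CENTERS))


def pdf_variance(density: np.ndarray) -> float:
    """Variance of the bin-center random variable under the density."""
    mu = float(np.dot(density, BIN_CENTERS))
    return float(np.dot(density, (BIN_CENTERS - mu) ** 2))


def group_pdf(
    cleaneds: Sequence[CleanedEpisode],
    window: Window,
    group: str = "all",
) -> WindowedPdf:
    """Sum episode histograms over a group and normalize by the total count.

    Raises :class:`UndefinedResultError` when no measured in-range sample
    falls in the window (a pdf cannot be normalized from zero counts).
    """
    counts = np.zeros(BIN_CENTERS.size, dtype=np.int64)
    overflow = 0
    n_episodes = 0
    for c in cleaneds:
        h, ov = episode_histogram(c, window)
        if h.sum() or ov:
            n_episodes += 1
        counts += h
        overflow += ov
    n = int(counts.sum())
    if n == 0:
        raise UndefinedResultError(
            f"no measured samples in [{window.start_s}, {window.end_s})"
        )
    density = counts / n
    return WindowedPdf(
        group=group,
        window=window,
        counts=counts,
        density=density,
        n_total=n,
        overflow=overflow,
        variance=pdf_variance(density),
        n_episodes=n_episodes,
    )


def episodes_with_data(
    cleaneds: Sequence[CleanedEpisode], window: Window
) -> int:
    """Number of episodes with any measured FHR in the window."""
    n = 0
    for c in cleaneds:
        t = c.fhr_times()
        if (window.contains(t) & c.retained_mask()).any():
            n += 1
    return n


def pdf_surface(
    cleaneds: Sequence[CleanedEpisode],
    windows: Sequence[Window],
    group: str = "all",
) -> tuple[list[Optional[WindowedPdf]], np.ndarray]:
    """One normalized histogram per window plus per-window episode counts.

    Windows with no measured data yield ``None`` (absent, not a zero pdf).
    The episode-count series is the falling support curve plotted alongside
    the surface.
    """
    pdfs: list[Optional[WindowedPdf]] = []
    counts = np.zeros(len(windows), dtype=int)
    for j, w in enumerate(windows):
        counts[j] = episodes_with_data(cleaneds, w)
        try:
            pdfs.append(group_pdf(cleaneds, w, group=group))
        except UndefinedResultError:
            pdfs.append(None)
    return pdfs, counts


def surface_long_table(
    pdfs: Sequence[Optional[WindowedPdf]],
    episode_counts: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format export of a pdf surface for plotting/CSV.

    Returns ``(long, sidecar)``: the long table has one row per
    (window, bin) with the density; the sidecar has one row per window
    with N, episode count and variance.
    """
    long_rows = []
    side_rows = []
    for j, pdf in enumerate(pdfs):
        if pdf is None:
            continue
        start_min = pdf.window.start_s / 60.0
        for bpm, dens in zip(BIN_CENTERS, pdf.density):
            long_rows.append(
                {
                    "group": pdf.group,
                    "window_start_min": start_min,
                    "bin_bpm": int(bpm),
                    "density": dens,
                }
            )
        side_rows.append(
            {
                "group": pdf.group,
                "window_start_min": start_min,
                "n_total": pdf.n_total,
                "n_episodes": int(episode_counts[j]),
                "variance": pdf.variance,
                "overflow": pdf.overflow,
            }
        )
    return pd.DataFrame(long_rows), pd.DataFrame(side_rows)
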