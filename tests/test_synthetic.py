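import filecmp
from pathlib import Path

import numpy as np
import pytest

from fhrtrend.episode import TICK_S, read_cohort
from fhrtrend.errors import ConfigurationError
from fhrtrend.simulate import (
    GeneratorConfig,
    generate_cohort,
    generate_episode,
    profile_value,
    profile_window_median,
)


def degenerate_config(**kw) -> GeneratorConfig:
    """All stochastic layers switched off: FHR == interpolated profile."""
    base = dict(
        n_normal=1, n_ncu=0, n_vend=0, n_fsb=0,
        episode_offset_sd_bpm=0.0,
        noise_sd_bpm=0.0,
        decel_rate_per_hour=0.0,
        dropout_mean=0.02, dropout_sd=0.0,  # min dropout; see test
        spike_fraction=0.0,
        mhr_episode_fraction=0.0,
        end_before_birth_fraction=0.0,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerateEpisode:
    def test_degenerate_generator_equals_profile(self):
        cfg = degenerate_config()
        rng = np.random.default_rng(0)
        ep, truth = generate_episode(cfg, "normal", rng)
        t = ep.fhr_times()
        expected = profile_value(cfg.profiles["normal"], t)
        measured = ep.measured_mask()
        assert np.allclose(ep.fhr[measured], expected[measured])
        assert np.allclose(truth.baseline, expected)

    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(n_normal=3, n_ncu=1, n_vend=1, n_fsb=0)
        a = generate_cohort(cfg, seed=99)
        b = generate_cohort(cfg, seed=99)
        for (ea, ta), (eb, tb) in zip(a, b):
            assert ea.episode_id == eb.episode_id
            assert np.array_equal(ea.fhr, eb.fhr, equal_nan=True)
            assert ea.fhr_start_s == eb.fhr_start_s
            assert np.array_equal(ea.mhr_t, eb.mhr_t)
            assert np.array_equal(ea.mhr_bpm, eb.mhr_bpm)
            assert ta.spike_segments == tb.spike_segments

    def test_different_seeds_differ(self):
        cfg = GeneratorConfig(n_normal=1, n_ncu=0, n_vend=0, n_fsb=0)
        (ea, _), = generate_cohort(cfg, seed=1)
        (eb, _), = generate_cohort(cfg, seed=2)
        assert not (
            ea.fhr.shape == eb.fhr.shape
            and np.array_equal(ea.fhr, eb.fhr, equal_nan=True)
        )

    def test_grid_is_2hz_and_pre_birth_without_drift(self, default_cohort):
        for ep, truth in default_cohort[:20]:
            t = ep.fhr_times()
            assert np.allclose(np.diff(t), TICK_S)
            assert truth.drift_s == 0.0
            assert (t < 0).all()

    def test_spike_segments_stay_below_30s(self, default_cohort):
        for _, truth in default_cohort:
            assert all((e - s) < 60 for s, e in truth.spike_segments)

    def test_spike_values_mostly_outside_normal_band(self, default_cohort):
        # spikes are offset >= 50 bpm from the signal; the bulk lands
        # outside the 110-160 bpm band (late low baselines can push an
        # up-spike's landing zone into it, as real artefacts do)
        in_band = total = 0
        for ep, truth in default_cohort[:20]:
            for s, e in truth.spike_segments:
                vals = ep.fhr[s:e]
                total += vals.size
                in_band += int(((vals >= 110) & (vals <= 160)).sum())
        assert total > 0
        assert in_band / total < 0.10

    def test_ambiguity_intervals_record_maternal_series(self, default_cohort):
        checked = 0
        for ep, truth in default_cohort:
            for a, b in truth.ambiguity_intervals:
                sel = (ep.mhr_t >= a) & (ep.mhr_t <= b)
                ticks = np.round(
                    (ep.mhr_t[sel] - ep.fhr_start_s) / TICK_S
                ).astype(int)
                measured = np.isfinite(ep.fhr[ticks])
                assert np.array_equal(
                    ep.fhr[ticks][measured], ep.mhr_bpm[sel][measured]
                )
                checked += 1
        assert checked > 0

    def test_clock_drift_applied_when_enabled(self):
        cfg = GeneratorConfig(
            n_normal=20, n_ncu=0, n_vend=0, n_fsb=0, drift_max_s=1800.0,
            end_before_birth_fraction=0.0,
        )
        cohort = generate_cohort(cfg, seed=3)
        drifts = np.array([t.drift_s for _, t in cohort])
        assert (np.abs(drifts) <= 1800.0).all()
        assert (drifts > 0).any() and (drifts < 0).any()
        for ep, truth in cohort:
            # recording runs to birth, so the logged end time is the drift
            assert ep.fhr_times()[-1] == pytest.approx(-TICK_S + truth.drift_s)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(drift_max_s=3600.0)


class TestCalibration:
    def test_realized_rates_match_config(self, default_cohort):
        cfg = GeneratorConfig()
        n = len(default_cohort)
        missing = np.array([t.missing_mask.mean() for _, t in default_cohort])
        spike = np.array(
            [
                sum(e - s for s, e in t.spike_segments)
                / max((~t.missing_mask).sum(), 1)
                for _, t in default_cohort
            ]
        )
        for realized, target in [
            (missing, cfg.dropout_mean),
            (spike, cfg.spike_fraction),
        ]:
            sem = realized.std(ddof=1) / np.sqrt(n)
            assert abs(realized.mean() - target) <= 3 * sem + 1e-4

        with_mhr = [
            (ep, t) for ep, t in default_cohort if ep.mhr_t.size
        ]
        assert len(with_mhr) / n == pytest.approx(
            cfg.mhr_episode_fraction, abs=0.10
        )
        coverage = np.array(
            [
                ep.mhr_t.size / (cfg.mhr_rate_hz * ep.n_ticks * TICK_S)
                for ep, _ in with_mhr
            ]
        )
        sem = coverage.std(ddof=1) / np.sqrt(coverage.size)
        assert abs(coverage.mean() - cfg.mhr_coverage_mean) <= 3 * sem + 5e-4

    def test_trend_profile_recovered_by_window_medians(self, default_cohort):
        # noise-free check of the profile oracle itself
        cfg = degenerate_config(dropout_mean=0.02)
        rng = np.random.default_rng(1)
        ep, _ = generate_episode(cfg, "normal", rng)
        from fhrtrend.trend import window_partition

        for w in window_partition(9000.0, 600.0):
            t = ep.fhr_times()
            in_w = w.contains(t) & ep.measured_mask()
            got = float(np.median(ep.fhr[in_w]))
            expected = profile_window_median(cfg, "normal", w)
            assert got == pytest.approx(expected, abs=0.2)


class TestCohortOnDisk:
    def test_round_trip_and_truth_sidecar(self, tmp_path):
        cfg = GeneratorConfig(
            n_normal=3, n_ncu=1, n_vend=1, n_fsb=1,
            span_start_min_s=-11000.0, span_start_max_s=-10800.0,
        )
        cohort = generate_cohort(cfg, seed=13, out_dir=tmp_path / "c")
        back = read_cohort(tmp_path / "c" / "manifest.csv")
        assert len(back) == 6
        for (orig, _), rt in zip(cohort, back):
            assert np.array_equal(rt.fhr, orig.fhr, equal_nan=True)
            assert rt.outcome == orig.outcome
        assert (tmp_path / "c" / "truth.csv").is_file()

    def test_refuses_non_empty_directory(self, tmp_path):
        target = tmp_path / "c"
        target.mkdir()
        (target / "junk.txt").write_text("x")
        cfg = GeneratorConfig(n_normal=1, n_ncu=0, n_vend=0, n_fsb=0)
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg, seed=1, out_dir=target)
        generate_cohort(cfg, seed=1, out_dir=target, force=True)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(spike_run_max_s=30.0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(noise_ar1=1.0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(dropout_mean=1.5)
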