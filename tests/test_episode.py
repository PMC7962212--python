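import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fhrtrend.episode import (
    Episode,
    Window,
    correct_clock_drift,
    index_time,
    missing_fraction,
    normalize_outcome,
    read_cohort,
    sample_index,
    write_cohort,
)
from fhrtrend.errors import (
    CohortValidationError,
    EmptyEpisodeError,
    OutOfRangeError,
    UndefinedResultError,
)

from .conftest import make_episode


class TestSampleIndex:
    @pytest.mark.parametrize(
        "t, t0, expected",
        [
            (-9000.0, 9000.0, 0),       # grid origin
            (0.0, 9000.0, 18000),       # birth
            (-8999.5, 9000.0, 1),       # one 0.5 s tick
            (-150.0, 300.0, 300),
        ],
    )
    def test_maps_time_to_grid_position(self, t, t0, expected):
        assert sample_index(t, t0) == expected

    def test_rejects_times_before_grid_origin(self):
        with pytest.raises(OutOfRangeError):
            sample_index(-9000.5, 9000.0)

    def test_rejects_off_grid_times(self):
        with pytest.raises(ValueError):
            sample_index(-8999.7, 9000.0)

    @given(st.integers(min_value=0, max_value=10**6))
    def test_invertible_on_grid(self, n):
        t0 = 9000.0
        assert sample_index(index_time(n, t0), t0) == n


class TestClockDrift:
    def test_post_birth_samples_shift_last_sample_to_birth(self):
        ep = make_episode([140.0, 141.0, 142.0], start_s=119.0)
        out = correct_clock_drift(ep)
        assert out.drift_shift_s == pytest.approx(120.0)
        assert out.fhr_times()[-1] == pytest.approx(0.0)

    def test_pre_birth_episode_unchanged(self):
        ep = make_episode([140.0, None, 142.0], start_s=-31.0)
        out = correct_clock_drift(ep)
        assert out is ep
        assert out.drift_shift_s == 0.0

    def test_single_sample_after_birth_ends_at_birth(self):
        ep = make_episode([150.0], start_s=1800.0)
        out = correct_clock_drift(ep)
        assert out.fhr_times()[-1] == pytest.approx(0.0)
        assert out.drift_shift_s == pytest.approx(1800.0)

    def test_trailing_missing_samples_ignored(self):
        # last *measured* sample defines the correction
        ep = make_episode([140.0, 141.0, None, None], start_s=59.5)
        out = correct_clock_drift(ep)
        assert out.drift_shift_s == pytest.approx(60.0)

    def test_idempotent(self):
        ep = make_episode([140.0, 141.0, 142.0], start_s=119.0)
        once = correct_clock_drift(ep)
        twice = correct_clock_drift(once)
        assert twice.fhr_start_s == once.fhr_start_s
        assert twice.drift_shift_s == once.drift_shift_s

    def test_mhr_times_shift_alongside(self):
        ep = make_episode(
            [140.0, 141.0], start_s=99.5, mhr_t=[-50.0], mhr_bpm=[85.0]
        )
        out = correct_clock_drift(ep)
        assert out.mhr_t[0] == pytest.approx(-150.0)

    def test_all_missing_episode_rejected(self):
        ep = make_episode([None, None], start_s=-100.0)
        with pytest.raises(EmptyEpisodeError):
            correct_clock_drift(ep)


class TestMissingFraction:
    def test_fully_measured_window_is_zero(self):
        ep = make_episode([140.0] * 20, start_s=-10.0)
        assert missing_fraction(ep, Window(-10.0, 10.0)) == 0.0

    def test_alternating_ticks_give_half(self):
        vals = [140.0, None] * 10 + [140.0]
        ep = make_episode(vals, start_s=-10.5)
        # window over the first 20 ticks: 10 measured, 10 missing
        assert missing_fraction(ep, Window(-10.5, 10.0)) == pytest.approx(0.5)

    def test_window_clipped_to_recorded_span(self):
        # leading/trailing missing ticks are outside the recorded span
        ep = make_episode([None, 140.0, None, 150.0, None], start_s=-100.0)
        frac = missing_fraction(ep, Window(-200.0, 200.0))
        assert frac == pytest.approx(1 / 3)  # ticks: 140, nan, 150

    def test_disjoint_window_is_undefined_not_zero(self):
        ep = make_episode([140.0] * 4, start_s=-10.0)
        with pytest.raises(UndefinedResultError):
            missing_fraction(ep, Window(-5000.0, 100.0))

    def test_generator_dropout_mask_agrees(self, default_cohort):
        # missing_fraction over the recorded span must match the
        # generator's own dropout mask restricted to that span
        for ep, truth in default_cohort[:10]:
            first, last = ep.recorded_span()
            frac = missing_fraction(ep, Window(first, last - first + 0.5))
            t = ep.fhr_times()
            in_span = (t >= first) & (t <= last)
            assert frac == pytest.approx(truth.missing_mask[in_span].mean())


class TestCohortIO:
    def test_round_trip_preserves_values_and_masks(self, small_cohort, tmp_path):
        _, cohort = small_cohort
        episodes = [ep for ep, _ in cohort]
        manifest = write_cohort(episodes, tmp_path)
        back = read_cohort(manifest)
        assert len(back) == len(episodes)
        for orig, rt in zip(episodes, back):
            assert rt.episode_id == orig.episode_id
            assert rt.outcome == orig.outcome
            assert np.array_equal(rt.fhr, orig.fhr, equal_nan=True)
            assert rt.fhr_start_s == orig.fhr_start_s
            assert np.array_equal(rt.mhr_t, orig.mhr_t)
            assert np.array_equal(rt.mhr_bpm, orig.mhr_bpm)

    @pytest.mark.parametrize(
        "raw, expected",
        [("FSB", "fsb"), ("Normal", "normal"), ("NCU", "ncu"),
         ("vend", "vend"), ("mystery", "unlabeled"), ("", "unlabeled")],
    )
    def test_outcome_mapping_case_insensitive(self, raw, expected):
        assert normalize_outcome(raw) == expected

    def test_missing_file_error_names_episode(self, tmp_path):
        (tmp_path / "manifest.csv").write_text(
            "episode_id,outcome,fhr_file,mhr_file\nepX,normal,absent.csv,\n"
        )
        with pytest.raises(FileNotFoundError, match="epX"):
            read_cohort(tmp_path / "manifest.csv")

    def test_duplicate_episode_id_rejected(self, tmp_path):
        ep = make_episode([140.0, 141.0])
        write_cohort([ep], tmp_path)
        manifest = tmp_path / "manifest.csv"
        lines = manifest.read_text().splitlines()
        manifest.write_text("\n".join(lines + [lines[1]]) + "\n")
        with pytest.raises(CohortValidationError, match="duplicate"):
            read_cohort(manifest)

    def test_zero_values_read_as_missing(self, tmp_path):
        (tmp_path / "e_fhr.csv").write_text(
            "time_s,fhr_bpm\n-1.0,140\n-0.5,0\n"
        )
        (tmp_path / "manifest.csv").write_text(
            "episode_id,outcome,fhr_file,mhr_file\ne,normal,e_fhr.csv,\n"
        )
        (ep,) = read_cohort(tmp_path / "manifest.csv")
        assert np.isnan(ep.fhr[1])

    def test_off_grid_times_rejected(self, tmp_path):
        (tmp_path / "e_fhr.csv").write_text(
            "time_s,fhr_bpm\n-1.0,140\n-0.3,141\n"
        )
        (tmp_path / "manifest.csv").write_text(
            "episode_id,outcome,fhr_file,mhr_file\ne,normal,e_fhr.csv,\n"
        )
        with pytest.raises(CohortValidationError, match="0.5 s grid"):
            read_cohort(tmp_path / "manifest.csv")


class TestEpisodeValidation:
    def test_negative_fhr_rejected(self):
        with pytest.raises(CohortValidationError):
            make_episode([-5.0, 140.0])

    def test_unknown_outcome_rejected(self):
        with pytest.raises(CohortValidationError):
            make_episode([140.0], outcome="mystery")

    def test_window_requires_positive_duration(self):
        with pytest.raises(ValueError):
            Window(start_s=0.0, duration_s=0.0)
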