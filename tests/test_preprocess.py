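"""Preprocessing chain: interpolation, downsampling, units, baselines, outliers."""

import numpy as np
import pandas as pd
import pytest

from pupilbreadth.preprocess import (PreprocParams, au_to_mm, baseline_correct,
                                     downsample, flag_baseline_outliers,
                                     interpolate_blinks)


def _samples(pupil, t_ms=None, pid="p01", trial=1, state="raw", blink=None):
    pupil = np.asarray(pupil, dtype=np.float32)
    if t_ms is None:
        t_ms = np.arange(len(pupil), dtype=np.float32) * 10.0
    df = pd.DataFrame({
        "participant_id": pd.Categorical([pid] * len(pupil)),
        "trial_index": np.full(len(pupil), trial, dtype=np.int32),
        "t_ms": np.asarray(t_ms, dtype=np.float32),
        "pupil": pupil,
        "gaze_x_deg": np.zeros(len(pupil), dtype=np.float32),
        "gaze_y_deg": np.zeros(len(pupil), dtype=np.float32),
        "blink_flag": np.zeros(len(pupil), bool) if blink is None else np.asarray(blink),
    })
    df.attrs["preprocessing_state"] = state
    return df


PARAMS = PreprocParams(mm_coeff_a=1.0, mm_coeff_b=0.0, blink_margin_ms=0.0,
                       blink_min_duration_ms=0.0)


class TestBlinkInterpolation:
    def test_clean_trace_unchanged(self):
        s = _samples([4.0, 4.5, 5.0, 4.8])
        out = interpolate_blinks(s, PARAMS)
        assert np.allclose(out["pupil"], s["pupil"])

    def test_linear_midpoint(self):
        s = _samples([4.0, 4.0, 0.0, 0.0, 0.0, 5.0, 5.0])
        out = interpolate_blinks(s, PARAMS)
        # blink spans samples 2-4; midpoint between flanking 4.0 and 5.0
        assert out["pupil"].iloc[3] == pytest.approx(4.5)
        assert np.allclose(out["pupil"].iloc[[2, 4]], [4.25, 4.75])

    def test_margin_extends_interpolated_region(self):
        params = PreprocParams(mm_coeff_a=1.0, mm_coeff_b=0.0,
                               blink_margin_ms=10.0, blink_min_duration_ms=0.0)
        s = _samples([4.0, 9.0, 0.0, 9.0, 5.0])
        out = interpolate_blinks(s, params)
        # the margin swallows the contaminated flanking samples
        assert np.allclose(out["pupil"], [4.0, 4.25, 4.5, 4.75, 5.0])

    def test_edge_blinks_take_nearest_valid(self):
        s = _samples([0.0, 0.0, 4.0, 5.0, 0.0])
        out = interpolate_blinks(s, PARAMS)
        assert np.allclose(out["pupil"], [4.0, 4.0, 4.0, 5.0, 5.0])

    def test_fully_blinked_trial_marked_missing(self):
        s = _samples([0.0, 0.0, 0.0])
        out = interpolate_blinks(s, PARAMS)
        assert out["pupil"].isna().all()

    def test_reconstruction_error_below_noise(self):
        # ground truth from the generator; artificial blinks punched in
        rng = np.random.default_rng(4)
        truth = 5.0 + 0.3 * np.sin(np.arange(600) / 60.0)
        noisy = truth + rng.normal(0, 0.05, 600)
        corrupted = noisy.copy()
        for start in (100, 340, 500):
            corrupted[start:start + 15] = 0.0
        out = interpolate_blinks(_samples(corrupted), PARAMS)
        rmse = np.sqrt(np.mean((out["pupil"].to_numpy() - truth) ** 2))
        assert rmse < 0.05


class TestDownsample:
    def test_length_contract(self):
        s = interpolate_blinks(_samples(np.ones(3000) * 4.0), PARAMS)
        out = downsample(s, 10)
        assert len(out) == 300

    def test_constant_preserved_and_t_is_block_start(self):
        s = interpolate_blinks(_samples(np.ones(100) * 4.2), PARAMS)
        out = downsample(s, 10)
        assert np.allclose(out["pupil"], 4.2)
        assert np.allclose(out["t_ms"], np.arange(10) * 100.0)

    def test_block_means(self):
        s = interpolate_blinks(_samples(np.arange(20, dtype=float) + 1.0), PARAMS)
        out = downsample(s, 10)
        assert np.allclose(out["pupil"], [5.5, 15.5])

    def test_factor_one_is_identity(self):
        s = interpolate_blinks(_samples(np.ones(30) * 2.0), PARAMS)
        out = downsample(s, 1)
        assert np.allclose(out["pupil"], s["pupil"])

    def test_trailing_remainder_dropped(self):
        s = interpolate_blinks(_samples(np.ones(25) * 1.0), PARAMS)
        assert len(downsample(s, 10)) == 2


class TestUnits:
    def _down(self, values):
        return downsample(interpolate_blinks(_samples(values), PARAMS), 1)

    def test_identity_coefficients(self):
        s = self._down([3.0, 4.0])
        out = au_to_mm(s, PreprocParams(mm_coeff_a=1.0, mm_coeff_b=0.0))
        assert np.allclose(out["pupil"], s["pupil"])

    def test_affine_map(self):
        s = self._down([5000.0, 5000.0])
        out = au_to_mm(s, PreprocParams(mm_coeff_a=0.001, mm_coeff_b=0.0))
        assert np.allclose(out["pupil"], 5.0)

    def test_inverts_generator_mapping(self):
        # generator: au = 500 * mm + 1000; inverse recovers mm
        mm_true = np.array([4.5, 5.0, 5.5])
        s = self._down(500.0 * mm_true + 1000.0)
        out = au_to_mm(s, PreprocParams(mm_coeff_a=1 / 500.0, mm_coeff_b=-2.0))
        assert np.allclose(out["pupil"], mm_true, atol=1e-4)

    def test_missing_coefficients_refused_with_key_names(self):
        s = self._down([1.0, 1.0])
        with pytest.raises(ValueError, match="mm_coeff_a"):
            au_to_mm(s, PreprocParams())


def _to_mm(values, **trial_kw):
    s = _samples(values, **trial_kw)
    s = downsample(interpolate_blinks(s, PARAMS), 1)
    return au_to_mm(s, PreprocParams(mm_coeff_a=1.0, mm_coeff_b=0.0))


class TestBaseline:
    def test_constant_trace_becomes_zero(self):
        s = _to_mm(np.ones(30) * 4.0)
        trials = pd.DataFrame({"participant_id": ["p01"], "trial_index": [1]})
        out, t = baseline_correct(s, trials, PARAMS)
        assert np.allclose(out["pupil"], 0.0)
        assert t["baseline_pupil"].iloc[0] == pytest.approx(4.0)

    def test_shift_invariance(self):
        base = np.sin(np.arange(30) / 5.0) + 5.0
        trials = pd.DataFrame({"participant_id": ["p01"], "trial_index": [1]})
        a, _ = baseline_correct(_to_mm(base), trials, PARAMS)
        b, _ = baseline_correct(_to_mm(base + 3.0), trials, PARAMS)
        assert np.allclose(a["pupil"], b["pupil"], atol=1e-5)

    def test_corrected_baseline_window_mean_is_zero(self, desk_processed):
        samples, _, _ = desk_processed
        w = samples[(samples.t_ms >= 0) & (samples.t_ms < 50)]
        means = w.groupby(["participant_id", "trial_index"], observed=True)["pupil"].mean()
        assert np.nanmax(np.abs(means.to_numpy())) < 1e-6


class TestOutlierFlagging:
    def _trials(self, baselines, pid="p01"):
        return pd.DataFrame({
            "participant_id": [pid] * len(baselines),
            "trial_index": np.arange(1, len(baselines) + 1),
            "baseline_pupil": baselines,
            "excluded": False,
            "exclusion_reason": "none",
        })

    def test_gaussian_flag_rate_matches_two_sigma_tail(self):
        rng = np.random.default_rng(0)
        t = flag_baseline_outliers(self._trials(rng.normal(size=10_000)), PARAMS)
        rate = t["excluded"].mean()
        assert 0.040 < rate < 0.052  # 2*Phi(-2) = 0.0455

    def test_zero_variance_flags_nothing(self):
        t = flag_baseline_outliers(self._trials(np.ones(50)), PARAMS)
        assert not t["excluded"].any()

    def test_single_extreme_baseline_flagged(self):
        b = np.concatenate([np.random.default_rng(1).normal(5, 0.1, 99), [9.0]])
        t = flag_baseline_outliers(self._trials(b), PARAMS)
        assert t["excluded"].iloc[-1]
        assert t["exclusion_reason"].iloc[-1] == "baseline_outlier"

    def test_tiny_participant_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            t = flag_baseline_outliers(self._trials([1.0, 2.0]), PARAMS)
        assert not t["excluded"].any()


class TestChain:
    def test_order_is_enforced(self):
        s = _samples(np.ones(30))
        with pytest.raises(ValueError, match="interpolate"):
            downsample(s, 10)  # skipping blink interpolation is refused

    def test_rerunning_a_stage_is_refused(self):
        s = interpolate_blinks(_samples(np.ones(30)), PARAMS)
        with pytest.raises(ValueError, match="raw"):
            interpolate_blinks(s, PARAMS)

    def test_default_synthetic_exclusion_fraction_plausible(self, desk_processed):
        _, _, report = desk_processed
        assert 0.03 <= report["fraction_excluded"] <= 0.10
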