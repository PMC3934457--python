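"""Preprocessing chain: denoising, detrending, segmentation, normalization."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from pulsewave.core import PERIOD_LENGTH, make_record, make_timeseries
from pulsewave.preprocess import (
    InsufficientBeatsError,
    OnsetList,
    PreprocessConfig,
    StageError,
    denoise,
    detect_onsets,
    extract_period,
    normalize_period,
    preprocess_pipeline,
    remove_baseline,
    segment_periods,
)
from pulsewave.synthetic import NoiseConfig, generate_record

CFG = PreprocessConfig()
RECORD_SEEDS = range(1000, 1050)  # 50 fixed records, 10 per class
LABELS = ("moderate", "slippery", "taut", "hollow", "unsmooth")


def _labeled_record(seed, noise=None):
    noise = noise if noise is not None else NoiseConfig(snr_db=25.0, drift_rel=0.3)
    label = LABELS[seed % 5]
    return generate_record(label, 8, noise, rng=seed)


class TestDenoise:
    def test_zero_signal_stays_zero(self):
        rec = make_record(np.zeros(512))
        np.testing.assert_array_equal(denoise(rec, CFG).series.values, 0.0)

    def test_length_preserved(self):
        rec, _ = _labeled_record(1000)
        assert len(denoise(rec, CFG)) == len(rec)

    def test_too_short_record_names_minimum(self):
        rec = make_record(np.arange(8.0))
        with pytest.raises(Exception, match=str(2**CFG.denoise_levels)):
            denoise(rec, CFG)

    def test_reduces_rms_error_against_clean_signal(self):
        """At 20 dB SNR the denoised record must be closer to the clean one."""
        improved = 0
        for seed in range(50):
            _, truth = _labeled_record(2000 + seed, noise=NoiseConfig.silent())
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.var(truth.clean) * 10 ** (-20 / 10))
            noisy = make_record(truth.clean + rng.normal(0, sigma, len(truth.clean)))
            out = denoise(noisy, CFG).series.values
            rms_in = np.sqrt(np.mean((noisy.series.values - truth.clean) ** 2))
            rms_out = np.sqrt(np.mean((out - truth.clean) ** 2))
            improved += rms_out < rms_in
        assert improved == 50


class TestRemoveBaseline:
    def test_slow_sinusoid_removed(self):
        t = np.arange(30 * 150) / 150.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = remove_baseline(make_record(sig), CFG).series.values
        assert np.sqrt(np.mean(out**2)) < 0.1 * np.sqrt(np.mean(sig**2))

    def test_low_distortion_on_drift_free_train(self):
        rels = []
        for seed in range(10):
            _, truth = _labeled_record(2000 + seed, noise=NoiseConfig.silent())
            out = remove_baseline(make_record(truth.clean), CFG).series.values
            resid = out - (truth.clean - truth.clean.mean())
            resid -= resid.mean()
            rels.append(np.sqrt(np.mean(resid**2)) / np.std(truth.clean))
        assert np.mean(rels) < 0.05

    def test_zero_signal_stays_zero(self):
        rec = make_record(np.zeros(512))
        np.testing.assert_allclose(remove_baseline(rec, CFG).series.values, 0.0, atol=1e-12)


class TestDetectOnsets:
    def test_constant_signal_has_no_beats(self):
        with pytest.raises(InsufficientBeatsError, match="insufficient beats"):
            detect_onsets(make_record(np.ones(1000)), CFG)

    def test_two_clean_periods_give_two_or_three_onsets(self):
        rec, _ = generate_record("moderate", 2, NoiseConfig.silent(), rng=5)
        onsets = detect_onsets(rec, CFG)
        assert len(onsets) in (2, 3)

    def test_accuracy_against_ground_truth(self):
        """>= 7 of 8 onsets within +/-0.05 s, on every fixed record."""
        tol = 0.05 * 150
        for seed in RECORD_SEEDS:
            rec, truth = _labeled_record(seed)
            d = remove_baseline(denoise(rec, CFG), CFG)
            found = detect_onsets(d, CFG).indices
            hits = sum(1 for o in truth.onsets if np.min(np.abs(found - o)) <= tol)
            assert hits >= 7, f"seed {seed}: only {hits}/8 onsets within tolerance"

    def test_onset_list_invariants(self):
        with pytest.raises(Exception, match="at least 2"):
            OnsetList(indices=np.array([5]))
        with pytest.raises(Exception, match="increasing"):
            OnsetList(indices=np.array([5, 5]))


class TestExtractPeriod:
    def test_identical_periods_tie_broken_to_first(self):
        base = np.concatenate([np.linspace(0, 1, 10), np.linspace(1, 0, 40)])
        x = np.tile(base, 4)
        rec = make_record(x)
        onsets = OnsetList(indices=np.arange(0, 200, 50))
        seg = extract_period(rec, onsets)
        np.testing.assert_array_equal(seg.values, x[0:51])

    def test_single_period_returned_as_is(self):
        rec = make_record(np.sin(np.arange(100) / 5.0))
        onsets = OnsetList(indices=np.array([10, 60]))
        seg = extract_period(rec, onsets)
        assert len(seg) == 51

    def test_artifact_period_rejected(self):
        """A spike-corrupted period must not be selected, across 50 seeds."""
        rng_master = np.random.default_rng(4242)
        for _ in range(50):
            seed = int(rng_master.integers(0, 2**31))
            rec, truth = generate_record(
                "moderate", 8, NoiseConfig.silent(), rng=seed
            )
            x = np.array(rec.series.values)
            rng = np.random.default_rng(seed + 1)
            corrupt = int(rng.integers(0, 7))
            s, e = truth.onsets[corrupt], truth.onsets[corrupt + 1]
            mid = (s + e) // 2
            x[mid : mid + 3] += 5.0  # pressure spike artifact
            onsets = OnsetList(indices=truth.onsets)
            seg = extract_period(make_record(x), onsets)
            chosen_start = int(np.flatnonzero(
                np.isclose(rec.series.timestamps, seg.timestamps[0])
            )[0])
            assert chosen_start != s, "corrupted period was selected"


class TestNormalizePeriod:
    def test_output_length_is_150(self):
        seg = make_timeseries(np.sin(np.arange(80) / 5.0))
        assert len(normalize_period(seg, CFG)) == PERIOD_LENGTH

    def test_length_150_input_unchanged(self):
        vals = np.sin(np.arange(150) / 7.0)
        out = normalize_period(make_timeseries(vals), CFG)
        np.testing.assert_allclose(out.values, vals, atol=1e-12)

    def test_amplitude_normalization_scales_to_unit_range(self):
        cfg = PreprocessConfig(amplitude_normalize=True)
        with pytest.raises(Exception, match="zero range"):
            normalize_period(make_timeseries(np.ones(10)), cfg)
        out = normalize_period(make_timeseries([0.0, 2.0, 0.0]), cfg)
        assert out.values.max() == 1.0 and out.values[0] == 0.0 and out.values[-1] == 0.0


class TestPipeline:
    def test_template_recovery(self):
        """Mean Pearson r > 0.95 against the generating template, 50 records."""
        rs = []
        for seed in RECORD_SEEDS:
            rec, truth = _labeled_record(seed)
            period = preprocess_pipeline(rec, CFG)
            rs.append(pearsonr(period.values, truth.template)[0])
        assert np.mean(rs) > 0.95

    def test_deterministic(self):
        rec, _ = _labeled_record(1003)
        a = preprocess_pipeline(rec, CFG)
        b = preprocess_pipeline(rec, CFG)
        np.testing.assert_array_equal(a.values, b.values)

    def test_all_outputs_valid_periods(self):
        for seed in list(RECORD_SEEDS)[:10]:
            rec, _ = _labeled_record(seed)
            out = preprocess_pipeline(rec, CFG)
            assert len(out) == PERIOD_LENGTH and np.isfinite(out.values).all()

    def test_short_record_fails_with_stage_name(self):
        rec = make_record(np.zeros(400))  # flat: no beats
        with pytest.raises(StageError, match="detect_onsets.*insufficient beats"):
            preprocess_pipeline(rec, CFG)

    def test_onset_count_stable_under_denoise_on_clean_records(self):
        for seed in range(2000, 2050):
            rec, _ = _labeled_record(seed, noise=NoiseConfig.silent())
            before = len(detect_onsets(rec, CFG))
            after = len(detect_onsets(denoise(rec, CFG), CFG))
            assert before == after

    def test_segment_periods_emits_every_beat(self):
        rec, truth = _labeled_record(1001)
        periods = segment_periods(rec, CFG)
        assert len(periods) in (7, 8)
        assert all(len(p) == PERIOD_LENGTH for p in periods)
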