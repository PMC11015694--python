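import numpy as np
import pytest

from erpvar.datatypes import ConfigError, StructuralError
from erpvar.preprocess import (
    ConditionChannelCounts,
    assess_inclusion,
    baseline_correct,
    preprocess_epochs,
    reject_artifact_trials,
    segment,
    select_correct_trials,
    smooth_trials,
)

from conftest import make_epochs


class TestSegment:
    def test_ramp_epoch_is_exact_slice(self):
        n = 2000
        continuous = np.vstack([np.arange(n, dtype=float),
                                np.arange(n, dtype=float) * 2.0])
        epochs = segment(continuous, [(2000.0, "target")])
        assert epochs.n_trials == 1
        onset_idx = 500  # 2000 ms at 250 Hz
        start = onset_idx - 50  # -200 ms
        np.testing.assert_array_equal(
            epochs.amplitudes[0, 0], continuous[0, start:start + 250]
        )
        np.testing.assert_array_equal(
            epochs.amplitudes[0, 1], continuous[1, start:start + 250]
        )
        assert epochs.time_axis[0] == -200.0
        assert epochs.time_axis[-1] == 796.0

    def test_event_near_edge_skipped(self, caplog):
        continuous = np.zeros((2, 1000))
        with caplog.at_level("WARNING"):
            epochs = segment(
                continuous, [(100.0, "target"), (2000.0, "standard")]
            )
        assert epochs.n_trials == 1
        assert epochs.stimulus_label[0] == "standard"
        assert "skipped" in caplog.text

    def test_full_session_event_count(self):
        # 64 + 256 events, spaced 1 s apart
        n_events = 320
        onsets = 1000.0 + 1000.0 * np.arange(n_events)
        labels = ["target"] * 64 + ["standard"] * 256
        continuous = np.zeros((2, int(250 * (n_events + 3))))
        epochs = segment(continuous, list(zip(onsets, labels)))
        assert epochs.n_trials == 320
        assert (epochs.stimulus_label == "target").sum() == 64


class TestBaselineCorrect:
    def test_baseline_mean_zero(self, rng):
        epochs = make_epochs(rng.normal(size=(5, 2, 250)) * 10)
        out = baseline_correct(epochs)
        pre = out.time_axis < 0
        np.testing.assert_allclose(
            out.amplitudes[:, :, pre].mean(axis=2), 0.0, atol=1e-12
        )

    def test_constant_trial_becomes_zero(self):
        epochs = make_epochs(np.full((1, 2, 250), 7.0))
        out = baseline_correct(epochs)
        np.testing.assert_allclose(out.amplitudes, 0.0, atol=1e-12)

    def test_ramp_hand_computed(self):
        epochs = make_epochs(np.zeros((1, 2, 250)))
        ramp = epochs.time_axis / 100.0
        epochs.amplitudes[0, :, :] = ramp
        out = baseline_correct(epochs)
        pre_mean = ramp[epochs.time_axis < 0].mean()
        np.testing.assert_allclose(out.amplitudes[0, 0], ramp - pre_mean)

    def test_idempotent(self, rng):
        epochs = make_epochs(rng.normal(size=(4, 2, 250)))
        once = baseline_correct(epochs)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.amplitudes, twice.amplitudes, atol=1e-12)

    def test_no_baseline_samples_raises(self, rng):
        epochs = make_epochs(
            rng.normal(size=(2, 2, 100)),
            time_axis=np.arange(100) * 4.0,  # starts at 0 ms
        )
        with pytest.raises(StructuralError):
            baseline_correct(epochs)


class TestSelectCorrectTrials:
    def test_counts(self, rng):
        labels = ["target"] * 64 + ["standard"] * 256
        correct = [True] * 60 + [False] * 4 + [True] * 250 + [False] * 6
        epochs = make_epochs(
            rng.normal(size=(320, 2, 250)), labels=labels, correct=correct
        )
        out = select_correct_trials(epochs)
        assert (out.stimulus_label == "target").sum() == 60
        assert (out.stimulus_label == "standard").sum() == 250

    def test_all_correct_identity(self, rng):
        epochs = make_epochs(rng.normal(size=(5, 2, 250)))
        out = select_correct_trials(epochs)
        np.testing.assert_array_equal(out.amplitudes, epochs.amplitudes)


class TestRejectArtifactTrials:
    def test_single_sample_over_threshold_rejected(self, rng):
        amps = rng.normal(size=(3, 2, 250))
        amps[1, 1, 100] = 101.0  # one sample on Fp2
        epochs = make_epochs(amps)
        out, keep = reject_artifact_trials(epochs, threshold=100.0)
        assert keep.tolist() == [True, False, True]
        assert out.n_trials == 2

    def test_bounded_trials_all_kept(self, rng):
        epochs = make_epochs(rng.uniform(-50, 50, size=(10, 2, 250)))
        out, keep = reject_artifact_trials(epochs)
        assert keep.all() and out.n_trials == 10

    def test_negative_threshold_excess(self, rng):
        amps = rng.normal(size=(4, 2, 250))
        amps[2, 0, 7] = -150.0
        epochs = make_epochs(amps)
        out, keep = reject_artifact_trials(epochs)
        assert keep.sum() == 3

    def test_infinite_threshold_identity(self, rng):
        amps = rng.normal(size=(6, 2, 250)) * 500
        epochs = make_epochs(amps)
        out, keep = reject_artifact_trials(epochs, threshold=np.inf)
        assert keep.all()

    def test_matches_brute_force_oracle(self, rng):
        amps = rng.normal(scale=60, size=(40, 2, 250))
        epochs = make_epochs(amps)
        _, keep = reject_artifact_trials(epochs, threshold=100.0)
        expected = [
            all(abs(amps[i, c, k]) <= 100.0
                for c in range(2) for k in range(250))
            for i in range(40)
        ]
        assert keep.tolist() == expected

    def test_nonpositive_threshold_rejected(self, rng):
        epochs = make_epochs(rng.normal(size=(2, 2, 250)))
        with pytest.raises(ConfigError):
            reject_artifact_trials(epochs, threshold=0.0)


class TestSmoothTrials:
    def test_constant_unchanged(self):
        epochs = make_epochs(np.full((2, 2, 250), 3.5))
        out = smooth_trials(epochs, order=9)
        np.testing.assert_allclose(out.amplitudes, 3.5)

    def test_impulse_spreads_to_nine_samples(self):
        amps = np.zeros((1, 2, 250))
        amps[0, :, 100] = 9.0
        out = smooth_trials(make_epochs(amps), order=9)
        np.testing.assert_allclose(out.amplitudes[0, 0, 96:105], 1.0)
        np.testing.assert_allclose(out.amplitudes[0, 0, :96], 0.0)
        np.testing.assert_allclose(out.amplitudes[0, 0, 105:], 0.0)

    def test_edge_window_shrinks(self):
        amps = np.zeros((1, 2, 250))
        amps[0, :, 0] = 5.0
        out = smooth_trials(make_epochs(amps), order=9)
        # at sample 0 the window is [0, 4] -> 5 samples
        assert out.amplitudes[0, 0, 0] == pytest.approx(1.0)

    def test_even_order_raises(self, rng):
        with pytest.raises(ConfigError):
            smooth_trials(make_epochs(rng.normal(size=(1, 2, 250))), order=8)

    def test_order_exceeding_samples_raises(self, rng):
        with pytest.raises(ConfigError):
            smooth_trials(make_epochs(rng.normal(size=(1, 2, 5))), order=9)

    def test_reduces_white_noise_variance(self):
        reduced = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            epochs = make_epochs(r.normal(size=(20, 2, 250)))
            out = smooth_trials(epochs, order=9)
            if out.amplitudes.var() < epochs.amplitudes.var():
                reduced += 1
        assert reduced == 10

    def test_matches_direct_windowed_mean(self, rng):
        amps = rng.normal(size=(3, 2, 60))
        out = smooth_trials(make_epochs(amps, time_axis=np.arange(60) * 4.0 - 120),
                            order=5)
        for k in range(60):
            lo, hi = max(k - 2, 0), min(k + 2, 59)
            np.testing.assert_allclose(
                out.amplitudes[:, :, k], amps[:, :, lo:hi + 1].mean(axis=2)
            )


def counts(n_total, n_clean, n_correct=None):
    return ConditionChannelCounts(
        n_total=n_total,
        n_correct=n_clean if n_correct is None else n_correct,
        n_clean=n_clean,
    )


class TestAssessInclusion:
    def keys(self):
        return [(c, ch) for c in ("target", "standard") for ch in ("Fp1", "Fp2")]

    def test_no_clean_trials(self):
        table = {k: counts(64, 64) for k in self.keys()}
        table[("standard", "Fp1")] = counts(256, 0)
        report = assess_inclusion(table)
        assert not report.included
        assert report.exclusion_reason == "no_clean_trials"

    def test_all_clean_included(self):
        report = assess_inclusion({k: counts(64, 64) for k in self.keys()})
        assert report.included and report.exclusion_reason == "none"

    def test_half_clean_boundary(self):
        table = {k: counts(100, 100) for k in self.keys()}
        table[("target", "Fp2")] = counts(100, 49)
        assert assess_inclusion(table).exclusion_reason == "below_half_clean"
        table[("target", "Fp2")] = counts(100, 50)
        assert assess_inclusion(table).included

    def test_inconsistent_counts_raise(self):
        bad = {k: counts(10, 10) for k in self.keys()}
        bad[("target", "Fp1")] = ConditionChannelCounts(10, 4, 6)
        with pytest.raises(StructuralError):
            assess_inclusion(bad)


class TestPreprocessChain:
    def test_report_counts_consistent(self, rng):
        labels = ["target"] * 20 + ["standard"] * 40
        correct = rng.random(60) > 0.2
        amps = rng.normal(scale=20, size=(60, 2, 250))
        amps[3, 0, 10] = 300.0  # artifact
        epochs = make_epochs(amps, labels=labels, correct=correct)
        clean, report = preprocess_epochs(epochs)
        for (cond, _), c in report.counts.items():
            assert 0 <= c.n_clean <= c.n_correct <= c.n_total
        n_clean_total = sum(
            report.counts[(cond, "Fp1")].n_clean
            for cond in ("target", "standard")
        )
        assert clean.n_trials == n_clean_total

    def test_smoothing_switch(self, rng):
        epochs = make_epochs(rng.normal(size=(10, 2, 250)))
        smoothed, _ = preprocess_epochs(epochs, smooth=True)
        raw, _ = preprocess_epochs(epochs, smooth=False)
        assert not np.allclose(smoothed.amplitudes, raw.amplitudes)
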