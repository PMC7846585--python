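"""Circular statistics, permutation null, trigger accuracy, scoring."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from behavloop import (
    ROI,
    investigation_time,
    mean_resultant_length,
    permutation_null,
    radial_histogram,
    stimulation_latency,
    trigger_accuracy,
)
from behavloop.analysis import preference_ttest
from behavloop.engine import SessionLog, StimulationEvent
from behavloop.posture import make_posture
import pandas as pd


class TestMeanResultantLength:
    def test_identical_angles_give_r_of_one(self):
        s = mean_resultant_length([42.0] * 10)
        assert s.r == pytest.approx(1.0)
        assert s.mean_angle == pytest.approx(42.0)
        assert s.n == 10

    def test_symmetric_quadruple_gives_zero(self):
        s = mean_resultant_length([0.0, 90.0, 180.0, 270.0])
        assert s.r == pytest.approx(0.0, abs=1e-12)

    def test_uniform_arc_matches_closed_form(self):
        """r of a uniform W-wide arc is sin(W/2)/(W/2); W=60 deg -> ~0.955."""
        rng = np.random.default_rng(0)
        angles = rng.uniform(-30.0, 30.0, size=100_000)
        expected = np.sin(np.pi / 6) / (np.pi / 6)
        assert mean_resultant_length(angles).r == pytest.approx(
            expected, abs=0.01
        )

    def test_agrees_with_scipy_directional_stats(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(-180, 180, size=500)
        got = mean_resultant_length(angles)
        vecs = np.column_stack([np.cos(np.radians(angles)),
                                np.sin(np.radians(angles))])
        ref = sp_stats.directional_stats(vecs)
        assert got.r == pytest.approx(float(ref.mean_resultant_length))

    def test_rotation_invariance_of_r(self):
        rng = np.random.default_rng(4)
        angles = rng.normal(20.0, 40.0, size=1000)
        r0 = mean_resultant_length(angles).r
        r1 = mean_resultant_length(angles + 123.4).r
        assert 0.0 <= r0 <= 1.0
        assert r1 == pytest.approx(r0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_resultant_length([])


class TestPermutationNull:
    def test_degenerate_identical_angles(self):
        null = permutation_null([33.0] * 50, [33.0] * 10, n_samples=100, seed=0)
        assert np.all(null.samples == pytest.approx(1.0))
        assert null.observed_r == pytest.approx(1.0)
        assert null.p == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        all_a = rng.uniform(-180, 180, 2000)
        stim = rng.uniform(-30, 30, 100)
        a = permutation_null(all_a, stim, n_samples=200, seed=9)
        b = permutation_null(all_a, stim, n_samples=200, seed=9)
        assert np.array_equal(a.samples, b.samples)
        assert a.p == b.p

    def test_concentrated_stimulation_is_detected(self):
        """Arc-confined stimulated angles beat the 99% cutoff of the null."""
        rng = np.random.default_rng(2)
        all_a = rng.uniform(-180, 180, 54_000)
        stim = rng.uniform(-30, 30, 500)
        for seed in range(5):
            null = permutation_null(all_a, stim, n_samples=1000, seed=seed)
            assert null.observed_r > null.cutoff_99
            assert null.p <= 0.01
        # null concentrates near sqrt(pi)/(2 sqrt(n))
        assert np.mean(null.samples) == pytest.approx(
            np.sqrt(np.pi) / (2 * np.sqrt(500)), rel=0.2
        )

    def test_p_decreases_with_stim_count_in_expectation(self):
        rng = np.random.default_rng(7)
        all_a = rng.uniform(-180, 180, 10_000)
        mean_p = []
        for k in (10, 100, 500):
            ps = []
            for seed in range(20):
                stim = rng.uniform(-30, 30, k)
                ps.append(
                    permutation_null(all_a, stim, n_samples=100, seed=seed).p
                )
            mean_p.append(np.mean(ps))
        assert mean_p[0] >= mean_p[1] >= mean_p[2]

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            permutation_null([1.0, 2.0], [], n_samples=10, seed=0)
        with pytest.raises(ValueError):
            permutation_null([1.0], [1.0, 2.0], n_samples=10, seed=0)


class TestRadialHistogram:
    def test_single_occupied_bin(self):
        edges, vals = radial_histogram([10.0, 11.0, 12.0], 60.0)
        assert vals.max() == 1.0
        assert (vals > 0).sum() == 1

    def test_equal_counts_everywhere(self):
        angles = np.arange(-180.0, 180.0, 1.0)
        _, vals = radial_histogram(angles, 60.0)
        assert np.all(vals == 1.0)

    def test_normalized_to_session_maximum_matches_hand_count(self):
        session = [5.0] * 8 + [65.0] * 4 + [-100.0] * 8
        stim = [5.0] * 6 + [65.0] * 2
        edges, sess_vals = radial_histogram(session, 60.0)
        counts, _ = np.histogram(session, bins=edges)
        _, stim_vals = radial_histogram(stim, 60.0, normalize_to=counts.max())
        # hand count: stim bin [0,60) holds 6 of session max 8 -> 0.75
        assert stim_vals[np.digitize(5.0, edges) - 1] == pytest.approx(6 / 8)
        assert stim_vals[np.digitize(65.0, edges) - 1] == pytest.approx(2 / 8)

    def test_bin_width_must_divide_360(self):
        with pytest.raises(ValueError):
            radial_histogram([0.0], 50.0)


class TestTriggerAccuracy:
    widths = (60, 50, 40, 30, 20, 10)

    def test_perfect_tracker_has_zero_rates(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-180, 180, 5000)
        report = trigger_accuracy(angles, angles, self.widths, n_rotations=3)
        for w in self.widths:
            assert report.per_width[w]["fp_mean"] == 0.0
            assert report.per_width[w]["fn_mean"] == 0.0

    def test_anti_aligned_estimates_miss_everything(self):
        rng = np.random.default_rng(1)
        angles = rng.uniform(-180, 180, 5000)
        report = trigger_accuracy(angles + 180.0, angles, (60, 30),
                                  n_rotations=3)
        for w in (60, 30):
            assert report.per_width[w]["fn_mean"] == pytest.approx(100.0)

    def test_matches_per_frame_set_comparison(self):
        """Brute-force per-frame oracle over every rotation and width."""
        rng = np.random.default_rng(2)
        true = rng.uniform(-180, 180, 2000)
        est = true + rng.normal(0, 8, 2000)  # wrapped Gaussian pose noise
        report = trigger_accuracy(est, true, self.widths, n_rotations=3)
        est_m, true_m = est % 360.0, true % 360.0
        for w in self.widths:
            fps_, fns_ = [], []
            for j in range(3):
                lo, hi = j * w % 360.0, j * w % 360.0 + w
                e_in = (est_m >= lo) & (est_m < hi)
                t_in = (true_m >= lo) & (true_m < hi)
                fps_.append(100 * np.sum(e_in & ~t_in) / max(e_in.sum(), 1))
                fns_.append(100 * np.sum(t_in & ~e_in) / max(t_in.sum(), 1))
            assert report.per_width[w]["fp_mean"] == pytest.approx(
                np.mean(fps_)
            )
            assert report.per_width[w]["fn_mean"] == pytest.approx(
                np.mean(fns_)
            )
            assert report.per_width[w]["fn_sd"] == pytest.approx(np.std(fns_))

    def test_fn_nonincreasing_in_window_width(self):
        rng = np.random.default_rng(3)
        true = rng.uniform(-180, 180, 20_000)
        est = true + rng.normal(0, 8, true.size)
        report = trigger_accuracy(est, true, self.widths, n_rotations=6)
        fns = [report.per_width[w]["fn_mean"] for w in (60, 40, 20, 10)]
        assert fns == sorted(fns)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trigger_accuracy(np.zeros(5), np.zeros(6))


def _log_with_delays(delays):
    events = [
        StimulationEvent("laser" if d == delays[0] else "screen",
                         onset_frame=i * 100, onset_t=i * 100 / 30.0,
                         offset_frame=i * 100 + 30, offset_t=(i * 100 + 30) / 30.0,
                         actuator_delay=d)
        for i, d in enumerate(delays)
    ]
    return SessionLog(
        protocol="head_direction_optogenetics", seed=0, config={}, fps=30.0,
        skeleton=("nose",), records=pd.DataFrame(), events=events,
    )


class TestStimulationLatency:
    def test_zero_delay(self):
        out = stimulation_latency(_log_with_delays([0, 0, 0]))
        assert out["mean"] == 0.0 and out["sd"] == 0.0

    def test_configured_delay(self):
        out = stimulation_latency(_log_with_delays([5, 5, 5, 5]))
        assert out["mean"] == 5.0 and out["sd"] == 0.0

    def test_per_channel_means_recomputed_from_events(self):
        out = stimulation_latency(_log_with_delays([3, 5, 5]))
        assert out["per_channel"]["laser"]["mean"] == 3.0
        assert out["per_channel"]["screen"]["mean"] == 5.0
        assert out["mean"] == pytest.approx(np.mean([3, 5, 5]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            stimulation_latency(_log_with_delays([]))


class TestInvestigationTime:
    rois = [ROI("A", (50.0, 50.0), 10.0), ROI("B", (150.0, 50.0), 10.0)]

    def _frames(self, positions):
        return [
            make_posture(i, i / 30.0, {"nose": p}) for i, p in enumerate(positions)
        ]

    def test_continuous_occupancy(self):
        frames = self._frames([(50.0, 50.0)] * (600 * 30))
        report = investigation_time(frames, self.rois, fps=30.0)
        assert report.seconds["A"] == pytest.approx(600.0)
        assert report.seconds["B"] == 0.0
        assert not report.excluded

    def test_no_investigation_is_flagged_for_exclusion(self):
        frames = self._frames([(100.0, 200.0)] * 100)
        report = investigation_time(frames, self.rois, fps=30.0)
        assert report.excluded
        assert all(v == 0 for v in report.seconds.values())

    def test_scripted_crossings_match_frame_count(self):
        positions = (
            [(50.0, 50.0)] * 45 + [(100.0, 50.0)] * 30 + [(150.0, 50.0)] * 75
        )
        report = investigation_time(self._frames(positions), self.rois, fps=30.0)
        assert report.seconds["A"] == pytest.approx(45 / 30.0)
        assert report.seconds["B"] == pytest.approx(75 / 30.0)

    def test_overlapping_rois_rejected_unless_declared(self):
        rois = [ROI("A", (50.0, 50.0), 30.0), ROI("B", (90.0, 50.0), 30.0)]
        frames = self._frames([(70.0, 50.0)] * 10)
        with pytest.raises(ValueError, match="overlap"):
            investigation_time(frames, rois, fps=30.0)
        report = investigation_time(frames, rois, fps=30.0, nonexclusive=True)
        assert report.seconds["A"] == report.seconds["B"] > 0


def test_preference_ttest_detects_preference():
    rng = np.random.default_rng(0)
    s_plus = rng.normal(60, 5, 11)
    s_minus = s_plus - rng.normal(15, 2, 11)
    res = preference_ttest(s_plus, s_minus)
    assert res.pvalue < 0.05
    ref = sp_stats.ttest_rel(s_plus, s_minus, alternative="greater")
    assert res.pvalue == ref.pvalue
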