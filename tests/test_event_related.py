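import numpy as np
import pytest

import lamvaso as lv
from lamvaso.acquisition import Trial
from lamvaso.io import VolumeSeries

BLOCK = 0.785
CYCLE = 4 * BLOCK


def upsampled_series(values, contrast="vaso", t0=BLOCK):
    return VolumeSeries(np.asarray(values, dtype=float), contrast, BLOCK, t0)


class TestExtractTrials:
    def test_window_arithmetic(self):
        series = upsampled_series(np.arange(100.0), t0=0.0)
        onset = 40 * BLOCK
        windows = lv.extract_trials(series, [Trial(onset, 2.0, 0, 10.0)])
        w = windows[0]
        assert w.onset_index == 40
        assert w.n_samples == round(12.0 / BLOCK)  # 15 samples
        np.testing.assert_array_equal(w.values, np.arange(40.0, 55.0))
        assert not w.truncated

    def test_four_jitters_have_distinct_native_phases(self):
        series = upsampled_series(np.zeros(400), t0=BLOCK)
        trials = [Trial(10 * CYCLE + j * BLOCK, 2.0, j, 10.0) for j in range(4)]
        windows = lv.extract_trials(series, trials)
        phases = {w.native_phase for w in windows}
        assert phases == {0, 1, 2, 3}
        # onset indices differ by exactly one block
        onsets = sorted(w.onset_index for w in windows)
        assert np.all(np.diff(onsets) == 1)

    def test_empty_design(self):
        series = upsampled_series(np.zeros(50))
        assert lv.extract_trials(series, []) == []

    def test_trial_past_run_end_truncated(self):
        series = upsampled_series(np.ones(50), t0=0.0)
        windows = lv.extract_trials(series, [Trial(40 * BLOCK, 4.0, 0, 20.0)])
        w = windows[0]
        assert w.truncated
        assert np.isfinite(w.values[:10]).all()
        assert np.isnan(w.values[10:]).all()

    def test_off_grid_onset_rejected(self):
        series = upsampled_series(np.zeros(50), t0=0.0)
        with pytest.raises(ValueError):
            lv.extract_trials(series, [Trial(1.0, 2.0, 0, 10.0)])


def brute_force_average(windows, interleave=True):
    """Independent per-timepoint loop oracle for average_trials."""
    length = max(w.n_samples for w in windows)
    out = np.full(length, np.nan)
    n = np.zeros(length)
    for k in range(length):
        acc = 0.0
        cnt = 0
        for w in windows:
            if k >= w.n_samples or not np.isfinite(w.values[k]):
                continue
            if interleave and (k % w.factor) != w.native_phase:
                continue
            acc += w.values[k]
            cnt += 1
        if cnt:
            out[k] = acc / cnt
            n[k] = cnt
    return out, n


def random_windows(rng, n_windows):
    windows = []
    for _ in range(n_windows):
        length = rng.integers(6, 30)
        vals = rng.normal(size=length)
        if rng.random() < 0.3:  # truncated tail
            vals[rng.integers(1, length):] = np.nan
        i0 = int(rng.integers(0, 200))
        windows.append(
            lv.TrialWindow(
                values=vals,
                duration_s=2.0,
                jitter_index=int(rng.integers(0, 4)),
                onset_index=i0,
                native_phase=(-i0) % 4,
                factor=4,
                truncated=bool(np.isnan(vals).any()),
            )
        )
    return windows


class TestAverageTrials:
    def test_single_window_is_identity(self):
        rng = np.random.default_rng(0)
        w = random_windows(rng, 1)
        w[0].values[:] = rng.normal(size=w[0].n_samples)  # no NaN
        eras = lv.average_trials(w, BLOCK, "vaso", interleave=False)
        np.testing.assert_allclose(eras[2.0].value, w[0].values)

    def test_opposite_trials_cancel(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=12)
        mk = lambda v: lv.TrialWindow(v.copy(), 2.0, 0, 0, 0, 4)
        eras = lv.average_trials([mk(vals), mk(-vals)], BLOCK, "vaso",
                                 interleave=False)
        np.testing.assert_allclose(eras[2.0].value, 0.0, atol=1e-12)

    @pytest.mark.parametrize("interleave", [True, False])
    def test_matches_brute_force_oracle(self, interleave):
        rng = np.random.default_rng(2)
        for _ in range(100):
            windows = random_windows(rng, int(rng.integers(1, 9)))
            eras = lv.average_trials(windows, BLOCK, "vaso",
                                     interleave=interleave)
            expected, n = brute_force_average(windows, interleave)
            got = eras[2.0]
            np.testing.assert_allclose(got.value, expected, atol=1e-12)
            np.testing.assert_array_equal(got.n, n)

    def test_jitter_interleaving_reconstructs_fine_curve(self):
        """4 jittered noise-free trials of a smooth response reconstruct it
        at 4x the volume rate."""
        p = lv.ResponseParams(0.02, 5.0, 2.5)
        n = 300
        t_native = np.arange(n) * CYCLE + BLOCK
        trials = [Trial((20 + 40 * j) * CYCLE + j * BLOCK, 4.0, j, 20.0)
                  for j in range(4)]

        def signal(t):
            return sum(p.response(t - tr.onset_s, 4.0) for tr in trials)

        native = VolumeSeries(signal(t_native), "nulled", CYCLE, BLOCK)
        up = lv.upsample_temporal(native, 4)
        windows = lv.extract_trials(up, trials)
        era = lv.average_trials(windows, BLOCK, "nulled")[4.0]
        truth = np.stack([signal(era.time_s + tr.onset_s) for tr in trials])
        np.testing.assert_allclose(era.value, truth.mean(axis=0), atol=1e-12)


class TestBaseline:
    def test_constant_run(self):
        s = upsampled_series(np.full((2, 100), 100.0))
        assert np.all(lv.baseline([s]) == 100.0)

    def test_mid_run_bump_ignored(self):
        data = np.full(120, 100.0)
        k = int(30.0 / BLOCK)
        data[k + 5:k + 15] = 150.0  # task bump outside both edge windows
        assert lv.baseline([upsampled_series(data)]) == pytest.approx(100.0)

    def test_two_runs_average(self):
        a = upsampled_series(np.full(100, 90.0))
        b = upsampled_series(np.full(100, 110.0))
        assert lv.baseline([a, b]) == pytest.approx(100.0)

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            lv.baseline([upsampled_series(np.ones(10))])


class TestPercentSignalChange:
    def era(self, values, contrast="vaso"):
        values = np.asarray(values, dtype=float)
        return lv.EventRelatedAverage(
            time_s=np.arange(values.shape[-1]) * BLOCK,
            value=values,
            n=np.ones(values.shape[-1]),
            duration_s=2.0,
            contrast=contrast,
        )

    def test_signal_equal_baseline_gives_100(self):
        out = lv.percent_signal_change(self.era(np.full(5, 42.0), "bold"), 42.0)
        np.testing.assert_allclose(out.value, 100.0)

    def test_vaso_inversion_makes_cbv_positive(self):
        v = 0.02
        out = lv.percent_signal_change(self.era([1.0, 1.0 - v]), 1.0)
        zeroed = lv.zero_first(out)
        assert zeroed.value[1] == pytest.approx(2.0)

    def test_doubling_baseline_halves_values(self):
        era = self.era(np.ones(4), "bold")
        one = lv.percent_signal_change(era, 1.0)
        two = lv.percent_signal_change(era, 2.0)
        np.testing.assert_allclose(one.value, 2 * two.value)

    def test_invalid_baseline_excluded(self):
        era = self.era(np.ones((2, 4)), "bold")
        out = lv.percent_signal_change(era, np.array([1.0, 0.0]))
        assert np.isfinite(out.value[0]).all()
        assert np.isnan(out.value[1]).all()


class TestStitchAndZero:
    def era(self, values, segment_len=None):
        values = np.asarray(values, dtype=float)
        return lv.EventRelatedAverage(
            time_s=np.arange(values.shape[-1]) * BLOCK,
            value=values,
            n=np.ones(values.shape[-1]),
            duration_s=2.0,
            contrast="vaso",
        )

    def test_offset_removed_and_junction_equal(self):
        short = self.era([0.0, 1.0, 2.0])
        long = self.era([0.0, 1.0, 2.1, 2.3, 1.0])  # +0.3 offset at junction
        out = lv.stitch_iti(short, long)
        # short-covered samples untouched
        np.testing.assert_array_equal(out.value[:3], short.value)
        # junction pair equal; long-only shape preserved
        assert out.value[3] == pytest.approx(out.value[2])
        assert out.value[4] == pytest.approx(1.0 - 0.3)
        np.testing.assert_array_equal(out.segment[:3], ["short"] * 3)
        np.testing.assert_array_equal(out.segment[3:], ["long_only"] * 2)

    def test_zero_offset_identity(self):
        # the first long-only point already equals the last short point
        short = self.era([0.0, 1.0, 2.0])
        long = self.era([0.0, 1.0, 2.2, 2.0, 1.5])
        out = lv.stitch_iti(short, long)
        np.testing.assert_allclose(out.value, [0.0, 1.0, 2.0, 2.0, 1.5])

    def test_junction_pair_takes_equal_values(self):
        short = self.era([0.0, 2.0])
        long = self.era([0.5, 2.7, 3.1, 2.0])
        out = lv.stitch_iti(short, long)
        assert out.value[1] == pytest.approx(out.value[2])

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            lv.stitch_iti(self.era([0.0, 1.0, 2.0]), self.era([0.0, 1.0]))

    def test_zero_first_example(self):
        out = lv.zero_first(self.era([100.0, 102.0, 101.0]))
        np.testing.assert_allclose(out.value, [0.0, 2.0, 1.0])
        assert out.zeroed

    def test_zero_first_idempotent(self):
        once = lv.zero_first(self.era([100.0, 102.0, 101.0]))
        twice = lv.zero_first(once)
        np.testing.assert_array_equal(once.value, twice.value)


def test_stitched_two_iti_pipeline_matches_long_reference(small_geometry):
    """Short- and long-ITI sessions stitched at the junction reproduce the
    long-session noise-free curve despite a baseline offset."""
    acq = lv.AcquisitionScheme()
    model = lv.CompartmentModel(noise_sd=0.0)
    gm = small_geometry.gm_mask

    def session_era(iti_class, dur):
        des = lv.make_design(acq, n_runs=1, iti_class=iti_class, seed=6)
        sim = lv.simulate_run(small_geometry, des, acq, model)
        vaso = lv.boco(lv.upsample_temporal(sim.nulled, 4),
                       lv.upsample_temporal(sim.bold, 4))
        course = VolumeSeries(vaso.data[gm].mean(axis=0), "vaso",
                              vaso.dt_s, vaso.t0_s)
        windows = lv.extract_trials(course, des.runs[0])
        era = lv.average_trials(windows, vaso.dt_s, "vaso")[dur]
        return lv.percent_signal_change(era, lv.baseline([course]))

    dur = 4.0
    era_short = session_era("short", dur)
    era_long = session_era("long", dur)
    # emulate a session-specific baseline offset on the long-ITI data
    shifted = lv.EventRelatedAverage(
        time_s=era_long.time_s, value=era_long.value + 0.4, n=era_long.n,
        duration_s=dur, contrast="vaso",
    )
    stitched = lv.zero_first(lv.stitch_iti(era_short, shifted))
    reference = lv.zero_first(era_long)
    ls = era_short.value.size
    # long-only samples recover the unshifted long-session curve up to the
    # value at the junction being matched to the short segment
    np.testing.assert_allclose(
        stitched.value[ls:] - stitched.value[ls - 1],
        reference.value[ls:] - reference.value[ls],
        atol=5e-3,
    )
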