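import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dttbp import (
    BaselineEstimate,
    CuffCalibration,
    baseline_offset,
    calibrate_m0,
    correct_and_extract,
    delineate_beats,
    estimate_dbp,
    moving_median,
    run_dtt_pipeline,
    to_pressure_units,
)
from dttbp.studies import cuff_from_truth, truth_bp_frame
from dttbp.waveform import WaveformRecording

from conftest import make_beat_table


class TestCalibrateM0:
    def test_worked_example(self, identical_beats, cuff_120_80):
        """Five identical beats, cuff 120/80: m0 = (40/2.0)*(2.0/0.7)."""
        cal = calibrate_m0(identical_beats, cuff_120_80, n=5)
        assert cal.m0 == pytest.approx(40.0 / 2.0 * 2.0 / 0.7, rel=1e-12)
        assert cal.m0 == pytest.approx(57.142857, abs=1e-6)
        assert cal.c0 == pytest.approx(10.0)
        assert cal.gain == pytest.approx(20.0)

    def test_sensor_scale_invariance_of_m0(self, cuff_120_80):
        """Doubling all sensor values leaves m0 unchanged (Eq. is unit-free)."""
        b1 = make_beat_table(peak_v=3.0, trough_v=1.0)
        b2 = make_beat_table(peak_v=6.0, trough_v=2.0)
        m1 = calibrate_m0(b1, cuff_120_80).m0
        m2 = calibrate_m0(b2, cuff_120_80).m0
        assert m1 == pytest.approx(m2, rel=1e-12)

    def test_pressure_anchoring(self, identical_beats, cuff_120_80):
        """gain 20 mmHg/u with trough 1.0 u -> 80 mmHg maps peak 3.0 u -> 120."""
        cal = calibrate_m0(identical_beats, cuff_120_80)
        assert cal.gain * 3.0 + cal.offset == pytest.approx(120.0)
        assert cal.gain * 1.0 + cal.offset == pytest.approx(80.0)

    def test_zero_dtt_beat_rejected(self, cuff_120_80):
        beats = make_beat_table()
        beats.loc[2, "dtt_s"] = 0.0
        with pytest.raises(ValueError, match="DTT"):
            calibrate_m0(beats, cuff_120_80)

    def test_too_few_beats_rejected(self, cuff_120_80):
        with pytest.raises(ValueError, match="calibration needs"):
            calibrate_m0(make_beat_table(n=3), cuff_120_80, n=5)

    def test_invalid_cuff_rejected(self):
        with pytest.raises(ValueError, match="SBP0 > DBP0"):
            CuffCalibration(sbp0=80.0, dbp0=80.0)


class TestEstimateDbp:
    @pytest.fixture
    def cal(self, identical_beats, cuff_120_80):
        return calibrate_m0(identical_beats, cuff_120_80)

    def test_calibration_identity(self, cal, identical_beats, cuff_120_80):
        """At the calibration operating point eDBP equals DBP0 exactly."""
        edbp = estimate_dbp(identical_beats, cal, cuff_120_80)
        np.testing.assert_allclose(edbp, 80.0, atol=1e-9)

    def test_shorter_dtt_raises_edbp(self, cal, cuff_120_80):
        beats = make_beat_table(dtt=0.6)
        edbp = estimate_dbp(beats, cal, cuff_120_80)
        assert edbp[0] == pytest.approx(120.0 - 57.142857 * 0.6, abs=1e-4)
        assert edbp[0] == pytest.approx(85.714, abs=1e-3)

    def test_contractility_ratio_scales_dtt(self, cal, cuff_120_80):
        beats = make_beat_table(contractility=20.0)  # C/C0 = 2
        edbp = estimate_dbp(beats, cal, cuff_120_80)
        assert edbp[0] == pytest.approx(120.0 - 57.142857 * 0.7 / 2.0, abs=1e-4)
        assert edbp[0] == pytest.approx(100.0, abs=1e-3)

    def test_monotone_in_dtt_and_contractility(self, cal, cuff_120_80):
        dtts = np.linspace(0.4, 0.9, 6)
        e = [estimate_dbp(make_beat_table(dtt=v), cal, cuff_120_80)[0] for v in dtts]
        assert np.all(np.diff(e) < 0)
        cs = np.linspace(5.0, 30.0, 6)
        e = [estimate_dbp(make_beat_table(contractility=v), cal, cuff_120_80)[0] for v in cs]
        assert np.all(np.diff(e) > 0)

    def test_nonpositive_contractility_gives_nan(self, cal, cuff_120_80):
        beats = make_beat_table()
        beats.loc[1, "contractility"] = -1.0
        edbp = estimate_dbp(beats, cal, cuff_120_80)
        assert np.isnan(edbp[1]) and np.isfinite(edbp[0])


class TestToPressureUnits:
    def test_affine_map(self, identical_beats, cuff_120_80):
        cal = calibrate_m0(identical_beats, cuff_120_80)
        rec = WaveformRecording(np.array([1.0, 3.0]), fs=250.0, units="sensor")
        out = to_pressure_units(rec, cal)
        np.testing.assert_allclose(out.samples, [80.0, 120.0])
        assert out.units == "mmHg"

    def test_mmhg_input_warns_and_passes_through(self, identical_beats, cuff_120_80):
        cal = calibrate_m0(identical_beats, cuff_120_80)
        rec = WaveformRecording(np.array([1.0, 3.0]), fs=250.0, units="mmHg")
        with pytest.warns(UserWarning, match="already in mmHg"):
            out = to_pressure_units(rec, cal)
        np.testing.assert_array_equal(out.samples, rec.samples)


class TestMovingMedian:
    def test_worked_example(self):
        np.testing.assert_allclose(
            moving_median([1, 9, 2, 8, 3], window=3), [5.0, 2.0, 8.0, 3.0, 5.5]
        )

    def test_constant_series_unchanged(self):
        np.testing.assert_array_equal(moving_median(np.full(40, 7.0), 30), np.full(40, 7.0))

    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(moving_median(x, 1), x)

    def test_empty_input(self):
        assert moving_median(np.array([]), 30).size == 0

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=80),
        window=st.integers(1, 40),
    )
    def test_matches_bruteforce_oracle(self, data, window):
        x = np.asarray(data)
        got = moving_median(x, window)
        left, right = (window - 1) // 2, window // 2
        expected = [
            float(np.sort(x[max(0, i - left) : min(x.size, i + right + 1)])[
                (min(x.size, i + right + 1) - max(0, i - left)) // 2
            ])
            if (min(x.size, i + right + 1) - max(0, i - left)) % 2 == 1
            else float(np.mean(np.sort(x[max(0, i - left) : min(x.size, i + right + 1)])[
                [(min(x.size, i + right + 1) - max(0, i - left)) // 2 - 1,
                 (min(x.size, i + right + 1) - max(0, i - left)) // 2]
            ]))
            for i in range(x.size)
        ]
        np.testing.assert_allclose(got, expected)


class TestBaselineOffset:
    def test_zero_offset_when_raw_equals_estimate(self):
        x = np.full(50, 80.0)
        base = baseline_offset(x, x)
        np.testing.assert_array_equal(base.raw_offset, 0.0)
        np.testing.assert_array_equal(base.smoothed_offset, 0.0)

    def test_median_tracks_linear_ramp(self):
        """A 0->10 mmHg ramp over 100 beats is tracked within the 15-beat lag."""
        edbp = np.full(100, 80.0)
        ramp = np.linspace(0.0, 10.0, 100)
        base = baseline_offset(edbp + ramp, edbp, window=30)
        increment_15 = 15 * 10.0 / 99
        assert np.max(np.abs(base.smoothed_offset - ramp)) <= increment_15 + 1e-9

    def test_median_rejects_single_outlier(self):
        edbp = np.full(100, 80.0)
        raw = edbp.copy()
        raw[40] += 50.0
        base = baseline_offset(raw, edbp, window=30)
        mask = np.ones(100, dtype=bool)
        np.testing.assert_array_equal(np.delete(base.smoothed_offset, 40), 0.0)
        assert base.smoothed_offset[40] == 0.0  # median of the window is still 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal lengths"):
            baseline_offset(np.zeros(5), np.zeros(6))


class TestCorrectAndExtract:
    def test_map_formula(self):
        """MAP = DBP + (SBP - DBP)/3: 120/80 -> 93.333; degenerate 100/100 -> 100."""
        assert 80.0 + (120.0 - 80.0) / 3.0 == pytest.approx(93.333333, abs=1e-5)
        bp = pd.DataFrame({"sbp": [120.0, 100.0], "dbp": [80.0, 100.0]})
        m = bp["dbp"] + (bp["sbp"] - bp["dbp"]) / 3.0
        assert m.iloc[0] == pytest.approx(93.3333, abs=1e-3)
        assert m.iloc[1] == pytest.approx(100.0)

    def test_known_offsets_fully_corrected(self):
        """Feeding the true wander as the baseline recovers true DBP on >=95%
        of beats within 1 mmHg."""
        from dttbp import SimConfig, simulate_recording

        cfg = SimConfig(duration_s=120.0, fs=250.0, hr_bpm=70.0,
                        sbp_mmHg=120.0, dbp_mmHg=80.0, seed=9)
        rec, truth = simulate_recording(cfg)
        beats = delineate_beats(rec)
        kept = beats[beats["valid"]].reset_index(drop=True)
        cuff = cuff_from_truth(truth)
        cal = calibrate_m0(kept, cuff)
        rec_p = to_pressure_units(rec, cal)
        w = truth.wander_trace * cal.gain  # true offsets in pressure units
        end_idx = kept["end_idx"].to_numpy()
        exact = BaselineEstimate(
            raw_offset=w[end_idx], smoothed_offset=w[end_idx],
            beat_t=kept["end_t"].to_numpy(),
        )
        bp = correct_and_extract(rec_p, kept, exact)
        tref = truth_bp_frame(truth)
        j = np.searchsorted(tref["t"].to_numpy(), bp["t"].to_numpy())
        j = np.clip(j, 1, len(tref) - 1)
        tt = tref["t"].to_numpy()
        j = np.where(np.abs(tt[j] - bp["t"]) < np.abs(tt[j - 1] - bp["t"]), j, j - 1)
        err = np.abs(bp["dbp"].to_numpy() - tref["dbp"].to_numpy()[j])
        assert np.mean(err <= 1.0) >= 0.95

    def test_output_ordering(self, default_sim):
        rec, truth = default_sim
        res = run_dtt_pipeline(rec, cuff_from_truth(truth))
        ok = res.bp[~res.bp["excluded"]]
        assert (ok["dbp"] < ok["map"]).all()
        assert (ok["map"] < ok["sbp"]).all()

    def test_outlier_beats_marked_excluded(self, default_sim):
        rec, truth = default_sim
        res = run_dtt_pipeline(rec, cuff_from_truth(truth))
        bp = res.bp.copy()
        # manufacture one gross outlier and re-run the exclusion rule
        from dttbp.dtt_engine import moving_median as mm

        sbp = bp["sbp"].to_numpy().copy()
        sbp[40] += 50.0
        dev = np.abs(sbp - mm(sbp, 30))
        assert dev[40] > 10.0


class TestPipelineInvariants:
    def test_calibration_closure(self, clean_sim):
        """Mean eDBP of the five calibration beats equals DBP0 to 1e-6 mmHg."""
        rec, truth = clean_sim
        res = run_dtt_pipeline(rec, CuffCalibration(120.0, 80.0))
        assert res.bp["edbp"].iloc[:5].mean() == pytest.approx(80.0, abs=1e-6)

    def test_additive_offset_leaves_intrabeat_features_unchanged(self, clean_sim):
        """DTT, contractility and pulse amplitude ignore additive constants."""
        rec, _ = clean_sim
        b1 = delineate_beats(rec)
        b2 = delineate_beats(rec.with_samples(rec.samples + 500.0))
        np.testing.assert_array_equal(b1["dtt_s"], b2["dtt_s"])
        np.testing.assert_allclose(b1["contractility"], b2["contractility"], rtol=1e-9)
        np.testing.assert_allclose(b1["pulse_amp"], b2["pulse_amp"], rtol=1e-9)

    def test_correction_idempotent(self):
        """Re-running the engine on a wander-corrected recording finds <1 mmHg
        residual offsets (median smoothing is idempotent on the residual)."""
        from dttbp import SimConfig, WanderSpec, simulate_recording

        cfg = SimConfig(
            duration_s=300.0, fs=250.0, hr_bpm=72.0, sbp_mmHg=125.0, dbp_mmHg=78.0,
            hrv_sd_s=0.0, bpv_sd_mmHg=0.0, resp_amp_mmHg=0.0,
            wander=WanderSpec("random_walk", amplitude=8.0),
            sensor={"gain": 1.0, "offset": 0.0, "noise_sd": 0.0}, seed=13,
        )
        rec, truth = simulate_recording(cfg)
        cuff = cuff_from_truth(truth)
        res1 = run_dtt_pipeline(rec, cuff)
        with pytest.warns(UserWarning, match="already in mmHg"):
            res2 = run_dtt_pipeline(res1.corrected, cuff)
        assert np.max(np.abs(res2.baseline.smoothed_offset)) < 1.0

    def test_pipeline_tracks_truth_under_wander(self, default_sim):
        rec, truth = default_sim
        res = run_dtt_pipeline(rec, cuff_from_truth(truth))
        from dttbp import pair_series

        pairs = pair_series(res.bp, truth_bp_frame(truth))
        err = pairs["est_dbp"] - pairs["ref_dbp"]
        assert abs(err.mean()) < 5.0
        assert err.std() < 8.0
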