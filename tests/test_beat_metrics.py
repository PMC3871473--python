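import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiopower.beat_metrics import (
    CycleSpan,
    alpha_calibration,
    apply_alpha,
    beat_summary,
    detect_r_peaks,
    oscillatory_fraction,
    power_curve,
    pwr_integral,
    segment_cycles,
    segment_record,
    stroke_volume_from_conductance,
    stroke_volume_from_flow,
    stroke_work,
)
from cardiopower.errors import CalibrationError, SegmentationError
from cardiopower.hemo_sim import measurement_model, simulate_record
from cardiopower.signal_io import WaveformRecord, to_si


def _record_from(p_ao, q_ao, fs=1000.0, ecg=None, p_lv=None, v_lv=None, **meta):
    n = len(p_ao)
    return WaveformRecord(
        fs=fs,
        ecg=np.zeros(n) if ecg is None else ecg,
        p_ao=np.asarray(p_ao, dtype=float),
        q_ao=np.asarray(q_ao, dtype=float),
        p_lv=np.zeros(n) if p_lv is None else p_lv,
        v_lv=np.full(n, 50.0) if v_lv is None else v_lv,
        meta=meta,
    )


class TestDetectRPeaks:
    def test_impulse_train_exact(self):
        fs = 1000.0
        truth = np.array([300, 900, 1500, 2100])
        ecg = np.zeros(2500)
        ecg[truth] = 1.0
        assert np.array_equal(detect_r_peaks(ecg, fs), truth)

    def test_flat_signal_raises(self):
        with pytest.raises(SegmentationError, match="flat"):
            detect_r_peaks(np.zeros(2000), 1000.0)

    def test_too_short_raises(self):
        with pytest.raises(SegmentationError, match="1 s"):
            detect_r_peaks(np.zeros(500), 1000.0)

    def test_noisy_recovery_within_2_samples(self, rng):
        fs = 1000.0
        truth = np.arange(200, 5000, 640)
        ecg = np.zeros(5200)
        ecg[truth] = 1.0
        noisy = ecg + rng.normal(0, 0.10, size=len(ecg))  # SD = 10% of spike
        found = detect_r_peaks(noisy, fs)
        assert len(found) == len(truth)
        assert np.all(np.abs(found - truth) <= 2)

    def test_refractory_period(self):
        ecg = np.zeros(2000)
        ecg[[500, 550, 1200]] = 1.0  # 50 ms apart: inside refractory
        found = detect_r_peaks(ecg, 1000.0)
        assert len(found) == 2


class TestSegmentCycles:
    def test_direct_construction(self):
        rec = _record_from(np.zeros(1300), np.zeros(1300))
        spans = segment_cycles(rec, [0, 600, 1200])
        assert spans == [CycleSpan(0, 600), CycleSpan(600, 1200)]

    def test_single_peak_raises(self):
        rec = _record_from(np.zeros(1300), np.zeros(1300))
        with pytest.raises(SegmentationError):
            segment_cycles(rec, [600])

    def test_non_increasing_raises(self):
        rec = _record_from(np.zeros(1300), np.zeros(1300))
        with pytest.raises(SegmentationError):
            segment_cycles(rec, [600, 600])

    def test_simulated_record_known_cycle_count(self, baseline_record, quiet_cfg):
        # onset 0 is undetectable (record edge), so n_cycles onsets give
        # n_cycles - 2 fully bracketed cycles
        spans = segment_record(baseline_record)
        assert len(spans) == quiet_cfg.n_cycles - 2
        truth = baseline_record.meta["r_onset_samples"][1:]
        assert [s.start for s in spans] == truth[:-1]


class TestPowerCurve:
    def test_hand_value(self):
        pwr = power_curve(np.array([100.0]), np.array([5.0]))
        assert pwr[0] == pytest.approx(1.1110, rel=1e-4)

    def test_zero_flow_zero_power(self):
        pwr = power_curve(np.full(100, 90.0), np.zeros(100))
        assert np.all(pwr == 0.0)

    def test_bilinearity(self, rng):
        p = 80 + 40 * rng.random(200)
        q = 6 * rng.random(200)
        assert np.allclose(power_curve(2 * p, q), 2 * power_curve(p, q))
        assert np.allclose(power_curve(p, 3 * q), 3 * power_curve(p, q))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            power_curve(np.zeros(5), np.zeros(6))


class TestPwrIntegral:
    def test_constant_power_closed_form(self):
        # constant 1.1110 W over exactly 1.000 s
        pwr = np.full(1500, 1.1110)
        assert pwr_integral(pwr, CycleSpan(0, 1000), 1000.0) == pytest.approx(1.1110, rel=1e-12)

    def test_half_sine_closed_form(self):
        # q(t) = Q0 sin(pi t / Ts) under constant pressure P on [0, Ts]:
        # integral = P_SI * Q0_SI * 2 Ts / pi
        fs, Ts, P, Q0 = 1000.0, 0.4, 90.0, 6.0
        t = np.arange(0, int(Ts * fs) + 1) / fs
        q = Q0 * np.sin(np.pi * t / Ts)
        pwr = power_curve(np.full_like(t, P), q)
        expected = to_si(P, "mmHg") * to_si(Q0, "L/min") * 2.0 * Ts / math.pi
        got = pwr_integral(pwr, CycleSpan(0, int(Ts * fs)), fs)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_zero_flow_zero_energy(self):
        assert pwr_integral(np.zeros(2000), CycleSpan(100, 900), 1000.0) == 0.0

    def test_short_span_raises(self):
        with pytest.raises(ValueError):
            pwr_integral(np.ones(10), CycleSpan(9, 10), 1000.0)

    def test_trapezoid_vs_high_res_rectangle_oracle(self, baseline_record):
        # independent oracle: resample power to 10 kHz and rectangle-rule it
        pwr = power_curve(baseline_record.p_ao, baseline_record.q_ao)
        spans = segment_record(baseline_record)
        fs = baseline_record.fs
        for span in spans[:3]:
            seg = pwr[span.start : span.end + 1]
            t = np.arange(len(seg)) / fs
            t_hi = np.linspace(0.0, t[-1], len(seg) * 10)
            rect = float(np.sum(np.interp(t_hi, t, seg)) * (t_hi[1] - t_hi[0]))
            trap = pwr_integral(pwr, span, fs)
            assert trap == pytest.approx(rect, rel=1e-3)


class TestStrokeWork:
    def test_rectangle_loop(self):
        # P: 0 <-> 100 mmHg, V: 40 <-> 100 mL -> 13332.2 Pa * 6e-5 m3
        p = np.array([0.0, 100.0, 100.0, 0.0])
        v = np.array([100.0, 100.0, 40.0, 40.0])
        assert stroke_work(p, v, CycleSpan(0, 4)) == pytest.approx(0.79993, rel=1e-4)

    def test_collinear_loop_zero(self):
        p = np.linspace(0, 50, 100)
        v = np.full(100, 70.0)
        assert stroke_work(p, v, CycleSpan(0, 100)) == 0.0

    def test_ellipse_oracle(self):
        # semi-axes a mmHg x b mL -> pi a b in SI
        a, b, n = 45.0, 25.0, 1000
        th = 2 * np.pi * np.arange(n) / n
        p = 60 + a * np.sin(th)
        v = 55 + b * np.cos(th)
        expected = math.pi * to_si(a, "mmHg") * to_si(b, "mL")
        assert stroke_work(p, v, CycleSpan(0, n)) == pytest.approx(expected, rel=1e-3)

    @given(shift=st.integers(1, 999))
    @settings(max_examples=25, deadline=None)
    def test_starting_point_invariance(self, shift):
        n = 1000
        th = 2 * np.pi * np.arange(n) / n
        p = 60 + 45 * np.sin(th) + 5 * np.sin(3 * th)
        v = 55 + 25 * np.cos(th)
        ref = stroke_work(p, v, CycleSpan(0, n))
        rolled = stroke_work(np.roll(p, shift), np.roll(v, shift), CycleSpan(0, n))
        assert abs(rolled - ref) / ref < 1e-9

    def test_direction_invariance(self):
        n = 500
        th = 2 * np.pi * np.arange(n) / n
        p, v = 60 + 45 * np.sin(th), 55 + 25 * np.cos(th)
        assert stroke_work(p, v, CycleSpan(0, n)) == pytest.approx(
            stroke_work(p[::-1].copy(), v[::-1].copy(), CycleSpan(0, n))
        )

    def test_degenerate_span(self):
        with pytest.raises(ValueError, match="degenerate"):
            stroke_work(np.ones(10), np.ones(10), CycleSpan(0, 2))


class TestAlphaCalibration:
    def test_direct_ratio(self):
        af = alpha_calibration([(66.0, 60.0), (66.0, 60.0)])
        assert af.alpha == pytest.approx(1.1)
        assert af.n_cycles_used == 2

    def test_identity(self):
        af = alpha_calibration([(45.0, 45.0)])
        assert af.alpha == pytest.approx(1.0)

    def test_nonpositive_sv_raises(self):
        with pytest.raises(CalibrationError):
            alpha_calibration([(50.0, 0.0)])
        with pytest.raises(CalibrationError):
            alpha_calibration([])

    @pytest.mark.parametrize("fs,tol", [(1000.0, 1e-4), (8000.0, 1e-6)])
    def test_generator_gain_recovery(self, base_animal, fs, tol):
        # noise-free, alpha_true = 1.2: the gain and the post-calibration
        # SW come back to the generator truth up to the O(h^2)
        # discretization floor of the sampling grid (~1e-5 at 1 kHz)
        from cardiopower.hemo_sim import SimConfig

        cfg = SimConfig(fs=fs, seed=42).noise_free()
        animal = dataclasses.replace(base_animal, alpha_true=1.2, volume_offset=15.0)
        true_rec = simulate_record(animal, None, cfg)
        measured = measurement_model(true_rec, animal, cfg)
        spans = segment_record(measured)
        pairs = [
            (
                stroke_volume_from_conductance(measured.v_lv, s),
                stroke_volume_from_flow(measured.q_ao, s, measured.fs),
            )
            for s in spans
        ]
        af = alpha_calibration(pairs)
        assert af.alpha == pytest.approx(1.2, abs=tol)
        calibrated = apply_alpha(measured, af)
        for s in spans:
            sw_cal = stroke_work(calibrated.p_lv, calibrated.v_lv, s)
            sw_true = stroke_work(true_rec.p_lv, true_rec.v_lv, s)
            assert sw_cal == pytest.approx(sw_true, rel=10 * tol)


class TestBeatSummary:
    def test_one_row_per_span(self, baseline_record):
        spans = segment_record(baseline_record)
        table = beat_summary(baseline_record, spans)
        assert len(table) == len(spans)
        assert list(table["cycle_index"]) == list(range(len(spans)))

    def test_steady_flow_limit(self):
        # constant pressure and flow: CPO equals the power integral per
        # second equals the hand-computed 1.1110 W
        n, fs = 3000, 1000.0
        ecg = np.zeros(n)
        ecg[[500, 1500, 2500]] = 1.0
        rec = _record_from(np.full(n, 100.0), np.full(n, 5.0), fs=fs, ecg=ecg)
        spans = segment_record(rec)
        table = beat_summary(rec, spans)
        assert table["cpo_W"].iloc[0] == pytest.approx(1.1110, rel=1e-4)
        per_second = table["pwr_integral_J"] / 1.0  # spans are exactly 1 s
        assert per_second.iloc[0] == pytest.approx(table["cpo_W"].iloc[0], rel=1e-6)
        assert table["map_mmHg"].iloc[0] == pytest.approx(100.0)
        assert table["co_Lmin"].iloc[0] == pytest.approx(5.0, rel=1e-3)

    def test_zero_flow_all_zero(self):
        n = 3000
        ecg = np.zeros(n)
        ecg[[500, 1500, 2500]] = 1.0
        rec = _record_from(np.full(n, 80.0), np.zeros(n), ecg=ecg)
        table = beat_summary(rec, segment_record(rec))
        assert np.allclose(table[["sv_mL", "co_Lmin", "cpo_W", "pwr_integral_J"]], 0.0)

    def test_pressure_scaling_scales_both_energies(self, baseline_record):
        spans = segment_record(baseline_record)
        t1 = beat_summary(baseline_record, spans)
        k = 1.7
        scaled = baseline_record.replace(
            p_ao=k * baseline_record.p_ao, p_lv=k * baseline_record.p_lv
        )
        t2 = beat_summary(scaled, spans)
        assert np.allclose(t2["sw_J"], k * t1["sw_J"], rtol=1e-12)
        assert np.allclose(t2["pwr_integral_J"], k * t1["pwr_integral_J"], rtol=1e-12)


class TestOscillatoryFraction:
    def test_constant_pressure_gives_zero(self):
        n, fs = 3000, 1000.0
        ecg = np.zeros(n)
        ecg[[500, 1500, 2500]] = 1.0
        t = np.arange(n) / fs
        q = 4.0 + 2.0 * np.sin(2 * np.pi * 1.0 * t)
        rec = _record_from(np.full(n, 95.0), q, fs=fs, ecg=ecg)
        f = oscillatory_fraction(rec, segment_record(rec))
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_covariance_closed_form(self):
        # p = P0 (1 + 0.2 sin), q = Q0 (1 + 0.5 sin), integer cycles:
        # f = (0.2*0.5/2) / (1 + 0.2*0.5/2) = 0.05/1.05
        fs, f_hz, n_cyc = 1000.0, 2.0, 6
        n = int(n_cyc * fs / f_hz)
        t = np.arange(n + 500) / fs
        s = np.sin(2 * np.pi * f_hz * t)
        p = 90.0 * (1 + 0.2 * s)
        q = 4.0 * (1 + 0.5 * s)
        ecg = np.zeros(len(t))
        onsets = (np.arange(n_cyc) * fs / f_hz).astype(int) + 250
        ecg[onsets] = 1.0
        rec = _record_from(p, q, fs=fs, ecg=ecg)
        f = oscillatory_fraction(rec, segment_record(rec))
        assert f == pytest.approx(0.05 / 1.05, rel=1e-3)

    def test_baseline_pig_in_target_band(self, baseline_record):
        f = oscillatory_fraction(baseline_record, segment_record(baseline_record))
        assert 0.10 <= f <= 0.20

    def test_zero_power_raises(self):
        n = 3000
        ecg = np.zeros(n)
        ecg[[500, 1500, 2500]] = 1.0
        rec = _record_from(np.full(n, 80.0), np.zeros(n), ecg=ecg)
        with pytest.raises(ValueError, match="total power"):
            oscillatory_fraction(rec, segment_record(rec))


class TestSwPwrRelationship:
    def test_pwr_at_least_sw_minus_filling(self, baseline_sim):
        # energy bookkeeping on clean signals: the aortic energy can fall
        # short of SW by at most the filling energy (plus valve loss)
        record, internals = baseline_sim
        spans = segment_record(record)
        pwr = power_curve(record.p_ao, record.q_ao)
        p_lv_si = to_si(record.p_lv, "mmHg")
        q_mit_si = to_si(internals["q_mit_mls"], "mL")  # mL/s -> m3/s
        filling = p_lv_si * q_mit_si
        for s in spans:
            sw = stroke_work(record.p_lv, record.v_lv, s)
            pi = pwr_integral(pwr, s, record.fs)
            fill = float(np.trapezoid(filling[s.start : s.end + 1], dx=1 / record.fs))
            assert pi >= sw - fill - 1e-6

    def test_noise_free_correlation_above_099(self, base_animal, quiet_cfg):
        from cardiopower.hemo_sim import ConditionSpec
        from scipy.stats import pearsonr

        sws, pwrs = [], []
        for name in ("baseline", "preload_reduced", "afterload_increased", "dobutamine"):
            rec = simulate_record(base_animal, ConditionSpec.default(name), quiet_cfg)
            spans = segment_record(rec)
            pwr = power_curve(rec.p_ao, rec.q_ao)
            for s in spans:
                sws.append(stroke_work(rec.p_lv, rec.v_lv, s))
                pwrs.append(pwr_integral(pwr, s, rec.fs))
        assert pearsonr(sws, pwrs).statistic > 0.99
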