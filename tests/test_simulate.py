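"""Synthetic generator: closed-form morphology, schedules, coupling, truth."""

import numpy as np
import pytest
from scipy import optimize
from scipy.signal import find_peaks, peak_prominences

import leapmea as lm
from conftest import FS_DESK, FS_FAST, FS_NATIVE, make_leap_trace


def apd_by_root_finding(shape, x):
    """Independent oracle: numerically invert the repolarization law."""
    if shape.family == "hill":
        f = lambda t: (t / shape.theta_ms) ** shape.h / (1 + (t / shape.theta_ms) ** shape.h) - x / 100
        hi = shape.theta_ms * 1000.0
        return optimize.brentq(f, 1e-9, hi)
    if shape.family == "linear":
        return x / 100 * shape.repol_ms
    return shape.plateau_ms


class TestTemplates:
    def test_template_shape_contract(self):
        shape = lm.APShapeParams(family="hill", rise_time_ms=2, theta_ms=200, h=3,
                                 diastolic_ms=100)
        w = lm.generate_ap_template(shape, FS_NATIVE)
        assert w[0] == 0.0 and w[-1] == 0.0
        assert w.max() == 1.0
        assert np.all((w >= 0.0) & (w <= 1.0))

    @pytest.mark.parametrize("theta", [100.0, 200.0, 300.0])
    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0, 8.0])
    def test_hill_closed_form_recovery(self, theta, h):
        """APD_x from the sampled waveform matches θ(x/(100−x))^(1/h)."""
        shape = lm.APShapeParams(family="hill", rise_time_ms=1000 / FS_NATIVE,
                                 theta_ms=theta, h=h, diastolic_ms=50)
        w = lm.generate_ap_template(shape, FS_NATIVE)
        apds = lm.compute_apd(w, FS_NATIVE, (10, 30, 50, 70, 90))
        tol = 1000 / FS_NATIVE + 0.1
        for x, val in apds.items():
            assert abs(val - shape.apd_from_onset(x)) <= tol + 1000 / FS_NATIVE

    @pytest.mark.parametrize("theta,h,x", [(250.0, 2.0, 50), (250.0, 2.0, 90),
                                           (150.0, 4.0, 70)])
    def test_hill_against_root_finding_oracle(self, theta, h, x):
        shape = lm.APShapeParams(family="hill", rise_time_ms=1000 / FS_NATIVE,
                                 theta_ms=theta, h=h, diastolic_ms=50)
        w = lm.generate_ap_template(shape, FS_NATIVE)
        apd = lm.compute_apd(w, FS_NATIVE, (x,))[x]
        oracle = apd_by_root_finding(shape, x)
        assert abs(apd - oracle) <= 2 * 1000 / FS_NATIVE + 0.1

    def test_linear_family_forces_proportional_apd(self):
        shape = lm.APShapeParams(family="linear", rise_time_ms=1000 / FS_NATIVE,
                                 plateau_ms=0, repol_ms=450, diastolic_ms=50)
        w = lm.generate_ap_template(shape, FS_NATIVE)
        apds = lm.compute_apd(w, FS_NATIVE, (50, 90))
        assert apds[50] == pytest.approx(225.0, abs=0.2)
        assert apds[90] == pytest.approx(405.0, abs=0.2)

    def test_square_family_step_repolarization(self):
        shape = lm.APShapeParams(family="square", rise_time_ms=1000 / FS_NATIVE,
                                 plateau_ms=200, diastolic_ms=50)
        w = lm.generate_ap_template(shape, FS_NATIVE)
        apds = lm.compute_apd(w, FS_NATIVE, (30, 50, 90))
        for v in apds.values():
            assert v == pytest.approx(200.0, abs=1000 / FS_NATIVE)

    @pytest.mark.parametrize("kwargs", [{"h": 0.0}, {"rise_time_ms": -1.0},
                                        {"family": "sigmoid"}])
    def test_invalid_shape_params(self, kwargs):
        with pytest.raises(ValueError):
            lm.APShapeParams(**kwargs)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            lm.generate_ap_template(lm.APShapeParams(), 0.0)


class TestBeatSchedules:
    def test_zero_cov_is_perfectly_regular(self):
        t = lm.generate_beat_times(lm.BeatSchedule(mean_bp_ms=1000, cov_percent=0), 10)
        np.testing.assert_array_equal(t, np.arange(0, 10000, 1000.0))

    def test_paced_returns_stimulus_train(self):
        stim = np.arange(0, 5000, 500.0)
        sched = lm.BeatSchedule(mode="paced", stimulus_times_ms=stim)
        t = lm.generate_beat_times(sched, 5)
        np.testing.assert_array_equal(t, stim)
        assert np.all(np.diff(t) == 500.0)

    def test_sample_cov_matches_setting(self):
        """A spontaneously varying train reproduces the requested CoV."""
        sched = lm.BeatSchedule(mean_bp_ms=1000, cov_percent=8.47)
        t = lm.generate_beat_times(sched, 502, rng=0)
        mean, cov = lm.compute_bp_cov(t)
        assert abs(cov - 8.47) <= 2.0
        assert mean == pytest.approx(1000, rel=0.02)

    def test_extreme_cov_rejected(self):
        sched = lm.BeatSchedule(mean_bp_ms=50, cov_percent=100.0)
        with pytest.raises(ValueError, match="rejection"):
            lm.generate_beat_times(sched, 600, rng=0)

    def test_strictly_increasing_under_high_cov(self):
        sched = lm.BeatSchedule(mean_bp_ms=1000, cov_percent=40.0)
        t = lm.generate_beat_times(sched, 120, rng=3)
        assert np.all(np.diff(t) > 0)


class TestElectrodeTraces:
    def test_noiseless_leap_amplitude_exact(self):
        tr, _ = make_leap_trace(amplitude_uV=1000.0)
        assert tr.max() - tr.min() == pytest.approx(1000.0, abs=1e-9)

    def test_electroporation_decay_closed_form(self):
        """2000 µV decaying with τ=30 s is at FP scale two minutes later."""
        shape = lm.APShapeParams(family="hill", rise_time_ms=3, theta_ms=150, h=3,
                                 diastolic_ms=100)
        coup = lm.CouplingParams(mode="electroporation", amplitude_uV=2000,
                                 decay_tau_s=30)
        tr, truth = lm.synthesize_electrode_trace(
            shape, lm.BeatSchedule(mean_bp_ms=1000), coup,
            sampling_rate_hz=FS_FAST, duration_s=2.0, start_time_s=120.0, rng=0)
        expected = 2000 * np.exp(-4.0)
        assert tr.max() - tr.min() == pytest.approx(expected, rel=0.05)
        assert truth[0]["amplitude_uV"] == pytest.approx(expected, rel=0.01)
        assert tr.max() - tr.min() < 350.0  # below the LEAP amplitude floor

    def test_overlapping_beats_warn_and_truncate(self):
        shape = lm.APShapeParams(family="linear", rise_time_ms=2, repol_ms=700,
                                 diastolic_ms=100)
        with pytest.warns(UserWarning, match="truncated"):
            lm.synthesize_electrode_trace(
                shape, lm.BeatSchedule(mean_bp_ms=400),
                lm.CouplingParams(mode="leap", amplitude_uV=500),
                sampling_rate_hz=FS_FAST, duration_s=3.0, rng=0)

    def test_too_short_duration_rejected(self):
        sched = lm.BeatSchedule(mode="paced", stimulus_times_ms=[5000.0])
        with pytest.raises(ValueError, match="shorter than one beat"):
            lm.synthesize_electrode_trace(
                lm.APShapeParams(), sched, lm.CouplingParams(),
                sampling_rate_hz=FS_FAST, duration_s=1.0, rng=0)

    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0, 6.0])
    @pytest.mark.filterwarnings("ignore:beat period shorter")
    def test_fp_repolarization_wave_between_apd50_and_apd90(self, h):
        """The synthetic T-wave extremum falls inside [APD50, APD90].

        Checked on the clean generated FP trace itself, not just the closed
        form: the extremum of the post-spike repolarization feature must sit
        between the coupled AP's 50% and 90% repolarization times.
        """
        theta = 450.0 / 9 ** (1 / h)  # APD90 fixed at 450 ms
        shape = lm.APShapeParams(family="hill", rise_time_ms=3, theta_ms=theta,
                                 h=h, diastolic_ms=150)
        bp = 1200.0
        tr, truth = lm.synthesize_electrode_trace(
            shape, lm.BeatSchedule(mean_bp_ms=bp),
            lm.CouplingParams(mode="fp", amplitude_uV=300),
            sampling_rate_hz=FS_DESK, duration_s=6.0, rng=0)
        row = truth[1]
        start = int(row["beat_start_ms"] * FS_DESK / 1000)
        a = start + int(0.04 * FS_DESK)
        b = start + int(0.9 * bp * FS_DESK / 1000)
        seg = np.abs(tr[a:b] - np.median(tr[a:b]))
        t_peak_ms = (a + np.argmax(seg) - start) * 1000 / FS_DESK
        apd50 = shape.apd_from_onset(50)
        apd90 = shape.apd_from_onset(90)
        assert apd50 <= t_peak_ms <= apd90
        assert row["true_fpd_ms"] == pytest.approx(t_peak_ms, rel=0.1)


class TestEADInjection:
    def test_realized_prominence_matches_target(self):
        shape = lm.APShapeParams(family="hill", rise_time_ms=2, theta_ms=300, h=4,
                                 diastolic_ms=100)
        tpl = lm.generate_ap_template(shape, FS_NATIVE) * 1000.0
        mod, realized, j = lm.inject_ead(tpl, FS_NATIVE, 0.5, 50.0, 40.0)
        assert realized == pytest.approx(50.0, rel=0.02)

    def test_walker_prominence_agrees_with_scipy(self):
        """The hand-rolled truth oracle matches scipy's topographic rule."""
        rng = np.random.default_rng(7)
        seg = np.cumsum(rng.normal(0, 1, 500))
        seg -= np.linspace(0, seg[-1], seg.size)  # bridge: many local maxima
        peaks, _ = find_peaks(seg)
        proms = peak_prominences(seg, peaks)[0]
        from leapmea.simulate import _prominence_at
        for p, expected in zip(peaks, proms):
            assert _prominence_at(seg, int(p)) == pytest.approx(expected)

    @pytest.mark.parametrize("kwargs", [{"onset_fraction": 0.0},
                                        {"probability": 1.5}, {"width_ms": 0.0}])
    def test_invalid_injection_params(self, kwargs):
        with pytest.raises(ValueError):
            lm.EADInjection(**kwargs)


class TestPlates:
    def desk_plate(self, duration_s=4.0, seed=0):
        return lm.uniform_plate(
            2, 2, 2, duration_s=duration_s,
            shape=lm.APShapeParams(family="hill", rise_time_ms=3, theta_ms=150,
                                   h=3, diastolic_ms=100),
            schedule=lm.BeatSchedule(mean_bp_ms=1000),
            coupling=lm.CouplingParams(mode="leap", amplitude_uV=1000),
            noise=lm.NoiseParams(white_sigma_uV=3, seed=1),
            sampling_rate_hz=FS_FAST, seed=seed,
        )

    @pytest.mark.filterwarnings("ignore:beat period shorter")
    def test_plate_dimensions(self):
        cfg = lm.uniform_plate(2, 4, 2, duration_s=2.0, sampling_rate_hz=FS_FAST)
        rec, truth = lm.synthesize_plate(cfg)
        assert len(rec.electrode_ids) == 16
        assert rec.n_samples == int(2.0 * FS_FAST)
        assert set(truth["well"]) == {"A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4"}

    def test_same_seed_bit_identical(self):
        rec1, t1 = lm.synthesize_plate(self.desk_plate())
        rec2, t2 = lm.synthesize_plate(self.desk_plate())
        for k in rec1.traces:
            assert rec1.traces[k].tobytes() == rec2.traces[k].tobytes()
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        rec1, _ = lm.synthesize_plate(self.desk_plate(seed=0))
        rec2, _ = lm.synthesize_plate(self.desk_plate(seed=1))
        assert any(
            rec1.traces[k].tobytes() != rec2.traces[k].tobytes() for k in rec1.traces
        )

    def test_all_quiescent_plate_reports_no_beats(self):
        cfg = lm.uniform_plate(
            1, 2, 2, duration_s=3.0,
            coupling=lm.CouplingParams(mode="quiescent", amplitude_uV=0),
            noise=lm.NoiseParams(white_sigma_uV=5, seed=2),
            sampling_rate_hz=FS_FAST,
        )
        rec, truth = lm.synthesize_plate(cfg)
        assert truth.empty
        results = lm.analyze_plate(rec)
        assert all(r.quiescent and r.n_beats == 0 for r in results)

    def test_duplicate_electrode_ids_rejected(self):
        cfg = self.desk_plate()
        cfg.electrodes[1].id = cfg.electrodes[0].id
        with pytest.raises(ValueError, match="duplicate"):
            lm.synthesize_plate(cfg)

    def test_simulation_config_yaml_roundtrip(self, tmp_path):
        cfg = self.desk_plate()
        cfg.restitution = lm.RestitutionMap()
        cfg.electrodes[0].eads = lm.EADInjection(probability=0.5)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = lm.SimulationConfig.from_yaml(tmp_path / "sim.yaml")
        assert back == cfg
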