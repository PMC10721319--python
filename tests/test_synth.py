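"""Generator behavior: determinism, ground-truth fidelity, closed-form physics."""

import numpy as np
import pytest

import apneamap as am
from apneamap.errors import InvalidParameterError, OutOfRangeError


class TestAirflow:
    def test_noiseless_trace_is_periodic_with_expected_peak_count(self, clean_params):
        tr = am.gen_airflow(clean_params, 60.0)
        x = tr.samples
        peaks = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]) & (x[1:-1] > 0.5))[0]
        # collapse plateaus within one breath
        t = tr.times[peaks + 1]
        distinct = 1 + int(np.sum(np.diff(t) > 1.0))
        assert distinct == 15
        period = clean_params.breath_period_s
        n = int(round(period * tr.fs))
        assert np.allclose(x[: -n], x[n:], atol=1e-12)

    def test_same_seed_is_bit_identical(self, noisy_params):
        a = am.gen_airflow(noisy_params, 60.0, seed=7)
        b = am.gen_airflow(noisy_params, 60.0, seed=7)
        assert np.array_equal(a.samples, b.samples)
        c = am.gen_airflow(noisy_params, 60.0, seed=8)
        assert not np.array_equal(a.samples, c.samples)

    def test_breath_detector_recovers_period_from_noisy_trace(self):
        params = am.BreathModelParams(noise_sd=0.1, seed=3)
        tr = am.gen_airflow(params, 300.0)
        breaths = am.detect_breaths(tr)
        period = np.mean(np.diff([b.onset for b in breaths]))
        assert abs(period - 4.0) / 4.0 < 0.05

    @pytest.mark.parametrize("bad", [{"breath_period_s": -1}, {"amplitude": 0.0},
                                     {"inspiratory_fraction": 1.2}, {"noise_sd": -0.1}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            am.BreathModelParams(**bad)

    def test_short_duration_rejected(self, clean_params):
        with pytest.raises(InvalidParameterError):
            am.gen_airflow(clean_params, 10.0)


class TestApplyOutcome:
    def test_no_apnea_scenario_is_identity(self, clean_params, epoch):
        tr = am.gen_airflow(clean_params, 150.0)
        out, gt = am.apply_outcome(tr, epoch, am.OutcomeScenario("no_apnea"))
        assert np.array_equal(out.samples, tr.samples)
        assert gt == []

    def test_ground_truth_matches_injected_interval(self, clean_params, epoch):
        sc = am.OutcomeScenario("transient_apnea", within_stim_apnea=((0.0, 10.0),))
        tr = am.gen_airflow(clean_params, 150.0)
        out, gt = am.apply_outcome(tr, epoch, sc)
        assert len(gt) == 1
        assert gt[0].start == epoch.start and gt[0].end == epoch.start + 10.0
        assert abs(gt[0].duration - 10.0) < 1e-9
        # airflow suppressed below the flatness criterion inside the interval
        t = out.times
        inside = (t >= gt[0].start) & (t < gt[0].end)
        assert np.max(np.abs(out.samples[inside])) < 0.25 * np.max(np.abs(out.samples))

    def test_persistent_scenario_round_trips_through_classifier(self, clean_params, epoch):
        sc = am.OutcomeScenario(
            "persistent_apnea",
            within_stim_apnea=((0.0, 30.0),),
            post_stim_apnea=((0.0, 12.0), (20.0, 33.0)),  # totals 25 s
        )
        tr = am.gen_airflow(clean_params, 220.0)
        out, _ = am.apply_outcome(tr, epoch, sc)
        scored = am.score_trial(out, epoch)
        assert scored.outcome.label == am.OutcomeLabel.PERSISTENT_APNEA
        assert abs(scored.metrics.post_window_apnea_s - 25.0) < 1.0

    def test_interval_outside_trace_raises(self, clean_params, epoch):
        sc = am.OutcomeScenario("persistent_apnea", within_stim_apnea=((0.0, 30.0),),
                                post_stim_apnea=((0.0, 500.0),))
        tr = am.gen_airflow(clean_params, 150.0)
        with pytest.raises(OutOfRangeError):
            am.apply_outcome(tr, epoch, sc)


class TestSpO2:
    def test_no_apneas_gives_constant_baseline(self):
        s = am.gen_spo2([], baseline=98.0, duration_s=60.0)
        assert np.all(s.samples == 98.0)

    def test_closed_form_minimum_during_long_apnea(self):
        apnea = am.ApneaInterval(start=10.0, end=50.0, missed_breaths=10)
        s = am.gen_spo2([apnea], desat_rate=0.5, lag_s=10.0, baseline=98.0, duration_s=80.0)
        expected_min = 98.0 - 0.5 * (40.0 - 10.0)
        assert abs(s.samples.min() - expected_min) < 0.5 + 1e-9
        assert s.samples.max() <= 98.0

    def test_desaturation_round_trip(self):
        # long enough apnea to cross 90%: needs (98-90)/0.5 + 10 = 26 s
        apnea = am.ApneaInterval(start=10.0, end=60.0, missed_breaths=12)
        s = am.gen_spo2([apnea], desat_rate=0.5, lag_s=10.0, baseline=98.0, duration_s=120.0)
        runs = am.detect_desaturation(s)
        assert len(runs) == 1

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            am.gen_spo2([], desat_rate=-1.0)


class TestVentilator:
    def test_zero_ventilation_makes_etco2_strictly_increase(self):
        co2 = am.CO2Params()
        # two onsets then nothing: VE = 0 over the probed span
        v = am.gen_ventilator(np.array([0.0, 4.0]), lambda t: 500.0, co2, duration_s=60.0)
        tail = v.etco2_mmhg[100:]
        assert np.all(np.diff(tail) > 0)

    def test_integrator_converges_to_analytic_fixed_point(self):
        co2 = am.CO2Params(baseline_etco2=40.0, production_rate=0.6,
                           clearance_coeff=0.01, floor=20.0)
        onsets = np.arange(0.0, 700.0, 5.0)  # RR 12 * TV 500 mL -> VE 6 L/min
        v = am.gen_ventilator(onsets, lambda t: 500.0, co2, duration_s=650.0)
        assert co2.steady_state(6.0) == pytest.approx(30.0)
        i = np.searchsorted(v.time, 600.0)
        assert abs(v.etco2_mmhg[i] - 30.0) < 0.1

    def test_halving_tidal_volume_raises_steady_state(self):
        co2 = am.CO2Params()
        onsets = np.arange(0.0, 900.0, 5.0)
        full = am.gen_ventilator(onsets, lambda t: 500.0, co2, duration_s=800.0)
        half = am.gen_ventilator(onsets, lambda t: 250.0, co2, duration_s=800.0)
        i = np.searchsorted(full.time, 750.0)
        assert half.etco2_mmhg[i] > full.etco2_mmhg[i]
        assert co2.steady_state(3.0) > co2.steady_state(6.0)

    def test_ve_identity_holds(self):
        v = am.gen_ventilator(np.arange(0.0, 130.0, 4.0), lambda t: 450.0,
                              am.CO2Params(), duration_s=120.0)
        active = v.ve_lpm > 0
        assert np.allclose(v.ve_lpm[active], v.rr[active] * v.tv_ml[active] / 1000.0, rtol=0.01)


class TestCohort:
    def test_same_seed_gives_identical_cohort(self):
        a = am.gen_cohort(am.CohortSpec(seed=5))
        b = am.gen_cohort(am.CohortSpec(seed=5))
        assert [s.coordinate for s in a] == [s.coordinate for s in b]
        assert [s.outcome.label for s in a] == [s.outcome.label for s in b]

    def test_zero_persistent_probability_yields_no_persistent_sites(self):
        def model(coord):
            coord = np.atleast_2d(coord)
            p = np.zeros((coord.shape[0], 4))
            p[:, 0] = 1.0
            return p

        sites = am.gen_cohort(am.CohortSpec(outcome_model=model, seed=1))
        assert all(s.outcome.label == am.OutcomeLabel.NO_APNEA for s in sites)

    def test_class_probabilities_sum_to_one_everywhere(self):
        spec = am.CohortSpec()
        model = am.default_outcome_model(spec)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-40, 40, size=(50, 3))
        p = model(pts)
        assert np.allclose(p.sum(axis=1), 1.0)
        # persistent probability peaks at the pAIR center
        at_center = model(np.array(spec.pair_center_pAIR))[0][3]
        assert at_center > p[:, 3].max() - 1e-9 or at_center > 0.7


class TestIEEG:
    def test_theta_dominates_when_theta_amplitude_is_large(self):
        tr = am.gen_ieeg(1, 400.0, 30.0, band_amplitudes={"theta": 8.0}, seed=0)
        powers = am.band_powers(tr)
        assert max(powers, key=powers.get) == "theta"

    def test_identical_seeds_identical_traces(self):
        a = am.gen_ieeg(2, 400.0, 10.0, seed=4)
        b = am.gen_ieeg(2, 400.0, 10.0, seed=4)
        assert np.array_equal(a.samples, b.samples)

    def test_seizure_epoch_raises_broadband_power_inside_only(self):
        seiz = am.StimEpoch(start=10.0, end=20.0, kind="seizure")
        tr = am.gen_ieeg(1, 400.0, 30.0, seizure=seiz, seed=2)
        inside = am.band_power(tr, (11.0, 19.0), "beta")
        outside = am.band_power(tr, (0.0, 8.0), "beta")
        assert inside > 3.0 * outside

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            am.gen_ieeg(1, 200.0, 10.0)
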