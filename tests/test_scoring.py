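"""Breath segmentation, apnea detection, trial metrics: rules and invariants."""

import numpy as np
import pytest

import apneamap as am
from apneamap.errors import InsufficientBaselineError

from oracles import gap_scan_apneas


def _suppress(params, total_s, epoch, within=(), post=()):
    sc = am.OutcomeScenario(
        "persistent_apnea" if post else ("apnea" if within else "no_apnea"),
        within_stim_apnea=tuple(within),
        post_stim_apnea=tuple(post),
    )
    tr = am.gen_airflow(params, total_s)
    return am.apply_outcome(tr, epoch, sc)


class TestDetectBreaths:
    def test_noiseless_periodic_trace_yields_expected_breaths(self, clean_params):
        tr = am.gen_airflow(clean_params, 60.0)
        breaths = am.detect_breaths(tr)
        assert len(breaths) == 15
        period = np.mean(np.diff([b.onset for b in breaths]))
        assert period == pytest.approx(4.0, abs=0.02)
        for b in breaths:
            assert b.onset < b.peak < b.end

    def test_all_zero_trace_returns_empty_list(self):
        tr = am.AirflowTrace(samples=np.zeros(1000), fs=40.0)
        assert am.detect_breaths(tr) == []

    def test_single_suppressed_breath_leaves_double_gap(self, clean_params, epoch):
        out, _ = _suppress(clean_params, 150.0, epoch, within=((0.0, 4.0),))
        breaths = am.detect_breaths(out)
        onsets = np.array([b.onset for b in breaths])
        gaps = np.diff(onsets)
        assert np.sum(gaps > 1.75 * 4.0) == 1
        assert gaps.max() == pytest.approx(8.0, abs=0.3)


class TestEstimateBaseline:
    def test_noiseless_baseline_period_is_exact(self, clean_params):
        tr = am.gen_airflow(clean_params, 120.0)
        base = am.estimate_baseline(tr, (0.0, 60.0))
        assert base.T0 == pytest.approx(4.0, abs=0.01)
        # amplitude is read off the conditioned (low-passed) signal; the
        # zero-phase filter overshoots the half-sine lobe by a few percent
        assert base.A0 == pytest.approx(1.0, abs=0.1)

    def test_window_overlapping_apnea_raises(self, clean_params):
        epoch = am.StimEpoch(start=8.0, end=48.0)
        out, _ = _suppress(clean_params, 150.0, epoch, within=((0.0, 40.0),))
        with pytest.raises(InsufficientBaselineError):
            am.estimate_baseline(out, (10.0, 45.0))

    def test_noisy_baseline_period_within_five_percent(self):
        tr = am.gen_airflow(am.BreathModelParams(noise_sd=0.1, seed=11), 120.0)
        base = am.estimate_baseline(tr, (0.0, 120.0))
        assert abs(base.T0 - 4.0) / 4.0 < 0.05


class TestDetectApneas:
    def _score(self, trace):
        breaths = am.detect_breaths(trace)
        base = am.estimate_baseline(trace, (0.0, 60.0), breaths=breaths)
        return breaths, base, am.detect_apneas(breaths, base, trace)

    def test_uninterrupted_breathing_yields_no_apneas(self, noisy_params):
        tr = am.gen_airflow(noisy_params, 180.0)
        _, _, apneas = self._score(tr)
        assert apneas == []

    def test_single_missed_breath_is_one_apnea(self, clean_params, epoch):
        out, _ = _suppress(clean_params, 150.0, epoch, within=((0.0, 4.0),))
        _, _, apneas = self._score(out)
        assert len(apneas) == 1
        assert apneas[0].missed_breaths == 1
        assert apneas[0].flat

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_gap_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = am.BreathModelParams(noise_sd=0.05, seed=seed)
        epoch = am.StimEpoch(start=60.0, end=90.0)
        n_bursts = int(rng.integers(1, 4))
        cursor = 0.0
        post = []
        for _ in range(n_bursts):
            d = float(rng.uniform(8.0, 20.0))
            post.append((cursor, cursor + d))
            cursor += d + float(rng.uniform(6.0, 15.0))
        out, _ = _suppress(params, 220.0, epoch, within=((0.0, 30.0),), post=post)
        breaths, base, apneas = self._score(out)
        oracle = gap_scan_apneas(breaths, base, out)
        assert len(apneas) == len(oracle)
        for got, (end, missed, _) in zip(apneas, oracle):
            assert got.end == pytest.approx(end, abs=1e-9)
            assert got.missed_breaths == missed

    def test_intervals_sorted_and_disjoint(self, clean_params, epoch):
        out, _ = _suppress(
            clean_params, 220.0, epoch, within=((0.0, 30.0),), post=((6.0, 18.0), (30.0, 42.0))
        )
        _, _, apneas = self._score(out)
        for a, b in zip(apneas[:-1], apneas[1:]):
            assert a.end <= b.start


class TestTrialMetrics:
    def test_no_apneas_gives_zero_metrics(self, noisy_params, epoch):
        tr = am.gen_airflow(noisy_params, 180.0)
        s = am.score_trial(tr, epoch)
        assert s.metrics.total_apnea_time_s == 0.0
        assert s.metrics.disrupted_breathing_time_s == 0.0

    def test_exact_epoch_apnea_with_immediate_recovery(self, clean_params, epoch):
        out, _ = _suppress(clean_params, 180.0, epoch, within=((0.0, 30.0),))
        s = am.score_trial(out, epoch)
        assert s.metrics.total_apnea_time_s == pytest.approx(30.0, abs=0.2)
        assert s.metrics.disrupted_breathing_time_s == pytest.approx(30.0, abs=0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_repeated_post_stim_apneas_match_ground_truth_total(self, seed):
        params = am.BreathModelParams(noise_sd=0.03, seed=seed)
        epoch = am.StimEpoch(start=60.0, end=90.0)
        rng = np.random.default_rng(100 + seed)
        post, cursor = [], 0.0
        for _ in range(2):
            d = float(rng.uniform(8.0, 16.0))
            post.append((cursor, cursor + d))
            cursor += d + float(rng.uniform(7.0, 14.0))
        out, gt = _suppress(params, 240.0, epoch, within=((0.0, 30.0),), post=post)
        s = am.score_trial(out, epoch)
        truth = sum(a.duration for a in gt)
        assert s.metrics.total_apnea_time_s == pytest.approx(truth, abs=1.0)

    def test_censoring_flagged_when_trace_ends_in_apnea(self, clean_params, epoch):
        sc = am.OutcomeScenario(
            "persistent_apnea", within_stim_apnea=((0.0, 30.0),), post_stim_apnea=((0.0, 55.0),)
        )
        tr = am.gen_airflow(clean_params, 150.0)  # ends at 150 = epoch.end + 60
        out, _ = am.apply_outcome(tr, epoch, sc)
        with pytest.warns(am.errors.RightCensoredWarning):
            s = am.score_trial(out, epoch)
        assert s.metrics.right_censored

    def test_monotonicity_longer_suppression_never_reduces_apnea_time(self, clean_params):
        epoch = am.StimEpoch(start=60.0, end=90.0)
        totals = []
        for d in (8.0, 16.0, 24.0, 32.0):
            out, _ = _suppress(clean_params, 220.0, epoch, within=((0.0, 30.0),), post=((0.0, d),))
            s = am.score_trial(out, epoch)
            totals.append(s.metrics.total_apnea_time_s)
        assert all(b >= a - 1e-6 for a, b in zip(totals[:-1], totals[1:]))


class TestInvariances:
    def _metrics(self, trace, epoch):
        s = am.score_trial(trace, epoch)
        return (
            len(s.breaths),
            [(round(a.start, 2), round(a.end, 2)) for a in s.apneas],
            round(s.metrics.total_apnea_time_s, 2),
        )

    def test_scale_invariance(self, epoch):
        params = am.BreathModelParams(noise_sd=0.05, seed=9)
        out, _ = _suppress(params, 200.0, epoch, within=((0.0, 30.0),), post=((0.0, 10.0),))
        ref = self._metrics(out, epoch)
        for c in (0.1, 3.0, 250.0):
            scaled = am.AirflowTrace(samples=c * out.samples, fs=out.fs, t0=out.t0)
            assert self._metrics(scaled, epoch) == ref

    def test_time_shift_equivariance(self, epoch):
        params = am.BreathModelParams(noise_sd=0.05, seed=10)
        out, _ = _suppress(params, 200.0, epoch, within=((0.0, 30.0),))
        s0 = am.score_trial(out, epoch)
        shift = 17.0
        shifted = am.AirflowTrace(samples=out.samples, fs=out.fs, t0=out.t0 + shift)
        ep2 = am.StimEpoch(start=epoch.start + shift, end=epoch.end + shift)
        s1 = am.score_trial(shifted, ep2)
        assert len(s0.apneas) == len(s1.apneas)
        for a, b in zip(s0.apneas, s1.apneas):
            assert b.start - a.start == pytest.approx(shift, abs=1e-6)
        assert s1.metrics.total_apnea_time_s == pytest.approx(
            s0.metrics.total_apnea_time_s, abs=1e-6
        )


class TestDesaturation:
    def test_constant_98_is_clean(self):
        s = am.SpO2Series(samples=np.full(120, 98.0), fs=1.0)
        assert am.detect_desaturation(s) == []

    def test_threshold_is_strict(self):
        just_below = am.SpO2Series(samples=np.full(120, 89.9), fs=1.0)
        runs = am.detect_desaturation(just_below)
        assert len(runs) == 1
        assert runs[0] == (0.0, 120.0)
        at_threshold = am.SpO2Series(samples=np.full(120, 90.0), fs=1.0)
        assert am.detect_desaturation(at_threshold) == []
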