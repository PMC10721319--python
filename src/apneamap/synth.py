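"""Seed-deterministic generators for every input the pipeline consumes.

The generators emulate the phenomenology of stimulation-evoked breathing
studies with known ground truth: quasi-periodic nasal airflow with
stimulation-locked apnea of each outcome class, SpO2 desaturation during
apneas, ventilator channels with a one-compartment CO2 store, iEEG with
canonical-band structure and optional seizure-like broadband bursts, and
cohorts of electrode sites whose outcome probabilities depend on distance to
a focal persistent-apnea cluster nested inside a broader apnea cluster.

Everything is deterministic given its seed: regenerating with the same
parameters yields bit-identical arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import (
    OutcomeLabel,
    SEVERITY_ORDER,
    SiteOutcome,
    StimEpoch,
    TrialOutcome,
    aggregate_site,
)
from .errors import InvalidParameterError, OutOfRangeError
from .scoring import AirflowTrace, ApneaInterval, SpO2Series
from .ventilation import VentilationSeries

__all__ = [
    "BreathModelParams",
    "OutcomeScenario",
    "CO2Params",
    "CohortSpec",
    "IEEGTrace",
    "gen_airflow",
    "apply_outcome",
    "random_scenario",
    "gen_spo2",
    "gen_ventilator",
    "gen_cohort",
    "default_outcome_model",
    "gen_ieeg",
    "SUPPRESSION_FACTOR",
]

#: airflow inside an injected apnea is scaled by this factor (well below the
#: flatness criterion) rather than zeroed, so noise statistics stay realistic
SUPPRESSION_FACTOR = 0.05


@dataclass(frozen=True)
class BreathModelParams:
    """Parameters of the quasi-periodic baseline breathing model.

    The waveform is a per-breath pair of half-sine lobes: an inspiratory lobe
    of duration ``inspiratory_fraction * breath_period_s`` and amplitude
    ``amplitude``, followed by a shallower, longer expiratory lobe scaled so
    each breath moves zero net volume. Units of amplitude are arbitrary, as
    in nasal-pressure recordings.
    """

    breath_period_s: float = 4.0
    amplitude: float = 1.0
    inspiratory_fraction: float = 0.35
    noise_sd: float = 0.05
    drift_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.breath_period_s > 0:
            raise InvalidParameterError("breath period must be positive")
        if not self.amplitude > 0:
            raise InvalidParameterError("amplitude must be positive")
        if not 0 < self.inspiratory_fraction < 1:
            raise InvalidParameterError("inspiratory fraction must lie in (0, 1)")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise InvalidParameterError("noise levels must be non-negative")


@dataclass(frozen=True)
class OutcomeScenario:
    """Ground-truth plan for one trial's respiratory outcome.

    Apnea intervals are (start, end) pairs relative to the stimulation start
    (``within_stim_apnea``) or to the epoch end (``post_stim_apnea``).
    """

    outcome_class: OutcomeLabel
    onset_latency_s: float = 0.0
    within_stim_apnea: tuple = ()
    post_stim_apnea: tuple = ()
    recovery_time_s: float = 25.0

    def __post_init__(self):
        object.__setattr__(self, "outcome_class", OutcomeLabel(self.outcome_class))
        for ivs in (self.within_stim_apnea, self.post_stim_apnea):
            prev_end = -math.inf
            for s, e in ivs:
                if not e > s:
                    raise InvalidParameterError("scenario intervals need end > start")
                if s < prev_end:
                    raise InvalidParameterError("scenario intervals must be ordered, disjoint")
                prev_end = e


@dataclass(frozen=True)
class CO2Params:
    """One-compartment end-tidal CO2 store.

    dC/dt = a - b * VE(t) * (C - Cmin), with C in mmHg, a in mmHg/s, VE in
    L/min and b in 1/(L/min)/s. During apnea (VE = 0) C rises linearly at
    rate a; at constant VE the fixed point is Cmin + a / (b * VE).
    """

    baseline_etco2: float = 40.0
    production_rate: float = 0.6
    clearance_coeff: float = 0.005
    floor: float = 20.0

    def __post_init__(self):
        if not (self.production_rate > 0 and self.clearance_coeff > 0):
            raise InvalidParameterError("CO2 rates must be positive")
        if not self.baseline_etco2 > self.floor:
            raise InvalidParameterError("baseline etCO2 must exceed the floor")

    def steady_state(self, ve_lpm: float) -> float:
        if ve_lpm <= 0:
            return math.inf
        return self.floor + self.production_rate / (self.clearance_coeff * ve_lpm)


@dataclass(frozen=True)
class CohortSpec:
    """Spatial cohort of stimulated sites with distance-dependent outcomes.

    Default centers sit in the right medial amygdala (MNI, mm); the
    persistent-apnea cluster (sd ``cluster_sd_mm``) is nested inside a
    broader apnea cluster (sd ``2 * cluster_sd_mm``).
    """

    n_patients: int = 20
    sites_per_patient: int = 4
    pair_center_pAIR: tuple = (23.0, -5.0, -18.0)
    pair_center_AIR: tuple = (25.0, -3.0, -17.0)
    cluster_sd_mm: float = 3.0
    site_scatter_mm: float = 8.0
    trials_per_site: tuple = (3, 5)
    outcome_model: object = None
    seed: int = 0

    def __post_init__(self):
        if not self.cluster_sd_mm > 0:
            raise InvalidParameterError("cluster_sd_mm must be positive")
        if self.n_patients < 1 or self.sites_per_patient < 1:
            raise InvalidParameterError("cohort counts must be positive")


@dataclass(frozen=True)
class IEEGTrace:
    """Multichannel intracranial EEG, channels x samples."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel_names: tuple = ()

    def __post_init__(self):
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise InvalidParameterError("sampling rate must be positive")
        if not self.channel_names:
            object.__setattr__(
                self, "channel_names", tuple(f"ch{i}" for i in range(samples.shape[0]))
            )

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.fs


# ---------------------------------------------------------------------------
# airflow


def _breath_onsets(
    t_start: float, t_end: float, period: float, intervals: list[tuple[float, float]]
) -> np.ndarray:
    """Breath onset schedule with phase reset after each suppression interval.

    Breathing walks forward at ``period``; inside a suppression interval no
    breath starts, and the first breath after the interval begins exactly at
    the interval end (resumption is not phase-locked to pre-apnea breathing).
    """
    onsets = []
    t = t_start
    guard = 0
    while t < t_end - 1e-9:
        inside = next((iv for iv in intervals if iv[0] - 1e-9 <= t < iv[1] - 1e-9), None)
        if inside is not None:
            t = inside[1]
        else:
            onsets.append(t)
            t += period
        guard += 1
        if guard > 10_000_000:  # pragma: no cover - defensive
            raise RuntimeError("breath schedule failed to terminate")
    return np.asarray(onsets)


def _render_airflow(
    params: BreathModelParams,
    duration_s: float,
    fs: float,
    onsets: np.ndarray,
    intervals: list[tuple[float, float]],
    t_start: float,
) -> np.ndarray:
    n = int(round(duration_s * fs))
    t = t_start + np.arange(n) / fs
    x = np.zeros(n)
    T0 = params.breath_period_s
    ti = params.inspiratory_fraction * T0
    te = T0 - ti
    amp_e = params.amplitude * ti / te  # zero net volume per breath
    for onset in onsets:
        i0 = int(np.ceil((onset - t_start) * fs - 1e-9))
        i1 = min(int(np.ceil((onset + T0 - t_start) * fs - 1e-9)), n)
        if i1 <= i0:
            continue
        u = t[i0:i1] - onset
        seg = np.where(
            u < ti,
            params.amplitude * np.sin(np.pi * np.clip(u, 0, ti) / ti),
            -amp_e * np.sin(np.pi * np.clip(u - ti, 0, te) / te),
        )
        x[i0:i1] += seg

    rng = np.random.default_rng(params.seed)
    if params.drift_sd > 0:
        freqs = rng.uniform(0.01, 0.05, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        drift = sum(
            params.drift_sd * np.sin(2 * np.pi * f * (t - t_start) + p)
            for f, p in zip(freqs, phases)
        )
        x = x + drift
    else:  # keep the rng draw order identical either way
        rng.uniform(0.01, 0.05, size=3)
        rng.uniform(0, 2 * np.pi, size=3)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=n)

    if intervals:
        mask = np.ones(n)
        for s, e in intervals:
            i0 = int(np.ceil((s - t_start) * fs - 1e-9))
            i1 = min(int(np.ceil((e - t_start) * fs - 1e-9)), n)
            mask[max(i0, 0) : i1] = SUPPRESSION_FACTOR
        x = x * mask
    return x


def gen_airflow(
    params: BreathModelParams,
    duration_s: float,
    seed: int | None = None,
    fs: float = 40.0,
    t0: float = 0.0,
) -> AirflowTrace:
    """Generate a quasi-periodic inspiration-positive airflow trace.

    With ``noise_sd = 0`` and ``drift_sd = 0`` the signal is exactly periodic
    with the model period. Same parameters + seed give bit-identical samples.
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    if duration_s < 3 * params.breath_period_s:
        raise InvalidParameterError("duration must cover at least 3 breath periods")
    if seed is not None:
        params = replace(params, seed=seed)
    onsets = _breath_onsets(t0, t0 + duration_s, params.breath_period_s, [])
    samples = _render_airflow(params, duration_s, fs, onsets, [], t0)
    meta = {"params": params, "onsets": onsets, "intervals": ()}
    return AirflowTrace(samples=samples, fs=fs, t0=t0, meta=meta)


def _scenario_intervals(stim: StimEpoch, scenario: OutcomeScenario) -> list[tuple[float, float]]:
    ivs = [(stim.start + s, stim.start + e) for s, e in scenario.within_stim_apnea]
    ivs += [(stim.end + s, stim.end + e) for s, e in scenario.post_stim_apnea]
    ivs.sort()
    for (s0, e0), (s1, e1) in zip(ivs[:-1], ivs[1:]):
        if s1 < e0:
            raise InvalidParameterError("scenario intervals overlap once mapped to the epoch")
    return ivs


def apply_outcome(
    trace: AirflowTrace, stim: StimEpoch, scenario: OutcomeScenario
) -> tuple[AirflowTrace, list[ApneaInterval]]:
    """Suppress airflow on the scenario's intervals; return trace + ground truth.

    The trace must come from :func:`gen_airflow` (its breath schedule and
    parameters travel in ``meta``). Suppressed breaths are removed from the
    schedule, breathing resumes with a fresh breath at each interval end, and
    airflow inside the intervals is scaled by :data:`SUPPRESSION_FACTOR`.
    A ``no_apnea`` scenario returns a bit-identical trace.
    """
    if "params" not in trace.meta:
        raise InvalidParameterError("apply_outcome requires a generated trace with model meta")
    params: BreathModelParams = trace.meta["params"]
    intervals = _scenario_intervals(stim, scenario)
    for s, e in intervals:
        if s < trace.t0 - 1e-9 or e > trace.t_end + 1e-9:
            raise OutOfRangeError(f"scenario interval [{s:g}, {e:g}) outside trace extent")
    onsets = _breath_onsets(trace.t0, trace.t_end, params.breath_period_s, intervals)
    samples = _render_airflow(params, trace.duration, trace.fs, onsets, intervals, trace.t0)
    out = AirflowTrace(
        samples=samples,
        fs=trace.fs,
        t0=trace.t0,
        meta={"params": params, "onsets": onsets, "intervals": tuple(intervals)},
    )
    T0 = params.breath_period_s
    gt = [
        ApneaInterval(start=s, end=e, missed_breaths=max(1, int(round((e - s) / T0))), flat=True)
        for s, e in intervals
    ]
    return out, gt


def random_scenario(
    outcome_class: OutcomeLabel | str,
    epoch_duration_s: float,
    rng: np.random.Generator,
    breath_period_s: float = 4.0,
    persistent_threshold_s: float = 20.0,
) -> OutcomeScenario:
    """Draw a scenario realizing ``outcome_class`` for a given epoch length.

    Persistent scenarios place 1–3 post-epoch apneas separated by short
    (< 20 s) breathing gaps so the disrupted-breathing window stays open,
    with total post-epoch apnea drawn from [threshold + 1, threshold + 20] s.
    """
    label = OutcomeLabel(outcome_class)
    T0 = breath_period_s
    if label == OutcomeLabel.NO_APNEA:
        return OutcomeScenario(outcome_class=label)
    if label == OutcomeLabel.TRANSIENT_APNEA:
        frac = rng.uniform(0.25, 0.6)
        end = max(2 * T0, frac * epoch_duration_s)
        return OutcomeScenario(
            outcome_class=label, within_stim_apnea=((0.0, float(end)),)
        )
    if label == OutcomeLabel.APNEA:
        return OutcomeScenario(
            outcome_class=label, within_stim_apnea=((0.0, float(epoch_duration_s)),)
        )
    # persistent: full-epoch apnea plus post-epoch apneas
    total = float(rng.uniform(persistent_threshold_s + 1.0, persistent_threshold_s + 20.0))
    n_post = int(rng.integers(1, 4))
    cuts = np.sort(rng.uniform(0.3, 0.7, size=n_post - 1)) if n_post > 1 else np.array([])
    parts = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * total
    parts = np.maximum(parts, 2 * T0)  # each burst must register as apnea
    post = []
    cursor = 0.0 if rng.random() < 0.5 else float(rng.uniform(T0 + 2.0, 10.0))
    for p in parts:
        post.append((cursor, cursor + float(p)))
        cursor += float(p) + float(rng.uniform(T0 + 2.0, 14.0))
    return OutcomeScenario(
        outcome_class=label,
        within_stim_apnea=((0.0, float(epoch_duration_s)),),
        post_stim_apnea=tuple(post),
    )


# ---------------------------------------------------------------------------
# SpO2 and ventilator


def gen_spo2(
    apneas: list[ApneaInterval],
    desat_rate: float = 0.5,
    lag_s: float = 10.0,
    baseline: float = 98.0,
    duration_s: float = 120.0,
    fs: float = 1.0,
    t0: float = 0.0,
    recovery_rate: float = 1.0,
    floor: float = 70.0,
) -> SpO2Series:
    """SpO2 declining at ``desat_rate`` %/s after ``lag_s`` inside apneas.

    Outside apneas saturation recovers toward baseline at ``recovery_rate``
    %/s and never exceeds it; the series is floored at ``floor``.
    """
    if desat_rate < 0 or recovery_rate < 0:
        raise InvalidParameterError("rates must be non-negative")
    if not 50 < baseline <= 100:
        raise InvalidParameterError("baseline SpO2 must lie in (50, 100]")
    n = int(round(duration_s * fs))
    dt = 1.0 / fs
    sat = np.empty(n)
    level = baseline
    for i in range(n):
        t = t0 + i * dt
        a = next((ap for ap in apneas if ap.start <= t < ap.end), None)
        if a is not None and t - a.start >= lag_s:
            level -= desat_rate * dt
        else:
            level = min(baseline, level + recovery_rate * dt)
        level = max(level, floor)
        sat[i] = level
    return SpO2Series(samples=sat, fs=fs, t0=t0)


def gen_ventilator(
    breaths: np.ndarray,
    tidal_volume_fn,
    co2: CO2Params,
    duration_s: float,
    fs: float = 10.0,
    t0: float = 0.0,
    apnea_gap_factor: float = 2.0,
) -> "VentilationSeries":
    """Ventilator channels (RR, TV, VE, etCO2) from a breath-onset schedule.

    RR at time t is 60 over the inter-onset gap containing t; gaps longer
    than ``apnea_gap_factor`` times the median gap count as apnea (RR = 0).
    TV comes from ``tidal_volume_fn(t)`` in mL, VE = RR * TV / 1000 L/min,
    and etCO2 integrates the one-compartment store with a fixed-step explicit
    scheme at the sampling rate.
    """
    onsets = np.sort(np.asarray(breaths, dtype=float))
    if onsets.size < 2:
        raise InvalidParameterError("need at least 2 breath onsets")
    n = int(round(duration_s * fs))
    t = t0 + np.arange(n) / fs
    gaps = np.diff(onsets)
    med = float(np.median(gaps))
    idx = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, onsets.size - 2)
    gap_at = gaps[idx]
    breathing = gap_at <= apnea_gap_factor * med
    # before the first / after the last breath: no breathing
    breathing &= (t >= onsets[0]) & (t < onsets[-1])
    rr = np.where(breathing, 60.0 / gap_at, 0.0)
    tv = np.asarray([float(tidal_volume_fn(tt)) for tt in t])
    tv = np.where(breathing, np.maximum(tv, 0.0), 0.0)
    ve = rr * tv / 1000.0

    c = np.empty(n)
    level = co2.baseline_etco2
    dt = 1.0 / fs
    for i in range(n):
        c[i] = level
        dlevel = co2.production_rate - co2.clearance_coeff * ve[i] * (level - co2.floor)
        level = max(co2.floor, level + dt * dlevel)
    return VentilationSeries(time=t, rr=rr, tv_ml=tv, ve_lpm=ve, etco2_mmhg=c)


# ---------------------------------------------------------------------------
# cohort


def default_outcome_model(spec: CohortSpec):
    """Distance-dependent four-class outcome probabilities.

    Persistent-apnea weight peaks sharply at the pAIR center
    (sd ``cluster_sd_mm``): sites inside the focal cluster elicit persistent
    apnea on nearly every trial, mirroring the deterministic per-site
    phenomenology of mapped pAIR sites. Apnea weight forms a broader cluster
    around the AIR center (sd ``2 * cluster_sd_mm``); transient apnea rings
    the apnea cluster more diffusely; a flat floor leaves no-effect
    probability everywhere. Weights are normalized so class probabilities
    sum to 1 at every coordinate.
    """
    c_p = np.asarray(spec.pair_center_pAIR, dtype=float)
    c_a = np.asarray(spec.pair_center_AIR, dtype=float)
    sd_p = spec.cluster_sd_mm
    sd_a = 2.0 * spec.cluster_sd_mm
    sd_t = 3.0 * spec.cluster_sd_mm

    def model(coord: np.ndarray) -> np.ndarray:
        coord = np.atleast_2d(np.asarray(coord, dtype=float))
        d_p = np.sum((coord - c_p) ** 2, axis=1)
        d_a = np.sum((coord - c_a) ** 2, axis=1)
        w = np.stack(
            [
                np.full(coord.shape[0], 0.4),  # no_apnea
                1.2 * np.exp(-d_a / (2 * sd_t**2)),  # transient
                4.0 * np.exp(-d_a / (2 * sd_a**2)),  # apnea
                25.0 * np.exp(-d_p / (2 * sd_p**2)),  # persistent (near-deterministic)
            ],
            axis=1,
        )
        return w / w.sum(axis=1, keepdims=True)

    return model


def _trial_outcome_for_label(label: OutcomeLabel, rng: np.random.Generator) -> TrialOutcome:
    """Nominal per-trial metrics consistent with a drawn label."""
    if label == OutcomeLabel.NO_APNEA:
        return TrialOutcome(label=label)
    if label == OutcomeLabel.TRANSIENT_APNEA:
        d = float(rng.uniform(5, 15))
        return TrialOutcome(label=label, total_apnea_time_s=d, disrupted_breathing_time_s=d)
    if label == OutcomeLabel.APNEA:
        d = float(rng.uniform(25, 35))
        return TrialOutcome(label=label, total_apnea_time_s=d, disrupted_breathing_time_s=d)
    post = float(rng.uniform(21, 45))
    return TrialOutcome(
        label=label,
        total_apnea_time_s=30.0 + post,
        disrupted_breathing_time_s=40.0 + post,
        post_window_apnea_s=post,
    )


def gen_cohort(spec: CohortSpec):
    """Generate labelled stimulated sites for classifier experiments.

    Returns a list of :class:`~apneamap.mapping.SiteRecord`. Site coordinates
    scatter around the AIR center (mirrored to the left hemisphere for half
    the patients); per-trial outcomes are drawn from the distance-dependent
    class probabilities, and the generating (argmax-probability) class is
    stored as each site's ground-truth label.
    """
    from .mapping import SiteRecord  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    model = spec.outcome_model or default_outcome_model(spec)
    c_a = np.asarray(spec.pair_center_AIR, dtype=float)
    lo, hi = spec.trials_per_site
    sites = []
    for p in range(spec.n_patients):
        left = p % 2 == 1
        for s in range(spec.sites_per_patient):
            coord = c_a + rng.normal(0.0, spec.site_scatter_mm, size=3)
            coord[0] = abs(coord[0])
            probs = model(coord)[0]
            true_label = SEVERITY_ORDER[int(np.argmax(probs))]
            n_trials = int(rng.integers(lo, hi + 1))
            labels = rng.choice(len(SEVERITY_ORDER), size=n_trials, p=probs)
            trials = [_trial_outcome_for_label(SEVERITY_ORDER[i], rng) for i in labels]
            site_id = f"P{p:03d}-S{s:02d}"
            outcome = aggregate_site(trials, site_id=site_id)
            xyz = coord.copy()
            if left:
                xyz[0] = -xyz[0]
            sites.append(
                SiteRecord(
                    patient_id=f"P{p:03d}",
                    site_id=site_id,
                    coordinate=tuple(float(v) for v in xyz),
                    hemisphere="left" if left else "right",
                    region_label="amygdala",
                    outcome=outcome,
                    true_label=true_label,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# iEEG

_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "low_gamma": (30.0, 80.0),
    "high_gamma": (80.0, 150.0),
}


def gen_ieeg(
    n_channels: int,
    fs: float,
    duration_s: float,
    band_amplitudes: dict | None = None,
    seizure: StimEpoch | None = None,
    seed: int = 0,
    seizure_gain: float = 3.0,
    t0: float = 0.0,
) -> IEEGTrace:
    """1/f background plus band-limited oscillations, optional seizure burst.

    Requires ``fs >= 400`` Hz so high gamma (up to 150 Hz) is resolved. If a
    seizure epoch is given, all components are amplified by ``seizure_gain``
    inside it only, with 0.5 s raised-cosine ramps (a broadband increase).
    """
    from scipy import signal as _sig

    if fs < 400:
        raise InvalidParameterError("fs must be >= 400 Hz to resolve high gamma")
    if duration_s <= 0 or n_channels < 1:
        raise InvalidParameterError("need positive duration and channel count")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    t = t0 + np.arange(n) / fs
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        shape = 1.0 / np.sqrt(np.maximum(f, 1.0))
        pink = np.fft.irfft(spec * shape, n=n)
        pink /= max(pink.std(), 1e-12)
        x = pink
        for band, amp in (band_amplitudes or {}).items():
            lo, hi = _BAND_EDGES[band]
            b, a = _sig.butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
            comp = _sig.lfilter(b, a, rng.standard_normal(n))
            comp *= amp / max(comp.std(), 1e-12)
            x = x + comp
        data[ch] = x
    if seizure is not None:
        gain = np.ones(n)
        ramp = 0.5
        rise = np.clip((t - seizure.start) / ramp, 0, 1)
        fall = np.clip((seizure.end - t) / ramp, 0, 1)
        win = 0.5 * (1 - np.cos(np.pi * np.minimum(rise, fall)))
        win[(t < seizure.start) | (t >= seizure.end)] = 0.0
        gain += (seizure_gain - 1.0) * win
        data = data * gain
    return IEEGTrace(samples=data, fs=fs, t0=t0)
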