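"""Breath segmentation, central-apnea detection and per-trial respiratory metrics.

The scoring rules implemented here follow the clinical definitions used in
stimulation-mapping studies of breathing:

* a breath is one complete inspiratory-plus-expiratory cycle of the nasal
  airflow signal (inspiration plotted positive);
* central apnea is at least one missed breath together with a flattened
  airflow trace;
* breathing counts as normalized again once at least ``normal_resume_s``
  (default 20 s) of regular, apnea-free, baseline-like breathing has occurred;
* oxygen desaturation is SpO2 strictly below ``desat_threshold`` (default 90%).

The airflow trace carries arbitrary units; every threshold in this module is
relative (fractions of the baseline amplitude, period and RMS), which makes
the scoring invariant to rescaling the signal and to shifting its time origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.ndimage import uniform_filter1d

from .errors import InsufficientBaselineError, InvalidParameterError, RightCensoredWarning

__all__ = [
    "AirflowTrace",
    "SpO2Series",
    "Breath",
    "BaselineStats",
    "ApneaInterval",
    "ScoringConfig",
    "TrialMetrics",
    "detect_breaths",
    "estimate_baseline",
    "detect_apneas",
    "trial_metrics",
    "detect_desaturation",
]


@dataclass(frozen=True)
class AirflowTrace:
    """Sampled nasal-airflow signal, inspiration positive.

    Parameters
    ----------
    samples : ndarray
        Airflow in arbitrary units.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    meta : dict
        Optional generator metadata (breath schedule, model parameters);
        ignored by the scoring functions themselves.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise InvalidParameterError("sampling rate must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidParameterError("trace needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise InvalidParameterError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class SpO2Series:
    """Pulse-oximetry series in percent saturation."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.fs > 0:
            raise InvalidParameterError("sampling rate must be positive")
        if np.any(samples < 0) or np.any(samples > 100):
            raise InvalidParameterError("SpO2 must lie in [0, 100]%")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class Breath:
    """One inspiratory-plus-expiratory cycle."""

    onset: float
    peak: float
    end: float
    amplitude: float

    def __post_init__(self):
        if not (self.onset < self.peak < self.end):
            raise InvalidParameterError("breath requires onset < peak < end")
        if not self.amplitude > 0:
            raise InvalidParameterError("breath amplitude must be positive")


@dataclass(frozen=True)
class BaselineStats:
    """Baseline breathing statistics over a pre-stimulation window.

    T0 is the median inter-breath (onset-to-onset) interval in seconds,
    A0 the median inspiratory peak amplitude, rms0 the RMS airflow of the
    (mean-subtracted) baseline window.
    """

    T0: float
    A0: float
    rms0: float

    def __post_init__(self):
        if not (self.T0 > 0 and self.A0 > 0 and self.rms0 > 0):
            raise InvalidParameterError("baseline statistics must be positive")


@dataclass(frozen=True)
class ApneaInterval:
    """A detected loss-of-breathing interval, half-open [start, end)."""

    start: float
    end: float
    missed_breaths: int
    flat: bool = True

    def __post_init__(self):
        if not self.end > self.start:
            raise InvalidParameterError("apnea interval requires end > start")
        if self.missed_breaths < 1:
            raise InvalidParameterError("apnea requires at least 1 missed breath")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ScoringConfig:
    """Thresholds for breath/apnea scoring.

    gap_factor
        A gap between consecutive breath onsets longer than
        ``gap_factor * T0`` implies at least one missed breath.
    flat_fraction
        "Flattened airflow": interior RMS below this fraction of the
        baseline RMS.
    normal_resume_s
        Duration of regular apnea-free breathing required before the
        breathing pattern counts as normal again (20 s).
    min_missed
        Minimum missed breaths for an interval to qualify as apnea (1).
    desat_threshold
        SpO2 desaturation threshold in percent; strictly below flags (90).
    persistent_apnea_s
        Total apnea beyond the epoch end that defines persistent apnea (20 s).
    rate_tol, amp_tol
        Relative tolerances around the baseline period/amplitude within
        which breathing counts as "regular baseline-like".
    time_tol_s
        Numerical slack used when comparing measured durations against the
        fixed thresholds; absorbs sampling-grid quantization of breath
        onsets (well below one sample period times typical missed counts).
    """

    gap_factor: float = 1.75
    flat_fraction: float = 0.25
    normal_resume_s: float = 20.0
    min_missed: int = 1
    desat_threshold: float = 90.0
    baseline_window_s: float = 60.0
    persistent_apnea_s: float = 20.0
    apnea_coverage_frac: float = 0.9
    rate_tol: float = 0.35
    amp_tol: float = 0.35
    lowpass_hz: float = 2.0
    detrend_window_s: float = 15.0
    amplitude_floor_frac: float = 0.2
    time_tol_s: float = 0.05

    def __post_init__(self):
        if not self.gap_factor > 1:
            raise InvalidParameterError("gap_factor must exceed 1")
        if not 0 < self.flat_fraction < 1:
            raise InvalidParameterError("flat_fraction must lie in (0, 1)")
        if not self.normal_resume_s > 0:
            raise InvalidParameterError("normal_resume_s must be positive")
        if self.min_missed < 1:
            raise InvalidParameterError("min_missed must be >= 1")


@dataclass(frozen=True)
class TrialMetrics:
    """Per-trial respiratory summary relative to one stimulation/seizure epoch."""

    total_apnea_time_s: float
    disrupted_breathing_time_s: float
    normalization_time_s: float
    right_censored: bool
    epoch_coverage: float
    resumed_within_epoch: bool
    post_window_apnea_s: float


# ---------------------------------------------------------------------------
# signal conditioning


def _prep(trace: AirflowTrace, config: ScoringConfig, lowpass: bool = True) -> np.ndarray:
    """Low-pass (zero phase) and remove slow baseline wander."""
    x = trace.samples.astype(float)
    nyq = trace.fs / 2.0
    if lowpass and config.lowpass_hz < nyq * 0.9:
        b, a = _sig.butter(4, config.lowpass_hz / nyq)
        padlen = min(3 * max(len(b), len(a)), x.size - 1)
        x = _sig.filtfilt(b, a, x, padlen=padlen)
    win = int(round(config.detrend_window_s * trace.fs))
    if win >= 3 and win < x.size:
        x = x - uniform_filter1d(x, size=win, mode="nearest")
    return x


def _upcross_times(x: np.ndarray, fs: float, t0: float) -> np.ndarray:
    """Positive-going zero-crossing times, linearly interpolated."""
    prev, nxt = x[:-1], x[1:]
    idx = np.nonzero((prev <= 0) & (nxt > 0))[0]
    denom = nxt[idx] - prev[idx]
    frac = np.where(denom > 0, -prev[idx] / denom, 0.0)
    return t0 + (idx + frac) / fs


def _refine_crossings(
    coarse: np.ndarray, raw: np.ndarray, fs: float, t0: float, window_s: float = 0.35
) -> np.ndarray:
    """Snap low-passed crossing estimates to the nearest raw-signal crossing.

    The zero-phase low-pass smears sharp inspiratory onsets backward by a few
    tens of milliseconds; the nearest positive-going crossing of the raw
    (detrended) signal within a small window removes that bias.
    """
    fine = _upcross_times(raw, fs, t0)
    if fine.size == 0:
        return coarse
    out = coarse.copy()
    for i, b in enumerate(coarse):
        j = int(np.argmin(np.abs(fine - b)))
        if abs(fine[j] - b) <= window_s:
            out[i] = fine[j]
    return np.maximum.accumulate(out)


# ---------------------------------------------------------------------------
# operations


def detect_breaths(trace: AirflowTrace, config: ScoringConfig | None = None) -> list[Breath]:
    """Segment breaths from an airflow trace.

    Breaths are delimited by positive-going zero crossings of the low-passed,
    detrended signal; the inspiratory peak is the maximum between crossings.
    Candidates whose peak falls below ``amplitude_floor_frac`` of the
    75th-percentile candidate amplitude are rejected as noise ripples.
    An all-flat trace yields an empty list.
    """
    config = config or ScoringConfig()
    x = _prep(trace, config)
    crossings = _upcross_times(x, trace.fs, trace.t0)
    raw = _prep(trace, config, lowpass=False)
    crossings = _refine_crossings(crossings, raw, trace.fs, trace.t0)
    boundaries = list(crossings)
    if not boundaries:
        return []
    if x[0] > 0 and boundaries[0] > trace.t0:
        boundaries.insert(0, trace.t0)
    boundaries.append(trace.t_end)

    t = trace.times
    cand = []  # (onset, close, peak_time, amplitude)
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        i0 = int(np.searchsorted(t, b0, side="left"))
        i1 = int(np.searchsorted(t, b1, side="left"))
        if i1 - i0 < 2:
            continue
        seg = x[i0:i1]
        ipk = int(np.argmax(seg))
        amp = float(seg[ipk])
        if amp <= 0:
            continue
        cand.append((b0, b1, t[i0 + ipk], amp))
    if not cand:
        return []

    amps = np.array([c[3] for c in cand])
    floor = config.amplitude_floor_frac * float(np.percentile(amps, 75))
    kept = [c for c in cand if c[3] > floor]
    if not kept:
        return []

    onsets = np.array([c[0] for c in kept])
    t_typ = float(np.median(np.diff(onsets))) if len(kept) > 1 else kept[0][1] - kept[0][0]
    breaths = []
    for onset, close, peak, amp in kept:
        end = min(close, onset + t_typ)
        end = max(end, peak + 1.0 / trace.fs)
        breaths.append(Breath(onset=onset, peak=peak, end=end, amplitude=amp))
    return breaths


def estimate_baseline(
    trace: AirflowTrace,
    window: tuple[float, float],
    config: ScoringConfig | None = None,
    breaths: list[Breath] | None = None,
) -> BaselineStats:
    """Characterize baseline breathing over ``window`` (absolute seconds).

    Raises :class:`InsufficientBaselineError` when the window holds fewer
    than 5 breaths (e.g., when it overlaps an apnea).
    """
    config = config or ScoringConfig()
    start, end = window
    if breaths is None:
        breaths = detect_breaths(trace, config)
    inw = [b for b in breaths if start <= b.onset < end]
    if len(inw) < 5:
        raise InsufficientBaselineError(
            f"baseline window [{start:g}, {end:g}) contains {len(inw)} breaths; need >= 5"
        )
    onsets = np.array([b.onset for b in inw])
    t0 = float(np.median(np.diff(onsets)))
    a0 = float(np.median([b.amplitude for b in inw]))
    t = trace.times
    i0, i1 = np.searchsorted(t, [start, end])
    seg = trace.samples[i0:i1]
    seg = seg - seg.mean()
    rms0 = float(np.sqrt(np.mean(seg**2)))
    return BaselineStats(T0=t0, A0=a0, rms0=rms0)


def _flow_end(
    x: np.ndarray,
    t: np.ndarray,
    prev: Breath,
    limit: float,
    thr: float,
    fs: float,
) -> float:
    """Last time airflow magnitude exceeds ``thr`` in [prev.peak, limit)."""
    i0 = int(np.searchsorted(t, prev.peak))
    i1 = int(np.searchsorted(t, limit))
    seg = np.abs(x[i0:i1])
    above = np.nonzero(seg >= thr)[0]
    if above.size == 0:
        return prev.peak
    return t[i0 + above[-1]] + 1.0 / fs


def _gap_start(
    x: np.ndarray,
    t: np.ndarray,
    prev: Breath,
    next_onset: float,
    T0: float,
    thr: float,
    fs: float,
) -> float:
    """Apnea onset inside a long inter-breath gap.

    A complete preceding breath implies the apnea starts one nominal period
    after its onset (the next expected breath fails to arrive); a breath
    clipped mid-cycle implies the apnea starts where its airflow vanishes.
    """
    nominal = prev.onset + T0
    fe = _flow_end(x, t, prev, next_onset, thr, fs)
    start = fe if fe < nominal - 0.1 * T0 else nominal
    start = min(start, next_onset - 1.0 / fs)
    return max(start, prev.peak)


def detect_apneas(
    breaths: list[Breath],
    baseline: BaselineStats,
    trace: AirflowTrace,
    config: ScoringConfig | None = None,
) -> list[ApneaInterval]:
    """Detect central apneas as long, flat inter-breath gaps.

    Every onset-to-onset gap exceeding ``gap_factor * T0`` whose interior RMS
    airflow falls below ``flat_fraction * rms0`` becomes one interval, with
    ``missed_breaths = round(gap / T0) - 1``. Gaps at the trace edges are
    treated the same way against the trace boundaries. Intervals with fewer
    than ``min_missed`` missed breaths, or whose interior is not flat, are
    discarded. The result is sorted and disjoint.
    """
    config = config or ScoringConfig()
    x = _prep(trace, config)
    t = trace.times
    T0 = baseline.T0
    k = config.gap_factor
    thr_rms = config.flat_fraction * baseline.rms0

    def interior_rms(s: float, e: float) -> float:
        i0, i1 = np.searchsorted(t, [s, e])
        if i1 - i0 < 1:
            return 0.0
        seg = x[i0:i1]
        return float(np.sqrt(np.mean(seg**2)))

    raw: list[tuple[float, float, int]] = []
    if not breaths:
        dur = trace.duration
        if dur > k * T0:
            raw.append((trace.t0, trace.t_end, int(round(dur / T0))))
    else:
        first, last = breaths[0], breaths[-1]
        lead = first.onset - trace.t0
        if lead > k * T0:
            raw.append((trace.t0, first.onset, int(round(lead / T0))))
        for prev, nxt in zip(breaths[:-1], breaths[1:]):
            gap = nxt.onset - prev.onset
            if gap > k * T0:
                start = _gap_start(x, t, prev, nxt.onset, T0, thr_rms, trace.fs)
                raw.append((start, nxt.onset, int(round(gap / T0)) - 1))
        tail = trace.t_end - last.onset
        if tail > k * T0:
            start = _gap_start(x, t, last, trace.t_end, T0, thr_rms, trace.fs)
            raw.append((start, trace.t_end, int(round(tail / T0)) - 1))

    out = []
    for start, end, missed in raw:
        missed = max(missed, 1)
        flat = interior_rms(start, end) < thr_rms
        if flat and missed >= config.min_missed:
            out.append(ApneaInterval(start=start, end=end, missed_breaths=missed, flat=True))
    return out


def _overlap(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _window_qualifies(
    s: float,
    breaths: list[Breath],
    apneas: list[ApneaInterval],
    baseline: BaselineStats,
    config: ScoringConfig,
) -> bool:
    """True if [s, s + normal_resume_s) is regular, apnea-free breathing."""
    w = config.normal_resume_s
    e = s + w
    tol = config.time_tol_s
    for a in apneas:
        if _overlap(a.start, a.end, s, e) > tol:
            return False
    inw = [b for b in breaths if s - tol <= b.onset < e]
    if not inw:
        return False
    onsets = np.array([b.onset for b in inw])
    T0, A0 = baseline.T0, baseline.A0
    spans_start = any(b.onset < s <= b.end for b in breaths)
    if not spans_start and onsets[0] - s > config.gap_factor * T0:
        return False
    if e - onsets[-1] > config.gap_factor * T0:
        return False
    if onsets.size > 1:
        diffs = np.diff(onsets)
        if np.any(np.abs(diffs - T0) > config.rate_tol * T0 + tol):
            return False
    amps = np.array([b.amplitude for b in inw])
    if np.any(np.abs(amps - A0) > config.amp_tol * A0):
        return False
    return True


def trial_metrics(
    apneas: list[ApneaInterval],
    stim,
    breaths: list[Breath],
    baseline: BaselineStats,
    config: ScoringConfig | None = None,
    t_end: float | None = None,
) -> TrialMetrics:
    """Total apnea time and disrupted-breathing time for one epoch.

    ``total_apnea_time_s`` sums apnea durations from the epoch onset until
    breathing normalizes; ``disrupted_breathing_time_s`` runs from the epoch
    onset until the start of the first window of at least ``normal_resume_s``
    seconds of regular, apnea-free, baseline-like breathing. When the trace
    ends before such a window occurs the metrics are right-censored (flagged,
    computed on the available data).
    """
    config = config or ScoringConfig()
    if t_end is None:
        cand_ends = [b.end for b in breaths] + [a.end for a in apneas]
        t_end = max(cand_ends) if cand_ends else stim.end
    tol = config.time_tol_s

    relevant = [a for a in apneas if a.end > stim.start + tol]
    epoch_dur = stim.end - stim.start
    coverage = (
        sum(_overlap(a.start, a.end, stim.start, stim.end) for a in relevant) / epoch_dur
        if epoch_dur > 0
        else 0.0
    )
    if not relevant:
        return TrialMetrics(0.0, 0.0, stim.start, False, coverage, False, 0.0)

    # did normal breathing resume before the epoch ended?
    in_epoch = [a for a in relevant if a.start < stim.end]
    last_in = max((min(a.end, stim.end) for a in in_epoch), default=stim.start)
    resumed = False
    if stim.end - last_in > baseline.T0 * (1 - config.rate_tol):
        gap_breaths = [
            b
            for b in breaths
            if last_in - tol <= b.onset < stim.end
            and abs(b.amplitude - baseline.A0) <= config.amp_tol * baseline.A0
        ]
        clear = all(_overlap(a.start, a.end, last_in + tol, stim.end) <= tol for a in relevant)
        resumed = bool(gap_breaths) and clear

    # normalization: first qualifying regular window at/after the epoch onset
    candidates = sorted(b.onset for b in breaths if b.onset >= stim.start - baseline.T0)
    t_norm = None
    for s in candidates:
        if s + config.normal_resume_s > t_end + tol:
            break
        if _window_qualifies(s, breaths, relevant, baseline, config):
            t_norm = max(s, stim.start)
            break
    censored = t_norm is None
    if censored:
        t_norm = t_end
        warnings.warn(
            "trace ended before breathing normalized; metrics right-censored",
            RightCensoredWarning,
            stacklevel=2,
        )

    total = sum(_overlap(a.start, a.end, stim.start, t_norm) for a in relevant)
    disrupted = max(0.0, t_norm - stim.start)
    post = sum(_overlap(a.start, a.end, stim.end, max(stim.end, t_norm)) for a in relevant)
    return TrialMetrics(
        total_apnea_time_s=float(total),
        disrupted_breathing_time_s=float(disrupted),
        normalization_time_s=float(t_norm),
        right_censored=censored,
        epoch_coverage=float(coverage),
        resumed_within_epoch=resumed,
        post_window_apnea_s=float(post),
    )


def detect_desaturation(
    spo2: SpO2Series, config: ScoringConfig | None = None
) -> list[tuple[float, float]]:
    """Maximal runs of SpO2 samples strictly below the desaturation threshold."""
    config = config or ScoringConfig()
    below = spo2.samples < config.desat_threshold
    if not below.any():
        return []
    d = np.diff(below.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(below.size)
    t = spo2.times
    out = []
    for i0, i1 in zip(starts, ends):
        end = t[i1] if i1 < t.size else spo2.t0 + i1 / spo2.fs
        out.append((float(t[i0]), float(end)))
    return out
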