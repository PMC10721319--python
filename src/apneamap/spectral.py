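"""Canonical-band iEEG power, band envelopes, and group-level statistics.

Tests whether apnea periods differ from baseline breathing in canonical-band
power (delta 1-4, theta 4-8, alpha 8-12, beta 13-30, low gamma 30-80, high
gamma 80-150 Hz) and whether band-amplitude envelopes track the respiratory
trace. Power is estimated by Welch's method (1 s windows, 50% overlap) and
compared on a log10 scale; envelopes are the magnitude of the analytic signal
of the zero-phase band-filtered trace. Group inference uses Wilcoxon's
signed-rank test per band (exact null distribution for n <= 25) with
Benjamini-Hochberg FDR correction across the six bands at alpha = 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError, OutOfRangeError

__all__ = [
    "BandDefinition",
    "BANDS",
    "TimeSeries",
    "band_power",
    "band_powers",
    "band_envelope",
    "envelope_resp_correlation",
    "group_test",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float


BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("low_gamma", 30.0, 80.0),
    BandDefinition("high_gamma", 80.0, 150.0),
)
BAND_NAMES = tuple(b.name for b in BANDS)


def _get_band(band) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    for b in BANDS:
        if b.name == band:
            return b
    raise InvalidParameterError(f"unknown band {band!r}")


@dataclass(frozen=True)
class TimeSeries:
    """A plain uniformly sampled series (used for envelopes)."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(np.asarray(self.samples).shape[-1]) / self.fs


def _epoch_slice(trace, epoch) -> np.ndarray:
    x = np.atleast_2d(trace.samples)
    if epoch is None:
        return x
    t = trace.t0 + np.arange(x.shape[1]) / trace.fs
    i0, i1 = np.searchsorted(t, [epoch[0], epoch[1]])
    return x[:, i0:i1]


def band_power(trace, epoch, band) -> float:
    """Average spectral power in ``band`` over ``epoch`` (Welch, 1 s, 50%).

    ``trace`` is any object with ``samples``/``fs``/``t0``; multichannel
    input is averaged across channels. ``epoch`` is a (start, end) pair in
    seconds or None for the full trace. The value is the integral of the
    Welch PSD over the band (signal-variance units).
    """
    b = _get_band(band)
    if trace.fs < 2 * b.high:
        raise InvalidParameterError(f"fs {trace.fs} too low for band {b.name} (<{2 * b.high})")
    x = _epoch_slice(trace, epoch)
    if x.shape[1] < 2 * trace.fs:
        raise OutOfRangeError("epoch must be at least 2 s long")
    nperseg = int(trace.fs)
    f, pxx = _sig.welch(x, fs=trace.fs, nperseg=nperseg, noverlap=nperseg // 2, axis=-1)
    pxx = pxx.mean(axis=0)
    mask = (f >= b.low) & (f <= b.high)
    return float(np.trapezoid(pxx[mask], f[mask]))


def band_powers(trace, epoch=None) -> dict:
    """Band -> integrated power for all six canonical bands."""
    return {b.name: band_power(trace, epoch, b) for b in BANDS}


def band_envelope(trace, band) -> TimeSeries:
    """Amplitude envelope: |analytic signal| of the zero-phase band-passed trace."""
    b = _get_band(band)
    if trace.fs < 2 * b.high:
        raise InvalidParameterError(f"fs {trace.fs} too low for band {b.name}")
    x = np.atleast_2d(trace.samples).mean(axis=0)
    sos = _sig.butter(4, [b.low, b.high], btype="band", fs=trace.fs, output="sos")
    filt = _sig.sosfiltfilt(sos, x)
    env = np.abs(_sig.hilbert(filt))
    return TimeSeries(samples=env, fs=trace.fs, t0=trace.t0)


def envelope_resp_correlation(envelope: TimeSeries, resp) -> float:
    """Pearson correlation between a band envelope and the respiratory trace.

    The respiratory signal is resampled (linear interpolation) onto the
    envelope's time base over their common support, which must span at
    least 10 s.
    """
    t_env = envelope.times
    t_resp = resp.t0 + np.arange(np.asarray(resp.samples).shape[-1]) / resp.fs
    lo = max(t_env[0], t_resp[0])
    hi = min(t_env[-1], t_resp[-1])
    if hi - lo < 10.0:
        raise OutOfRangeError("need at least 10 s of overlap")
    mask = (t_env >= lo) & (t_env <= hi)
    resp_i = np.interp(t_env[mask], t_resp, np.asarray(resp.samples, dtype=float))
    env = np.asarray(envelope.samples)[mask]
    r = np.corrcoef(env, resp_i)[0, 1]
    return float(r)


def _signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank p, exact for n <= 25 without ties."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = _stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not ties:
        stat, p = _stats.wilcoxon(d, alternative="two-sided", method="exact")
    else:
        stat, p = _stats.wilcoxon(d, alternative="two-sided", method="approx")
    return w_plus, float(p)


def group_test(values, alpha: float = 0.01, method: str = "signed_rank") -> pd.DataFrame:
    """Per-band group test against zero with BH-FDR across bands.

    ``values`` maps band name -> per-patient differences (signed_rank), or
    band name -> (before, after) sample pair (rank_sum). Requires n >= 3 per
    band. All-zero differences yield p = 1 by convention (with a warning).
    Returns a DataFrame with statistic, raw p, BH-adjusted p and a
    significance flag at ``alpha``.
    """
    if method not in ("signed_rank", "rank_sum"):
        raise InvalidParameterError("method must be 'signed_rank' or 'rank_sum'")
    rows = []
    for name, vals in values.items():
        if method == "rank_sum":
            before, after = vals
            if min(len(before), len(after)) < 3:
                raise InvalidParameterError("need n >= 3 per group")
            stat, p = _stats.ranksums(np.asarray(after), np.asarray(before))
        else:
            d = np.asarray(vals, dtype=float)
            if d.size < 3:
                raise InvalidParameterError("need n >= 3 patients")
            if np.all(d == 0):
                warnings.warn(f"band {name}: all differences zero; p = 1", stacklevel=2)
                stat, p = 0.0, 1.0
            else:
                stat, p = _signed_rank_exact_p(d)
        rows.append({"band": name, "statistic": float(stat), "p_raw": float(p)})
    df = pd.DataFrame(rows).set_index("band")
    reject, p_adj, _, _ = multipletests(df["p_raw"].to_numpy(), alpha=alpha, method="fdr_bh")
    df["p_fdr"] = np.maximum(p_adj, df["p_raw"])  # adjusted p never below raw
    df["significant"] = df["p_fdr"] < alpha
    df.attrs["alpha"] = alpha
    df.attrs["method"] = method
    return df
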