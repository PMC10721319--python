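"""Ventilatory summary channels and hypoventilation-despite-hypercapnia detection.

Works on ventilator-derived channels: respiratory rate (RR, breaths/min),
tidal volume (TV, mL), minute ventilation (VE = RR * TV / 1000, L/min) and
end-tidal CO2 (etCO2, mmHg). Hypoventilation is flagged where TV and VE sit
below their pre-stimulation baselines while etCO2 sits above its baseline —
i.e., reduced breathing that persists despite an elevated CO2 drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, OutOfRangeError

__all__ = [
    "VentilationSeries",
    "HypoventilationInterval",
    "compute_ve",
    "window_stats",
    "detect_hypoventilation",
]


@dataclass(frozen=True)
class VentilationSeries:
    """Time-indexed RR / TV / VE / etCO2 channels on a common time base."""

    time: np.ndarray
    rr: np.ndarray
    tv_ml: np.ndarray
    ve_lpm: np.ndarray
    etco2_mmhg: np.ndarray

    def __post_init__(self):
        arrays = {}
        n = None
        for name in ("time", "rr", "tv_ml", "ve_lpm", "etco2_mmhg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = arr
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise InvalidParameterError("all channels must share one time base")
            object.__setattr__(self, name, arr)
        for name in ("rr", "tv_ml", "ve_lpm", "etco2_mmhg"):
            if np.any(arrays[name] < -1e-9):
                raise InvalidParameterError(f"channel {name} must be non-negative")
        active = (arrays["rr"] > 0) & (arrays["tv_ml"] > 0) & (arrays["ve_lpm"] > 0)
        if active.any():
            implied = arrays["rr"][active] * arrays["tv_ml"][active] / 1000.0
            rel = np.abs(arrays["ve_lpm"][active] - implied) / implied
            if np.max(rel) > 0.01:
                raise InvalidParameterError("VE inconsistent with RR*TV/1000 beyond 1%")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class HypoventilationInterval:
    """Interval of reduced ventilation despite elevated etCO2."""

    start: float
    end: float
    mean_tv_deficit_pct: float
    mean_etco2_excess_mmhg: float

    def __post_init__(self):
        if not self.end > self.start:
            raise InvalidParameterError("interval requires end > start")


def compute_ve(rr, tv_ml):
    """Minute ventilation VE [L/min] = RR [breaths/min] * TV [mL] / 1000."""
    rr = np.asarray(rr, dtype=float)
    tv = np.asarray(tv_ml, dtype=float)
    if np.any(rr < 0) or np.any(tv < 0):
        raise InvalidParameterError("RR and TV must be non-negative")
    out = rr * tv / 1000.0
    return float(out) if out.ndim == 0 else out


def window_stats(series: VentilationSeries, window: tuple[float, float]) -> dict:
    """Per-channel means over ``window`` (absolute seconds, half-open)."""
    start, end = window
    if not end > start:
        raise OutOfRangeError("window must have positive length")
    if start < series.time[0] - 1e-9 or end > series.time[-1] + 1.0 / series.fs + 1e-9:
        raise OutOfRangeError("window outside series extent")
    mask = (series.time >= start) & (series.time < end)
    if not mask.any():
        raise OutOfRangeError("window contains no samples")
    return {
        "rr": float(series.rr[mask].mean()),
        "tv_ml": float(series.tv_ml[mask].mean()),
        "ve_lpm": float(series.ve_lpm[mask].mean()),
        "etco2_mmhg": float(series.etco2_mmhg[mask].mean()),
    }


def detect_hypoventilation(
    series: VentilationSeries,
    baseline_means: dict,
    min_duration_s: float = 10.0,
    require_breathing: bool = True,
) -> list[HypoventilationInterval]:
    """Maximal intervals with TV and VE below baseline AND etCO2 above it.

    Both conditions are required (low ventilation alone, or hypercapnia
    alone, does not qualify). With ``require_breathing`` (default) samples
    with VE = 0 — apnea, which is scored separately from airflow — never
    count as hypoventilation, keeping the two states disjoint.
    """
    low = (series.tv_ml < baseline_means["tv_ml"]) & (series.ve_lpm < baseline_means["ve_lpm"])
    high_co2 = series.etco2_mmhg > baseline_means["etco2_mmhg"]
    mask = low & high_co2
    if require_breathing:
        mask &= series.ve_lpm > 0
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    dt = 1.0 / series.fs
    out = []
    for i0, i1 in zip(starts, ends):
        t_start = float(series.time[i0])
        t_end = float(series.time[i1 - 1]) + dt
        if t_end - t_start < min_duration_s:
            continue
        tv_def = 100.0 * (1.0 - series.tv_ml[i0:i1].mean() / baseline_means["tv_ml"])
        co2_exc = float(series.etco2_mmhg[i0:i1].mean() - baseline_means["etco2_mmhg"])
        out.append(
            HypoventilationInterval(
                start=t_start,
                end=t_end,
                mean_tv_deficit_pct=float(tv_def),
                mean_etco2_excess_mmhg=co2_exc,
            )
        )
    return out
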