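"""On-disk formats: time-series tables, events JSON, sites TSV, run config.

Conventions (printed into every file header where the format allows): time is
in seconds, intervals are half-open [start, end), coordinates are millimeters
in RAS orientation. Tabular outputs are TSV; events and configuration are
JSON/YAML; probability volumes are NIfTI-1; EDF is read-only (via ``mne``
when installed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import OutcomeLabel, SiteOutcome, StimEpoch
from .errors import FormatError
from .mapping import SiteRecord
from .scoring import AirflowTrace, SpO2Series
from .ventilation import VentilationSeries

__all__ = [
    "EVENTS_SCHEMA_VERSION",
    "RunConfig",
    "read_timeseries",
    "write_timeseries",
    "read_events",
    "write_events",
    "read_sites",
    "write_sites",
    "load_config",
    "dump_config",
]

EVENTS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# time series


def write_timeseries(path, channels: dict, fs: float, t0: float = 0.0) -> None:
    """Write named channels sampled at ``fs`` as a TSV with a time column."""
    n = len(next(iter(channels.values())))
    t = t0 + np.arange(n) / fs
    df = pd.DataFrame({"t": t, **{k: np.asarray(v) for k, v in channels.items()}})
    with open(path, "w") as fh:
        fh.write("# apneamap time series; t in seconds; uniform rate %.9g Hz\n" % fs)
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


def read_timeseries(path) -> tuple[pd.DataFrame, float]:
    """Read a delimited time-series table (or EDF) into uniform channels.

    Returns ``(frame, fs)`` where the frame has a ``t`` column in seconds.
    Non-uniform sampling is resampled onto a uniform grid with a warning;
    non-monotone time or a missing time column raises :class:`FormatError`.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse delimited table: {exc}") from exc
    if "t" not in df.columns:
        raise FormatError(f"{path}: missing time column 't'")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise FormatError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    if df["t"].isna().any() or df.isna().any().any():
        raise FormatError(f"{path}: missing values in table")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    dt = np.diff(t)
    fs = 1.0 / float(np.median(dt))
    if np.max(np.abs(dt - dt[0])) > 1e-6 * dt[0]:
        warnings.warn(f"{path}: non-uniform sampling; resampling to {fs:g} Hz", stacklevel=2)
        tu = np.arange(t[0], t[-1], 1.0 / fs)
        df = pd.DataFrame(
            {"t": tu, **{c: np.interp(tu, t, df[c].to_numpy(float)) for c in df.columns if c != "t"}}
        )
    return df, fs


def _read_edf(path) -> tuple[pd.DataFrame, float]:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError("EDF support requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()
    t = raw.times
    df = pd.DataFrame({"t": t, **{name: data[i] for i, name in enumerate(raw.ch_names)}})
    return df, fs


def airflow_from_frame(df: pd.DataFrame, fs: float, column: str = "airflow") -> AirflowTrace:
    return AirflowTrace(samples=df[column].to_numpy(float), fs=fs, t0=float(df["t"].iloc[0]))


def spo2_from_frame(df: pd.DataFrame, fs: float, column: str = "spo2") -> SpO2Series:
    return SpO2Series(samples=df[column].to_numpy(float), fs=fs, t0=float(df["t"].iloc[0]))


def ventilation_from_frame(df: pd.DataFrame) -> VentilationSeries:
    cols = ("t", "rr", "tv_ml", "ve_lpm", "etco2_mmhg")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"ventilation table missing columns {missing}")
    return VentilationSeries(
        time=df["t"].to_numpy(float),
        rr=df["rr"].to_numpy(float),
        tv_ml=df["tv_ml"].to_numpy(float),
        ve_lpm=df["ve_lpm"].to_numpy(float),
        etco2_mmhg=df["etco2_mmhg"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# events JSON


def write_events(path, epochs: list[StimEpoch], traces: dict | None = None) -> None:
    doc = {
        "version": EVENTS_SCHEMA_VERSION,
        "units": {"time": "seconds", "intervals": "half-open [start, end)"},
        "traces": traces or {},
        "events": [
            {
                "start": e.start,
                "end": e.end,
                "kind": e.kind,
                "site_id": e.site_id,
                "voltage": e.voltage,
                "frequency": e.frequency,
                "pulse_width_us": e.pulse_width_us,
            }
            for e in epochs
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_events(path) -> list[StimEpoch]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    if doc.get("version") != EVENTS_SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported events schema version {doc.get('version')!r}")
    out = []
    for ev in doc.get("events", []):
        try:
            out.append(
                StimEpoch(
                    start=float(ev["start"]),
                    end=float(ev["end"]),
                    kind=ev.get("kind", "stimulation"),
                    site_id=ev.get("site_id"),
                    voltage=ev.get("voltage"),
                    frequency=ev.get("frequency", 50.0),
                    pulse_width_us=ev.get("pulse_width_us", 200.0),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed event record {ev!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# sites TSV

_SITE_COLUMNS = [
    "site_id",
    "patient_id",
    "x_mm",
    "y_mm",
    "z_mm",
    "hemisphere",
    "region",
    "label",
    "n_trials",
    "n_no_apnea",
    "n_transient_apnea",
    "n_apnea",
    "n_persistent_apnea",
]


def write_sites(path, sites: list[SiteRecord]) -> None:
    rows = []
    for s in sites:
        x, y, z = s.coordinate
        c = s.outcome.counts or {}
        rows.append(
            {
                "site_id": s.site_id,
                "patient_id": s.patient_id,
                "x_mm": x,
                "y_mm": y,
                "z_mm": z,
                "hemisphere": s.hemisphere,
                "region": s.region_label,
                "label": OutcomeLabel(s.outcome.label).value,
                "n_trials": s.outcome.n_trials,
                "n_no_apnea": c.get("no_apnea", 0),
                "n_transient_apnea": c.get("transient_apnea", 0),
                "n_apnea": c.get("apnea", 0),
                "n_persistent_apnea": c.get("persistent_apnea", 0),
            }
        )
    with open(path, "w") as fh:
        fh.write("# apneamap sites; coordinates in mm, RAS common space\n")
        pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_sites(path) -> list[SiteRecord]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse sites TSV: {exc}") from exc
    missing = [c for c in _SITE_COLUMNS[:9] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sites TSV missing columns {missing}")
    sites = []
    for _, row in df.iterrows():
        counts = {
            lbl.value: int(row.get(f"n_{lbl.value}", 0) or 0) for lbl in OutcomeLabel
        }
        outcome = SiteOutcome(
            site_id=row["site_id"],
            label=OutcomeLabel(row["label"]),
            n_trials=int(row["n_trials"]),
            counts=counts,
        )
        sites.append(
            SiteRecord(
                patient_id=str(row["patient_id"]),
                site_id=str(row["site_id"]),
                coordinate=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                hemisphere=str(row["hemisphere"]),
                region_label=str(row["region"]),
                outcome=outcome,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run; unknown keys are rejected."""

    seed: int = 0
    output_dir: str = "."
    scoring: dict = field(default_factory=dict)
    classification: dict = field(default_factory=dict)
    mapping: dict = field(default_factory=dict)
    ieeg: dict = field(default_factory=dict)
    ventilation: dict = field(default_factory=dict)
    synthesis: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))
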