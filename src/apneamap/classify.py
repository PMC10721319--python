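"""Respiratory outcome classification of stimulation/seizure trials and sites.

Each trial is assigned one of four outcome classes:

* ``persistent_apnea`` — central apnea totaling at least 20 s beyond the end
  of stimulation or seizure (counted until breathing normalizes);
* ``apnea`` — breathing interrupted for (essentially) the entire epoch, with
  no normal resumption before the epoch ends;
* ``transient_apnea`` — apnea occurred but normal baseline breathing resumed
  before the epoch ended;
* ``no_apnea`` — no qualifying apnea.

Persistent apnea takes precedence over all other labels. A stimulated site is
labelled by the outcome of the majority of its trials; ties are broken toward
the more prolonged (more severe) respiratory effect.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .errors import InvalidParameterError, OutOfRangeError
from .scoring import ApneaInterval, ScoringConfig, TrialMetrics

__all__ = [
    "OutcomeLabel",
    "SEVERITY_ORDER",
    "StimEpoch",
    "TrialOutcome",
    "SiteOutcome",
    "classify_trial",
    "aggregate_site",
    "summarize_cohort",
]


class OutcomeLabel(str, Enum):
    NO_APNEA = "no_apnea"
    TRANSIENT_APNEA = "transient_apnea"
    APNEA = "apnea"
    PERSISTENT_APNEA = "persistent_apnea"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: least to most prolonged respiratory effect
SEVERITY_ORDER = (
    OutcomeLabel.NO_APNEA,
    OutcomeLabel.TRANSIENT_APNEA,
    OutcomeLabel.APNEA,
    OutcomeLabel.PERSISTENT_APNEA,
)


def severity(label: OutcomeLabel) -> int:
    return SEVERITY_ORDER.index(OutcomeLabel(label))


@dataclass(frozen=True)
class StimEpoch:
    """One stimulation and/or stimulation-induced seizure epoch, [start, end).

    For ``stimulation_plus_seizure`` the epoch end is the later of stimulation
    end and electrographic seizure termination (the postictal accounting
    convention); seizure boundaries come from the events file, never from
    automated iEEG analysis.
    """

    start: float
    end: float
    kind: str = "stimulation"
    site_id: str | None = None
    voltage: float | None = None
    frequency: float = 50.0
    pulse_width_us: float = 200.0

    _KINDS = ("stimulation", "seizure", "stimulation_plus_seizure")

    def __post_init__(self):
        if not self.end > self.start:
            raise InvalidParameterError("epoch requires end > start")
        if self.kind not in self._KINDS:
            raise InvalidParameterError(f"unknown epoch kind {self.kind!r}")
        if self.voltage is not None and not 2.5 <= self.voltage <= 15.0:
            raise InvalidParameterError("stimulation voltage must lie in [2.5, 15] V")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TrialOutcome:
    """Categorical outcome plus summary metrics for one trial."""

    label: OutcomeLabel
    total_apnea_time_s: float = 0.0
    disrupted_breathing_time_s: float = 0.0
    post_window_apnea_s: float = 0.0
    right_censored: bool = False


@dataclass(frozen=True)
class SiteOutcome:
    """Aggregated outcome of all trials at one stimulated contact pair."""

    site_id: str | None
    label: OutcomeLabel
    n_trials: int
    counts: dict = field(default_factory=dict)


def classify_trial(
    apneas: list[ApneaInterval],
    epoch: StimEpoch,
    metrics: TrialMetrics,
    config: ScoringConfig | None = None,
) -> TrialOutcome:
    """Assign the four-way respiratory outcome for one trial.

    ``persistent_apnea`` if apnea beyond the epoch end (up to breathing
    normalization) totals at least ``persistent_apnea_s``; otherwise
    ``apnea`` if apnea covers at least ``apnea_coverage_frac`` of the epoch
    with no normal resumption inside it; otherwise ``transient_apnea`` if
    apnea occurred but breathing resumed before the epoch end; otherwise
    ``no_apnea``. Threshold comparisons carry the ``time_tol_s`` slack to
    absorb sampling quantization of detected breath boundaries.
    """
    config = config or ScoringConfig()
    tol = config.time_tol_s
    if epoch.end <= epoch.start:
        raise OutOfRangeError("degenerate epoch")
    del apneas  # summaries arrive via metrics; kept in the signature for symmetry

    post = metrics.post_window_apnea_s
    if post >= config.persistent_apnea_s - tol:
        label = OutcomeLabel.PERSISTENT_APNEA
    elif (
        metrics.epoch_coverage >= config.apnea_coverage_frac - tol / max(epoch.duration, tol)
        and not metrics.resumed_within_epoch
    ):
        label = OutcomeLabel.APNEA
    elif metrics.epoch_coverage > 0 and metrics.resumed_within_epoch:
        label = OutcomeLabel.TRANSIENT_APNEA
    else:
        label = OutcomeLabel.NO_APNEA
    return TrialOutcome(
        label=label,
        total_apnea_time_s=metrics.total_apnea_time_s,
        disrupted_breathing_time_s=metrics.disrupted_breathing_time_s,
        post_window_apnea_s=post,
        right_censored=metrics.right_censored,
    )


def aggregate_site(trials: list[TrialOutcome], site_id: str | None = None) -> SiteOutcome:
    """Label a site by the modal trial outcome, ties toward the more severe.

    E.g., one ``apnea`` trial plus one ``transient_apnea`` trial yields
    ``apnea``; a three-way tie including ``persistent_apnea`` yields
    ``persistent_apnea``.
    """
    if not trials:
        raise InvalidParameterError("cannot aggregate an empty trial list")
    counts = Counter(OutcomeLabel(t.label) for t in trials)
    best = max(counts, key=lambda lbl: (counts[lbl], severity(lbl)))
    full = {lbl.value: counts.get(lbl, 0) for lbl in SEVERITY_ORDER}
    return SiteOutcome(site_id=site_id, label=best, n_trials=len(trials), counts=full)


def summarize_cohort(sites: list[SiteOutcome]) -> tuple[dict, pd.DataFrame]:
    """Per-label site counts plus a per-site table."""
    counts = {lbl.value: 0 for lbl in SEVERITY_ORDER}
    rows = []
    for s in sites:
        counts[OutcomeLabel(s.label).value] += 1
        rows.append(
            {
                "site_id": s.site_id,
                "label": OutcomeLabel(s.label).value,
                "n_trials": s.n_trials,
                **{f"n_{k}": v for k, v in (s.counts or {}).items()},
            }
        )
    counts["total_sites"] = len(sites)
    return counts, pd.DataFrame(rows)
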