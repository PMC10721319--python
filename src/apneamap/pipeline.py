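"""Convenience chains over the scoring and classification stages."""

from __future__ import annotations

from dataclasses import dataclass

from .classify import StimEpoch, TrialOutcome, classify_trial
from .scoring import (
    AirflowTrace,
    ApneaInterval,
    BaselineStats,
    Breath,
    ScoringConfig,
    TrialMetrics,
    detect_apneas,
    detect_breaths,
    estimate_baseline,
    trial_metrics,
)

__all__ = ["ScoredTrial", "score_trial"]


@dataclass(frozen=True)
class ScoredTrial:
    breaths: list
    baseline: BaselineStats
    apneas: list
    metrics: TrialMetrics
    outcome: TrialOutcome


def score_trial(
    trace: AirflowTrace,
    epoch: StimEpoch,
    config: ScoringConfig | None = None,
    baseline_window: tuple[float, float] | None = None,
) -> ScoredTrial:
    """Breaths -> baseline -> apneas -> metrics -> outcome for one trial.

    The baseline window defaults to the ``baseline_window_s`` seconds
    immediately preceding the epoch onset.
    """
    config = config or ScoringConfig()
    if baseline_window is None:
        baseline_window = (max(trace.t0, epoch.start - config.baseline_window_s), epoch.start)
    breaths = detect_breaths(trace, config)
    baseline = estimate_baseline(trace, baseline_window, config, breaths=breaths)
    apneas = detect_apneas(breaths, baseline, trace, config)
    metrics = trial_metrics(apneas, epoch, breaths, baseline, config, t_end=trace.t_end)
    outcome = classify_trial(apneas, epoch, metrics, config)
    return ScoredTrial(
        breaths=breaths, baseline=baseline, apneas=apneas, metrics=metrics, outcome=outcome
    )
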