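"""Classify several trials at one site and aggregate the site outcome.

The site label is the modal trial outcome; ties break toward the more
prolonged respiratory effect (e.g. apnea beats transient apnea 1:1).
"""

import numpy as np

import apneamap as am

epoch = am.StimEpoch(start=60.0, end=90.0)
rng = np.random.default_rng(0)

trials = []
for i, label in enumerate(["apnea", "apnea", "transient_apnea", "no_apnea"]):
    scenario = am.random_scenario(label, epoch.duration, rng)
    trace = am.gen_airflow(am.BreathModelParams(seed=i), 240.0)
    trace, _ = am.apply_outcome(trace, epoch, scenario)
    outcome = am.score_trial(trace, epoch).outcome
    trials.append(outcome)
    print(f"trial {i}: declared={label:16s} classified={outcome.label.value}")

site = am.aggregate_site(trials, site_id="R2-R3")
print(f"\nsite R2-R3 -> {site.label.value}  (trial counts: {site.counts})")
# 2/4 trials gave apnea for the whole stimulation: the site is an apnea site.
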