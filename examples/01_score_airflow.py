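"""Score a stimulation trial: breaths, central apneas, summary metrics.

Generates 4 s-period breathing with a 30 s stimulation fully covered by
apnea plus 25 s of post-stimulation apnea, then runs the scoring chain.
"""

import apneamap as am

params = am.BreathModelParams(seed=0)  # 4 s period, 5% noise
epoch = am.StimEpoch(start=60.0, end=90.0, voltage=10.0)
scenario = am.OutcomeScenario(
    "persistent_apnea",
    within_stim_apnea=((0.0, 30.0),),
    post_stim_apnea=((0.0, 25.0),),
)

trace = am.gen_airflow(params, 220.0)
trace, ground_truth = am.apply_outcome(trace, epoch, scenario)
scored = am.score_trial(trace, epoch)

print(f"breaths detected : {len(scored.breaths)}")
print(f"baseline period  : {scored.baseline.T0:.2f} s")
for a in scored.apneas:
    print(f"apnea            : [{a.start:7.2f}, {a.end:7.2f}) s,"
          f" {a.missed_breaths} missed breath(s)")
print(f"total apnea time : {scored.metrics.total_apnea_time_s:.1f} s")
print(f"disrupted time   : {scored.metrics.disrupted_breathing_time_s:.1f} s")
print(f"post-epoch apnea : {scored.metrics.post_window_apnea_s:.1f} s")
print(f"trial outcome    : {scored.outcome.label.value}")
# The 55 s gap (30 s stimulation + 25 s beyond it) is one detected apnea;
# >= 20 s of apnea past the epoch end makes the trial persistent apnea.
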