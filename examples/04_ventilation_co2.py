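"""Hypoventilation despite hypercapnia from ventilator channels.

Tidal volume is halved for five minutes while the one-compartment CO2 store
responds; detection requires BOTH reduced TV/VE and elevated etCO2 relative
to the pre-stimulation baseline.
"""

import numpy as np

import apneamap as am

co2 = am.CO2Params(baseline_etco2=30.0, production_rate=0.6,
                   clearance_coeff=0.01, floor=20.0)
onsets = np.arange(0.0, 1000.0, 5.0)  # RR 12/min throughout


def tidal_volume(t):
    return 250.0 if 300.0 <= t < 600.0 else 500.0  # mL


series = am.gen_ventilator(onsets, tidal_volume, co2, duration_s=900.0)
baseline = am.window_stats(series, (100.0, 290.0))
print("baseline:", {k: round(v, 1) for k, v in baseline.items()})
print(f"steady-state etCO2 at VE=6 L/min: {co2.steady_state(6.0):.1f} mmHg,"
      f" at VE=3: {co2.steady_state(3.0):.1f} mmHg")

for h in am.detect_hypoventilation(series, baseline):
    print(f"hypoventilation [{h.start:.0f}, {h.end:.0f}) s: "
          f"TV deficit {h.mean_tv_deficit_pct:.0f}%, "
          f"etCO2 excess +{h.mean_etco2_excess_mmhg:.1f} mmHg")
# One interval covering the low-TV segment: ventilation stays low even as
# CO2 climbs above baseline - the reduced-chemosensitivity signature.
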