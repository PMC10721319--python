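"""Map respiratory outcome probabilities over electrode coordinates.

A synthetic cohort has a focal persistent-apnea (pAIR-like) cluster nested
inside a broader apnea (AIR-like) cluster in the right medial amygdala;
left-sided sites are mirrored before fitting. The fitted map should place
the persistent-apnea peak at the generating center.
"""

import warnings

import numpy as np

import apneamap as am

spec = am.CohortSpec(n_patients=20, sites_per_patient=4, seed=0)
sites = am.gen_cohort(spec)
config = am.MappingConfig(grid_spacing_mm=2.0)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = am.fit_outcome_classifier(sites, config)
    pmap = am.predict_probability_map(model, config)

peak = pmap.peak_coordinate("persistent_apnea")
err = np.linalg.norm(peak - np.asarray(spec.pair_center_pAIR))
vol = pmap.volume("persistent_apnea")
print(f"sites fitted               : {len(sites)}")
print(f"generating pAIR center     : {spec.pair_center_pAIR} mm")
print(f"persistent-apnea peak voxel: {np.round(peak, 1).tolist()} mm "
      f"(error {err:.1f} mm)")
print(f"peak probability           : {vol.max():.2f} "
      f"(volume median {np.median(vol):.3f})")

import os

os.makedirs("scratch", exist_ok=True)
paths = am.export_map(pmap, os.path.join("scratch", "pmap"))
print("wrote:", ", ".join(paths))
# The peak sits a few mm from the generating center; the high peak
# probability against a near-zero volume median marks a focal site.
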