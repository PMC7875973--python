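"""Generate a synthetic cohort with planted rest-task structure.

Every subject shares a set of latent spatial networks; each subject
expresses small deviations of those networks in BOTH their resting
series and their task contrast maps.  Association-like vertices carry
predictable inter-subject variance (SNR ratio 1.0), primary-sensory
vertices are stereotyped (SNR 0.1) — so the per-vertex ceiling of
predictive R^2 is known exactly: s^2 / (s^2 + 1).
"""

import numpy as np

import restpred as rp

cfg = rp.SimConfig(n_subjects=20, seed=0)
cohort = rp.simulate_cohort(cfg)
gt = cohort.ground_truth

print(f"subjects:        {len(cohort.subject_ids)}")
print(f"grayordinates:   {cohort.geometry.n_total} ({cohort.geometry.n_cortex} cortical)")
scan = cohort.rest_scans[cohort.subject_ids[0]]
print(f"rest series:     {scan.t} frames in runs {scan.run_boundaries}")
print(f"contrasts:       {', '.join(cohort.contrasts)}")

ceiling = gt.r2_ceiling()
assoc = gt.snr_profile >= 0.9
print(f"\nplanted R^2 ceiling, association vertices: {ceiling[assoc].mean():.3f}")
print(f"planted R^2 ceiling, sensory vertices:     {ceiling[~assoc].mean():.3f}")
print("(the ceiling is the variance fraction any model could explain at a vertex)")

y = cohort.task_matrix("MATH-STORY", cohort.subject_ids)
print(f"\nempirical task-map variance across subjects: "
      f"association {y.var(axis=0, ddof=1)[assoc].mean():.2f}, "
      f"sensory {y.var(axis=0, ddof=1)[~assoc].mean():.2f}")
print("(association variance ~2 = signal 1 + noise 1; sensory ~1 = noise only)")
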