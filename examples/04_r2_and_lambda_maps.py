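"""Where is prediction possible?  Per-vertex R^2 and lambda maps.

Predictive R^2 (test-mean denominator, negative allowed) resolves the
whole-cortex score spatially, and the per-vertex GCV penalty lambda is
its mirror image: the fit shrinks hardest exactly where rest features
carry no usable signal.
"""

import numpy as np
from scipy import stats

import restpred as rp

cohort = rp.simulate_cohort(rp.SimConfig(n_subjects=80, seed=3))
split = rp.make_split(cohort.subject_ids, 40, 40, seed=0)
res = rp.evaluate_models(cohort, ["mmp-rr"], "MATH-STORY", split, seed=0)["mmp-rr"]

gt = cohort.ground_truth
assoc = gt.snr_profile >= 0.9
r2 = res.r2map.r2
print(f"median R^2, association vertices: {np.nanmedian(r2[assoc]):+.3f}")
print(f"median R^2, sensory vertices:     {np.nanmedian(r2[~assoc]):+.3f}")
print(f"median log10 lambda, association: {np.median(np.log10(res.lambdas[assoc])):.2f}")
print(f"median log10 lambda, sensory:     {np.median(np.log10(res.lambdas[~assoc])):.2f}")

ok = res.r2map.mask & (res.lambdas > 0)
rho = stats.spearmanr(np.log(res.lambdas[ok]), r2[ok]).statistic
print(f"\nSpearman(log lambda, R^2) = {rho:.3f}")
print("strongly negative: regularization strength is a usable map of "
      "where prediction fails (negative R^2 = worse than the test mean).")
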