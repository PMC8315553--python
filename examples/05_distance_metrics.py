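"""The three descriptive distance metrics between brain states.

Computes, for pairs of synthetic states, (i) the connectivity correlation
distance (fraction of regions whose FC-change profile relative to
wakefulness does not correlate between the states), (ii) the
classification distance 1 - AUC of a random-forest transfer classifier,
and (iii) the model parameter distance between generating regional
bifurcation parameters. Nearby states on the synthetic depth gradient
should be close under all three metrics.
"""

import numpy as np

from hopfbrain import (
    RandomForestConfig,
    classification_distance,
    connectivity_correlation_distance,
    fc_pipeline,
    model_parameter_distance,
)
from hopfbrain.synthetic import default_ground_truth, make_multistate_cohort

gt = default_ground_truth(seed=1)
cohorts = make_multistate_cohort(gt)
fcs = {n: fc_pipeline(ds.subjects) for n, ds in cohorts.items()}

pairs = [("N2", "N3"), ("N1", "N3")]
rf = RandomForestConfig(n_estimators=200)
print(f"{'pair':>10}  {'corr dist':>9}  {'class dist':>10}  {'model dist':>10}")
for s1, s2 in pairs:
    d_corr, *_ = connectivity_correlation_distance(
        fcs[s1], fcs["W"], fcs[s2], fcs["W"]
    )
    rep = classification_distance(cohorts[s1], cohorts[s2], rf_config=rf,
                                  n_permutations=0, seed=0, n_repeats=3)
    d_model = model_parameter_distance(gt.a_for(s1), gt.a_for(s2))
    print(f"{s1 + '-' + s2:>10}  {d_corr:9.3f}  {rep.distance:10.3f}  {d_model:10.3f}")

print("\nthe model parameter distance resolves the depth ordering "
      "(N2-N3 adjacent, hence closer than N1-N3); at this desk scale the "
      "two data-driven metrics saturate near their floors because every "
      "state separates almost perfectly from wakefulness. the "
      "classification distance is 1 - transfer AUC.")
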