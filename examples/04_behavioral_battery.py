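"""The double dissociation: attention-causal vs post-decisional gaze.

Runs the two diagnostic regressions on data simulated from each model:

- MELFB interaction: does the last-fixation bias grow with the overall
  value sum_r?  (predicted by multiplicative attention, not by PDG)
- Consistency regression: is the chosen item's dwell advantage larger
  when the choice contradicts the ratings?  (same dissociation)

plus the post-report gaze test, which only the PDG model passes.
"""

import numpy as np

from gazeflux.analyses import (
    dwell_consistency_regression,
    melfb_interaction,
    post_report_gaze_test,
)
from gazeflux.data_model import derive_features
from gazeflux.simulators import AddmParams, ModelSpec, PdgParams
from gazeflux.synthetic import DwellModel, StudyDesign, generate_dataset

dwell = DwellModel()
for name, spec, design in [
    ("aDDM", ModelSpec("addm_mult", AddmParams()), StudyDesign(n_reps=4)),
    ("PDG", ModelSpec("pdg", PdgParams()), StudyDesign()),
]:
    ts = generate_dataset(spec, design, dwell, np.random.default_rng(7))
    f = derive_features(ts)
    inter = melfb_interaction(f).extra
    cons = dwell_consistency_regression(f).extra
    _, post = post_report_gaze_test(ts)
    print(f"\n{name} ({len(ts)} trials)")
    print(f"  MELFB interaction slope = {inter['interaction_slope']:+.4f}, "
          f"p = {inter['interaction_p']:.2e}")
    print(f"  consistency beta_c      = {cons['beta_c']:+.4f}, one-tailed "
          f"p = {cons['p_one_tailed']:.2e}")
    print(f"  post- vs pre-report gaze on chosen: Wilcoxon "
          f"p = {post['pvalue']:.2e}")

print("\nReading: the aDDM shows a positive MELFB slope and beta_c < 0; "
      "the PDG shows neither,\nbut uniquely predicts the post-report rise "
      "in gaze to the chosen item.")
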