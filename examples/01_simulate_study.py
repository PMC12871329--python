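"""Simulate synthetic food-choice studies under two gaze models.

Generates a study with the canonical design (39 participants x 100
trials, non-negative integer ratings 0-10, |delta_r| <= 5, log-normal
dwells, first fixation left with p = 0.74) under (a) the multiplicative
attentional drift-diffusion model with its published parameters and
(b) the post-decision-gaze model, then prints basic behavior.
"""

import numpy as np

from gazeflux import derive_features, save_trials
from gazeflux.simulators import AddmParams, ModelSpec, PdgParams
from gazeflux.synthetic import DwellModel, StudyDesign, generate_dataset

design = StudyDesign()          # 39 x 100, |delta_r| <= 5
dwell = DwellModel()            # log-normal dwells, p_first_left = 0.74

for name, spec in [
    ("aDDM (multiplicative, published parameters)",
     ModelSpec("addm_mult", AddmParams())),
    ("PDG (post-decision gaze)", ModelSpec("pdg", PdgParams())),
]:
    ts = generate_dataset(spec, design, dwell, np.random.default_rng(1))
    f = derive_features(ts)
    print(f"\n{name}: {len(ts)} trials")
    print(f"  P(choose higher-rated item) = {f.consistent.mean():.3f}")
    print(f"  mean RT                     = {f.rt.mean():.2f} s")
    print(f"  P(last fixation = choice)   = "
          f"{(f.last_fixated == f.choice).mean():.3f}")
    # save_trials(ts, f"{spec.variant}_study.csv")  # CSV round-trips losslessly

print("\nBoth models produce accurate, value-guided choices with a "
      "last-fixation bias;\nthey differ in *why* gaze and choice are "
      "linked, which the analysis battery exposes.")
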