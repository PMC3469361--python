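"""Effect statistics and micro-step choice probabilities.

An actor evaluates candidate network states through a linear objective
f_i = sum_k beta_k s_ik(x, z, v); choices follow a multinomial logit over
the candidate states.  This example evaluates a few statistics by hand and
shows how a density parameter of ln 2 doubles the odds of each tie.
"""

import numpy as np
import pandas as pd

from sabm import CenteringConstants, EffectSpec, ModelSpec, network_effect_statistic
from sabm.simulator import SimState, network_choice_probabilities

# three actors: 0 -> 1, 1 -> 0, 1 -> 2
x = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 0]])
z = np.array([1, 3, 6])  # alcohol levels: abstainer .. more than weekly
cov = pd.DataFrame(index=pd.Index(["a", "b", "c"], name="actor_id"))
cen = CenteringConstants(behavior_mean=float(z.mean()))

recip = network_effect_statistic(EffectSpec("reciprocity", "network"), 1, x, z, cov, cen)
sim = network_effect_statistic(
    EffectSpec("similarity", "network", "alcohol"), 1, x, z, cov, cen
)
print(f"actor b reciprocity statistic: {recip:.0f}   (one mutual dyad with a)")
print(f"actor b alcohol-similarity statistic: {sim:.2f}")

model = ModelSpec([EffectSpec("density", "network", parameter=np.log(2))], [])
p = network_choice_probabilities(0, SimState(np.zeros((3, 3), int), z), model, cen, cov)
print(f"choice probabilities for an isolated actor: {np.round(p, 3)}")
# slot 0 is "change nothing"; each tie creation is worth ln 2 of utility,
# so creating is exactly twice as likely as standing pat: (0.2, 0.4, 0.4).
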