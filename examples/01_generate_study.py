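"""Generate a synthetic multi-school friendship/alcohol panel study.

Builds the default 13-school study (about 2,500 students) whose descriptive
statistics mirror a saturated-school adolescent survey: sparse directed
friendship nominations (mean ~2 per student), half the students abstaining
from alcohol, moderate between-wave tie stability, and ~10% wave-2
attrition that falls hardest on weekly-plus drinkers.
"""

import numpy as np

from sabm import SyntheticConfig, attrition_summary, generate_study, jaccard_counts, jaccard_index

study = generate_study(SyntheticConfig(seed=20120806))

out_deg = np.concatenate([p.wave1.sum(axis=1) for p in study.panels])
js = [jaccard_index(jaccard_counts(p)) for p in study.panels]
att = attrition_summary(study.panels)

print(f"schools: {len(study.panels)}, students: {out_deg.size}")
print(f"mean wave-1 nominations per student: {out_deg.mean():.3f}")
print(f"between-wave Jaccard stability: {min(js):.3f} .. {max(js):.3f}")
print(f"wave-2 retention: {att.retention_pct}%")
print(f"config hash: {study.manifest['config_hash']}")

# The nomination mean sits near the survey's 2.04, every school's Jaccard
# clears the 0.20 stability screen, and retention lands near the survey's
# 89.6% with heavier drinkers over-represented among the lost.
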