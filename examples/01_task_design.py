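"""Generate a flexible-rule session and inspect its counterbalancing.

Prints the per-condition trial counts, the category split of the sample
set under both rules, and the expected trial duration over the ITI set.
"""

import numpy as np

from flexwm import task_design as td

design = td.generate_design(experiment=1, seed=0)
print("trials per condition:")
print(design.groupby("rule").size().rename({"n/a": "maintenance"}))

grid = design.attrs["orientation_set"]
for rule in (td.RULE_A, td.RULE_B):
    labels = td.category_labels(grid.values, rule)
    arc1 = np.sort(grid.values[labels == 1])
    print(
        f"rule {rule.name} ({rule.boundary1:g}/{rule.boundary2:g} deg): "
        f"category 1 spans {arc1[0]:g}-{arc1[-1]:g} deg ({len(arc1)} orientations)"
    )

durations = [float(td.trial_timeline(iti=i)["duration"].sum()) for i in (3, 5, 7)]
print(f"trial durations over the ITI set: {durations}, mean {np.mean(durations):g} s")
# Equal counts per condition, 15/15 category splits and a 20 s expected
# trial length reproduce the printed design of the scanner session.
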