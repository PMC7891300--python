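"""qPCR comparative-Ct and dual-luciferase post-processing.

Relative expression RQ = 2^-ddCt against a reference gene and a calibrator
group; luciferase activity = firefly/Renilla scaled to the control mean;
group differences by Welch's t-test with star annotation.
"""

import pandas as pd

from cerna.validation import (delta_delta_ct, luciferase_relative_activity,
                              two_group_test)

qpcr = pd.DataFrame({
    "sample_id": ["c1", "c2", "c3", "t1", "t2", "t3"],
    "group": ["control"] * 3 + ["overexpression"] * 3,
    "ct_target": [24.1, 23.9, 24.0, 22.2, 22.0, 21.9],
    "ct_reference": [15.0, 15.1, 14.9, 15.0, 15.2, 14.9],
})
rq = delta_delta_ct(qpcr, calibrator_group="control")
print(rq[["sample_id", "group", "delta_delta_ct", "rq"]].round(3).to_string(index=False))
p, star = two_group_test(rq.loc[rq.group == "control", "rq"],
                         rq.loc[rq.group != "control", "rq"])
print(f"Welch test control vs overexpression: p = {p:.4g} ({star})")
# RQ ~ 4 means the target is ~4-fold more abundant than in the calibrator.

luc = pd.DataFrame({
    "well_id": [f"w{i}" for i in range(6)],
    "group": ["control"] * 3 + ["miR"] * 3,
    "firefly": [410.0, 395.0, 402.0, 205.0, 198.0, 212.0],
    "renilla": [101.0, 99.0, 100.0, 100.0, 98.0, 102.0],
})
act = luciferase_relative_activity(luc, control_group="control")
print(act[["well_id", "group", "relative_activity"]].round(3).to_string(index=False))
p, star = two_group_test(act.loc[act.group == "control", "relative_activity"],
                         act.loc[act.group == "miR", "relative_activity"])
print(f"Welch test: p = {p:.4g} ({star})")
# Relative activity ~ 0.5 in the miR wells: the miRNA represses the reporter
# carrying the target site, evidence of direct binding.
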