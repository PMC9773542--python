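"""Simulate a two-group treatment cohort and run the comparison policy.

Emulates a hypertrophy experiment: a control group and a treated group whose
week-3 wall thickness is programmed 35 % higher. Each organoid's videos are
segmented and phenotyped, thickness is normalized to week 0 per organoid,
and the groups are compared with the small-sample policy (Mann-Whitney U).
"""

import pandas as pd

from ccopheno import (
    CohortSpec,
    EffectMultipliers,
    OrganoidSimParams,
    make_cohort,
    segment_stack,
)
from ccopheno.contraction import summarize_contraction, weekly_normalize
from ccopheno.stats import compare_two_groups

spec = CohortSpec(
    groups={
        "control": {0: EffectMultipliers(), 3: EffectMultipliers()},
        "edn1_100": {0: EffectMultipliers(),
                     3: EffectMultipliers(wall_thickness=1.35, beat_rate=1.5)},
    },
    n_per_group=4,
    base_params=OrganoidSimParams(duration=15.0),
    seed=21,
)
records, manifest = make_cohort(spec)

rows = []
for rec in records:
    summary = summarize_contraction(segment_stack(rec["stack"]))
    rows.append(dict(group=rec["group"], organoid=rec["organoid"],
                     week=rec["week"], wall_thickness=summary.diastolic_thickness,
                     frequency_bpm=summary.contraction_frequency))
table = weekly_normalize(pd.DataFrame(rows))
week3 = table[table.week == 3]

for metric in ("wall_thickness_fold", "frequency_bpm"):
    ctl = week3.loc[week3.group == "control", metric]
    trt = week3.loc[week3.group == "edn1_100", metric]
    res = compare_two_groups(ctl, trt, metric=metric, labels=("control", "edn1_100"))
    print(f"{metric:20s} control {ctl.mean():6.2f}  treated {trt.mean():6.2f}  "
          f"{res.test} p={res.p_value:.4f} {res.stars}")
# The treated group's week-3 thickness fold change recovers the programmed
# 1.35x effect and its beat rate the programmed 1.5x speed-up; with n=4 per
# group the policy routes to the exact Mann-Whitney U test.
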